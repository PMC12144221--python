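"""Aggregation over the dose x reconstruction x repetition grid.

Takes per-scan, per-lesion detection records (with the matched label's
size and intensity) and produces the study-level summary: per-cell
detection counts, per-lesion rates, triage true-positive/false-negative
fractions, per-cell label summaries, and coefficient-of-variation (CV)
reproducibility.

The CV follows a restriction rule: only cells (dose x reconstruction) in
which *every* repetition produced a matched label contribute — a cell
with a missing repeat says nothing about repeat-to-repeat reproducibility
of the measurement. Two poolings are reported: the default computes a CV
within each qualifying dose (across its repeats) and averages those over
doses, isolating repeat variability from dose-driven trends; the pooled
mode computes one CV over all contributing values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import StudyDesign
from .errors import CompletenessError, ValidationError

MEASURES = ("size", "intensity")
POOLINGS = ("per_dose_mean", "pooled")

#: detections-table column holding each measure
MEASURE_COLUMNS = {"size": "size_mm2", "intensity": "intensity"}


def _check_complete(detections: pd.DataFrame, design: StudyDesign, lesion_ids) -> None:
    expected = {
        (c.scan_id, lid) for c in design.scans() for lid in lesion_ids
    }
    present = set(zip(detections["scan_id"], detections["lesion_id"]))
    missing = sorted(expected - present)
    if missing:
        raise CompletenessError(
            f"detection records missing for {len(missing)} scan/lesion pairs "
            f"(first: {missing[:5]})",
            missing=missing,
        )


def detection_table(detections: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    """Matched-label counts per lesion x dose x reconstruction.

    Each count lies in [0, repetitions]. Raises CompletenessError listing
    absent scan ids when records do not cover the full design.
    """
    lesion_ids = sorted(detections["lesion_id"].unique())
    _check_complete(detections, design, lesion_ids)
    tab = (
        detections.groupby(["lesion_id", "dose_mGy", "reconstruction"], as_index=False)
        .agg(n_matched=("matched", "sum"), n_repetitions=("matched", "size"))
    )
    tab["n_matched"] = tab["n_matched"].astype(int)
    return tab.sort_values(["lesion_id", "reconstruction", "dose_mGy"]).reset_index(
        drop=True
    )


def detection_rate(count: int, n_total: int) -> float:
    """Percentage of scans with a matched label: 100 * count / n_total."""
    if n_total <= 0:
        raise ValidationError("n_total must be > 0")
    if not 0 <= count <= n_total:
        raise ValidationError("count must be in [0, n_total]")
    return 100.0 * count / n_total


def triage_summary(triage: pd.DataFrame) -> tuple[float, float]:
    """(true-positive %, false-negative %) of scan-level triage decisions.

    The phantom is lesion-positive by construction, so a positive heatmap
    is a scan-level true positive and a negative summary report a false
    negative.
    """
    n = len(triage)
    if n == 0:
        raise ValidationError("no triage results")
    n_pos = int((triage["decision"] == "positive").sum())
    return 100.0 * n_pos / n, 100.0 * (n - n_pos) / n


def _qualifying_cells(detections: pd.DataFrame, repetitions: int) -> pd.DataFrame:
    """Rows from cells where all repetitions produced a matched label."""
    g = detections.groupby(["lesion_id", "reconstruction", "dose_mGy"])
    full = g["matched"].transform(lambda s: s.sum() == repetitions and len(s) == repetitions)
    return detections[full & detections["matched"]]


def reproducibility_cv(
    detections: pd.DataFrame,
    design: StudyDesign,
    measure: str = "size",
    pooling: str = "per_dose_mean",
    ddof: int = 1,
) -> pd.DataFrame:
    """CV (sample SD / mean) of a label measure per lesion x reconstruction.

    Only cells with a matched label in every repetition contribute.
    ``per_dose_mean`` averages within-dose CVs over qualifying doses;
    ``pooled`` computes one CV over all contributing values. Lesion x
    reconstruction pairs with no qualifying cell are flagged
    ``computable = False`` (CV is NaN, never zero).
    """
    if measure not in MEASURES:
        raise ValidationError(f"measure must be one of {MEASURES}")
    if pooling not in POOLINGS:
        raise ValidationError(f"pooling must be one of {POOLINGS}")
    col = MEASURE_COLUMNS[measure]
    qual = _qualifying_cells(detections, design.repetitions)

    rows = []
    lesion_ids = sorted(detections["lesion_id"].unique())
    for lid in lesion_ids:
        for recon in design.reconstructions:
            sub = qual[(qual["lesion_id"] == lid) & (qual["reconstruction"] == recon)]
            n_doses = sub["dose_mGy"].nunique()
            if n_doses == 0:
                rows.append(
                    {
                        "lesion_id": lid, "reconstruction": recon,
                        "measure": measure, "pooling": pooling,
                        "cv": np.nan, "n_qualifying_doses": 0,
                        "computable": False,
                    }
                )
                continue
            if pooling == "per_dose_mean":
                per_dose = sub.groupby("dose_mGy")[col].agg(
                    lambda v: np.std(v, ddof=ddof) / np.mean(v)
                )
                cv = float(per_dose.mean())
            else:
                vals = sub[col].to_numpy(dtype=float)
                cv = float(np.std(vals, ddof=ddof) / np.mean(vals))
            rows.append(
                {
                    "lesion_id": lid, "reconstruction": recon,
                    "measure": measure, "pooling": pooling,
                    "cv": cv, "n_qualifying_doses": int(n_doses),
                    "computable": True,
                }
            )
    return pd.DataFrame(rows)


def label_summary(detections: pd.DataFrame) -> pd.DataFrame:
    """Per-cell mean size and intensity over matched repeats.

    Cells with zero matched repeats yield NaN means (absent, not zero);
    the repeat-level values stay available in the detections table.
    """
    g = detections.groupby(["lesion_id", "reconstruction", "dose_mGy"])

    def _cell(sub: pd.DataFrame) -> pd.Series:
        m = sub[sub["matched"]]
        return pd.Series(
            {
                "n_matched": int(sub["matched"].sum()),
                "mean_size_mm2": m["size_mm2"].mean() if len(m) else np.nan,
                "mean_intensity": m["intensity"].mean() if len(m) else np.nan,
            }
        )

    out = g.apply(_cell, include_groups=False).reset_index()
    out["n_matched"] = out["n_matched"].astype(int)
    return out.sort_values(["lesion_id", "reconstruction", "dose_mGy"]).reset_index(
        drop=True
    )


def build_report(
    detections: pd.DataFrame,
    triage: pd.DataFrame,
    design: StudyDesign,
) -> dict:
    """Assemble the study-level consistency report as a plain dict."""
    tab = detection_table(detections, design)
    n_scans = design.n_scans
    per_lesion = {}
    for lid, sub in tab.groupby("lesion_id"):
        total = int(sub["n_matched"].sum())
        per_recon = {
            recon: int(s["n_matched"].sum())
            for recon, s in sub.groupby("reconstruction")
        }
        per_lesion[lid] = {
            "labels": total,
            "rate_pct": round(detection_rate(total, n_scans), 1),
            "rate_pct_full": detection_rate(total, n_scans),
            "labels_by_reconstruction": per_recon,
        }
    tp, fn = triage_summary(triage)
    cvs = []
    for measure in MEASURES:
        for pooling in POOLINGS:
            cvs.append(
                reproducibility_cv(detections, design, measure, pooling)
            )
    cv_records = pd.concat(cvs, ignore_index=True)
    cv_records["cv_rounded"] = cv_records["cv"].round(2)
    return {
        "n_scans": n_scans,
        "total_labels": int(tab["n_matched"].sum()),
        "per_lesion": per_lesion,
        "triage": {
            "true_positive_pct": round(tp, 1),
            "false_negative_pct": round(fn, 1),
            "true_positive_pct_full": tp,
            "false_negative_pct_full": fn,
        },
        "reproducibility_cv": cv_records.to_dict(orient="records"),
    }
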