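"""Reader visual-grading analysis: visibility and image-quality ratings.

Five (by default) neuroradiologist readers rate, for every scan and
lesion, whether the lesion is visible (yes/no; source tables may encode
this 1 = yes, 2 = no) and the image quality for assessing it on an
ordinal 1-3 scale (3 = good, 2 = intermediate, 1 = poor).

Before aggregation, quality ratings of 1 are recoded to 0 when the reader
also rated the lesion as not visible — "poor but visible" and "not
assessable" are different outcomes. Quality is then averaged in two
stages: within reader across the repeated acquisitions of each dose x
reconstruction cell, then across readers; the error bar is the standard
error of the mean across readers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import StudyDesign
from .errors import CompletenessError, ValidationError

VALID_QUALITY = (1, 2, 3)

_YES = {"yes", "y", "1", "true", 1, True}
_NO = {"no", "n", "2", "false", 2, False}


def normalize_visible(value) -> bool:
    """Map the accepted visibility encodings (yes/no, 1/2, bool) to bool."""
    v = value.strip().lower() if isinstance(value, str) else value
    if v in _YES:
        return True
    if v in _NO:
        return False
    raise ValidationError(f"unrecognized visibility value {value!r}")


def recode_quality(visible, quality_raw: int) -> int:
    """Recode a raw quality rating for aggregation.

    Returns 0 iff quality_raw is 1 (poor) and the lesion was rated not
    visible; all other ratings pass through unchanged.
    """
    q = int(quality_raw)
    if q not in VALID_QUALITY:
        raise ValidationError(f"quality_raw must be in {VALID_QUALITY}, got {quality_raw}")
    vis = normalize_visible(visible)
    if q == 1 and not vis:
        return 0
    return q


def validate_responses(responses: pd.DataFrame) -> pd.DataFrame:
    """Normalize a raw response table in place-free fashion.

    Expects columns reader_id, scan_id, lesion_id, visible, quality_raw
    (or quality); returns a copy with boolean ``visible`` and integer
    ``quality_raw``/``quality`` (recoded) columns.
    """
    df = responses.copy()
    if "quality_raw" not in df.columns and "quality" in df.columns:
        df = df.rename(columns={"quality": "quality_raw"})
    required = {"reader_id", "scan_id", "lesion_id", "visible", "quality_raw"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"response table missing columns: {sorted(missing)}")
    df["visible"] = df["visible"].map(normalize_visible)
    df["quality"] = [
        recode_quality(v, q) for v, q in zip(df["visible"], df["quality_raw"])
    ]
    return df


def visibility_rate(
    responses: pd.DataFrame, lesion_id: str
) -> tuple[int, int, float]:
    """(positive count, total, percent visible) for one lesion."""
    sub = responses[responses["lesion_id"] == lesion_id]
    if len(sub) == 0:
        raise ValidationError(f"no responses for lesion {lesion_id!r}")
    vis = sub["visible"]
    if vis.dtype != bool:
        vis = vis.map(normalize_visible)
    pos = int(vis.sum())
    total = int(len(sub))
    return pos, total, 100.0 * pos / total


def aggregate_quality(
    responses: pd.DataFrame, design: StudyDesign
) -> pd.DataFrame:
    """Two-stage mean quality per lesion x dose x reconstruction.

    Stage 1 averages each reader's recoded ratings across the cell's
    repetitions; stage 2 averages those per-reader means across readers
    and attaches their standard error (SD / sqrt(n_readers)). Raises
    CompletenessError listing the gaps when any reader x scan x lesion
    response is absent.
    """
    df = validate_responses(responses)
    readers = sorted(df["reader_id"].unique())
    lesion_ids = sorted(df["lesion_id"].unique())
    expected = {
        (r, c.scan_id, lid)
        for r in readers
        for c in design.scans()
        for lid in lesion_ids
    }
    present = set(zip(df["reader_id"], df["scan_id"], df["lesion_id"]))
    gaps = sorted(expected - present)
    if gaps:
        raise CompletenessError(
            f"{len(gaps)} missing reader responses (first: {gaps[:5]})",
            missing=gaps,
        )

    meta = {c.scan_id: (c.dose_mGy, c.reconstruction) for c in design.scans()}
    df["dose_mGy"] = df["scan_id"].map(lambda s: meta[s][0])
    df["reconstruction"] = df["scan_id"].map(lambda s: meta[s][1])

    per_reader = (
        df.groupby(["lesion_id", "reconstruction", "dose_mGy", "reader_id"],
                   as_index=False)["quality"].mean()
        .rename(columns={"quality": "reader_mean"})
    )
    out = (
        per_reader.groupby(["lesion_id", "reconstruction", "dose_mGy"], as_index=False)
        .agg(
            mean_quality=("reader_mean", "mean"),
            sem_quality=("reader_mean", lambda v: np.std(v, ddof=1) / np.sqrt(len(v))),
            n_readers=("reader_mean", "size"),
        )
    )
    out["n_readers"] = out["n_readers"].astype(int)
    return out.sort_values(["lesion_id", "reconstruction", "dose_mGy"]).reset_index(
        drop=True
    )
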