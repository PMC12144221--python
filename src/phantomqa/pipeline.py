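"""End-to-end pipeline: simulate/load -> quantify -> match -> aggregate.

Scans are processed as a stream — each heatmap stack is quantified and
matched as soon as it is produced and its pixels are then released — so
the full 126-scan reference design runs in a small memory footprint.
Every stage's output is persisted as a tidy CSV (plus a JSON report), all
tagged with seed and config hash, and the whole run is deterministic:
identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .consistency import build_report, detection_table, label_summary
from .design import LesionSpec, StudyDesign, default_lesions, make_default_design
from .errors import ConfigurationError
from .io import (
    config_hash,
    read_heatmap_series,
    scan_directory,
    write_csv,
    write_json,
    write_manifest,
    write_png_stack,
)
from .matching import match_labels, triage_decision
from .quantify import (
    DEFAULT_BLUE_THRESHOLD,
    extract_components,
    measure_components,
    segment_label_mask,
)
from .readers import aggregate_quality, validate_responses, visibility_rate
from .simulate import (
    DetectionModelParams,
    ReaderParams,
    default_detection_params,
    default_reader_params,
    iter_simulated_scans,
    simulate_readers,
)
from .stats import cell_means, compare_family, comparisons_frame

log = logging.getLogger("phantomqa")


@dataclass
class PipelineConfig:
    """Everything one run needs; every field has a sensible default."""

    seed: int = 0
    simulate: bool = True
    design: StudyDesign = field(default_factory=make_default_design)
    lesions: list[LesionSpec] | None = None
    detection_params: DetectionModelParams = field(
        default_factory=default_detection_params
    )
    reader_params: ReaderParams = field(default_factory=default_reader_params)
    blue_threshold: int = DEFAULT_BLUE_THRESHOLD
    connectivity: str = "volume26"
    luma: str = "bt601"
    tolerance_mm: float = 10.0
    write_images: bool = False
    input_root: Path | None = None  # when simulate=False: study tree root
    reader_responses: Path | None = None  # optional CSV instead of simulation

    def resolved_lesions(self) -> list[LesionSpec]:
        return self.lesions or default_lesions(self.design.geometry)

    def hash_source(self) -> dict:
        return {
            "seed": self.seed,
            "simulate": self.simulate,
            "design": self.design.to_dict(),
            "lesions": [
                (l.lesion_id, tuple(l.centroid), l.max_diameter_mm)
                for l in self.resolved_lesions()
            ],
            "blue_threshold": self.blue_threshold,
            "connectivity": self.connectivity,
            "luma": self.luma,
            "tolerance_mm": self.tolerance_mm,
        }


def _iter_input_scans(config: PipelineConfig):
    """Yield (condition, series, truth_rows=None) from a study tree."""
    root = Path(config.input_root)
    g = config.design.geometry
    for cond in config.design.scans():
        directory = scan_directory(root, cond)
        series = read_heatmap_series(
            directory,
            dialect="png-stack",
            pixel_size_mm=g.pixel_size_mm,
            slice_thickness_mm=g.slice_thickness_mm,
            acquisition=cond,
        )
        yield cond, series, None


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage and persist all tables under ``outdir``.

    Returns the consistency report dict (also written as report.json).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = config.design
    lesions = config.resolved_lesions()
    cfg_hash = config_hash(config.hash_source())
    log.info("pipeline start: %d scans, config %s", design.n_scans, cfg_hash)

    if config.simulate:
        source = iter_simulated_scans(
            design, lesions, config.detection_params, config.seed, render=True
        )
    elif config.input_root is not None:
        source = _iter_input_scans(config)
    else:
        raise ConfigurationError("simulate=False requires input_root")

    truth_rows: list[dict] = []
    component_frames: list[pd.DataFrame] = []
    detection_rows: list[dict] = []
    triage_rows: list[dict] = []
    manifest_scans: list[dict] = []

    for cond, series, scan_truth in source:
        if scan_truth:
            truth_rows.extend(scan_truth)
        mask = segment_label_mask(series, config.blue_threshold)
        comps = extract_components(mask, config.connectivity)
        comp_df = measure_components(series, comps, config.luma)
        if len(comp_df):
            component_frames.append(comp_df)
        records, unmatched = match_labels(
            comps, lesions, design.geometry, config.tolerance_mm, cond.scan_id
        )
        if unmatched:
            log.warning(
                "scan %s: %d unmatched label component(s) (candidate false "
                "positives)", cond.scan_id, len(unmatched),
            )
        triage = triage_decision(comps, unmatched, cond.scan_id)
        triage_rows.append(
            {
                "scan_id": cond.scan_id,
                "dose_mGy": cond.dose_mGy,
                "reconstruction": cond.reconstruction,
                "repetition": cond.repetition,
                "decision": triage.decision,
                "n_components": triage.n_components,
                "n_unmatched": len(unmatched),
            }
        )
        by_id = comp_df.set_index("component_id") if len(comp_df) else None
        for rec in records:
            row = {
                "scan_id": cond.scan_id,
                "dose_mGy": cond.dose_mGy,
                "reconstruction": cond.reconstruction,
                "repetition": cond.repetition,
                "lesion_id": rec.lesion_id,
                "matched": rec.matched,
                "component_id": rec.matched_component,
                "offset_mm": rec.centroid_offset_mm,
                "size_mm2": None,
                "size_linear": None,
                "intensity": None,
            }
            if rec.matched and by_id is not None:
                c = by_id.loc[rec.matched_component]
                row.update(
                    size_mm2=float(c["size_mm2"]),
                    size_linear=float(c["size_linear"]),
                    intensity=float(c["intensity"]),
                )
            detection_rows.append(row)

        if config.write_images and config.simulate:
            directory = scan_directory(outdir / "heatmaps", cond)
            write_png_stack(series, directory)
            manifest_scans.append(
                {
                    "scan_id": cond.scan_id,
                    "dose_mGy": cond.dose_mGy,
                    "reconstruction": cond.reconstruction,
                    "repetition": cond.repetition,
                    "path": str(directory.relative_to(outdir)),
                }
            )
        else:
            manifest_scans.append(
                {
                    "scan_id": cond.scan_id,
                    "dose_mGy": cond.dose_mGy,
                    "reconstruction": cond.reconstruction,
                    "repetition": cond.repetition,
                }
            )

    detections = pd.DataFrame(detection_rows)
    triage = pd.DataFrame(triage_rows)
    components = (
        pd.concat(component_frames, ignore_index=True)
        if component_frames
        else pd.DataFrame()
    )

    write_manifest(
        outdir / "manifest.json", design, manifest_scans, config.seed, cfg_hash
    )
    if truth_rows:
        write_csv(outdir / "truth.csv", pd.DataFrame(truth_rows))
    write_csv(outdir / "components.csv", components)
    write_csv(outdir / "detections.csv", detections)
    write_csv(outdir / "triage.csv", triage)
    write_csv(outdir / "detection_table.csv", detection_table(detections, design))
    write_csv(outdir / "label_summary.csv", label_summary(detections))

    # statistical comparisons on per-cell means of the AI measures
    comparisons = []
    for measure in ("size_mm2", "intensity"):
        units = cell_means(detections, measure)
        try:
            comparisons.extend(
                compare_family(
                    units, measure, group_col="lesion_id",
                    within_col="reconstruction",
                    family_label=f"ai_{measure}_lesion_pairwise",
                )
            )
        except Exception as exc:  # a lesion may have no matched cell at all
            log.warning("skipping AI %s comparisons: %s", measure, exc)
    # reader arm
    if config.reader_responses is not None:
        responses = validate_responses(pd.read_csv(config.reader_responses))
    else:
        responses = validate_responses(
            simulate_readers(design, lesions, config.reader_params, config.seed)
        )
    write_csv(outdir / "reader_responses.csv", responses)
    reader_agg = aggregate_quality(responses, design)
    write_csv(outdir / "reader_aggregate.csv", reader_agg)
    for within, group in (("reconstruction", "lesion_id"), ("lesion_id", "reconstruction")):
        comparisons.extend(
            compare_family(
                reader_agg, "mean_quality", group_col=group, within_col=within,
                family_label=f"reader_quality_{group}_pairwise",
            )
        )
    if comparisons:
        write_csv(outdir / "comparisons.csv", comparisons_frame(comparisons))

    report = build_report(detections, triage, design)
    report["reader_visibility"] = {
        lid: {
            "positive": pos, "total": tot,
            "percent": round(pct, 1), "percent_full": pct,
        }
        for lid in sorted(responses["lesion_id"].unique())
        for pos, tot, pct in [visibility_rate(responses, lid)]
    }
    report["provenance"] = {
        "seed": config.seed,
        "config_hash": cfg_hash,
        "n_comparisons": len(comparisons),
    }
    write_json(outdir / "report.json", report)
    log.info("pipeline done: %s", outdir)
    return report
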