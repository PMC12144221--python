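"""Assignment of heatmap label components to ground-truth lesions.

A human label review is replaced by geometric matching: component
centroids are assigned one-to-one to lesion centroids by greedy
nearest-distance, accepting pairs within a millimetre tolerance (default
10 mm, wide enough to accept slightly offset low-dose labels while
rejecting distant blobs). Distances are anisotropic: in-plane pixel size
and through-plane slice thickness.

The scan-level triage decision is independent of matching: a scan with at
least one label component of any kind is triage-positive; zero components
is the negative summary report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import Geometry, LesionSpec
from .errors import ValidationError
from .quantify import LabelComponent

DEFAULT_TOLERANCE_MM = 10.0


@dataclass(frozen=True)
class DetectionRecord:
    """Per-scan, per-lesion outcome of the matching step."""

    scan_id: str | None
    lesion_id: str
    matched: bool
    matched_component: int | None = None
    centroid_offset_mm: float | None = None


@dataclass(frozen=True)
class TriageResult:
    """Scan-level verdict: positive heatmap or negative summary report."""

    scan_id: str | None
    decision: str  # "positive" | "negative"
    n_components: int
    unmatched_components: tuple[int, ...] = ()


def _component_centroids_mm(
    components: list[LabelComponent], geometry: Geometry
) -> np.ndarray:
    if not components:
        return np.zeros((0, 3))
    return np.array(
        [
            c.centroid_mm(geometry.pixel_size_mm, geometry.slice_thickness_mm)
            for c in components
        ]
    )


def match_labels(
    components: list[LabelComponent],
    lesions: list[LesionSpec],
    geometry: Geometry,
    tolerance_mm: float = DEFAULT_TOLERANCE_MM,
    scan_id: str | None = None,
) -> tuple[list[DetectionRecord], list[int]]:
    """Greedy nearest-distance one-to-one matching within tolerance.

    Candidate (lesion, component) pairs are visited in order of increasing
    centroid distance (ties broken by lesion_id lexicographically, then by
    component id, so the result is deterministic and invariant to input
    order); a pair is accepted when both sides are still free and the
    distance is within ``tolerance_mm``. Returns one DetectionRecord per
    lesion plus the ids of leftover components (candidate false
    positives).
    """
    if tolerance_mm < 0:
        raise ValidationError("tolerance_mm must be >= 0")

    lesion_pos = np.array([l.centroid_mm(geometry) for l in lesions]).reshape(-1, 3)
    comp_pos = _component_centroids_mm(components, geometry)

    pairs = []
    for i, lesion in enumerate(lesions):
        for j, comp in enumerate(components):
            d = float(np.linalg.norm(lesion_pos[i] - comp_pos[j]))
            if d <= tolerance_mm:
                pairs.append((d, lesion.lesion_id, comp.component_id, i, j))
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))

    assigned: dict[int, tuple[int, float]] = {}
    used_components: set[int] = set()
    for d, _, _, i, j in pairs:
        if i in assigned or j in used_components:
            continue
        assigned[i] = (j, d)
        used_components.add(j)

    records = []
    for i, lesion in enumerate(lesions):
        if i in assigned:
            j, d = assigned[i]
            records.append(
                DetectionRecord(
                    scan_id=scan_id,
                    lesion_id=lesion.lesion_id,
                    matched=True,
                    matched_component=components[j].component_id,
                    centroid_offset_mm=d,
                )
            )
        else:
            records.append(
                DetectionRecord(scan_id=scan_id, lesion_id=lesion.lesion_id, matched=False)
            )
    unmatched = [
        c.component_id
        for k, c in enumerate(components)
        if k not in used_components
    ]
    return records, unmatched


def triage_decision(
    components: list[LabelComponent],
    unmatched: list[int] | None = None,
    scan_id: str | None = None,
) -> TriageResult:
    """Positive iff the heatmap carries at least one label component."""
    n = len(components)
    return TriageResult(
        scan_id=scan_id,
        decision="positive" if n >= 1 else "negative",
        n_components=n,
        unmatched_components=tuple(unmatched or ()),
    )
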