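"""Factorial study design: dose x reconstruction x repetition grid.

The default design mirrors a phantom consistency-testing protocol on a
128-row CT scanner: 21 CTDIvol levels between 0.47 and 20.09 mGy at
120 kVp (tube current-time product varied, rotation time 0.3 s at the
lowest dose and 0.5 s elsewhere), two reconstruction families (iterative
reconstruction, IR, and filtered back projection, FBP), and three repeated
acquisitions per cell — 126 scans in total. Axial 512 x 512 images with
0.41 mm in-plane pixel size and 0.75 mm slice thickness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

from .errors import ValidationError

#: (CTDIvol mGy, tube current-time product mAs, rotation time s) at 120 kVp
DOSE_TABLE: tuple[tuple[float, int, float], ...] = (
    (0.47, 7, 0.3),
    (1.01, 15, 0.5),
    (2.02, 30, 0.5),
    (3.00, 44, 0.5),
    (4.01, 59, 0.5),
    (5.02, 74, 0.5),
    (6.03, 89, 0.5),
    (7.05, 104, 0.5),
    (8.06, 119, 0.5),
    (9.07, 134, 0.5),
    (10.08, 149, 0.5),
    (11.09, 164, 0.5),
    (12.11, 179, 0.5),
    (13.04, 193, 0.5),
    (14.06, 208, 0.5),
    (15.07, 223, 0.5),
    (16.04, 238, 0.5),
    (17.05, 253, 0.5),
    (18.07, 268, 0.5),
    (19.08, 283, 0.5),
    (20.09, 298, 0.5),
)

DEFAULT_KVP = 120


@dataclass(frozen=True)
class TubeSetting:
    """Tube parameters for one dose level."""

    kvp: int
    mAs: int
    rotation_time_s: float


@dataclass(frozen=True)
class Geometry:
    """Image-stack geometry shared by every scan in a study."""

    n_slices: int = 8
    n_rows: int = 512
    n_cols: int = 512
    pixel_size_mm: float = 0.41
    slice_thickness_mm: float = 0.75

    def __post_init__(self):
        if min(self.n_slices, self.n_rows, self.n_cols) < 1:
            raise ValidationError("image dimensions must be positive")
        if self.pixel_size_mm <= 0 or self.slice_thickness_mm <= 0:
            raise ValidationError("voxel spacing must be positive")


@dataclass(frozen=True)
class LesionSpec:
    """One ground-truth lesion: identity, voxel centroid and size.

    ``centroid`` is a 0-based (slice, row, col) voxel position;
    millimetre positions are index x spacing from the first voxel centre.
    """

    lesion_id: str
    centroid: tuple[float, float, float]
    max_diameter_mm: float

    def __post_init__(self):
        if self.max_diameter_mm <= 0:
            raise ValidationError(
                f"lesion {self.lesion_id}: max_diameter_mm must be > 0"
            )
        if len(self.centroid) != 3:
            raise ValidationError("centroid must be (slice, row, col)")

    def centroid_mm(self, geometry: Geometry) -> tuple[float, float, float]:
        s, r, c = self.centroid
        return (
            s * geometry.slice_thickness_mm,
            r * geometry.pixel_size_mm,
            c * geometry.pixel_size_mm,
        )

    def in_bounds(self, geometry: Geometry) -> bool:
        s, r, c = self.centroid
        return (
            0 <= s < geometry.n_slices
            and 0 <= r < geometry.n_rows
            and 0 <= c < geometry.n_cols
        )


@dataclass(frozen=True)
class AcquisitionCondition:
    """Identity and metadata of a single scan (one design-grid point)."""

    scan_id: str
    dose_mGy: float
    reconstruction: str
    repetition: int
    geometry: Geometry


def scan_id_for(dose_mGy: float, reconstruction: str, repetition: int) -> str:
    """Stable scan identifier, sortable by dose within reconstruction."""
    return f"{dose_mGy:06.2f}mGy-{reconstruction}-r{repetition}"


@dataclass(frozen=True)
class StudyDesign:
    """The full factorial acquisition plan.

    Total scan count is ``len(doses_mGy) * len(reconstructions) *
    repetitions``.
    """

    doses_mGy: tuple[float, ...]
    reconstructions: tuple[str, ...] = ("IR", "FBP")
    repetitions: int = 3
    geometry: Geometry = field(default_factory=Geometry)
    tube: Mapping[float, TubeSetting] = field(default_factory=dict)

    def __post_init__(self):
        doses = tuple(self.doses_mGy)
        if not doses or any(d <= 0 for d in doses):
            raise ValidationError("all doses must be > 0")
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValidationError("doses must be strictly increasing")
        if self.repetitions < 1:
            raise ValidationError("repetitions must be >= 1")
        if not self.reconstructions:
            raise ValidationError("at least one reconstruction required")

    @property
    def n_scans(self) -> int:
        return len(self.doses_mGy) * len(self.reconstructions) * self.repetitions

    def scans(self) -> list[AcquisitionCondition]:
        """All acquisition conditions, ordered dose-major then
        reconstruction then repetition (repetitions are 1-based)."""
        out = []
        for dose in self.doses_mGy:
            for recon in self.reconstructions:
                for rep in range(1, self.repetitions + 1):
                    out.append(
                        AcquisitionCondition(
                            scan_id=scan_id_for(dose, recon, rep),
                            dose_mGy=dose,
                            reconstruction=recon,
                            repetition=rep,
                            geometry=self.geometry,
                        )
                    )
        return out

    def to_dict(self) -> dict:
        return {
            "doses_mGy": list(self.doses_mGy),
            "reconstructions": list(self.reconstructions),
            "repetitions": self.repetitions,
            "geometry": asdict(self.geometry),
            "tube": {
                f"{d:.2f}": asdict(t) for d, t in sorted(self.tube.items())
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        tube = {
            float(k): TubeSetting(**v) for k, v in d.get("tube", {}).items()
        }
        return cls(
            doses_mGy=tuple(d["doses_mGy"]),
            reconstructions=tuple(d.get("reconstructions", ("IR", "FBP"))),
            repetitions=int(d.get("repetitions", 3)),
            geometry=Geometry(**d.get("geometry", {})),
            tube=tube,
        )


def make_default_design(geometry: Geometry | None = None) -> StudyDesign:
    """The reference 21-dose x {IR, FBP} x 3-repetition design (126 scans)."""
    geometry = geometry or Geometry()
    tube = {
        dose: TubeSetting(kvp=DEFAULT_KVP, mAs=mas, rotation_time_s=rot)
        for dose, mas, rot in DOSE_TABLE
    }
    return StudyDesign(
        doses_mGy=tuple(d for d, _, _ in DOSE_TABLE),
        reconstructions=("IR", "FBP"),
        repetitions=3,
        geometry=geometry,
        tube=tube,
    )


def default_lesions(geometry: Geometry | None = None) -> list[LesionSpec]:
    """Three aneurysm targets: MCA and ACoA (4 mm) and BA (2 mm).

    Centroids are placed well apart so rendered labels can never merge at
    the default offset scale; positions scale with the image matrix.
    """
    g = geometry or Geometry()
    mid_s = g.n_slices // 2
    return [
        LesionSpec("MCA", (max(mid_s - 1, 0), 0.50 * g.n_rows, 0.33 * g.n_cols), 4.0),
        LesionSpec("ACoA", (mid_s, 0.45 * g.n_rows, 0.60 * g.n_cols), 4.0),
        LesionSpec("BA", (min(mid_s + 1, g.n_slices - 1), 0.70 * g.n_rows, 0.50 * g.n_cols), 2.0),
    ]
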