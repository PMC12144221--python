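"""Synthetic phantom study generator.

Emulates the statistical structure of a phantom consistency test of a
lesion-detection AI without any scanner data: for every scan of the
dose x reconstruction x repetition grid it draws, per lesion, whether the
AI produces a label (a Bernoulli draw from a logistic dose-response in
log-dose, optionally degraded at high dose for a reconstruction), and
renders each produced label into an 8-bit RGB heatmap overlay as a filled
in-plane disc in a hot color (high red, blue <= the segmentation
threshold) on a neutral light background. Label size and color depth grow
with dose through saturating curves with small multiplicative jitter, and
label centres carry a random isotropic in-plane offset (low-dose labels
sit slightly off the lesion). A parallel reader model draws per-reader
visibility (logistic in log-dose) and ordinal 1-3 image-quality ratings
(cumulative-logit in log-dose, forced to 1 when invisible).

No CT physics, noise texture or anatomy is simulated: the analysis
consumes only overlay pixels and geometry, so heatmaps are standalone
overlays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import (
    AcquisitionCondition,
    Geometry,
    LesionSpec,
    StudyDesign,
)
from .errors import ConfigurationError, RenderError, ValidationError
from .quantify import HeatmapSeries
from .rng import substream

#: neutral background of rendered overlays (blue well above threshold)
BACKGROUND_RGB = (230, 230, 230)


@dataclass(frozen=True)
class HighDoseDegradation:
    """Optional label-probability drop above a knee dose.

    Models a reconstruction whose labeling becomes unreliable at high
    dose (contrary to the usual dose-quality intuition): the logistic
    probability is multiplied by 1 - amplitude * sigmoid(steepness *
    log(dose / knee)).
    """

    amplitude: float = 0.35
    knee_mGy: float = 14.0
    steepness: float = 3.0


@dataclass(frozen=True)
class LesionResponse:
    """Per lesion x reconstruction generating behavior.

    Label probability is p = sigmoid(intercept + slope * log(dose)),
    optionally degraded at high dose. size_scale multiplies the rendered
    label radius and intensity_scale the color depth, letting conspicuous
    lesions produce larger, hotter labels than hard ones at equal dose.
    """

    intercept: float
    slope: float
    degradation: HighDoseDegradation | None = None
    size_scale: float = 1.0
    intensity_scale: float = 1.0

    def __post_init__(self):
        if self.size_scale < 0 or self.intensity_scale < 0:
            raise ValidationError("scale factors must be >= 0")


@dataclass
class DetectionModelParams:
    """Generating model for AI labels.

    response maps (lesion_id, reconstruction) to a logistic dose-response.
    Label radius is max_diameter/2 scaled by dose/(dose + size_d50_mGy)
    (saturating at 1) with lognormal jitter; color depth follows
    dose/(dose + intensity_d50_mGy) with additive jitter; label centres
    are offset isotropically in-plane with scale offset_scale_mm.
    """

    response: dict[tuple[str, str], LesionResponse]
    size_d50_mGy: float = 1.0
    size_jitter_sigma: float = 0.10
    intensity_d50_mGy: float = 1.0
    intensity_jitter_sigma: float = 0.05
    offset_scale_mm: float = 2.0

    def __post_init__(self):
        if self.size_d50_mGy < 0 or self.intensity_d50_mGy < 0:
            raise ValidationError("saturation half-doses must be >= 0")
        if self.offset_scale_mm < 0:
            raise ValidationError("offset_scale_mm must be >= 0")


def detection_params_from_dict(d: dict) -> DetectionModelParams:
    """Build DetectionModelParams from a config mapping; response keys are
    "<lesion_id>/<reconstruction>" strings."""
    response = {}
    for key, r in d.get("response", {}).items():
        lesion_id, recon = key.split("/")
        deg = r.get("degradation")
        response[(lesion_id, recon)] = LesionResponse(
            intercept=float(r["intercept"]),
            slope=float(r["slope"]),
            degradation=HighDoseDegradation(**deg) if deg else None,
            size_scale=float(r.get("size_scale", 1.0)),
            intensity_scale=float(r.get("intensity_scale", 1.0)),
        )
    kwargs = {
        k: float(d[k])
        for k in ("size_d50_mGy", "size_jitter_sigma", "intensity_d50_mGy",
                  "intensity_jitter_sigma", "offset_scale_mm")
        if k in d
    }
    return DetectionModelParams(response=response, **kwargs)


def default_detection_params() -> DetectionModelParams:
    """Defaults emulating the qualitative study structure: one lesion
    labeled almost everywhere (slightly less often with FBP), one with a
    mid-dose threshold and FBP degradation at high dose, one labeled
    rarely, essentially never with FBP."""
    response = {
        ("MCA", "IR"): LesionResponse(3.0, 8.0),
        ("MCA", "FBP"): LesionResponse(2.5, 8.0),
        ("ACoA", "IR"): LesionResponse(-4.5, 3.0, size_scale=0.7,
                                       intensity_scale=0.8),
        ("ACoA", "FBP"): LesionResponse(-4.5, 3.0, HighDoseDegradation(),
                                        size_scale=0.7, intensity_scale=0.8),
        ("BA", "IR"): LesionResponse(-3.0, 0.0, size_scale=0.8,
                                     intensity_scale=0.7),
        ("BA", "FBP"): LesionResponse(-5.0, 0.0, size_scale=0.8,
                                      intensity_scale=0.7),
    }
    return DetectionModelParams(response=response)


def label_probability(
    dose_mGy: float,
    reconstruction: str,
    lesion_id: str,
    params: DetectionModelParams,
) -> float:
    """Probability that the AI labels a lesion at a given dose.

    Monotonically non-decreasing in dose (slope >= 0) unless the
    lesion x reconstruction carries a high-dose degradation term.
    """
    if dose_mGy <= 0:
        raise ValidationError("dose_mGy must be > 0")
    key = (lesion_id, reconstruction)
    if key not in params.response:
        raise ConfigurationError(
            f"no dose-response configured for lesion {lesion_id!r} with "
            f"reconstruction {reconstruction!r}"
        )
    r = params.response[key]
    p = float(expit(r.intercept + r.slope * np.log(dose_mGy)))
    if r.degradation is not None:
        d = r.degradation
        p *= 1.0 - d.amplitude * float(
            expit(d.steepness * np.log(dose_mGy / d.knee_mGy))
        )
    return float(np.clip(p, 0.0, 1.0))


@dataclass(frozen=True)
class RenderedLabel:
    """Bookkeeping for one rendered blob (for round-trip checks)."""

    lesion_id: str
    n_pixels: int
    center_voxel: tuple[float, float, float]
    offset_mm: float
    color: tuple[int, int, int]


def _size_factor(dose_mGy: float, d50: float) -> float:
    return 1.0 if d50 == 0 else dose_mGy / (dose_mGy + d50)


def _label_color(depth: float) -> tuple[int, int, int]:
    """Hot label color; blue stays <= 90 for any depth in [0, 1]."""
    depth = float(np.clip(depth, 0.0, 1.0))
    return (255, int(round(140 * (1 - depth))), int(round(90 * (1 - depth))))


def render_heatmap(
    condition: AcquisitionCondition,
    lesions: Iterable[LesionSpec],
    detected_ids: Iterable[str],
    params: DetectionModelParams,
    rng: np.random.Generator,
) -> tuple[HeatmapSeries, list[RenderedLabel]]:
    """Render one scan's overlay stack with one blob per detected lesion.

    Each detected lesion becomes a filled disc on its centroid slice,
    centred at the centroid plus a Gaussian in-plane offset; discs are
    clipped at the image border and a blob that would fall entirely
    outside the image raises RenderError. Blobs never have zero pixels:
    a sub-pixel disc lights the pixel nearest its centre.
    """
    g = condition.geometry
    detected = set(detected_ids)
    lesion_map = {l.lesion_id: l for l in lesions}
    unknown = detected - set(lesion_map)
    if unknown:
        raise ValidationError(f"detected ids not in ground truth: {sorted(unknown)}")

    px = np.empty((g.n_slices, g.n_rows, g.n_cols, 3), dtype=np.uint8)
    px[...] = BACKGROUND_RGB
    records: list[RenderedLabel] = []

    for lesion in lesions:  # fixed draw order = lesion list order
        if lesion.lesion_id not in detected:
            continue
        if not lesion.in_bounds(g):
            raise RenderError(f"lesion {lesion.lesion_id} centroid out of bounds")
        dy_mm, dx_mm = rng.normal(0.0, params.offset_scale_mm, size=2)
        jitter = rng.lognormal(0.0, params.size_jitter_sigma) if params.size_jitter_sigma else 1.0
        depth_jit = rng.normal(0.0, params.intensity_jitter_sigma) if params.intensity_jitter_sigma else 0.0

        resp = params.response.get(
            (lesion.lesion_id, condition.reconstruction)
        )
        size_scale = resp.size_scale if resp else 1.0
        intensity_scale = resp.intensity_scale if resp else 1.0
        radius_mm = (
            lesion.max_diameter_mm / 2.0
            * _size_factor(condition.dose_mGy, params.size_d50_mGy)
            * size_scale * jitter
        )
        depth = (
            intensity_scale
            * _size_factor(condition.dose_mGy, params.intensity_d50_mGy)
            + depth_jit
        )
        color = _label_color(depth)

        s = int(round(lesion.centroid[0]))
        cr = lesion.centroid[1] + dy_mm / g.pixel_size_mm
        cc = lesion.centroid[2] + dx_mm / g.pixel_size_mm
        radius_px = radius_mm / g.pixel_size_mm

        rows = np.arange(g.n_rows)[:, None]
        cols = np.arange(g.n_cols)[None, :]
        disc = (rows - cr) ** 2 + (cols - cc) ** 2 <= radius_px**2
        if not disc.any():
            # sub-pixel blob: light the nearest pixel if it exists
            rr, cci = int(round(cr)), int(round(cc))
            if 0 <= rr < g.n_rows and 0 <= cci < g.n_cols:
                disc[rr, cci] = True
            else:
                raise RenderError(
                    f"label for {lesion.lesion_id} falls entirely outside "
                    f"the image (centre row {cr:.1f}, col {cc:.1f})"
                )
        px[s][disc] = color
        records.append(
            RenderedLabel(
                lesion_id=lesion.lesion_id,
                n_pixels=int(disc.sum()),
                center_voxel=(float(s), float(cr), float(cc)),
                offset_mm=float(np.hypot(dy_mm, dx_mm)),
                color=color,
            )
        )
    series = HeatmapSeries(
        pixels=px,
        pixel_size_mm=g.pixel_size_mm,
        slice_thickness_mm=g.slice_thickness_mm,
        acquisition=condition,
    )
    return series, records


def iter_simulated_scans(
    design: StudyDesign,
    lesions: list[LesionSpec],
    params: DetectionModelParams,
    seed: int,
    render: bool = True,
) -> Iterator[tuple[AcquisitionCondition, HeatmapSeries | None, list[dict]]]:
    """Stream the simulated study scan by scan.

    Yields (condition, heatmap-or-None, truth rows). Each scan consumes
    its own named substream keyed by scan id, so the realization of any
    scan is independent of which other scans exist and of iteration
    order. Detection draws always precede rendering draws within a scan.
    """
    for cond in design.scans():
        rng = substream(seed, "scan", cond.scan_id)
        truth_rows = []
        detected = []
        for lesion in lesions:
            p = label_probability(
                cond.dose_mGy, cond.reconstruction, lesion.lesion_id, params
            )
            hit = bool(rng.random() < p)
            if hit:
                detected.append(lesion.lesion_id)
            truth_rows.append(
                {
                    "scan_id": cond.scan_id,
                    "dose_mGy": cond.dose_mGy,
                    "reconstruction": cond.reconstruction,
                    "repetition": cond.repetition,
                    "lesion_id": lesion.lesion_id,
                    "detected": hit,
                    "p_label": p,
                }
            )
        series = None
        if render:
            series, _ = render_heatmap(cond, lesions, detected, params, rng)
        yield cond, series, truth_rows


def simulate_study(
    design: StudyDesign,
    lesions: list[LesionSpec],
    params: DetectionModelParams,
    seed: int,
    render: bool = True,
) -> tuple[dict[str, HeatmapSeries], pd.DataFrame]:
    """Materialize the whole study: heatmaps keyed by scan id + truth table.

    For large designs prefer :func:`iter_simulated_scans`, which streams
    scans without holding every pixel stack in memory.
    """
    heatmaps: dict[str, HeatmapSeries] = {}
    rows: list[dict] = []
    for cond, series, truth_rows in iter_simulated_scans(
        design, lesions, params, seed, render=render
    ):
        if series is not None:
            heatmaps[cond.scan_id] = series
        rows.extend(truth_rows)
    return heatmaps, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reader model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReaderLesionModel:
    """Per-lesion reader behavior.

    visibility: P(visible) = sigmoid(vis_intercept + vis_slope * log d).
    quality: cumulative logit, P(q >= k) = sigmoid(t_k + q_slope * log d)
    for k in {2, 3} with t3 < t2; rating forced to 1 when not visible.
    """

    vis_intercept: float
    vis_slope: float
    q_threshold_2: float
    q_threshold_3: float
    q_slope: float = 1.5


@dataclass
class ReaderParams:
    """Reader panel: per-lesion models plus small per-reader bias added to
    every logit (readers differ slightly in leniency)."""

    lesion_models: dict[str, ReaderLesionModel]
    reader_ids: tuple[str, ...] = ("R1", "R2", "R3", "R4", "R5")
    reader_bias: tuple[float, ...] = (-0.4, -0.2, 0.0, 0.2, 0.4)

    def __post_init__(self):
        if len(self.reader_bias) != len(self.reader_ids):
            raise ValidationError("one bias per reader required")


def reader_params_from_dict(d: dict) -> ReaderParams:
    """Build ReaderParams from a config mapping keyed by lesion id."""
    models = {
        lid: ReaderLesionModel(**m) for lid, m in d.get("lesion_models", {}).items()
    }
    kwargs = {}
    if "reader_ids" in d:
        kwargs["reader_ids"] = tuple(d["reader_ids"])
    if "reader_bias" in d:
        kwargs["reader_bias"] = tuple(float(b) for b in d["reader_bias"])
    return ReaderParams(lesion_models=models, **kwargs)


def default_reader_params() -> ReaderParams:
    """Near-ceiling visibility degrading only at the lowest doses; quality
    improves with dose; the most conspicuous lesion rated higher, the two
    harder ones alike."""
    models = {
        "MCA": ReaderLesionModel(5.0, 4.0, q_threshold_2=3.5, q_threshold_3=1.2),
        "ACoA": ReaderLesionModel(3.8, 3.0, q_threshold_2=2.5, q_threshold_3=0.3),
        "BA": ReaderLesionModel(0.9, 2.4, q_threshold_2=2.5, q_threshold_3=0.3),
    }
    return ReaderParams(lesion_models=models)


def simulate_readers(
    design: StudyDesign,
    lesions: list[LesionSpec],
    reader_params: ReaderParams,
    seed: int,
) -> pd.DataFrame:
    """One response per reader x scan x lesion.

    Columns: reader_id, scan_id, lesion_id, dose_mGy, reconstruction,
    repetition, visible ("yes"/"no"), quality_raw in {1,2,3}. Draws are
    keyed by (reader, scan), independent of panel size or scan count.
    """
    rp = reader_params
    missing = {l.lesion_id for l in lesions} - set(rp.lesion_models)
    if missing:
        raise ConfigurationError(f"no reader model for lesions: {sorted(missing)}")

    rows = []
    for cond in design.scans():
        logd = np.log(cond.dose_mGy)
        for reader_id, bias in zip(rp.reader_ids, rp.reader_bias):
            rng = substream(seed, "reader", reader_id, cond.scan_id)
            for lesion in lesions:
                m = rp.lesion_models[lesion.lesion_id]
                p_vis = expit(m.vis_intercept + m.vis_slope * logd + bias)
                visible = bool(rng.random() < p_vis)
                if not visible:
                    q = 1
                else:
                    u = rng.random()
                    p2 = expit(m.q_threshold_2 + m.q_slope * logd + bias)
                    p3 = expit(m.q_threshold_3 + m.q_slope * logd + bias)
                    q = 1 + int(u < p2) + int(u < p3)
                rows.append(
                    {
                        "reader_id": reader_id,
                        "scan_id": cond.scan_id,
                        "lesion_id": lesion.lesion_id,
                        "dose_mGy": cond.dose_mGy,
                        "reconstruction": cond.reconstruction,
                        "repetition": cond.repetition,
                        "visible": "yes" if visible else "no",
                        "quality_raw": q,
                    }
                )
    return pd.DataFrame(rows)


def fit_dose_response(
    truth: pd.DataFrame, lesion_id: str, reconstruction: str
) -> tuple[float, float]:
    """Recover (intercept, slope) of the logistic dose-response from a
    simulated truth table by binomial GLM on log-dose."""
    import statsmodels.api as sm

    sub = truth[
        (truth["lesion_id"] == lesion_id)
        & (truth["reconstruction"] == reconstruction)
    ]
    if len(sub) == 0:
        raise ValidationError("no truth rows for requested lesion/reconstruction")
    X = sm.add_constant(np.log(sub["dose_mGy"].to_numpy()))
    y = sub["detected"].to_numpy(dtype=float)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit()
    return float(res.params[0]), float(res.params[1])
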