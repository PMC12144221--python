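"""Synthetic study generator: dose response, rendering, reproducibility."""

import numpy as np
import pandas as pd
import pytest

from phantomqa.errors import ConfigurationError, RenderError, ValidationError
from phantomqa.quantify import extract_components, segment_label_mask
from phantomqa.simulate import (
    DetectionModelParams,
    LesionResponse,
    default_detection_params,
    default_reader_params,
    fit_dose_response,
    label_probability,
    render_heatmap,
    simulate_readers,
    simulate_study,
)


def flat_params(p_logit=0.0, **kwargs):
    """Same logistic for every lesion x reconstruction."""
    response = {
        (lid, recon): LesionResponse(p_logit, 0.0)
        for lid in ("MCA", "ACoA", "BA")
        for recon in ("IR", "FBP")
    }
    return DetectionModelParams(response=response, **kwargs)


def sure_params(**kwargs):
    return flat_params(p_logit=1e9, **kwargs)


def never_params(**kwargs):
    return flat_params(p_logit=-1e9, **kwargs)


class TestLabelProbability:
    def test_saturates_at_one(self):
        assert label_probability(5.0, "IR", "MCA", sure_params()) == pytest.approx(1.0)

    def test_zero_logit_gives_half_everywhere(self):
        params = flat_params(0.0)
        for dose in (0.5, 1.0, 5.0, 20.0):
            assert label_probability(dose, "IR", "MCA", params) == pytest.approx(0.5)

    def test_monotone_without_degradation(self):
        params = default_detection_params()
        doses = np.linspace(0.47, 20.09, 200)
        probs = [label_probability(d, "IR", "ACoA", params) for d in doses]
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_degradation_breaks_monotonicity(self):
        params = default_detection_params()
        p_mid = label_probability(10.0, "FBP", "ACoA", params)
        p_high = label_probability(20.09, "FBP", "ACoA", params)
        assert p_high < p_mid

    def test_formula_matches_grid_interpolation(self):
        """The closed form agrees with interpolation on a fine evaluation
        grid, i.e. the implementation is the smooth logistic it claims."""
        from scipy.interpolate import interp1d
        from scipy.special import expit

        params = default_detection_params()
        grid = np.linspace(0.1, 25.0, 20001)
        resp = params.response[("ACoA", "IR")]
        curve = expit(resp.intercept + resp.slope * np.log(grid))
        f = interp1d(grid, curve, kind="cubic")
        for dose in (0.47, 1.7, 5.02, 19.3):
            assert label_probability(dose, "IR", "ACoA", params) == pytest.approx(
                float(f(dose)), abs=1e-9
            )

    def test_unknown_lesion_rejected(self):
        with pytest.raises(ConfigurationError):
            label_probability(1.0, "IR", "PICA", default_detection_params())

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValidationError):
            label_probability(0.0, "IR", "MCA", default_detection_params())


class TestRender:
    def test_no_detections_no_positive_pixels(self, small_design, small_lesions):
        cond = small_design.scans()[0]
        series, records = render_heatmap(
            cond, small_lesions, [], sure_params(), np.random.default_rng(0)
        )
        assert not segment_label_mask(series).any()
        assert records == []

    def test_zero_offset_blob_centred_on_lesion(self, small_design, small_lesions):
        cond = small_design.scans()[-1]  # highest dose: full-size blob
        params = sure_params(offset_scale_mm=0.0, size_jitter_sigma=0.0,
                             intensity_jitter_sigma=0.0)
        series, _ = render_heatmap(
            cond, small_lesions, ["MCA"], params, np.random.default_rng(0)
        )
        comps = extract_components(segment_label_mask(series))
        assert len(comps) == 1
        centroid = comps[0].centroid_voxel
        lesion = small_lesions[0]
        assert abs(centroid[1] - lesion.centroid[1]) <= 0.5
        assert abs(centroid[2] - lesion.centroid[2]) <= 0.5

    def test_roundtrip_segmentation_recovers_rendered_pixels(
        self, small_design, small_lesions
    ):
        cond = small_design.scans()[-1]
        series, records = render_heatmap(
            cond, small_lesions, ["MCA", "ACoA", "BA"], sure_params(),
            np.random.default_rng(5),
        )
        mask = segment_label_mask(series)
        comps = extract_components(mask)
        assert len(comps) == 3
        assert sum(c.n_pixels for c in comps) == sum(r.n_pixels for r in records)
        assert int(mask.sum()) == sum(r.n_pixels for r in records)

    def test_blob_never_empty_at_lowest_dose(self, small_design, small_lesions):
        cond = small_design.scans()[0]
        series, records = render_heatmap(
            cond, small_lesions, ["BA"], sure_params(), np.random.default_rng(1)
        )
        assert records[0].n_pixels >= 1
        assert segment_label_mask(series).sum() == records[0].n_pixels

    def test_blob_outside_bounds_raises(self, small_design):
        from phantomqa.design import LesionSpec

        # lesion centre far outside the in-plane field of view
        lesion = LesionSpec("EDGE", (1, 2.0, 63.0), 2.0)
        params = sure_params(offset_scale_mm=200.0, size_jitter_sigma=0.0)
        cond = small_design.scans()[0]
        with pytest.raises(RenderError):
            for seed in range(100):  # some offset draw will leave the image
                render_heatmap(
                    cond, [lesion], ["EDGE"], params,
                    np.random.default_rng(seed),
                )

    def test_unknown_detected_id_rejected(self, small_design, small_lesions):
        with pytest.raises(ValidationError):
            render_heatmap(
                small_design.scans()[0], small_lesions, ["XXX"],
                sure_params(), np.random.default_rng(0),
            )


class TestSimulateStudy:
    def test_all_detected_when_probability_one(self, small_design, small_lesions):
        heatmaps, truth = simulate_study(
            small_design, small_lesions, sure_params(), seed=0
        )
        assert len(heatmaps) == small_design.n_scans
        assert truth["detected"].all()
        per_lesion = truth.groupby("lesion_id")["detected"].sum()
        assert (per_lesion == small_design.n_scans).all()

    def test_none_detected_when_probability_zero(self, small_design, small_lesions):
        heatmaps, truth = simulate_study(
            small_design, small_lesions, never_params(), seed=0
        )
        assert not truth["detected"].any()
        for series in heatmaps.values():
            assert not segment_label_mask(series).any()

    def test_bit_identical_given_seed(self, small_design, small_lesions):
        params = default_detection_params()
        h1, t1 = simulate_study(small_design, small_lesions, params, seed=7)
        h2, t2 = simulate_study(small_design, small_lesions, params, seed=7)
        pd.testing.assert_frame_equal(t1, t2)
        for sid in h1:
            np.testing.assert_array_equal(h1[sid].pixels, h2[sid].pixels)

    def test_different_seeds_differ(self, small_design, small_lesions):
        params = default_detection_params()
        _, t1 = simulate_study(small_design, small_lesions, params, seed=1,
                               render=False)
        _, t2 = simulate_study(small_design, small_lesions, params, seed=2,
                               render=False)
        assert not t1["detected"].equals(t2["detected"])

    def test_adding_doses_preserves_existing_scans(
        self, small_design, small_lesions, small_geometry
    ):
        """Substreams are keyed by scan identity, so enlarging the design
        never changes scans that already existed."""
        from phantomqa.design import StudyDesign

        bigger = StudyDesign(
            doses_mGy=small_design.doses_mGy + (16.0,),
            reconstructions=small_design.reconstructions,
            repetitions=small_design.repetitions,
            geometry=small_geometry,
        )
        params = default_detection_params()
        h1, t1 = simulate_study(small_design, small_lesions, params, seed=3)
        h2, t2 = simulate_study(bigger, small_lesions, params, seed=3)
        shared = t2[t2["scan_id"].isin(t1["scan_id"])].reset_index(drop=True)
        pd.testing.assert_frame_equal(
            t1.sort_values(["scan_id", "lesion_id"]).reset_index(drop=True),
            shared.sort_values(["scan_id", "lesion_id"]).reset_index(drop=True),
        )
        for sid in h1:
            np.testing.assert_array_equal(h1[sid].pixels, h2[sid].pixels)

    def test_component_count_equals_truth_detections(
        self, small_design, small_lesions
    ):
        params = default_detection_params()
        heatmaps, truth = simulate_study(small_design, small_lesions, params, seed=11)
        for sid, series in heatmaps.items():
            n_truth = int(
                truth[(truth["scan_id"] == sid)]["detected"].sum()
            )
            comps = extract_components(segment_label_mask(series))
            assert len(comps) == n_truth

    def test_empirical_fraction_matches_probability(self, small_geometry, small_lesions):
        """Fixed p = 0.7 over 2000 scans: empirical fraction within 3 SE."""
        from phantomqa.design import StudyDesign
        from scipy.special import logit

        design = StudyDesign(
            doses_mGy=tuple(np.linspace(1, 20, 500)),
            reconstructions=("IR",),
            repetitions=4,
            geometry=small_geometry,
        )
        p = 0.7
        _, truth = simulate_study(
            design, small_lesions,
            flat_params(float(logit(p))), seed=123, render=False,
        )
        n = design.n_scans
        frac = truth[truth["lesion_id"] == "MCA"]["detected"].mean()
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) <= 3 * se

    def test_logistic_slope_recovery(self, small_geometry, small_lesions):
        """50 repetitions per cell recover the generating slope within 20%."""
        from phantomqa.design import StudyDesign

        from phantomqa.design import DOSE_TABLE

        design = StudyDesign(
            doses_mGy=tuple(d for d, _, _ in DOSE_TABLE),
            reconstructions=("IR",),
            repetitions=50,
            geometry=small_geometry,
        )
        slope_true, intercept_true = 3.0, -4.5
        response = {
            (lid, "IR"): LesionResponse(intercept_true, slope_true)
            for lid in ("MCA", "ACoA", "BA")
        }
        params = DetectionModelParams(response=response)
        _, truth = simulate_study(design, small_lesions, params, seed=5, render=False)
        _, slope_hat = fit_dose_response(truth, "ACoA", "IR")
        assert abs(slope_hat - slope_true) / slope_true <= 0.20


class TestSimulateReaders:
    def test_certain_visibility_counts(self, small_design, small_lesions):
        from phantomqa.simulate import ReaderLesionModel, ReaderParams

        models = {
            lid: ReaderLesionModel(1e9, 0.0, q_threshold_2=0.0, q_threshold_3=-1.0)
            for lid in ("MCA", "ACoA", "BA")
        }
        rp = ReaderParams(lesion_models=models)
        resp = simulate_readers(small_design, small_lesions, rp, seed=0)
        n_expected = 5 * small_design.n_scans
        for lid in ("MCA", "ACoA", "BA"):
            sub = resp[resp["lesion_id"] == lid]
            assert (sub["visible"] == "yes").sum() == n_expected

    def test_zero_visibility(self, small_design, small_lesions):
        from phantomqa.simulate import ReaderLesionModel, ReaderParams

        models = {
            lid: ReaderLesionModel(-1e9, 0.0, q_threshold_2=0.0, q_threshold_3=-1.0)
            for lid in ("MCA", "ACoA", "BA")
        }
        rp = ReaderParams(lesion_models=models)
        resp = simulate_readers(small_design, small_lesions, rp, seed=0)
        assert (resp["visible"] == "no").all()
        assert (resp["quality_raw"] == 1).all()

    def test_reproducible_and_valid_ranges(self, small_design, small_lesions):
        rp = default_reader_params()
        r1 = simulate_readers(small_design, small_lesions, rp, seed=4)
        r2 = simulate_readers(small_design, small_lesions, rp, seed=4)
        pd.testing.assert_frame_equal(r1, r2)
        assert set(r1["quality_raw"]).issubset({1, 2, 3})
        assert set(r1["visible"]).issubset({"yes", "no"})
        assert len(r1) == 5 * small_design.n_scans * 3

    def test_visibility_increases_with_dose_on_average(
        self, small_geometry, small_lesions
    ):
        """Averaged over many seeds, positive responses are non-decreasing
        in dose under a dose-increasing visibility model."""
        from phantomqa.design import StudyDesign

        design = StudyDesign(
            doses_mGy=(0.5, 2.0, 8.0), reconstructions=("IR",),
            repetitions=2, geometry=small_geometry,
        )
        rp = default_reader_params()
        totals = np.zeros(3)
        for seed in range(500):
            resp = simulate_readers(design, small_lesions, rp, seed=seed)
            ba = resp[resp["lesion_id"] == "BA"]
            counts = (
                ba.assign(pos=ba["visible"] == "yes")
                .groupby("dose_mGy")["pos"].sum()
                .reindex(design.doses_mGy)
            )
            totals += counts.to_numpy()
        assert totals[0] <= totals[1] <= totals[2]
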