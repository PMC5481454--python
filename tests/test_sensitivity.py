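"""Experimental design, KS testing, Bonferroni bookkeeping, ROI perturbation."""

import math

import numpy as np
import pandas as pd
import pytest

import adctexture as at
from adctexture.features import FEATURE_NAMES
from adctexture.sensitivity import dilate_roi

from _reference import naive_ks


class TestDesignArithmetic:
    def test_glioma_test_count(self):
        assert at.count_tests(at.ExperimentDesign.glioma()) == 475

    def test_prostate_test_count(self):
        assert at.count_tests(at.ExperimentDesign.prostate()) == 361

    def test_joint_test_count(self):
        total = (at.count_tests(at.ExperimentDesign.glioma())
                 + at.count_tests(at.ExperimentDesign.prostate()))
        assert total == 836

    def test_count_matches_pair_enumeration(self):
        design = at.ExperimentDesign.glioma()
        pairs = {p: math.comb(len(v), 2)
                 for p, v in design.varied_parameters().items()}
        assert pairs == {"resolution": 3, "noise": 3, "b_values": 6,
                         "gray_levels": 10, "quantization": 3}
        assert at.count_tests(design) == 19 * sum(pairs.values())

    def test_settings_per_roi(self):
        glioma = at.ExperimentDesign.glioma()
        prostate = at.ExperimentDesign.prostate()
        n_g = sum(len(glioma.settings_for(p)) for p in glioma.varied_parameters())
        n_p = sum(len(prostate.settings_for(p)) for p in prostate.varied_parameters())
        assert n_g == 18
        assert n_p == 14

    def test_every_varied_list_contains_the_reference(self):
        design = at.ExperimentDesign.glioma()
        ref = design.reference
        for parameter in design.varied_parameters():
            assert any(s == ref for _, s in design.settings_for(parameter))


class TestBonferroni:
    def test_threshold_for_joint_design(self):
        assert at.bonferroni_threshold(0.01, 836) == pytest.approx(1.196e-5, rel=1e-3)

    def test_identity_for_single_test(self):
        assert at.bonferroni_threshold(0.01, 1) == 0.01

    def test_large_p_not_significant(self):
        assert not (0.5 < at.bonferroni_threshold(0.01, 836))

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1])
    def test_invalid_alpha_rejected(self, alpha):
        with pytest.raises(ValueError):
            at.bonferroni_threshold(alpha, 10)


class TestKSTwoSample:
    def test_identical_samples(self):
        d, p = at.ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = at.ks_two_sample([1, 2, 3], [11, 12, 13])
        assert d == 1.0

    def test_matches_reference_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n1, n2 = rng.integers(10, 60, size=2)
            a = rng.normal(0, 1, n1)
            b = rng.normal(rng.uniform(0, 1), 1, n2)
            d, p = at.ks_two_sample(a, b)
            d_ref, p_ref = naive_ks(a.tolist(), b.tolist())
            assert d == pytest.approx(d_ref, abs=1e-12)
            assert p == pytest.approx(p_ref, abs=1e-8)

    def test_strong_shift_is_detected(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(100):
            a = rng.normal(0, 1, 72)
            b = rng.normal(3, 1, 72)
            _, p = at.ks_two_sample(a, b)
            hits += p < 1e-6
        assert hits >= 99

    def test_insufficient_sample_gives_missing(self):
        d, p = at.ks_two_sample([1.0], [1.0, 2.0, 3.0])
        assert math.isnan(d) and math.isnan(p)

    def test_missing_values_dropped_pairwise(self):
        a = [1.0, np.nan, 2.0, 3.0]
        b = [1.5, 2.5, np.nan, 3.5]
        d, p = at.ks_two_sample(a, b)
        assert np.isfinite(d) and np.isfinite(p)


def _tiny_batch(n=6, seed=0):
    specs = at.make_phantom_batch(n, seed=seed, grid_shape=(24, 24, 2))
    proto = at.make_protocol("glioma")
    return at.simulate_batch(specs, proto, seed=seed + 1)


class TestRunDesign:
    def test_row_count_and_reference_duplication(self):
        batch = _tiny_batch(3)
        design = at.ExperimentDesign.glioma()
        table = at.run_design(batch, design, seed=2)
        assert len(table) == 3 * 18
        # the reference setting recurs in every parameter's list and must
        # be bit-identical wherever it appears
        ref_rows = table[
            ((table.parameter == "resolution") & (table.setting == "1x"))
            | ((table.parameter == "gray_levels") & (table.setting == "N=32"))
        ]
        for roi, grp in ref_rows.groupby("roi"):
            vals = grp[list(FEATURE_NAMES)].to_numpy()
            assert np.array_equal(vals[0], vals[1], equal_nan=True)

    def test_full_pipeline_deterministic(self):
        design = at.ExperimentDesign.glioma()
        t1 = at.run_design(_tiny_batch(2), design, seed=3)
        t2 = at.run_design(_tiny_batch(2), design, seed=3)
        pd.testing.assert_frame_equal(t1, t2)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            at.run_design([], at.ExperimentDesign.glioma())


class TestAllPairsTests:
    def test_pair_counts_by_parameter(self):
        batch = _tiny_batch(4)
        design = at.ExperimentDesign.glioma()
        table = at.run_design(batch, design, seed=4)
        res = at.all_pairs_tests(table, design)
        counts = (res.pairwise.groupby("parameter")["feature"].count() // 19)
        assert counts.to_dict() == {"b_values": 6, "gray_levels": 10,
                                    "noise": 3, "quantization": 3,
                                    "resolution": 3}
        assert len(res.pairwise) == at.count_tests(design)

    def test_identical_settings_never_flagged(self):
        # constant table: every feature identical across settings
        design = at.ExperimentDesign.glioma()
        rows = []
        for parameter in design.varied_parameters():
            for label, _ in design.settings_for(parameter):
                for roi in range(5):
                    rows.append({"roi": roi, "parameter": parameter,
                                 "setting": label,
                                 **{f: float(roi) for f in FEATURE_NAMES}})
        res = at.all_pairs_tests(pd.DataFrame(rows), design)
        assert not res.significant.to_numpy().any()

    def test_injected_shift_is_flagged(self):
        design = at.ExperimentDesign.glioma()
        rng = np.random.default_rng(5)
        rows = []
        for parameter in design.varied_parameters():
            for label, _ in design.settings_for(parameter):
                for roi in range(40):
                    vals = {f: rng.normal() for f in FEATURE_NAMES}
                    if parameter == "noise" and label == "4x":
                        vals["contrast"] += 10.0  # constructed positive control
                    rows.append({"roi": roi, "parameter": parameter,
                                 "setting": label, **vals})
        res = at.all_pairs_tests(pd.DataFrame(rows), design)
        assert res.significant.loc["noise", "contrast"]
        assert not res.significant.loc["resolution", "contrast"]

    def test_bonferroni_denominator_override(self):
        batch = _tiny_batch(4)
        design = at.ExperimentDesign.glioma(n_tests_total=836)
        table = at.run_design(batch, design, seed=6)
        res = at.all_pairs_tests(table, design)
        assert res.n_tests == 836
        assert res.threshold == pytest.approx(0.01 / 836)


class TestROIPerturbation:
    def test_constant_field_changes_nothing(self):
        adc = at.ADCVolume(np.full((20, 20, 2), 1000.0), 1.2)
        roi = np.zeros((20, 20, 2), bool)
        roi[6:14, 6:14, :] = True
        tab = at.roi_perturbation(adc, roi)
        defined = tab.dropna(subset=["autoroi_pct"])
        assert np.allclose(defined["autoroi_pct"], 0.0, atol=1e-9)
        defined_m = tab.dropna(subset=["manual_pct"])
        assert np.allclose(defined_m["manual_pct"], 0.0, atol=1e-9)

    def test_dilation_widens_roi_range(self):
        fluid = at.FluidSpec(center=(30.0, 20.0, 1.0), radii=(6.0, 6.0, 2.0))
        spec = at.PhantomSpec(grid_shape=(40, 40, 2), roi_center=(20.0, 20.0, 0.5),
                              roi_radii=(10.0, 10.0, 1.4), adjacent_fluid=fluid,
                              seed=8)
        adc, roi = at.generate_adc_phantom(spec)
        big = dilate_roi(roi)
        assert big.sum() > roi.sum()
        assert adc.values[big].min() <= adc.values[roi].min()
        assert adc.values[big].max() >= adc.values[roi].max()

    def test_manual_less_sensitive_than_autoroi_near_fluid(self):
        # the ROI-expansion experiment: with fluid adjacent, Manual limits
        # damp the feature change relative to AutoROI for most features
        specs = at.make_phantom_batch(20, seed=12, include_fluid=True)
        wins = []
        for spec in specs:
            adc, roi = at.generate_adc_phantom(spec, voxel_size=1.2)
            tab = at.roi_perturbation(adc, roi)
            cmp = tab.dropna()
            wins.append((cmp["manual_pct"].abs()
                         < cmp["autoroi_pct"].abs()).mean())
        assert np.median(wins) > 0.5
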