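"""Cohort generator: mixture calibration, determinism, conversion logic,
phantom rendering and grey-matter map contracts."""

import dataclasses
import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from pibquant.synthcohort import (
    CentreProfile,
    GeneratorConfig,
    InfeasibleMomentsError,
    MixtureParams,
    default_mixtures,
    moment_match_mixture,
    render_gm_probability_maps,
    render_phantom,
    sample_cohort,
    solve_noncarrier_weight,
    truth_value_map,
    write_cohort_csv,
)


class TestMomentMatching:
    @pytest.mark.parametrize("args, expected", [
        ((1.5, 0.2, 1.0, 99.0, 99.0), (1.5, 0.2)),       # single component
        ((1.85, 0.32, 0.90, 1.30, 0.08), (1.91111, 0.27517)),
        ((1.64, 0.35, 0.65, 1.26, 0.07), (1.84462, 0.25730)),
    ])
    def test_closed_form(self, args, expected):
        pos_mean, pos_sd = moment_match_mixture(*args)
        assert pos_mean == pytest.approx(expected[0], abs=1e-4)
        assert pos_sd == pytest.approx(expected[1], abs=1e-4)

    def test_monte_carlo_oracle(self, rng):
        """10^6 mixture draws reproduce the requested total mean and SD."""
        m, s, w, nm, nsd = 1.85, 0.32, 0.90, 1.30, 0.08
        pm, psd = moment_match_mixture(m, s, w, nm, nsd)
        n = 1_000_000
        pos = rng.random(n) < w
        draws = np.where(pos, rng.normal(pm, psd, n), rng.normal(nm, nsd, n))
        assert draws.mean() == pytest.approx(m, abs=4 * s / np.sqrt(n))
        assert draws.std() == pytest.approx(s, abs=4 * s / np.sqrt(2 * n))

    def test_infeasible_moments_raise(self):
        # negative component already carries more spread than the total
        with pytest.raises(InfeasibleMomentsError):
            moment_match_mixture(1.4, 0.05, 0.5, 1.0, 0.5)

    @given(m=st.floats(1.2, 2.5), s=st.floats(0.1, 0.5),
           w=st.floats(0.3, 0.99), nm=st.floats(1.0, 1.4),
           nsd=st.floats(0.01, 0.1))
    @settings(max_examples=200, derandomize=True)
    def test_roundtrip_property(self, m, s, w, nm, nsd):
        """Whenever the solve succeeds, the mixture moments are exact."""
        try:
            pm, psd = moment_match_mixture(m, s, w, nm, nsd)
        except InfeasibleMomentsError:
            return
        mix = MixtureParams(w, nm, nsd, pm, psd)
        assert mix.mean == pytest.approx(m, rel=1e-9)
        assert np.sqrt(mix.var) == pytest.approx(s, rel=1e-6)


class TestCohortSampling:
    def test_seed_reproducibility_byte_identical(self):
        buf_a, buf_b = io.StringIO(), io.StringIO()
        write_cohort_csv(sample_cohort(GeneratorConfig(seed=42)), buf_a)
        write_cohort_csv(sample_cohort(GeneratorConfig(seed=42)), buf_b)
        assert buf_a.getvalue() == buf_b.getvalue()
        buf_c = io.StringIO()
        write_cohort_csv(sample_cohort(GeneratorConfig(seed=43)), buf_c)
        assert buf_a.getvalue() != buf_c.getvalue()

    def test_degenerate_controls_collapse_to_negative_mean(self):
        cfg = GeneratorConfig(seed=0)
        cfg.mixture_params["control"] = MixtureParams(0.0, 1.26, 0.0, 1.674, 0.1)
        controls = [s for s in sample_cohort(cfg) if s.diagnosis == "control"]
        assert all(s.true_composite == pytest.approx(1.26) for s in controls)

    def test_mci_positivity_matches_mixture_tail(self):
        """Large-sample fraction above 1.41 converges to the analytic
        mixture tail (not the raw component weight)."""
        n = 10_000
        cfg = GeneratorConfig(group_sizes={"mci": n}, seed=7)
        comps = np.array([s.true_composite for s in sample_cohort(cfg)])
        mix = cfg.mixture_params["mci"]
        expected = mix.tail_above(1.41)
        se = np.sqrt(expected * (1 - expected) / n)
        assert np.mean(comps > 1.41) == pytest.approx(expected, abs=3 * se)

    def test_group_moments_converge(self):
        """Simulated per-group mean/SD match the configured totals at large n."""
        n = 100_000
        cfg = GeneratorConfig(group_sizes={"mci": n}, seed=3)
        comps = np.array([s.true_composite for s in sample_cohort(cfg)])
        mix = cfg.mixture_params["mci"]
        sd = np.sqrt(mix.var)
        assert comps.mean() == pytest.approx(mix.mean, abs=3 * sd / np.sqrt(n))
        assert comps.std() == pytest.approx(sd, abs=3 * sd / np.sqrt(2 * n))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_conversion_logic(self, seed):
        subjects = sample_cohort(GeneratorConfig(seed=seed))
        for s in subjects:
            if s.converted:
                assert s.diagnosis == "mci"
                assert s.true_composite > 1.41
                assert s.conversion_month <= s.followup_months
            if s.diagnosis != "mci":
                assert s.followup_months is None and s.converted is None

    def test_truth_invariants(self, default_cohort):
        for s in default_cohort:
            assert s.true_regional["cerebellum"] == 1.0
            assert s.true_regional["white_matter"] == pytest.approx(1.8)
            # hippocampus stays control-like even in AD
            assert s.true_regional["hippocampus"] < 1.6

    def test_apoe_carriers_more_often_positive_in_mci(self):
        cfg = GeneratorConfig(group_sizes={"mci": 20_000}, seed=9)
        subs = sample_cohort(cfg)
        # genotype is None at centre C; truth still exists for the rest
        pos = {True: [], False: []}
        for s in subs:
            if s.apoe_e4 is not None:
                pos[s.apoe_e4].append(s.true_composite > 1.41)
        frac_carrier = np.mean(pos[True])
        frac_non = np.mean(pos[False])
        assert frac_carrier > frac_non + 0.2
        # marginal positivity preserved by the carrier/non-carrier solve
        w = solve_noncarrier_weight(0.65, 31 / 45, 0.80)
        assert 31 / 45 * 0.80 + (1 - 31 / 45) * w == pytest.approx(0.65)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(group_sizes={"control": 0})
        with pytest.raises(ValueError):
            GeneratorConfig(apoe_carrier_prob={"control": 1.5,
                                               "mci": 0.5, "ad": 0.5})
        with pytest.raises(ValueError):
            CentreProfile("X", 5, 0.05, 1.0,
                          ((40, 50), (45, 55))).validate()


class TestPhantomRendering:
    def test_identity_rendering(self, full_atlas, default_cohort,
                                identity_centre):
        subject = default_cohort[0]
        frames = render_phantom(subject, identity_centre, full_atlas)
        expected = truth_value_map(subject, full_atlas)
        for frame in frames.data:
            np.testing.assert_array_equal(frame, expected)

    def test_dose_scaling_doubles_voxels(self, full_atlas, default_cohort,
                                         identity_centre):
        subject = default_cohort[5]
        double = dataclasses.replace(identity_centre, dose_scale=2.0)
        f1 = render_phantom(subject, identity_centre, full_atlas)
        f2 = render_phantom(subject, double, full_atlas)
        np.testing.assert_allclose(f2.data, 2.0 * f1.data, rtol=1e-12)

    def test_fov_truncation_zeroes_slices(self, full_atlas, default_cohort,
                                          identity_centre):
        trunc = dataclasses.replace(identity_centre, fov_z_range=(10, 40))
        frames = render_phantom(default_cohort[0], trunc, full_atlas)
        assert np.all(frames.data[..., :10] == 0)
        assert np.all(frames.data[..., 40:] == 0)
        assert frames.data[..., 10:40].max() > 0

    def test_unassigned_label_raises(self, full_atlas, default_cohort,
                                     identity_centre):
        subject = dataclasses.replace(default_cohort[0])
        subject.true_regional = {k: v for k, v
                                 in subject.true_regional.items()
                                 if k != "frontal"}
        with pytest.raises(ValueError, match="frontal"):
            render_phantom(subject, identity_centre, full_atlas)


class TestGreyMatterMaps:
    def test_zero_amplitude_equals_base(self, full_atlas):
        maps = render_gm_probability_maps(3, full_atlas, seed=0, amplitude=0.0)
        base = np.where(full_atlas.gm_indicator, 0.9, 0.1)
        for m in maps:
            np.testing.assert_array_equal(m, base)

    def test_mean_map_separates_tissue(self, full_atlas):
        maps = render_gm_probability_maps(10, full_atlas, seed=2)
        mean = np.mean(maps, axis=0)
        gm = full_atlas.gm_indicator
        assert np.all(mean[gm] >= 0.5)
        assert np.all(mean[~gm] < 0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_values_always_in_unit_interval(self, full_atlas, seed):
        for m in render_gm_probability_maps(2, full_atlas, seed=seed,
                                            amplitude=0.3):
            assert m.min() >= 0.0 and m.max() <= 1.0

    def test_deterministic_given_seed(self, full_atlas):
        a = render_gm_probability_maps(2, full_atlas, seed=8)
        b = render_gm_probability_maps(2, full_atlas, seed=8)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_n_must_be_positive(self, full_atlas):
        with pytest.raises(ValueError):
            render_gm_probability_maps(0, full_atlas)


def test_default_mixture_tails_match_published_positivity():
    """Mixture-implied P(composite > 1.41) sits near the published rates."""
    mixes = default_mixtures()
    assert mixes["ad"].tail_above(1.41) == pytest.approx(0.90, abs=0.05)
    assert mixes["mci"].tail_above(1.41) == pytest.approx(0.65, abs=0.05)
    assert mixes["control"].tail_above(1.41) == pytest.approx(5 / 51, abs=0.03)
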