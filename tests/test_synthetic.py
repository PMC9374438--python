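"""Generator: determinism, degenerate limits, renewal statistics and
ground-truth feature laws."""

import numpy as np
import pytest

from plumeloc import (
    OdorTimeSeries,
    compute_features,
    generate_plume,
    ground_truth_laws,
)
from plumeloc.synthetic import (
    ConfigurationError,
    PlumeConfig,
    concentrated_config,
    dilute_config,
)


def small_config(**kw):
    base = dict(
        domain_length=16.0,
        grid_shape=(16, 5),
        n_frames=2000,
        whiff_duration_law=(5.0, 0.0),
        blank_duration_law=(15.0, 0.0),
        sparsity_profile="custom",
        seed=7,
    )
    base.update(kw)
    return PlumeConfig(**base)


class TestValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"domain_length": -1.0},
            {"grid_shape": (0, 3)},
            {"n_frames": 0},
            {"dt": 0.0},
            {"cone_half_angle": 2.0},
            {"intensity_decay_exponent": -0.1},
            {"whiff_duration_law": (0.0, 0.0)},
            {"height_factor": -1.0},
            {"sparsity_profile": "bogus"},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            small_config(**kw)


def test_seed_determinism():
    a = generate_plume(small_config())
    b = generate_plume(small_config())
    np.testing.assert_array_equal(a.concentration, b.concentration)
    c = generate_plume(small_config(seed=8))
    assert not np.array_equal(a.concentration, c.concentration)


def test_out_of_cone_cells_are_zero():
    plume = generate_plume(small_config())
    mask = plume.config.cone_mask()
    assert np.all(plume.concentration[~mask] == 0)
    # in-cone cells carry signal
    assert np.all(plume.concentration[mask].max(axis=-1) > 0)


def test_no_blanks_limit():
    """Vanishing blank duration degenerates into a never-off signal."""
    plume = generate_plume(small_config(blank_duration_law=(0.0, 0.0)))
    mask = plume.config.cone_mask()
    assert np.all(plume.concentration[mask] > 0)


def test_flat_whiffs_without_decay_or_dispersion():
    """alpha=0, sigma_ln=0, no height scaling: every whiff sample is c0."""
    plume = generate_plume(
        small_config(
            intensity_decay_exponent=0.0,
            lognormal_dispersion=0.0,
            source_intensity=2.5,
        )
    )
    vals = plume.concentration[plume.config.cone_mask()]
    nonzero = vals[vals > 0]
    np.testing.assert_allclose(nonzero, 2.5)


def test_intermittency_matches_renewal_theory():
    """Long-run duty cycle approaches tau_w/(tau_w+tau_b) per cell."""
    cfg = small_config(n_frames=10000)
    plume = generate_plume(cfg)
    mask = cfg.cone_mask()
    phi_emp = (plume.concentration > 0).mean(axis=-1)[mask]
    # discretization-corrected expectation and its renewal-CLT spread
    mw = float(cfg.discrete_whiff_mean(5.0))
    mb = float(cfg.discrete_blank_mean(5.0))
    phi = mw / (mw + mb)
    n_cycles = cfg.n_frames * cfg.dt / (mw + mb)
    se = np.sqrt(phi * (1 - phi) / n_cycles)
    # continuous-time expectation 5/(5+15)=0.25 holds within 3 SE per cell
    assert np.all(np.abs(phi_emp - 0.25) < 3 * se + abs(phi - 0.25))
    # the cell-averaged duty cycle pins down the discretized law sharply
    assert abs(phi_emp.mean() - phi) < 3 * se / np.sqrt(mask.sum())


def test_centerline_intensity_nonincreasing():
    """With alpha>0 the mean in-whiff concentration decays downwind."""
    cfg = small_config(intensity_decay_exponent=1.0, lognormal_dispersion=0.2)
    plume = generate_plume(cfg)
    j_mid = cfg.grid_shape[1] // 2
    means = []
    for i in range(cfg.grid_shape[0]):
        s = plume.concentration[i, j_mid]
        means.append(s[s > 0].mean())
    means = np.array(means)
    envelope = cfg.envelope(plume.z1)
    assert np.all(np.diff(envelope) <= 0)
    # empirical means track the envelope: strong rank agreement
    from scipy.stats import spearmanr

    assert spearmanr(plume.z1, means).statistic < -0.9


def test_height_factor_increases_sparsity():
    """Raising the sampling plane makes the dilute plume sparser."""
    lo = generate_plume(dilute_config(seed=3, height_factor=0.0))
    hi = generate_plume(dilute_config(seed=3, height_factor=2.0))
    mask = lo.config.cone_mask()
    phi_lo = (lo.concentration > 0).mean(axis=-1)[mask].mean()
    phi_hi = (hi.concentration > 0).mean(axis=-1)[mask].mean()
    assert phi_hi < phi_lo
    # and the odor weaker
    assert hi.concentration.max() < lo.concentration.max()


class TestGroundTruthLaws:
    def test_memory_shorter_than_dt_rejected(self):
        with pytest.raises(ConfigurationError):
            ground_truth_laws(small_config(), memory=0.5)

    def test_zero_dispersion_mean_equals_envelope(self):
        cfg = small_config(lognormal_dispersion=0.0, intensity_decay_exponent=1.0)
        laws = ground_truth_laws(cfg, memory=100.0)
        y = np.array([2.0, 5.0, 10.0])
        np.testing.assert_allclose(laws.g(1, y), cfg.envelope(y))

    def test_homogeneous_process_has_flat_timing_laws(self):
        laws = ground_truth_laws(small_config(), memory=100.0)
        y = np.linspace(2.0, 15.0, 8)
        for k in (3, 4, 5):
            vals = laws.g(k, y)
            np.testing.assert_allclose(vals, vals[0])

    def test_g1_and_g5_against_monte_carlo(self):
        """Window-averaged features over 10^4 windows match the stated laws
        within 3 standard errors (features of the raw on/off state)."""
        y_target = 8.0
        memory = 100
        cfg = PlumeConfig(
            domain_length=2 * y_target,
            grid_shape=(1, 1),
            n_frames=memory * 10_000,
            whiff_duration_law=(5.0, 0.0),
            blank_duration_law=(15.0, 0.0),
            sparsity_profile="custom",
            intensity_decay_exponent=0.8,
            lognormal_dispersion=0.4,
            r_min=1.0,
            seed=11,
        )
        plume = generate_plume(cfg)
        laws = ground_truth_laws(cfg, memory=float(memory))
        series = plume.concentration[0, 0]
        x1s, x5s = [], []
        for w in range(series.size // memory):
            window = OdorTimeSeries(series[w * memory : (w + 1) * memory])
            fv = compute_features(window, cthr=0.0)
            if fv.valid:
                x1s.append(fv.x1)
                x5s.append(fv.x5)
        x1s, x5s = np.array(x1s), np.array(x5s)
        for emp, k in ((x1s, 1), (x5s, 5)):
            se = emp.std(ddof=1) / np.sqrt(emp.size)
            assert abs(emp.mean() - float(laws.g(k, y_target))) < 3 * se
        # the delta-method dispersion law is a usable approximation
        assert 0.5 < x5s.std() / float(laws.s(5, y_target)) < 2.0


def test_profiles_have_documented_sparsity_direction():
    """Both profiles are sparsest near the source (duty cycle rises
    downwind); intensity decay dominates the concentrated profile while the
    sparsity gradient dominates the dilute one."""
    y = np.linspace(4.0, 60.0, 12)
    dil = dilute_config()
    conc = concentrated_config()
    phi_d = dil.intermittency(y)
    phi_c = conc.intermittency(y)
    assert np.all(np.diff(phi_d) > 0)
    assert np.all(np.diff(phi_c) > 0)
    assert phi_d[-1] - phi_d[0] > phi_c[-1] - phi_c[0]
    conc_env = conc.envelope(y)
    dil_env = dil.envelope(y)
    assert conc_env[0] / conc_env[-1] > 10 * dil_env[0] / dil_env[-1]
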