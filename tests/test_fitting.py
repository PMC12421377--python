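"""Kd estimation from titration curves: recovery, flags, bootstrap, I/O."""

import random

import numpy as np
import pytest

from pasbind.fitting import (
    TitrationCurve,
    TitrationPoint,
    estimate_uncertainty,
    fit_competition,
    fit_curve,
    fit_direct,
    predict_anisotropy,
    read_curve,
    write_curve,
)
from pasbind.simulate import (
    AssayDesign,
    competition_design,
    direct_design,
    simulate_competition_curve,
    simulate_direct_curve,
)


class TestPredictAnisotropy:
    def test_endpoints(self):
        assert predict_anisotropy(0.0, 0.05, 0.20) == 0.05
        assert predict_anisotropy(1.0, 0.05, 0.20) == 0.20

    def test_linear_midpoint(self):
        assert predict_anisotropy(0.5, 0.05, 0.20) == pytest.approx(0.125)

    def test_intensity_weighting(self):
        # Q=2: (2*0.5*0.2 + 0.5*0.05) / (2*0.5 + 0.5) = 0.225/1.5
        assert predict_anisotropy(0.5, 0.05, 0.20, intensity_ratio=2.0) == pytest.approx(0.15)

    def test_domain(self):
        with pytest.raises(ValueError):
            predict_anisotropy(1.5, 0.05, 0.2)
        with pytest.raises(ValueError):
            predict_anisotropy(0.5, 0.05, 0.2, intensity_ratio=0)


@pytest.mark.parametrize("kind,kd_true", [
    ("direct", 19.0),
    ("competition", 40.0),
    ("competition", 13000.0),
])
def test_noiseless_recovery(kind, kd_true):
    """Noiseless fits recover the generating parameters to 1e-6 relative."""
    if kind == "direct":
        curve = simulate_direct_curve(direct_design(noise_sd=0.0), kd_true)
        res = fit_direct(curve)
    else:
        curve = simulate_competition_curve(competition_design(noise_sd=0.0), 19.0, kd_true)
        res = fit_competition(curve)
    assert res.converged
    assert res.kd_hat == pytest.approx(kd_true, rel=1e-6)
    assert res.r_free_hat == pytest.approx(0.05, rel=1e-6)
    assert res.r_bound_hat == pytest.approx(0.20, rel=1e-6)
    assert res.rss < 1e-16


def test_refit_own_predictions_gives_zero_rss():
    curve = simulate_competition_curve(competition_design(seed=4), 19.0, 500.0)
    res = fit_competition(curve)
    # rebuild a noiseless curve at the fitted parameters and refit it
    design = competition_design(noise_sd=0.0)
    clean = simulate_competition_curve(design, 19.0, res.kd_hat,
                                       r_free=res.r_free_hat, r_bound=res.r_bound_hat)
    res2 = fit_competition(clean)
    assert res2.rss < 1e-16
    assert res2.kd_hat == pytest.approx(res.kd_hat, rel=1e-6)


def test_constant_signal_flagged_unidentifiable():
    points = [TitrationPoint(t, 0.1, r) for t in (1, 2, 4, 8, 16, 32) for r in (1, 2)]
    curve = TitrationCurve(assay_kind="direct", probe_total=3.0, points=points)
    res = fit_direct(curve)
    assert not res.converged
    assert "constant_signal" in res.flags


def test_truncated_range_gives_lower_bound_flag():
    """A competitor series stopping at 5 uM cannot resolve a 13 uM Kd."""
    design = AssayDesign(probe_total=3.0, receptor_total=30.0,
                         titrant_max=5000.0, titrant_min=0.5, noise_sd=0.0)
    curve = simulate_competition_curve(design, 19.0, 13000.0)
    res = fit_competition(curve)
    assert "lower_bound_only" in res.flags


def test_full_range_is_identifiable():
    curve = simulate_competition_curve(competition_design(noise_sd=0.0), 19.0, 13000.0)
    assert "lower_bound_only" not in fit_competition(curve).flags


def test_fit_invariant_to_point_order_and_replicate_labels():
    curve = simulate_competition_curve(competition_design(seed=9), 19.0, 800.0)
    res = fit_competition(curve)
    shuffled = list(curve.points)
    random.Random(0).shuffle(shuffled)
    relabeled = [TitrationPoint(p.titrant, p.anisotropy, {1: 3, 2: 1, 3: 2}[p.replicate_id])
                 for p in shuffled]
    curve2 = TitrationCurve(assay_kind="competition", probe_total=3.0,
                            receptor_total=30.0, kd_probe=19.0, points=relabeled)
    res2 = fit_competition(curve2)
    assert res2.kd_hat == res.kd_hat
    assert res2.rss == res.rss


def test_noisy_direct_median_recovery():
    """Median recovered Kd over 50 seeded noisy triplicate runs within 15%."""
    ests = []
    for seed in range(50):
        curve = simulate_direct_curve(direct_design(seed=seed), 19.0)
        res = fit_direct(curve)
        assert res.converged
        ests.append(res.kd_hat)
    assert abs(np.median(ests) - 19.0) / 19.0 < 0.15


def test_assay_kind_mismatch_rejected():
    curve = simulate_direct_curve(direct_design(noise_sd=0.0), 19.0)
    with pytest.raises(ValueError):
        fit_competition(curve)


class TestBootstrap:
    def test_noiseless_se_near_zero(self):
        curve = simulate_direct_curve(direct_design(noise_sd=0.0), 19.0)
        res = fit_direct(curve)
        ses = estimate_uncertainty(curve, res, n_boot=20, seed=0)
        assert ses["log10_kd"] < 1e-6
        assert res.standard_errors is ses

    def test_deterministic_given_seed(self):
        curve = simulate_direct_curve(direct_design(seed=2), 19.0)
        res = fit_direct(curve)
        a = estimate_uncertainty(curve, res, n_boot=30, seed=7)
        b = estimate_uncertainty(curve, res, n_boot=30, seed=7)
        assert a == b

    def test_rejects_tiny_n_boot(self):
        curve = simulate_direct_curve(direct_design(seed=2), 19.0)
        res = fit_direct(curve)
        with pytest.raises(ValueError):
            estimate_uncertainty(curve, res, n_boot=1, seed=0)

    def test_se_shrinks_with_replicates(self):
        """Mean bootstrap SE of log10 Kd decreases as replicates go 1 -> 3 -> 10."""
        mean_se = {}
        for n_rep in (1, 3, 10):
            ses = []
            for seed in range(20):
                curve = simulate_direct_curve(
                    direct_design(seed=seed, n_replicates=n_rep), 19.0)
                res = fit_direct(curve)
                if not res.converged:
                    continue
                ses.append(estimate_uncertainty(curve, res, n_boot=30, seed=seed)["log10_kd"])
            mean_se[n_rep] = np.mean(ses)
        assert mean_se[1] > mean_se[3] > mean_se[10]


def test_curve_file_round_trip(tmp_path):
    curve = simulate_competition_curve(competition_design(seed=11), 19.0, 250.0)
    path = tmp_path / "curve.tsv"
    write_curve(curve, path)
    back = read_curve(path)
    assert back.assay_kind == "competition"
    assert back.probe_total == curve.probe_total
    assert back.receptor_total == curve.receptor_total
    assert back.kd_probe == curve.kd_probe
    assert [(p.titrant, p.anisotropy, p.replicate_id) for p in back.points] == [
        (p.titrant, p.anisotropy, p.replicate_id) for p in curve.points
    ]
    assert fit_competition(back).kd_hat == fit_competition(curve).kd_hat


def test_curve_requires_metadata():
    points = [TitrationPoint(t, 0.1, 1) for t in (1, 2, 4, 8, 16, 32)]
    with pytest.raises(ValueError):
        TitrationCurve(assay_kind="competition", probe_total=3.0, points=points)
    with pytest.raises(ValueError):
        TitrationCurve(assay_kind="direct", probe_total=3.0, points=points[:3])
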