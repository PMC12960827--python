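"""Receptor composites, spin nulls, participation and dominance."""

import numpy as np
import pandas as pd
import pytest

from boldvar.containers import RECEPTOR_ANNOTATIONS, ReceptorPanel, RegionalMap
from boldvar.multiscale import (
    class_density,
    cross_sample_consistency,
    dominance_analysis,
    ei_ratio,
    hungarian_spins,
    metric_correlation_matrix,
    participation_coefficient,
    receptor_entropy,
    spin_correlation_test,
)
from boldvar.synthetic import make_parcellation, simulate_receptor_panel, simulate_regional_maps

RECEPTORS = list(RECEPTOR_ANNOTATIONS["receptor"])


def _panel(values: np.ndarray) -> ReceptorPanel:
    return ReceptorPanel(
        densities=pd.DataFrame(values, columns=RECEPTORS,
                               index=np.arange(1, len(values) + 1))
    )


def test_entropy_bounds_and_composition_sensitivity():
    # one region has all receptors at their maximum -> every term 0 -> H = 0
    vals = np.vstack([np.ones(13), np.full(13, 0.3)])
    H = receptor_entropy(_panel(vals)).values
    assert H[0] == pytest.approx(0.0, abs=1e-12)
    # densities of 1/e maximize -d log d per receptor: H = 13*(1/e)/log(13)
    vals = np.vstack([np.ones(13), np.full(13, np.exp(-1))])
    H = receptor_entropy(_panel(vals)).values
    assert H[1] == pytest.approx(13 * np.exp(-1) / np.log(13), abs=1e-12)


def test_ei_ratio_and_class_density_manual_case():
    vals = np.vstack([np.ones(13), np.ones(13)])
    panel = _panel(vals)
    assert np.allclose(ei_ratio(panel).values, 1.0)
    assert np.allclose(class_density(panel, "ionotropic").values, 1.0)
    # doubling every excitatory receptor in region 2 doubles its E/I ratio
    exc = [RECEPTORS.index(r) for r in panel.receptors_with("effect", "excitatory")]
    vals2 = vals.copy()
    vals2[1, exc] = 2.0
    panel2 = _panel(vals2)
    r = ei_ratio(panel2, normalized=False).values
    assert r[1] == pytest.approx(2 * r[0], abs=1e-12)
    with pytest.raises(ValueError, match="ionotropic"):
        class_density(panel, "nuclear")


def test_spins_are_hemisphere_preserving_bijections():
    parc = make_parcellation(40, seed=1)
    nulls = hungarian_spins(parc, n_spins=25, seed=2)
    assert nulls.permutations.shape == (25, 40)
    for perm in nulls.permutations:
        assert np.array_equal(np.sort(perm), np.arange(40))  # bijective
        assert np.array_equal(parc.hemisphere[perm], parc.hemisphere)
    # deterministic per seed
    again = hungarian_spins(parc, n_spins=25, seed=2)
    assert np.array_equal(nulls.permutations, again.permutations)


def test_spins_preserve_spatial_autocorrelation():
    parc = make_parcellation(120, seed=0)
    nulls = hungarian_spins(parc, n_spins=50, seed=3)
    (m,) = simulate_regional_maps(parc, 0.5, 1, seed=4)
    aligned = parc.aligned_centroids
    d = np.arccos(np.clip(aligned @ aligned.T, -1, 1))
    near = (d < 0.4) & (d > 0)

    def moran_like(v):
        z = (v - v.mean()) / v.std()
        return np.outer(z, z)[near].mean()

    original = moran_like(m.values)
    spun = np.mean([moran_like(m.values[p]) for p in nulls.permutations])
    assert spun > 0.75 * original  # smoothness survives the spin


def test_spin_test_detects_true_association():
    parc = make_parcellation(100, seed=0)
    nulls = hungarian_spins(parc, n_spins=200, seed=5)
    (a,) = simulate_regional_maps(parc, 0.5, 1, seed=6)
    rng = np.random.default_rng(7)
    b = RegionalMap(values=a.values + 0.3 * rng.standard_normal(100))
    r, p = spin_correlation_test(a, b, nulls)
    assert r > 0.9
    assert p == pytest.approx(1 / 201, abs=1e-12)  # smoothed minimum, never 0
    with pytest.raises(ValueError, match="constant"):
        spin_correlation_test(a, RegionalMap(values=np.ones(100)), nulls)


def test_cross_sample_consistency_fisher_z():
    a = np.array([0.1, 0.5, 0.9, -0.3])
    assert cross_sample_consistency(a, a) == pytest.approx(1.0, abs=1e-12)
    assert cross_sample_consistency(a, -a) == pytest.approx(-1.0, abs=1e-12)
    # tolerates |r| = 1 without overflow
    assert np.isfinite(cross_sample_consistency([1.0, 0.2, -0.5], [0.9, 0.1, -0.4]))
    with pytest.raises(ValueError):
        cross_sample_consistency([0.1, 0.2], [0.3, 0.4])


def test_participation_coefficient_closed_forms_and_isolated_nodes():
    # star node into communities sized per the closed form
    W = np.array(
        [
            [0, 1, 1, 1, 1],
            [1, 0, 0, 0, 0],
            [1, 0, 0, 0, 0],
            [1, 0, 0, 0, 0],
            [1, 0, 0, 0, 0],
        ],
        float,
    )
    pc = participation_coefficient(W, ["a", "a", "b", "b", "c"])
    # k=4, per-community strengths 1,2,1 -> 1 - (1+4+1)/16 = 0.625
    assert pc[0] == pytest.approx(0.625, abs=1e-12)
    W2 = np.zeros((4, 4))
    W2[0, 1] = W2[1, 0] = 1.0
    with pytest.warns(UserWarning, match="isolated"):
        pc2 = participation_coefficient(W2, ["a", "b", "a", "b"])
    assert pc2[2] == 0.0 and pc2[3] == 0.0
    with pytest.raises(ValueError, match="symmetric"):
        participation_coefficient(np.arange(9.0).reshape(3, 3), ["a", "b", "a"])


def test_dominance_weights_sum_to_full_r2_with_correlated_predictors():
    rng = np.random.default_rng(9)
    n = 300
    X = rng.standard_normal((n, 4))
    X[:, 1] += 0.7 * X[:, 0]  # correlated predictors
    y = X @ np.array([1.0, 0.5, 0.2, 0.0]) + rng.standard_normal(n)
    tab = dominance_analysis(X, y)
    assert tab["dominance_weight"].sum() == pytest.approx(
        tab["full_r2"].iloc[0], abs=1e-10
    )
    assert (tab["dominance_weight"] >= -1e-12).all()
    # strongest true predictor dominates
    assert tab["dominance_weight"].idxmax() == 0
    with pytest.raises(ValueError, match="rank"):
        dominance_analysis(np.repeat(X[:, :1], 2, axis=1), y)
    with pytest.raises(ValueError, match="constant"):
        dominance_analysis(X, np.zeros(n))


def test_metric_correlation_matrix_structure():
    parc = make_parcellation(60, seed=3)
    maps = simulate_regional_maps(parc, 0.5, 3, seed=8)
    panel = simulate_receptor_panel(parc, seed=9)
    maps.append(receptor_entropy(panel))
    nulls = hungarian_spins(parc, n_spins=100, seed=10)
    corr, pvals = metric_correlation_matrix(maps, nulls=nulls, variability_indices=(0,))
    assert corr.shape == (4, 4) and pvals.shape == (4, 4)
    assert np.allclose(np.diag(corr), 1.0)
    assert pvals.iloc[0, 1:].notna().all()  # variability row tested
    assert pvals.iloc[2, 3:].isna().all()  # non-variability pairs untested
    assert np.isnan(pvals.iloc[0, 0])
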