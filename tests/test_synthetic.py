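"""Synthetic data generators: geometry, ground truth, simulators."""

import numpy as np
import pytest
from scipy import stats

from boldvar.synthetic import (
    ACQUISITION_PROFILES,
    linear_age_dampening,
    make_dynamics_ground_truth,
    make_parcellation,
    simulate_bold_dataset,
    simulate_receptor_panel,
    simulate_regional_maps,
)


def test_acquisition_profiles_match_study_designs():
    assert ACQUISITION_PROFILES["young1"][:2] == (200, 3.0)
    assert ACQUISITION_PROFILES["young2"][:2] == (399, 1.4)
    assert ACQUISITION_PROFILES["lifespan1"][:2] == (297, 2.0)
    assert ACQUISITION_PROFILES["lifespan2"][:2] == (399, 1.4)


def test_parcellation_geometry_and_networks():
    parc = make_parcellation(30, seed=5)
    assert np.allclose(np.linalg.norm(parc.centroids, axis=1), 1.0, atol=1e-9)
    assert (parc.hemisphere == "L").sum() == 15
    assert (parc.hemisphere == "R").sum() == 15
    assert len(set(parc.network7)) == 7
    # fine networks merge into their principal network by prefix
    for lab17, lab7 in zip(parc.network17, parc.network7):
        assert lab17.startswith(lab7)
        assert parc.map17to7[lab17] == lab7
    # homotopic pairs sit close together in the mirror-aligned space
    aligned = parc.aligned_centroids
    d = np.linalg.norm(aligned[:15] - aligned[15:30], axis=1)
    assert d.max() < 0.5


def test_parcellation_is_deterministic_per_seed():
    a = make_parcellation(16, seed=9)
    b = make_parcellation(16, seed=9)
    assert np.allclose(a.centroids, b.centroids)
    assert np.array_equal(a.network17, b.network17)
    c = make_parcellation(16, seed=10)
    assert not np.allclose(a.centroids, c.centroids)


def test_parcellation_input_validation():
    with pytest.raises(ValueError):
        make_parcellation(1)
    with pytest.raises(ValueError, match="per coarse network"):
        make_parcellation(5, n_networks7=7)


def test_ground_truth_unit_variance_and_spread_semantics():
    parc = make_parcellation(12, seed=0)
    gt = make_dynamics_ground_truth(parc, per_region_spread=0.3, seed=1)
    assert gt.state_covariances.shape == (8, 12, 12)
    for C in gt.state_covariances:
        assert np.allclose(np.diag(C), 1.05, atol=1e-12)  # unit signal + 0.05
    # zero spread -> identical loading directions -> identical states
    gt0 = make_dynamics_ground_truth(parc, per_region_spread=0.0, seed=1)
    assert np.allclose(gt0.state_covariances[0], gt0.state_covariances[1])
    # larger spread -> larger across-state fluctuation of covariance rows
    gt5 = make_dynamics_ground_truth(parc, per_region_spread=0.5, seed=1)
    fluct = lambda g: np.linalg.norm(
        g.state_covariances - g.state_covariances.mean(axis=0)
    )
    assert fluct(gt5) > fluct(gt)


def test_age_dampening_is_monotone_and_bounded():
    damp = linear_age_dampening(age_min=18, age_max=90, floor=0.3)
    assert damp(18) == pytest.approx(1.0)
    assert damp(90) == pytest.approx(0.3)
    assert damp(10) == pytest.approx(1.0)  # clipped below
    ages = np.linspace(18, 90, 10)
    vals = [damp(a) for a in ages]
    assert all(x >= y for x, y in zip(vals, vals[1:]))


def test_bold_dataset_shapes_ages_and_determinism():
    parc = make_parcellation(10, seed=0)
    gt = make_dynamics_ground_truth(parc, seed=1)
    runs = simulate_bold_dataset(parc, "young1", 4, gt, seed=7)
    assert len(runs) == 4
    for r in runs:
        assert r.data.shape == (10, 200)
        assert r.tr_s == 3.0
        assert 18.0 <= r.age <= 34.0
    again = simulate_bold_dataset(parc, "young1", 4, gt, seed=7)
    assert np.allclose(runs[0].data, again[0].data)
    with pytest.raises(ValueError, match="unknown profile"):
        simulate_bold_dataset(parc, "nope", 2, gt)


def test_gp_maps_are_standardized_and_length_controls_smoothness():
    parc = make_parcellation(60, seed=2)
    rough = simulate_regional_maps(parc, 0.05, 3, seed=4)
    smooth = simulate_regional_maps(parc, 2.0, 3, seed=4)
    aligned = parc.aligned_centroids
    d = np.arccos(np.clip(aligned @ aligned.T, -1, 1))
    near = (d < 0.4) & (d > 0)

    def mean_neighbor_corr(maps):
        out = []
        for m in maps:
            assert m.values.mean() == pytest.approx(0.0, abs=1e-12)
            assert m.values.std() == pytest.approx(1.0, abs=1e-12)
            prod = np.outer(m.values, m.values)
            out.append(prod[near].mean())
        return np.mean(out)

    assert mean_neighbor_corr(smooth) > mean_neighbor_corr(rough) + 0.3


def test_receptor_panel_positive_and_seeded():
    parc = make_parcellation(14, seed=0)
    panel = simulate_receptor_panel(parc, seed=3)
    assert panel.densities.shape == (14, 13)
    assert (panel.densities.to_numpy() > 0).all()
    again = simulate_receptor_panel(parc, seed=3)
    assert np.allclose(panel.densities, again.densities)
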