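"""Windowing, filtering, Rv algebra, compromise and hull scores."""

import numpy as np
import pytest

from boldvar.containers import ParcellatedRun
from boldvar.covstatis import (
    ConnectivityStack,
    WindowSpec,
    count_windows,
    fit_compromise,
    global_variability,
    hull_area,
    leonardi_highpass,
    partial_projection,
    rv_coefficient,
    window_width_trs,
    windowed_connectivity,
)


def test_window_width_rounds_halves_away_from_zero():
    assert window_width_trs(45.0, 2.0) == 23  # 22.5 -> 23, not banker's 22
    assert window_width_trs(45.0, 3.0) == 15
    assert window_width_trs(100.0, 1.4) == 71  # 71.43 -> 71
    with pytest.raises(ValueError, match="fewer than 2"):
        window_width_trs(2.0, 3.0)
    with pytest.raises(ValueError):
        window_width_trs(-45.0, 2.0)


def test_count_windows_step_and_bounds():
    assert count_windows(200, 20) == 181
    assert count_windows(200, 20, step_trs=5) == 37
    assert count_windows(20, 20) == 1
    with pytest.raises(ValueError, match="exceeds"):
        count_windows(10, 20)


def test_window_spec_warns_outside_recommended_range():
    with pytest.warns(UserWarning, match="45-100"):
        WindowSpec(window_s=30.0)
    with pytest.raises(ValueError, match="square"):
        WindowSpec(window_s=60.0, shape="gaussian")


def test_highpass_removes_slow_and_keeps_fast_oscillations():
    tr = 2.0
    t = np.arange(2000) * tr
    slow = np.sin(2 * np.pi * 0.005 * t)  # below 1/45 Hz cutoff
    fast = np.sin(2 * np.pi * 0.1 * t)
    run = ParcellatedRun(subject_id="x", tr_s=tr, data=np.vstack([slow, fast]))
    filtered = leonardi_highpass(run, 45.0)
    assert filtered.data[0].std() / slow.std() < 0.01
    assert filtered.data[1].std() / fast.std() == pytest.approx(1.0, abs=0.01)
    # constant series maps to (numerically) zero
    const = ParcellatedRun(subject_id="c", tr_s=tr, data=np.full((1, 500), 4.0))
    assert np.allclose(leonardi_highpass(const, 45.0).data, 0.0, atol=1e-9)
    with pytest.raises(ValueError, match="Nyquist"):
        leonardi_highpass(run, 1.0)


def test_windowed_connectivity_tables_are_valid_correlations():
    rng = np.random.default_rng(0)
    run = ParcellatedRun(subject_id="s", tr_s=2.0, data=rng.standard_normal((5, 100)))
    spec = WindowSpec(window_s=46.0)
    stack = windowed_connectivity(run, spec)
    assert stack.n_windows == count_windows(100, 23)
    for C in stack.tables:
        assert np.allclose(np.diag(C), 1.0)
        assert np.allclose(C, C.T)
        assert np.abs(C).max() <= 1.0
    # first table equals the plain correlation of the first window
    assert np.allclose(stack.tables[0], np.corrcoef(run.data[:, :23]), atol=1e-12)


def test_windowed_connectivity_flags_zero_variance_region():
    rng = np.random.default_rng(1)
    data = rng.standard_normal((3, 60))
    data[2] = 5.0  # constant region
    run = ParcellatedRun(subject_id="s", tr_s=2.0, data=data)
    with pytest.warns(UserWarning, match="zero-variance"):
        stack = windowed_connectivity(run, WindowSpec(window_s=46.0))
    assert np.allclose(stack.tables[:, 2, :2], 0.0)
    assert np.allclose(stack.tables[:, 2, 2], 1.0)


def test_rv_coefficient_properties():
    rng = np.random.default_rng(2)
    A = rng.standard_normal((5, 5))
    A = A @ A.T
    B = rng.standard_normal((5, 5))
    B = B @ B.T
    assert rv_coefficient(A, A) == pytest.approx(1.0, abs=1e-12)
    rv = rv_coefficient(A, B)
    assert 0.0 <= rv <= 1.0  # PSD inputs
    assert rv_coefficient(A, B, squared=True) == pytest.approx(rv**2, abs=1e-12)
    assert rv_coefficient(A, 3.0 * B) == pytest.approx(rv, abs=1e-12)  # scale-free
    with pytest.raises(ValueError, match="symmetric"):
        rv_coefficient(np.arange(4.0).reshape(2, 2), np.eye(2))
    with pytest.raises(ValueError, match="zero"):
        rv_coefficient(np.zeros((2, 2)), np.eye(2))


def test_compromise_weights_and_projection_shapes():
    rng = np.random.default_rng(3)
    runs = [
        ParcellatedRun(subject_id=f"s{i}", tr_s=2.0, data=rng.standard_normal((6, 90)))
        for i in range(3)
    ]
    spec = WindowSpec(window_s=46.0)
    stacks = [windowed_connectivity(r, spec) for r in runs]
    model = fit_compromise(stacks)
    assert model.table_weights.sum() == pytest.approx(1.0, abs=1e-10)
    assert (model.table_weights >= 0).all()
    assert np.all(np.diff(model.eigenvalues) <= 1e-12)  # descending
    assert (model.eigenvalues > 0).all()
    coords, mean_coords = partial_projection(stacks[0], model, n_components=2)
    assert coords.shape == (stacks[0].n_windows, 6, 2)
    assert mean_coords.shape == (6, 2)
    assert np.allclose(coords.mean(axis=0), mean_coords, atol=1e-12)
    with pytest.warns(UserWarning, match="retained"):
        partial_projection(stacks[0], model, n_components=99)


def test_hull_area_oracles_and_peeling():
    square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
    assert hull_area(square, peel_fraction=1.0) == pytest.approx(1.0, abs=1e-12)
    # an interior point changes nothing
    with_center = np.vstack([square, [0.5, 0.5]])
    assert hull_area(with_center, peel_fraction=1.0) == pytest.approx(1.0, abs=1e-12)
    # a far outlier is removed by peeling: 21 points -> drop ceil(0.05*21)=2
    cloud = np.vstack([square, np.tile([0.5, 0.5], (15, 1)),
                       [50.0, 50.0], [40.0, 40.0]])
    assert hull_area(cloud, peel_fraction=0.95) == pytest.approx(1.0, abs=1e-12)
    # degenerate clouds
    assert hull_area(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]), 1.0) == 0.0
    assert hull_area(np.array([[0.0, 0.0], [1.0, 1.0]]), 1.0) == 0.0
    with pytest.raises(ValueError, match="peel_fraction"):
        hull_area(square, peel_fraction=0.0)


def test_global_variability_returns_nonnegative_scores():
    rng = np.random.default_rng(4)
    runs = [
        ParcellatedRun(subject_id=f"s{i}", tr_s=3.0, data=rng.standard_normal((5, 200)))
        for i in range(3)
    ]
    hulls = global_variability(runs, WindowSpec(window_s=60.0))
    assert hulls.areas.shape == (3, 5)
    assert (hulls.areas >= 0).all()
    assert hulls.group_mean().shape == (5,)
    assert hulls.subject_ids == ["s0", "s1", "s2"]
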