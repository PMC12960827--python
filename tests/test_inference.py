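"""ICC, test-retest, Welch reliability and behavioral PLS."""

import numpy as np
import pandas as pd
import pingouin
import pytest

from boldvar.inference import icc_consistency_avg, pls_brain_age, welch_reliability
from boldvar.inference import test_retest as retest  # alias: not a test item


def test_icc_matches_independent_reference_implementation():
    rng = np.random.default_rng(5)
    for _ in range(5):
        n, k = 12, 4
        Y = (
            rng.standard_normal((n, 1))
            + 0.5 * rng.standard_normal((1, k))
            + 0.7 * rng.standard_normal((n, k))
        )
        icc, lo, hi = icc_consistency_avg(Y)
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(n), k),
                "raters": np.tile(np.arange(k), n),
                "ratings": Y.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            df, targets="targets", raters="raters", ratings="ratings"
        )
        row = ref[ref["Type"].isin(["ICC3k", "ICC(C,k)"])].iloc[0]
        assert icc == pytest.approx(row["ICC"], abs=1e-8)
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        assert np.allclose([lo, hi], row[ci_col], atol=0.02)


def test_icc_edge_cases():
    with pytest.warns(UserWarning, match="between-subject"):
        icc, lo, hi = icc_consistency_avg(np.tile([[1.0, 2.0]], (5, 1)))
    assert icc == 0.0
    with pytest.raises(ValueError):
        icc_consistency_avg(np.ones((2, 3)))  # too few subjects


def test_test_retest_perfect_and_planted_reliability():
    rng = np.random.default_rng(6)
    A = rng.standard_normal((10, 25))
    res = retest(A, A.copy())
    assert res.group_r == pytest.approx(1.0, abs=1e-12)
    assert res.mean_subject_r == pytest.approx(1.0, abs=1e-6)
    # degenerate case: all subject rhos identical, SE 0 -> t = inf, p = 0,
    # CI collapses on the back-transformed mean correlation
    assert res.t == np.inf and res.p == 0.0
    assert res.ci[0] == pytest.approx(1.0, abs=1e-6)

    # planted shared signal: observed correlation near its attenuation bound
    rs = []
    for _ in range(10):
        base = rng.standard_normal((25, 40))
        a = base + 1.2 * rng.standard_normal((25, 40))
        b = base + 1.2 * rng.standard_normal((25, 40))
        rs.append(retest(a, b).mean_subject_r)
    planted = 1.0 / (1.0 + 1.2**2)  # Pearson attenuation, Spearman slightly lower
    assert np.mean(rs) == pytest.approx(planted, abs=0.05)

    with pytest.raises(ValueError, match="matched"):
        retest(A, A[:, :5])


def test_welch_reliability_levels_and_alpha():
    rng = np.random.default_rng(7)
    a = rng.standard_normal((20, 6))
    b = rng.standard_normal((20, 6))
    b[:, 0] += 3.0  # one clearly shifted region
    tab = welch_reliability(a, b, level="region")
    assert list(tab["unit"]) == [str(i) for i in range(1, 7)]
    assert not tab.loc[0, "reliable"]
    assert tab.loc[1:, "reliable"].mean() > 0.5

    nets = ["x", "x", "x", "y", "y", "y"]
    net_tab = welch_reliability(a, b, level="network", networks=nets)
    assert list(net_tab["unit"]) == ["x", "y"]
    with pytest.raises(ValueError, match="network label"):
        welch_reliability(a, b, level="network")
    with pytest.raises(ValueError, match="level"):
        welch_reliability(a, b, level="voxel")


def test_pls_recovers_planted_brain_age_pattern():
    rng = np.random.default_rng(13)
    n_sub, n_reg = 40, 30
    w = np.zeros(n_reg)
    w[:10] = 1.0
    brains, ages = [], []
    for _ in range(2):
        age = rng.uniform(18, 34, n_sub)
        brains.append(
            rng.standard_normal((n_sub, n_reg))
            + 0.08 * np.outer(age - age.mean(), w)
        )
        ages.append(age)
    res = pls_brain_age(brains, ages, n_perm=300, n_boot=300, seed=3)
    assert res.perm_p[0] <= 0.05
    assert res.covariance_explained.sum() == pytest.approx(1.0, abs=1e-12)
    planted_hits = np.mean(np.abs(res.bootstrap_ratios[:10, 0]) >= res.bsr_threshold)
    assert planted_hits >= 0.7
    sc = res.score_age_correlations.query("lv == 1")
    assert (sc["r"].abs() > 0.3).all()
    # saliences are unit-norm singular vectors
    assert np.linalg.norm(res.saliences[:, 0]) == pytest.approx(1.0, abs=1e-10)


def test_pls_null_data_is_not_significant():
    rng = np.random.default_rng(21)
    brains = [rng.standard_normal((30, 15)) for _ in range(2)]
    ages = [rng.uniform(18, 34, 30) for _ in range(2)]
    res = pls_brain_age(brains, ages, n_perm=300, n_boot=100, seed=5)
    assert res.perm_p[0] > 0.05


def test_pls_input_validation():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((12, 5))
    a = rng.uniform(18, 30, 12)
    with pytest.raises(ValueError, match="region count"):
        pls_brain_age([X, X[:, :3]], [a, a])
    with pytest.raises(ValueError, match="constant age"):
        pls_brain_age([X], [np.full(12, 25.0)])
    with pytest.raises(ValueError, match="10 subjects"):
        pls_brain_age([X[:5]], [a[:5]])
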