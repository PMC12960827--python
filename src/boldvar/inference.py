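"""Validation and reliability statistics.

Consistency across window lengths is summarized with the average-measures,
consistency, two-way mixed-effects intraclass correlation ICC(3,k); test-retest
reliability with group-level correlations and within-subject Fisher-z averaged
rank correlations (one-sample t and Cohen's d on the z values); inter-sample
reliability with per-region / per-network Welch t-tests where "reliable" means
no detectable sample difference (p > 0.05); and brain-age covariance with a
behavioral partial-least-squares model (within-group brain-age correlations
stacked, singular value decomposition, permutation test on singular values,
bootstrap ratios on the region saliences).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "icc_consistency_avg",
    "TestRetestResult",
    "test_retest",
    "welch_reliability",
    "PLSResult",
    "pls_brain_age",
]

_Z_MAX = np.arctanh(1 - 1e-12)


def _fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15)).clip(-_Z_MAX, _Z_MAX)


def icc_consistency_avg(measures: np.ndarray, ci_level: float = 0.95):
    """ICC(3,k): two-way mixed effects, consistency, average of k measures.

    Returns ``(icc, ci_low, ci_high)``. Computed from the two-way ANOVA
    decomposition of the subjects-by-measures matrix: ``(MS_subj - MS_err) /
    MS_subj``; the confidence interval follows from the F ratio
    ``MS_subj / MS_err`` with ``(n-1)`` and ``(n-1)(k-1)`` degrees of freedom.
    """
    X = np.asarray(measures, dtype=float)
    if X.ndim != 2:
        raise ValueError("measures must be a subjects x k matrix")
    n, k = X.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 subjects and 2 measures")
    if not np.isfinite(X).all():
        raise ValueError("missing values are not supported")
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows <= 0:
        warnings.warn("no between-subject variance; ICC set to 0", stacklevel=2)
        return 0.0, 0.0, 0.0
    icc = (ms_rows - ms_err) / ms_rows
    alpha = 1 - ci_level
    if ms_err == 0:
        return float(icc), float(icc), float(icc)
    F = ms_rows / ms_err
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_upper = stats.f.ppf(1 - alpha / 2, df1, df2)
    f_lower = stats.f.ppf(1 - alpha / 2, df2, df1)
    lo = 1 - 1 / (F / f_upper)
    hi = 1 - 1 / (F * f_lower)
    return float(icc), float(lo), float(hi)


@dataclass
class TestRetestResult:
    group_r: float
    mean_subject_r: float
    t: float
    p: float
    ci: tuple[float, float]
    cohens_d: float
    subject_r: np.ndarray


def test_retest(run1_scores: np.ndarray, run2_scores: np.ndarray,
                ci_level: float = 0.95) -> TestRetestResult:
    """Test-retest reliability of subjects-by-regions score matrices.

    Group level: Pearson correlation of the two runs' group-mean regional
    vectors. Individual level: within-subject Spearman rank correlation across
    regions, Fisher-z transformed (clipped at atanh(1 - 1e-12)), averaged and
    back-transformed; a one-sample t-test contrasts the z values against zero,
    with Cohen's d = mean(z)/SD(z).
    """
    A = np.asarray(run1_scores, float)
    B = np.asarray(run2_scores, float)
    if A.shape != B.shape or A.ndim != 2:
        raise ValueError("need matched subjects x regions matrices")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for the t-test")
    group_r = float(stats.pearsonr(A.mean(axis=0), B.mean(axis=0)).statistic)
    subj_r = np.array(
        [stats.spearmanr(A[i], B[i]).statistic for i in range(n)]
    )
    z = _fisher_z(subj_r)
    mean_z = z.mean()
    sd_z = z.std(ddof=1)
    se = sd_z / np.sqrt(n)
    if se == 0:
        t_val, p_val = np.inf, 0.0
        ci = (float(np.tanh(mean_z)), float(np.tanh(mean_z)))
    else:
        t_val = mean_z / se
        p_val = 2 * stats.t.sf(abs(t_val), n - 1)
        h = stats.t.ppf(0.5 + ci_level / 2, n - 1) * se
        ci = (float(np.tanh(mean_z - h)), float(np.tanh(mean_z + h)))
    d = float(mean_z / sd_z) if sd_z > 0 else np.inf
    return TestRetestResult(
        group_r=group_r,
        mean_subject_r=float(np.tanh(mean_z)),
        t=float(t_val),
        p=float(p_val),
        ci=ci,
        cohens_d=d,
        subject_r=subj_r,
    )


def welch_reliability(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    level: str = "region",
    networks: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-region or per-network Welch t-tests between two samples.

    Inputs are subjects-by-regions matrices. At the network level all
    region-level values within a network are pooled as observations within each
    sample. A unit is flagged *reliable* when the two samples do not differ
    (p > alpha).
    """
    A = np.asarray(sample_a, float)
    B = np.asarray(sample_b, float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError("samples must be subjects x regions with equal region counts")
    if level == "region":
        units = [(str(j + 1), A[:, j], B[:, j]) for j in range(A.shape[1])]
    elif level == "network":
        if networks is None:
            raise ValueError("network-level tests need a network label per region")
        networks = np.asarray(networks, dtype=object)
        if networks.size != A.shape[1]:
            raise ValueError("one network label per region required")
        units = [
            (str(net), A[:, networks == net].ravel(), B[:, networks == net].ravel())
            for net in pd.unique(networks)
        ]
    else:
        raise ValueError("level must be 'region' or 'network'")
    rows = []
    for name, a, b in units:
        if a.size < 2 or b.size < 2:
            warnings.warn(f"unit {name}: fewer than 2 observations, skipped", stacklevel=2)
            continue
        res = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "unit": name,
                "t": float(res.statistic),
                "p": float(res.pvalue),
                "reliable": bool(res.pvalue > alpha),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PLSResult:
    singular_values: np.ndarray
    covariance_explained: np.ndarray
    saliences: np.ndarray  # (R, n_lv) region loadings
    group_weights: np.ndarray  # (G, n_lv) left singular vectors
    brain_scores: list[np.ndarray]  # per group, (S_g, n_lv)
    perm_p: np.ndarray
    bootstrap_ratios: np.ndarray  # (R, n_lv)
    bsr_threshold: float
    score_age_correlations: pd.DataFrame


def _corr_matrix(brains: list[np.ndarray], ages: list[np.ndarray]) -> np.ndarray:
    rows = []
    for X, a in zip(brains, ages):
        ac = a - a.mean()
        Xc = X - X.mean(axis=0)
        num = ac @ Xc
        den = np.sqrt((ac @ ac) * np.sum(Xc * Xc, axis=0))
        den[den == 0] = np.inf
        rows.append(num / den)
    return np.vstack(rows)


def _procrustes_rotation(V_boot: np.ndarray, V_ref: np.ndarray) -> np.ndarray:
    u, _, vt = np.linalg.svd(V_boot.T @ V_ref)
    return u @ vt


def pls_brain_age(
    brain: list[np.ndarray],
    age: list[np.ndarray],
    n_perm: int = 1000,
    n_boot: int = 1000,
    bsr_threshold: float = 2.0,
    seed: int = 0,
) -> PLSResult:
    """Behavioral PLS relating regional scores to age across groups.

    The within-group correlation of age with each region's values is stacked
    across groups (one row per group) and decomposed by SVD. Covariance
    explained per latent variable is the squared singular value over their sum;
    subject brain scores multiply each regional salience by the subject's value
    and sum. Permutations shuffle age within group; bootstrap resamples
    subjects within group, with saliences aligned to the original basis by
    orthogonal Procrustes before the bootstrap ratio (salience over bootstrap
    SE) is formed.
    """
    if len(brain) != len(age) or not brain:
        raise ValueError("brain and age must be matching non-empty group lists")
    brain = [np.asarray(X, float) for X in brain]
    age = [np.asarray(a, float).ravel() for a in age]
    R = brain[0].shape[1]
    for X, a in zip(brain, age):
        if X.ndim != 2 or X.shape[1] != R:
            raise ValueError("all groups must share the region count")
        if X.shape[0] != a.size:
            raise ValueError("ages must match subjects")
        if X.shape[0] < 10:
            raise ValueError("need at least 10 subjects per group")
        if a.std() == 0:
            raise ValueError("constant age vector")
    rng = np.random.default_rng(seed)

    M = _corr_matrix(brain, age)
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    V = Vt.T  # (R, n_lv)
    n_lv = S.size
    cov_exp = S**2 / np.sum(S**2)
    scores = [X @ V for X in brain]

    exceed = np.zeros(n_lv)
    for _ in range(n_perm):
        perm_ages = [rng.permutation(a) for a in age]
        Sp = np.linalg.svd(_corr_matrix(brain, perm_ages), compute_uv=False)
        exceed += Sp >= S
    perm_p = (1.0 + exceed) / (1.0 + n_perm)

    boot_sal = np.empty((n_boot, R, n_lv))
    boot_score_r = np.empty((n_boot, len(brain), n_lv))
    for b in range(n_boot):
        bb, ba = [], []
        for X, a in zip(brain, age):
            idx = rng.integers(X.shape[0], size=X.shape[0])
            bb.append(X[idx])
            ba.append(a[idx])
        Mb = _corr_matrix(bb, ba)
        Ub, Sb, Vbt = np.linalg.svd(Mb, full_matrices=False)
        Vb = Vbt.T
        rot = _procrustes_rotation(Vb, V)
        boot_sal[b] = Vb @ rot
        for g, (Xg, ag) in enumerate(zip(bb, ba)):
            sc = Xg @ V
            for l in range(n_lv):
                if ag.std() == 0 or sc[:, l].std() == 0:
                    boot_score_r[b, g, l] = 0.0
                else:
                    boot_score_r[b, g, l] = np.corrcoef(ag, sc[:, l])[0, 1]
    se = boot_sal.std(axis=0, ddof=1)
    se[se == 0] = np.inf
    bsr = V / se

    rows = []
    for g, (a, sc) in enumerate(zip(age, scores)):
        for l in range(n_lv):
            r = float(np.corrcoef(a, sc[:, l])[0, 1])
            lo, hi = np.percentile(boot_score_r[:, g, l], [2.5, 97.5])
            rows.append(
                {"group": g, "lv": l + 1, "r": r, "ci_low": float(lo), "ci_high": float(hi)}
            )
    return PLSResult(
        singular_values=S,
        covariance_explained=cov_exp,
        saliences=V,
        group_weights=U,
        brain_scores=scores,
        perm_p=perm_p,
        bootstrap_ratios=bsr,
        bsr_threshold=bsr_threshold,
        score_age_correlations=pd.DataFrame(rows),
    )
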