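"""Multiscale association of regional maps.

Receptor composite scores (normalized Shannon entropy of the receptor
composition, excitatory/inhibitory ratio, ionotropic/metabotropic mean
densities), spatial-autocorrelation-preserving null permutations built by
rotating parcel centroids on the sphere and re-matching parcels with the
Hungarian algorithm, map-map correlation tests against those nulls,
cross-sample comparison of Fisher-z correlation vectors, participation
coefficients quantifying how evenly a metric's associations spread over
spatial-scale communities, and dominance analysis decomposing a regression
R-squared into per-predictor contributions over all submodels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from scipy.stats import special_ortho_group

from .containers import Parcellation, ReceptorPanel, RegionalMap

__all__ = [
    "receptor_entropy",
    "ei_ratio",
    "class_density",
    "SpinNull",
    "hungarian_spins",
    "spin_correlation_test",
    "cross_sample_consistency",
    "participation_coefficient",
    "dominance_analysis",
    "metric_correlation_matrix",
]


def _normalized_densities(panel: ReceptorPanel) -> pd.DataFrame:
    D = panel.densities
    colmax = D.max(axis=0)
    if (colmax <= 0).any():
        bad = list(colmax.index[colmax <= 0])
        raise ValueError(f"receptor column(s) with no positive density: {bad}")
    return D / colmax


def receptor_entropy(panel: ReceptorPanel) -> RegionalMap:
    """Regional receptor diversity: H = -sum(d log d) / log L, 0 log 0 := 0.

    ``d`` is each receptor's density normalized to its maximum across regions
    and ``L`` the number of receptors (13). The log-ratio makes H invariant to
    the logarithm base; H is 0 when every normalized density is 1.
    """
    d = _normalized_densities(panel).to_numpy()
    L = d.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(d > 0, d * np.log(d), 0.0)
    H = -terms.sum(axis=1) / math.log(L)
    return RegionalMap(values=H, parcellation_ref=panel.parcellation_ref,
                       label="receptor-entropy")


def ei_ratio(panel: ReceptorPanel, normalized: bool = True) -> RegionalMap:
    """Mean excitatory over mean inhibitory receptor density per region.

    Densities are max-normalized by default (consistent with the entropy
    score); ``normalized=False`` uses raw densities.
    """
    D = _normalized_densities(panel) if normalized else panel.densities
    exc = panel.receptors_with("effect", "excitatory")
    inh = panel.receptors_with("effect", "inhibitory")
    inh_mean = D[inh].mean(axis=1).to_numpy()
    if (inh_mean <= 0).any():
        raise ValueError("E/I ratio undefined where the inhibitory mean is zero")
    return RegionalMap(
        values=D[exc].mean(axis=1).to_numpy() / inh_mean,
        parcellation_ref=panel.parcellation_ref,
        label="ei-ratio",
    )


def class_density(panel: ReceptorPanel, receptor_class: str,
                  normalized: bool = True) -> RegionalMap:
    """Mean density of one receptor class ('ionotropic' or 'metabotropic')."""
    if receptor_class not in {"ionotropic", "metabotropic"}:
        raise ValueError("receptor_class must be 'ionotropic' or 'metabotropic'")
    D = _normalized_densities(panel) if normalized else panel.densities
    members = panel.receptors_with("type", receptor_class)
    return RegionalMap(
        values=D[members].mean(axis=1).to_numpy(),
        parcellation_ref=panel.parcellation_ref,
        label=f"{receptor_class}-density",
    )


@dataclass
class SpinNull:
    """Hemisphere-preserving bijective region permutations."""

    permutations: np.ndarray  # (n_spins, R)
    seed: int
    parcellation_ref: str = "synthetic"

    @property
    def n_spins(self) -> int:
        return self.permutations.shape[0]


def hungarian_spins(parcellation: Parcellation, n_spins: int = 10000,
                    seed: int = 0) -> SpinNull:
    """Build spin-null permutations by sphere rotation + optimal matching.

    Per spin, one uniform random 3-D rotation is applied to the left-hemisphere
    centroids and its sagittal mirror to the right-hemisphere centroids; within
    each hemisphere the rotated parcels are re-assigned to original parcel
    slots by the exact minimum-total-distance one-to-one matching, so every
    permutation is bijective and hemisphere-preserving.
    """
    rng = np.random.default_rng(seed)
    left = np.flatnonzero(parcellation.hemisphere == "L")
    right = np.flatnonzero(parcellation.hemisphere == "R")
    if left.size < 2 or right.size < 2:
        raise ValueError("need at least 2 regions per hemisphere")
    mirror = np.diag([-1.0, 1.0, 1.0])
    C = parcellation.centroids
    perms = np.empty((n_spins, parcellation.n_regions), dtype=int)
    for s in range(n_spins):
        rot = special_ortho_group.rvs(3, random_state=rng)
        rot_r = mirror @ rot @ mirror
        for idx, Rm in ((left, rot), (right, rot_r)):
            spun = C[idx] @ Rm.T
            cost = cdist(spun, C[idx])
            src, dst = linear_sum_assignment(cost)
            # slot dst receives the value of source region src under this spin
            perms[s, idx[dst]] = idx[src]
    return SpinNull(permutations=perms, seed=seed,
                    parcellation_ref=parcellation.name)


def spin_correlation_test(map_a: RegionalMap, map_b: RegionalMap,
                          nulls: SpinNull) -> tuple[float, float]:
    """Pearson r of two maps with a two-sided spin-permutation p-value.

    Nulls permute ``map_a`` (the map whose parcellation generated the spins);
    p = (1 + #{|r_null| >= |r_obs|}) / (1 + n_spins), so never exactly 0.
    """
    a, b = map_a.values, map_b.values
    if a.size != b.size or a.size != nulls.permutations.shape[1]:
        raise ValueError("maps and nulls must share the parcellation size")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for a constant map")
    r_obs = float(stats.pearsonr(a, b).statistic)
    A = a[nulls.permutations]  # (n_spins, R)
    Ac = A - A.mean(axis=1, keepdims=True)
    bc = b - b.mean()
    num = Ac @ bc
    den = np.sqrt((Ac * Ac).sum(axis=1) * (bc @ bc))
    r_null = num / den
    p = (1.0 + np.sum(np.abs(r_null) >= abs(r_obs))) / (1.0 + nulls.n_spins)
    return r_obs, float(p)


def cross_sample_consistency(corr_vector_a: np.ndarray,
                             corr_vector_b: np.ndarray) -> float:
    """Pearson correlation of two Fisher-z transformed correlation vectors."""
    a = np.asarray(corr_vector_a, float).ravel()
    b = np.asarray(corr_vector_b, float).ravel()
    if a.size != b.size or a.size < 3:
        raise ValueError("need equal-length vectors of at least 3 correlations")
    za = np.arctanh(np.clip(a, -1 + 1e-15, 1 - 1e-15))
    zb = np.arctanh(np.clip(b, -1 + 1e-15, 1 - 1e-15))
    return float(stats.pearsonr(za, zb).statistic)


def participation_coefficient(corr_matrix: np.ndarray,
                              communities: Sequence) -> np.ndarray:
    """PC_i = 1 - sum_s (k_is / k_i)^2 on absolute weights, self-loops excluded."""
    W = np.abs(np.asarray(corr_matrix, float))
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("corr_matrix must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("corr_matrix must be symmetric")
    communities = np.asarray(communities, dtype=object)
    if communities.size != W.shape[0]:
        raise ValueError("one community label per node required")
    labels = pd.unique(communities)
    if labels.size < 2:
        raise ValueError("need at least 2 communities")
    np.fill_diagonal(W, 0.0)
    k = W.sum(axis=1)
    pc = np.zeros(W.shape[0])
    iso = k == 0
    if iso.any():
        warnings.warn("isolated node(s); participation coefficient set to 0",
                      stacklevel=2)
    ratios = np.zeros_like(pc)
    for lab in labels:
        ks = W[:, communities == lab].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratios += np.where(iso, 0.0, (ks / np.where(iso, 1.0, k)) ** 2)
    pc = np.where(iso, 0.0, 1.0 - ratios)
    return pc


def dominance_analysis(predictors: np.ndarray, response) -> pd.DataFrame:
    """General dominance weights: per-predictor share of the full-model R².

    For every predictor the incremental R² of adding it to each subset of the
    remaining predictors is averaged within subset size and then across sizes
    (all 2^p - 1 submodels are visited). Weights sum to the full-model R²;
    percentages are weights over that total.
    """
    X = np.asarray(predictors, float)
    y = np.asarray(response.values if isinstance(response, RegionalMap) else response,
                   float).ravel()
    if X.ndim != 2:
        raise ValueError("predictors must be a 2-D matrix")
    n, p = X.shape
    if p > 20:
        raise ValueError("more than 20 predictors: 2^p submodels intractable")
    if n != y.size or n <= p + 2:
        raise ValueError("need n > p + 2 observations matching the response")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    if np.linalg.matrix_rank(Xc) < p:
        raise ValueError("rank-deficient predictor matrix")
    Sxx = Xc.T @ Xc
    sxy = Xc.T @ yc
    syy = float(yc @ yc)
    if syy == 0:
        raise ValueError("constant response")

    r2 = np.zeros(1 << p)
    for size in range(1, p + 1):
        for subset in combinations(range(p), size):
            idx = list(subset)
            beta = np.linalg.solve(Sxx[np.ix_(idx, idx)], sxy[idx])
            mask = sum(1 << i for i in idx)
            r2[mask] = float(sxy[idx] @ beta) / syy

    weights = np.zeros(p)
    for i in range(p):
        bit = 1 << i
        size_sums = np.zeros(p)
        size_counts = np.zeros(p)
        for mask in range(1 << p):
            if mask & bit:
                continue
            s = bin(mask).count("1")
            size_sums[s] += r2[mask | bit] - r2[mask]
            size_counts[s] += 1
        weights[i] = np.mean(size_sums / size_counts)
    full_r2 = r2[(1 << p) - 1]
    return pd.DataFrame(
        {
            "predictor": np.arange(p),
            "dominance_weight": weights,
            "percentage": 100.0 * weights / full_r2,
        }
    ).assign(full_r2=full_r2)


def metric_correlation_matrix(
    maps: Sequence[RegionalMap],
    nulls: Optional[SpinNull] = None,
    variability_indices: Sequence[int] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise map correlations plus spin p-values for the variability rows.

    Returns ``(corr, pvals)`` as labelled DataFrames; p-values are computed
    only for pairs involving a map listed in ``variability_indices`` (spinning
    that map), and are NaN elsewhere.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    labels = [m.label or f"map{i}" for i, m in enumerate(maps)]
    M = np.vstack([m.values for m in maps])
    corr = np.corrcoef(M)
    pvals = np.full_like(corr, np.nan)
    if nulls is not None:
        for i in variability_indices:
            for j in range(len(maps)):
                if i == j:
                    continue
                _, p = spin_correlation_test(maps[i], maps[j], nulls)
                pvals[i, j] = pvals[j, i] = p
    return (
        pd.DataFrame(corr, index=labels, columns=labels),
        pd.DataFrame(pvals, index=labels, columns=labels),
    )
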