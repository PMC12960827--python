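"""Synthetic study data with known ground truth.

Everything downstream (rMSSD, covSTATIS hull areas, spin tests, receptor
composites) is exercised on data generated here: a spherical parcellation with
spatially compact networks, parcellated BOLD runs from a hidden-Markov Gaussian
model with controllable per-region connectivity dynamics and age-dampened
dynamics, spatially autocorrelated regional maps (Gaussian process on the
sphere), and a 13-receptor density panel.

The hidden-Markov generator is used instead of phase randomization because the
hull-area metric measures non-stationarity of windowed connectivity: the
generator plants region-specific between-state connectivity differences whose
magnitude downstream hull areas should recover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.stats import special_ortho_group
from sklearn.cluster import KMeans

from .containers import (
    RECEPTOR_ANNOTATIONS,
    RECEPTOR_NAMES,
    Parcellation,
    ParcellatedRun,
    ReceptorPanel,
    RegionalMap,
)

__all__ = [
    "ACQUISITION_PROFILES",
    "DynamicsGroundTruth",
    "make_parcellation",
    "make_dynamics_ground_truth",
    "linear_age_dampening",
    "simulate_bold_dataset",
    "simulate_regional_maps",
    "simulate_receptor_panel",
]

#: Acquisition profiles: (n_timepoints, tr_s, age range). Timepoint counts are
#: the acquired volumes minus the initial volumes discarded in preprocessing
#: (204 - 4 @ TR 3 s; 404 - 5 @ TR 1.4 s; 297 @ TR 2 s).
ACQUISITION_PROFILES = {
    "young1": (200, 3.0, (18.0, 34.0)),
    "young2": (399, 1.4, (18.0, 34.0)),
    "lifespan1": (297, 2.0, (20.0, 86.0)),
    "lifespan2": (399, 1.4, (20.0, 86.0)),
}

CANONICAL_NETWORKS7 = (
    "Vis",
    "SomMot",
    "DorsAttn",
    "SalVentAttn",
    "Limbic",
    "Cont",
    "Default",
)


def make_parcellation(n_regions: int, n_networks7: int = 7, seed: int = 0) -> Parcellation:
    """Build a synthetic spherical parcellation.

    As in surface-based registration, each hemisphere is represented on its own
    full unit sphere: ``ceil(R/2)`` quasi-uniform right-hemisphere centroids
    are laid out on a randomly rotated Fibonacci sphere lattice, and the
    first ``floor(R/2)`` of them -- perturbed by a small angular jitter so
    homotopic pairs are similar but not identical -- are reflected through the
    sagittal plane to give the left-hemisphere sphere. Full-sphere coverage per
    hemisphere is what makes rotation-based spin nulls near-isometries instead
    of folding points across a boundary. Coarse networks are assigned by
    k-means on the mirror-aligned coordinates, so networks are spatially
    compact and bilateral (homotopic regions share a network); each coarse
    network with at least 4 regions is split into two subnetworks (suffix A/B)
    to emulate a finer granularity that merges back into its principal network
    by name prefix.
    """
    if n_regions < 2 or n_networks7 < 1:
        raise ValueError("n_regions and n_networks7 must be positive (R >= 2)")
    if n_regions < n_networks7:
        raise ValueError("need at least one region per coarse network")
    rng = np.random.default_rng(seed)
    n_left = n_regions // 2
    n_right = n_regions - n_left
    # Quasi-uniform centroids (parcel centroids tile the cortex evenly):
    # Fibonacci sphere lattice, randomly rotated per seed.
    i = np.arange(n_right) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * np.arange(n_right)
    z = 1.0 - 2.0 * i / n_right
    r_xy = np.sqrt(1.0 - z**2)
    lattice = np.column_stack([r_xy * np.cos(phi), r_xy * np.sin(phi), z])
    right = lattice @ special_ortho_group.rvs(3, random_state=rng).T
    left_aligned = right[:n_left] + 0.08 * rng.standard_normal((n_left, 3))
    left_aligned /= np.linalg.norm(left_aligned, axis=1, keepdims=True)
    left = left_aligned * np.array([-1.0, 1.0, 1.0])
    pts = np.vstack([left, right])
    aligned = np.vstack([left_aligned, right])
    hemisphere = np.array(["L"] * n_left + ["R"] * n_right, dtype=object)

    if n_networks7 == 1:
        labels = np.zeros(n_regions, dtype=int)
    else:
        km = KMeans(
            n_clusters=n_networks7,
            n_init=4,
            random_state=int(rng.integers(2**31 - 1)),
        )
        labels = km.fit_predict(aligned)
    if n_networks7 == 7:
        names7 = CANONICAL_NETWORKS7
    else:
        names7 = tuple(f"Net{i + 1}" for i in range(n_networks7))

    network7 = np.array([names7[k] for k in labels], dtype=object)
    network17 = np.empty(n_regions, dtype=object)
    map17to7: dict = {}
    for k, name in enumerate(names7):
        idx = np.flatnonzero(labels == k)
        if idx.size >= 4:
            sub = KMeans(
                n_clusters=2, n_init=2, random_state=int(rng.integers(2**31 - 1))
            ).fit_predict(aligned[idx])
            for j, i in enumerate(idx):
                network17[i] = f"{name}{'A' if sub[j] == 0 else 'B'}"
            map17to7[f"{name}A"] = name
            map17to7[f"{name}B"] = name
        else:
            network17[idx] = f"{name}A"
            map17to7[f"{name}A"] = name

    return Parcellation(
        region_ids=np.arange(1, n_regions + 1),
        network17=network17,
        network7=network7,
        hemisphere=hemisphere,
        centroids=pts,
        map17to7=map17to7,
        name=f"synthetic-{n_regions}",
    )


@dataclass
class DynamicsGroundTruth:
    """Planted connectivity dynamics for the hidden-Markov generator.

    ``per_region_spread`` is the target relative fluctuation of each region's
    connectivity profile across states; regions with larger spread should show
    larger downstream hull areas. ``age_dampening`` maps a subject's age to a
    multiplier in (0, 1] shrinking between-state covariance differences toward
    their mean (1 = no dampening).
    """

    state_covariances: np.ndarray  # (K, R, R)
    dwell_mean_s: float
    per_region_spread: np.ndarray
    age_dampening: Optional[Callable[[float], float]] = None

    def __post_init__(self) -> None:
        self.state_covariances = np.asarray(self.state_covariances, dtype=float)
        if self.state_covariances.ndim != 3:
            raise ValueError("state_covariances must be (K, R, R)")
        K = self.state_covariances.shape[0]
        if K < 1:
            raise ValueError("need at least one state")
        self.per_region_spread = np.asarray(self.per_region_spread, dtype=float)
        if (self.per_region_spread < 0).any():
            raise ValueError("per_region_spread must be non-negative")
        if self.dwell_mean_s <= 0:
            raise ValueError("dwell_mean_s must be positive")
        for C in self.state_covariances:
            if not np.allclose(C, C.T, atol=1e-10):
                raise ValueError("state covariances must be symmetric")
            if np.linalg.eigvalsh(C).min() < -1e-8:
                raise ValueError("state covariances must be PSD")

    @property
    def n_states(self) -> int:
        return self.state_covariances.shape[0]

    @property
    def n_regions(self) -> int:
        return self.state_covariances.shape[1]


def linear_age_dampening(age_min: float = 18.0, age_max: float = 90.0,
                         floor: float = 0.3) -> Callable[[float], float]:
    """Multiplier decreasing linearly from 1 at ``age_min`` to ``floor`` at ``age_max``."""

    def damp(age: float) -> float:
        frac = np.clip((age - age_min) / (age_max - age_min), 0.0, 1.0)
        return float(1.0 - (1.0 - floor) * frac)

    return damp


def make_dynamics_ground_truth(
    parcellation: Parcellation,
    n_states: int = 8,
    per_region_spread: float | Sequence[float] = 0.3,
    dwell_mean_s: float = 45.0,
    seed: int = 0,
    n_factors: int = 4,
    age_dampening: Optional[Callable[[float], float]] = None,
) -> DynamicsGroundTruth:
    """Construct state covariances with planted per-region dynamics.

    Each state's covariance is low-rank-plus-diagonal, ``C_k = A_k A_k' +
    0.05 I`` where region ``i``'s unit loading direction in state ``k`` mixes a
    shared baseline direction with a state-specific random direction,
    ``u_ki = normalize((1 - s_i) u0_i + s_i w_ki)``. Regions with larger spread
    ``s_i`` rotate further between states, so their connectivity profile
    fluctuates more over time, while every region keeps unit signal variance.
    """
    R = parcellation.n_regions
    spread = np.broadcast_to(np.asarray(per_region_spread, float), (R,)).copy()
    rng = np.random.default_rng(seed)

    def unit_rows(M: np.ndarray) -> np.ndarray:
        return M / np.linalg.norm(M, axis=1, keepdims=True)

    U0 = unit_rows(rng.standard_normal((R, n_factors)))
    covs = np.empty((n_states, R, R))
    for k in range(n_states):
        Wk = unit_rows(rng.standard_normal((R, n_factors)))
        Ak = unit_rows((1.0 - spread[:, None]) * U0 + spread[:, None] * Wk)
        covs[k] = Ak @ Ak.T + 0.05 * np.eye(R)
    return DynamicsGroundTruth(
        state_covariances=covs,
        dwell_mean_s=dwell_mean_s,
        per_region_spread=spread,
        age_dampening=age_dampening,
    )


def simulate_bold_dataset(
    parcellation: Parcellation,
    profile: str,
    n_subjects: int,
    ground_truth: DynamicsGroundTruth,
    seed: int = 0,
    obs_noise_sd: float = 0.5,
    run_label: str = "run-1",
) -> list[ParcellatedRun]:
    """Sample parcellated BOLD runs from the hidden-Markov Gaussian model.

    States switch with exponential dwell times (mean ``dwell_mean_s``),
    observations are drawn from the active state's covariance plus white
    observation noise. Per-subject age dampening shrinks state covariances
    toward their mean: ``C_k(age) = lam * C_k + (1 - lam) * mean_k C_k``.
    """
    if profile not in ACQUISITION_PROFILES:
        raise ValueError(f"unknown profile {profile!r}; options: {sorted(ACQUISITION_PROFILES)}")
    if ground_truth.n_regions != parcellation.n_regions:
        raise ValueError("ground truth region count does not match parcellation")
    n_tp, tr_s, (age_lo, age_hi) = ACQUISITION_PROFILES[profile]
    rng = np.random.default_rng(seed)
    K = ground_truth.n_states
    mean_cov = ground_truth.state_covariances.mean(axis=0)
    runs = []
    for s in range(n_subjects):
        age = float(rng.uniform(age_lo, age_hi))
        lam = 1.0
        if ground_truth.age_dampening is not None:
            lam = float(ground_truth.age_dampening(age))
            if not 0.0 < lam <= 1.0:
                raise ValueError("age_dampening must return a multiplier in (0, 1]")
        chols = [
            np.linalg.cholesky(lam * C + (1.0 - lam) * mean_cov)
            for C in ground_truth.state_covariances
        ]
        data = np.empty((parcellation.n_regions, n_tp))
        t = 0
        state = int(rng.integers(K))
        while t < n_tp:
            dwell = max(1, int(np.ceil(rng.exponential(ground_truth.dwell_mean_s / tr_s))))
            seg = min(dwell, n_tp - t)
            z = rng.standard_normal((parcellation.n_regions, seg))
            data[:, t : t + seg] = chols[state] @ z
            t += seg
            state = int(rng.integers(K))
        data += obs_noise_sd * rng.standard_normal(data.shape)
        runs.append(
            ParcellatedRun(
                subject_id=f"sub-{s + 1:03d}",
                tr_s=tr_s,
                data=data,
                age=age,
                run_label=run_label,
            )
        )
    return runs


def _sphere_gp_cholesky(parcellation: Parcellation, correlation_length: float) -> np.ndarray:
    """Cholesky factor of exp(-geodesic/length) on mirror-aligned centroids.

    Aligned coordinates put homotopic regions close together, so maps are
    bilaterally similar -- and the kernel is exactly invariant under the
    mirrored rotations used by the spin nulls.
    """
    C = parcellation.aligned_centroids
    cos = np.clip(C @ C.T, -1.0, 1.0)
    dist = np.arccos(cos)
    K = np.exp(-dist / correlation_length)
    return np.linalg.cholesky(K + 1e-8 * np.eye(len(K)))


def simulate_regional_maps(
    parcellation: Parcellation,
    correlation_length: float,
    n_maps: int,
    seed: int = 0,
) -> list[RegionalMap]:
    """Zero-mean unit-variance Gaussian-process maps on the sphere.

    Covariance is the exponential kernel ``exp(-arc_length / correlation_length)``
    (positive definite on the sphere); small lengths give near-white maps, large
    lengths near-constant maps.
    """
    if correlation_length <= 0:
        raise ValueError("correlation_length must be positive")
    if n_maps < 1:
        raise ValueError("n_maps must be positive")
    rng = np.random.default_rng(seed)
    L = _sphere_gp_cholesky(parcellation, correlation_length)
    maps = []
    for i in range(n_maps):
        v = L @ rng.standard_normal(parcellation.n_regions)
        v = (v - v.mean()) / v.std()
        maps.append(
            RegionalMap(
                values=v,
                parcellation_ref=parcellation.name,
                label=f"gp-map-{i + 1}",
                standardized=True,
            )
        )
    return maps


def simulate_receptor_panel(
    parcellation: Parcellation,
    seed: int = 0,
    correlation_length: float = 0.75,
) -> ReceptorPanel:
    """Positive, spatially autocorrelated densities for the 13 receptors."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    L = _sphere_gp_cholesky(parcellation, correlation_length)
    cols = {}
    for name in RECEPTOR_NAMES:
        g = L @ rng.standard_normal(parcellation.n_regions)
        g = (g - g.mean()) / g.std()
        base = rng.uniform(0.5, 2.0)  # receptor-specific overall density level
        cols[name] = base * np.exp(0.4 * g)
    densities = pd.DataFrame(cols, index=parcellation.region_ids)
    return ReceptorPanel(
        densities=densities,
        annotations=RECEPTOR_ANNOTATIONS.copy(),
        parcellation_ref=parcellation.name,
    )
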