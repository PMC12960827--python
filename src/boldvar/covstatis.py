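"""Global BOLD signal variability via covSTATIS dynamic functional connectivity.

The pipeline: zero-phase high-pass filtering of each regional timeseries at
1/window_length Hz (so retained frequencies exceed the window's resolvable
band), sliding-window ("square" shape, 1-TR step) product-moment correlation
tables, a covSTATIS compromise across all subjects' tables (Rv-coefficient
similarity, first-eigenvector weights, weighted-average compromise,
eigendecomposition), back-projection of every window table into the compromise
space, and finally the area of the (95%-peeled) convex hull of each region's
per-window coordinates. A larger hull means a region's connectivity profile
wanders more across windows, i.e. greater global variability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import eigh
from scipy.signal import butter, sosfiltfilt
from scipy.sparse.linalg import LinearOperator, eigsh
from scipy.spatial import ConvexHull, QhullError

from .containers import ParcellatedRun

__all__ = [
    "WindowSpec",
    "ConnectivityStack",
    "CompromiseModel",
    "HullScores",
    "window_width_trs",
    "count_windows",
    "leonardi_highpass",
    "windowed_connectivity",
    "rv_coefficient",
    "fit_compromise",
    "partial_projection",
    "hull_area",
    "global_variability",
]


@dataclass
class WindowSpec:
    """Sliding-window parameters: width in seconds, step in TRs, square shape."""

    window_s: float
    step_trs: int = 1
    shape: str = "square"
    highpass: bool = True

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.step_trs < 1:
            raise ValueError("window_s must be positive and step_trs >= 1")
        if self.shape != "square":
            raise ValueError("only the square window shape is supported")
        if not 45.0 <= self.window_s <= 100.0:
            warnings.warn(
                f"window of {self.window_s} s is outside the recommended 45-100 s range",
                stacklevel=2,
            )

    def width_trs(self, tr_s: float) -> int:
        return window_width_trs(self.window_s, tr_s)


def window_width_trs(window_s: float, tr_s: float) -> int:
    """Window width in TRs: nearest integer, halves rounded away from zero."""
    if window_s <= 0 or tr_s <= 0:
        raise ValueError("window_s and tr_s must be positive")
    w = math.floor(window_s / tr_s + 0.5)
    if w < 2:
        raise ValueError(f"window of {window_s} s spans fewer than 2 TRs at TR {tr_s} s")
    return w


def count_windows(n_timepoints: int, width_trs: int, step_trs: int = 1) -> int:
    """Number of sliding windows of ``width_trs`` shifted by ``step_trs``."""
    if width_trs > n_timepoints:
        raise ValueError("window width exceeds run length")
    if width_trs < 1 or step_trs < 1:
        raise ValueError("width and step must be positive")
    return (n_timepoints - width_trs) // step_trs + 1


def leonardi_highpass(run: ParcellatedRun, window_s: float) -> ParcellatedRun:
    """Zero-phase high-pass at 1/window_s Hz per region.

    Removes fluctuations slower than one window length, which a window of that
    length cannot resolve and which otherwise inflate windowed correlations.
    Realized as an order-4 Butterworth applied forward-backward after mean
    removal; a constant series maps to zeros exactly.
    """
    fs = 1.0 / run.tr_s
    wn = (1.0 / window_s) / (fs / 2.0)
    if not 0 < wn < 1:
        raise ValueError("high-pass cutoff must fall below the Nyquist frequency")
    data = run.data - run.data.mean(axis=1, keepdims=True)
    sos = butter(4, wn, btype="highpass", output="sos")
    filtered = sosfiltfilt(sos, data, axis=1)
    return run.with_data(filtered)


@dataclass
class ConnectivityStack:
    """Per-subject sequence of windowed region-by-region correlation tables."""

    subject_id: str
    tables: np.ndarray  # (T, R, R)
    window_spec: Optional[WindowSpec] = None

    def __post_init__(self) -> None:
        self.tables = np.asarray(self.tables, dtype=float)
        if self.tables.ndim != 3 or self.tables.shape[1] != self.tables.shape[2]:
            raise ValueError("tables must be (T, R, R)")

    @property
    def n_windows(self) -> int:
        return self.tables.shape[0]

    @property
    def n_regions(self) -> int:
        return self.tables.shape[1]


def windowed_connectivity(run: ParcellatedRun, spec: WindowSpec) -> ConnectivityStack:
    """Correlation table of every sliding window of the run."""
    w = spec.width_trs(run.tr_s)
    T = count_windows(run.n_timepoints, w, spec.step_trs)
    R = run.n_regions
    tables = np.empty((T, R, R))
    warned = False
    for t in range(T):
        seg = run.data[:, t * spec.step_trs : t * spec.step_trs + w]
        sd = seg.std(axis=1)
        if (sd == 0).any():
            if not warned:
                warnings.warn(
                    "zero-variance region within a window; its correlations set to 0",
                    stacklevel=2,
                )
                warned = True
            C = np.zeros((R, R))
            ok = sd > 0
            if ok.sum() >= 2:
                C[np.ix_(ok, ok)] = np.corrcoef(seg[ok])
            np.fill_diagonal(C, 1.0)
        else:
            C = np.corrcoef(seg)
        tables[t] = np.clip(C, -1.0, 1.0)
    return ConnectivityStack(subject_id=run.subject_id, tables=tables, window_spec=spec)


def rv_coefficient(A: np.ndarray, B: np.ndarray, squared: bool = False) -> float:
    """Rv similarity of two symmetric matrices: tr(AB)/sqrt(tr(AA) tr(BB)).

    For PSD inputs this lies in [0, 1]. With ``squared=True`` the squared
    variant is returned instead.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("inputs must be square matrices of the same shape")
    if not (np.allclose(A, A.T, atol=1e-8) and np.allclose(B, B.T, atol=1e-8)):
        raise ValueError("inputs must be symmetric")
    num = float(np.sum(A * B))  # tr(AB) for symmetric B
    den = math.sqrt(float(np.sum(A * A)) * float(np.sum(B * B)))
    if den == 0:
        raise ValueError("Rv undefined for a zero matrix")
    rv = num / den
    return rv * rv if squared else rv


@dataclass
class CompromiseModel:
    """Rv weights, compromise matrix and eigen-basis shared by a sample."""

    table_weights: np.ndarray
    compromise: np.ndarray
    eigenvalues: np.ndarray  # retained, descending, > 0
    eigenvectors: np.ndarray  # (R, C), orthonormal columns
    factor_scores: np.ndarray = field(init=False)  # U * sqrt(lambda)

    def __post_init__(self) -> None:
        if (self.table_weights < -1e-12).any():
            raise ValueError("table weights must be non-negative")
        if abs(self.table_weights.sum() - 1.0) > 1e-10:
            raise ValueError("table weights must sum to 1")
        if (self.eigenvalues <= 0).any():
            raise ValueError("retained eigenvalues must be positive")
        self.factor_scores = self.eigenvectors * np.sqrt(self.eigenvalues)

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size


def _first_eigvec_gram(W: np.ndarray) -> np.ndarray:
    """Leading eigenvector of W W' (rows of W are unit-norm vectorized tables)."""
    Y = W.shape[0]
    if Y <= 2:
        G = W @ W.T
        vals, vecs = np.linalg.eigh(G)
        return vecs[:, -1]
    op = LinearOperator((Y, Y), matvec=lambda x: W @ (W.T @ x), dtype=float)
    vals, vecs = eigsh(op, k=1, which="LA", v0=np.ones(Y))
    return vecs[:, 0]


def fit_compromise(all_stacks: Sequence[ConnectivityStack]) -> CompromiseModel:
    """Fit the covSTATIS compromise over all tables of all subjects.

    The Rv matrix over the Y pooled tables is never formed explicitly: with
    each table vectorized and Frobenius-normalized as a row of ``W``, the Rv
    matrix is ``W W'`` and its leading eigenvector is found by Lanczos
    iteration on that product. The eigenvector is non-negative
    (Perron-Frobenius, since Rv entries of PSD tables are non-negative) and is
    normalized to sum 1 to serve as table weights.
    """
    if not all_stacks:
        raise ValueError("need at least one connectivity stack")
    R = all_stacks[0].n_regions
    for s in all_stacks:
        if s.n_regions != R:
            raise ValueError("all stacks must share the region count")
    V = np.concatenate([s.tables.reshape(s.n_windows, -1) for s in all_stacks], axis=0)
    Y = V.shape[0]
    if Y < 2:
        raise ValueError("need at least 2 tables in total")
    norms = np.linalg.norm(V, axis=1)
    if (norms == 0).any():
        raise ValueError("zero table encountered")
    W = V / norms[:, None]
    w = _first_eigvec_gram(W)
    if w.sum() < 0:
        w = -w
    w = np.clip(w, 0.0, None)
    w /= w.sum()
    compromise = (w @ V).reshape(R, R)
    compromise = 0.5 * (compromise + compromise.T)
    vals, vecs = eigh(compromise)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(1e-12, 1e-12 * abs(vals[0]))
    keep = vals > tol
    vals, vecs = vals[keep], vecs[:, keep]
    # Fix the arbitrary eigenvector sign: largest-magnitude loading positive.
    for j in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return CompromiseModel(
        table_weights=w, compromise=compromise, eigenvalues=vals, eigenvectors=vecs
    )


def partial_projection(
    stack: ConnectivityStack,
    model: CompromiseModel,
    n_components: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Back-project a subject's window tables into the compromise space.

    Each window table ``X_t`` maps to ``X_t U diag(1/sqrt(lambda))``; the
    subject's mean point per region is the projection of the across-window
    mean table. Projecting the compromise itself returns the factor scores.

    Returns ``(window_coords, mean_coords)`` with shapes ``(T, R, C)`` and
    ``(R, C)``.
    """
    if stack.n_regions != model.compromise.shape[0]:
        raise ValueError("stack and model region counts differ")
    c = model.n_components if n_components is None else min(n_components, model.n_components)
    if n_components is not None and n_components > model.n_components:
        warnings.warn(
            f"only {model.n_components} positive components retained; "
            f"requested {n_components}",
            stacklevel=2,
        )
    P = model.eigenvectors[:, :c] / np.sqrt(model.eigenvalues[:c])
    window_coords = stack.tables @ P
    mean_coords = stack.tables.mean(axis=0) @ P
    return window_coords, mean_coords


def hull_area(points_2d: np.ndarray, peel_fraction: float = 0.95) -> float:
    """Convex-hull area of a 2-D point cloud after peeling distant outliers.

    ``ceil((1 - peel_fraction) * T)`` points with the largest Euclidean
    distance from the cloud centroid are dropped first. Degenerate clouds
    (fewer than 3 distinct points, collinear points) have zero area.
    """
    pts = np.asarray(points_2d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (T, 2)")
    T = pts.shape[0]
    if T < 1:
        raise ValueError("need at least one point")
    if not 0 < peel_fraction <= 1:
        raise ValueError("peel_fraction must be in (0, 1]")
    drop = math.ceil((1.0 - peel_fraction) * T)
    if drop > 0:
        d = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
        keep_idx = np.argsort(d, kind="stable")[: T - drop]
        pts = pts[keep_idx]
    if pts.shape[0] < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # .volume is area in 2-D
    except QhullError:
        return 0.0  # coincident or collinear points


@dataclass
class HullScores:
    """Per-subject, per-region hull areas (arbitrary units, >= 0)."""

    subject_ids: list[str]
    areas: np.ndarray  # (S, R)
    peel_fraction: float = 0.95
    model: Optional[CompromiseModel] = None

    def group_mean(self) -> np.ndarray:
        return self.areas.mean(axis=0)


def global_variability(
    dataset: Sequence[ParcellatedRun],
    spec: WindowSpec,
    n_components: int = 2,
    peel_fraction: float = 0.95,
) -> HullScores:
    """End-to-end global variability: per-subject per-region hull areas.

    High-pass filter each run (if ``spec.highpass``), compute windowed
    connectivity, fit one compromise over the whole sample, back-project each
    subject, and take the peeled hull area of every region's window coordinates
    on the first ``n_components`` (default 2) components.
    """
    if not dataset:
        raise ValueError("need at least one subject")
    runs = [leonardi_highpass(r, spec.window_s) if spec.highpass else r for r in dataset]
    stacks = [windowed_connectivity(r, spec) for r in runs]
    model = fit_compromise(stacks)
    S, R = len(stacks), stacks[0].n_regions
    areas = np.empty((S, R))
    for s, stack in enumerate(stacks):
        coords, _ = partial_projection(stack, model, n_components=n_components)
        for r in range(R):
            areas[s, r] = hull_area(coords[:, r, :2], peel_fraction)
    return HullScores(
        subject_ids=[st.subject_id for st in stacks],
        areas=areas,
        peel_fraction=peel_fraction,
        model=model,
    )
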