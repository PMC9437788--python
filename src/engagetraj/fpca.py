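"""Functional principal component analysis by smoothed covariance.

Each participant's presmoothed log-in trajectory X_i(t) is treated as a
densely observed functional datum on the integer-day grid t = 0..181.
The sample covariance surface G(s, t) is smoothed with a local-linear
kernel smoother (product Gaussian kernel, default bandwidth 7 days — the
natural weekly scale of the data), symmetrized and projected to the
positive-semidefinite cone.  The integral eigenproblem

    ∫ G(s, t) φ(t) dt = λ φ(s)

is solved by a quadrature-weighted matrix eigendecomposition (trapezoidal
weights), eigenfunctions are scaled to unit norm under the quadrature
inner product, and each curve is summarized by its projection scores on
the leading eigenfunctions.  The number of retained components K is the
smallest K whose cumulative eigenvalue share reaches the variance
threshold (default 90%).

Dense, complete grids only: scores are direct numerical integrals, not
conditional expectations, so sparse/irregular designs are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from engagetraj.preprocess import SmoothedTrajectoryMatrix
from engagetraj.synth import N_DAYS


def trapezoid_weights(m: int = N_DAYS) -> np.ndarray:
    """Trapezoidal quadrature weights on the unit-spaced grid 0..m-1."""
    w = np.ones(m)
    w[0] = w[-1] = 0.5
    return w


def estimate_mean(smoothed: SmoothedTrajectoryMatrix | np.ndarray) -> np.ndarray:
    """Pointwise mean function across participants (requires n >= 2)."""
    x = smoothed.values if isinstance(smoothed, SmoothedTrajectoryMatrix) else np.asarray(smoothed, float)
    if x.shape[0] < 2:
        raise ValueError("at least 2 trajectories are required")
    return x.mean(axis=0)


def _local_linear_smoother(grid: np.ndarray, bandwidth: float) -> np.ndarray:
    """Row-stochastic-ish matrix L with (L f)(t_i) = local-linear fit at t_i.

    Rows where the local-linear normal equations degenerate (effectively a
    single support point, e.g. at tiny bandwidths) fall back to the
    Nadaraya-Watson (local-constant) estimate.
    """
    d = grid[None, :] - grid[:, None]          # d[i, j] = t_j - t_i
    w = np.exp(-0.5 * (d / bandwidth) ** 2)
    s0 = w.sum(axis=1)
    s1 = (w * d).sum(axis=1)
    s2 = (w * d * d).sum(axis=1)
    denom = s0 * s2 - s1 ** 2
    L = np.empty_like(w)
    ok = denom > 1e-10 * np.maximum(s0 * s2, 1e-300)
    L[ok] = (w[ok] * (s2[ok, None] - d[ok] * s1[ok, None])) / denom[ok, None]
    L[~ok] = w[~ok] / s0[~ok, None]
    return L


def estimate_smoothed_covariance(
    smoothed: SmoothedTrajectoryMatrix | np.ndarray,
    mean: np.ndarray,
    bandwidth: float = 7.0,
) -> np.ndarray:
    """Smoothed, symmetrized, PSD-projected covariance surface.

    The raw pooled covariance G(s,t) = (n-1)^-1 Σ_i (X_i(s)-μ(s))(X_i(t)-μ(t))
    is smoothed separably along each axis with the local-linear smoother
    (the fast tensor-grid realization of a 2D product-kernel smoother).
    ``bandwidth = 0`` is the no-smoothing limit and returns the projected
    raw covariance; the diagonal is not excluded — daily measurement noise
    is already absorbed by the 7-day presmoothing.
    """
    if bandwidth < 0:
        raise ValueError("bandwidth must be nonnegative")
    x = smoothed.values if isinstance(smoothed, SmoothedTrajectoryMatrix) else np.asarray(smoothed, float)
    n, m = x.shape
    xc = x - np.asarray(mean)[None, :]
    G = (xc.T @ xc) / (n - 1)
    if bandwidth > 0:
        L = _local_linear_smoother(np.arange(m, dtype=float), bandwidth)
        G = L @ G @ L.T
    G = (G + G.T) / 2.0
    # PSD projection: clip negative eigenvalues to zero
    vals, vecs = np.linalg.eigh(G)
    vals = np.clip(vals, 0.0, None)
    G = (vecs * vals) @ vecs.T
    return (G + G.T) / 2.0


def eigendecompose(
    cov: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the integral eigenproblem on the quadrature grid.

    Returns eigenvalues (nonincreasing, clipped at 0) and eigenfunctions
    (rows), unit-norm under the quadrature inner product
    <f, g> = Σ_t w_t f(t) g(t), with the sign convention that each
    eigenfunction's largest-magnitude element is positive.
    """
    cov = np.asarray(cov, dtype=float)
    if not np.allclose(cov, cov.T, atol=1e-8):
        raise ValueError("covariance must be symmetric")
    m = cov.shape[0]
    w = trapezoid_weights(m) if weights is None else np.asarray(weights, float)
    sq = np.sqrt(w)
    B = cov * sq[:, None] * sq[None, :]
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    phis = (vecs[:, order] / sq[:, None]).T      # K x m, quadrature-orthonormal
    for k in range(phis.shape[0]):
        j = np.argmax(np.abs(phis[k]))
        if phis[k, j] < 0:
            phis[k] = -phis[k]
    return vals, phis


def compute_scores(
    smoothed: SmoothedTrajectoryMatrix | np.ndarray,
    mean: np.ndarray,
    eigenfunctions: np.ndarray,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Projection scores: score_ik = Σ_t w_t (X_i(t) - μ(t)) φ_k(t)."""
    x = smoothed.values if isinstance(smoothed, SmoothedTrajectoryMatrix) else np.asarray(smoothed, float)
    mean = np.asarray(mean, float)
    phis = np.asarray(eigenfunctions, float)
    if x.shape[1] != mean.shape[0] or phis.shape[1] != mean.shape[0]:
        raise ValueError("grid dimensions of curves, mean and eigenfunctions disagree")
    w = trapezoid_weights(x.shape[1]) if weights is None else np.asarray(weights, float)
    return (x - mean[None, :]) @ (phis * w[None, :]).T


def select_num_components(eigenvalues: np.ndarray, threshold: float = 0.90) -> int:
    """Smallest K with cumulative variance share >= threshold."""
    vals = np.asarray(eigenvalues, float)
    total = vals.sum()
    if total <= 0:
        raise ValueError("all eigenvalues are zero; no variance to explain")
    cum = np.cumsum(vals) / total
    return int(np.argmax(cum >= threshold - 1e-12)) + 1


@dataclass
class FPCModel:
    """Fitted FPCA: mean, leading eigenfunctions/eigenvalues and scores."""

    grid: np.ndarray
    mean_function: np.ndarray
    eigenfunctions: np.ndarray       # K x m, retained components
    eigenvalues: np.ndarray          # K retained eigenvalues
    scores: np.ndarray               # n x K
    pct_variance: np.ndarray         # share of total variance, per component
    variance_threshold: float
    all_eigenvalues: np.ndarray      # full spectrum (for bookkeeping)
    quadrature_weights: np.ndarray

    @property
    def n_components(self) -> int:
        return self.eigenfunctions.shape[0]

    def reconstruct(self, n_components: int | None = None) -> np.ndarray:
        """Mean + truncated Karhunen-Loeve expansion of each curve."""
        K = self.n_components if n_components is None else n_components
        return self.mean_function[None, :] + self.scores[:, :K] @ self.eigenfunctions[:K]

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"day": self.grid, "mean": self.mean_function}).to_csv(
            d / "mean.csv", index=False)
        pd.DataFrame(self.eigenfunctions.T,
                     columns=[f"phi{k + 1}" for k in range(self.n_components)]
                     ).to_csv(d / "eigenfunctions.csv", index=False)
        pd.DataFrame({"eigenvalue": self.eigenvalues,
                      "pct_variance": self.pct_variance}).to_csv(
            d / "eigenvalues.csv", index=False)
        pd.DataFrame(self.scores,
                     columns=[f"score{k + 1}" for k in range(self.n_components)]
                     ).to_csv(d / "scores.csv", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "FPCModel":
        d = Path(directory)
        mean = pd.read_csv(d / "mean.csv")
        phis = pd.read_csv(d / "eigenfunctions.csv").to_numpy().T
        ev = pd.read_csv(d / "eigenvalues.csv")
        scores = pd.read_csv(d / "scores.csv").to_numpy()
        vals = ev["eigenvalue"].to_numpy()
        return cls(
            grid=mean["day"].to_numpy(float),
            mean_function=mean["mean"].to_numpy(),
            eigenfunctions=phis,
            eigenvalues=vals,
            scores=scores,
            pct_variance=ev["pct_variance"].to_numpy(),
            variance_threshold=float("nan"),
            all_eigenvalues=vals,
            quadrature_weights=trapezoid_weights(len(mean)),
        )


def fit_fpca(
    smoothed: SmoothedTrajectoryMatrix | np.ndarray,
    threshold: float = 0.90,
    bandwidth: float = 7.0,
) -> FPCModel:
    """Full FPCA fit: mean -> smoothed covariance -> eigendecomposition ->
    component selection at the variance threshold -> projection scores.

    Raises on degenerate input (fewer than 2 curves, or zero total
    variance — e.g. identical curves)."""
    x = smoothed.values if isinstance(smoothed, SmoothedTrajectoryMatrix) else np.asarray(smoothed, float)
    mean = estimate_mean(x)
    total_var = ((x - mean) ** 2).sum() / (x.shape[0] - 1)
    if total_var <= 1e-12:
        raise ValueError("curves are (numerically) identical; no variance to decompose")
    cov = estimate_smoothed_covariance(x, mean, bandwidth)
    w = trapezoid_weights(x.shape[1])
    vals, phis = eigendecompose(cov, w)
    K = select_num_components(vals, threshold)
    scores = compute_scores(x, mean, phis[:K], w)
    total = vals.sum()
    return FPCModel(
        grid=np.arange(x.shape[1], dtype=float),
        mean_function=mean,
        eigenfunctions=phis[:K],
        eigenvalues=vals[:K],
        scores=scores,
        pct_variance=vals[:K] / total,
        variance_threshold=threshold,
        all_eigenvalues=vals,
        quadrature_weights=w,
    )
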