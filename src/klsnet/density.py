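"""KL-divergence similarity (KLS) networks from regional GM value distributions.

Each brain region contributes a probability density of its voxelwise GM
volume values, estimated by Gaussian kernel density estimation with an
automatic bandwidth and discretised on a grid shared by every region and
subject.  The edge weight between regions i and j is

    KLS(P, Q) = exp(-D_KL(P, Q)),

where D_KL(P, Q) is the *symmetric* Kullback-Leibler divergence

    D_KL(P, Q) = sum_i [ P(i) log(P(i)/Q(i)) + Q(i) log(Q(i)/P(i)) ],

so KLS lies in (0, 1]: 1 for identical distributions, approaching 0 as the
distributions separate.  Stacking all region pairs gives one symmetric
n_regions x n_regions similarity matrix per subject — the individual GM
morphological network.

Numerical conventions (recorded in each matrix's metadata):

* natural logarithm throughout;
* discrete probabilities are renormalised to sum to 1, floored at ``eps``
  and renormalised again, which keeps the divergence finite where the
  supports barely overlap;
* the matrix diagonal is fixed at 0 and never treated as an edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .atlas import SubjectParcellation

__all__ = [
    "RegionPDF",
    "SimilarityMatrix",
    "DegenerateDistributionError",
    "estimate_pdf",
    "make_grid",
    "cohort_grid_bounds",
    "kl_divergence",
    "symmetric_kl",
    "kls",
    "build_similarity_matrix",
]

DEFAULT_GRID_SIZE = 256
DEFAULT_EPS = 1e-12


class DegenerateDistributionError(ValueError):
    """Raised when a value vector has zero variance (no density estimate)."""


@dataclass(frozen=True)
class RegionPDF:
    """A discretised probability distribution on a common evaluation grid."""

    grid: np.ndarray
    probs: np.ndarray
    bandwidth: float = float("nan")

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        probs = np.asarray(self.probs, dtype=float)
        if grid.ndim != 1 or probs.shape != grid.shape:
            raise ValueError("grid and probs must be 1-D arrays of equal length")
        if grid.size < 2:
            raise ValueError("grid needs at least two points")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(probs <= 0):
            raise ValueError("probs must be strictly positive (floored upstream)")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("probs must sum to 1 within 1e-9")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "probs", probs)

    def same_grid(self, other: "RegionPDF") -> bool:
        return self.grid.shape == other.grid.shape and np.array_equal(
            self.grid, other.grid
        )


@dataclass
class SimilarityMatrix:
    """Per-subject symmetric matrix of pairwise KLS edge weights."""

    subject_id: str
    node_ids: tuple[int, ...]
    W: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        n = len(self.node_ids)
        if W.shape != (n, n):
            raise ValueError(f"W must be {n}x{n}")
        if not np.all(np.isfinite(W)):
            raise ValueError("W contains non-finite entries")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("W must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("W diagonal must be 0")
        off = W[~np.eye(n, dtype=bool)]
        if off.size and (np.any(off <= 0) or np.any(off > 1 + 1e-12)):
            raise ValueError("off-diagonal KLS values must lie in (0, 1]")
        self.W = W
        self.node_ids = tuple(int(i) for i in self.node_ids)


def make_grid(grid_bounds: tuple[float, float], grid_size: int = DEFAULT_GRID_SIZE) -> np.ndarray:
    lo, hi = float(grid_bounds[0]), float(grid_bounds[1])
    if not hi > lo:
        raise ValueError("grid_bounds must satisfy lo < hi")
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    return np.linspace(lo, hi, int(grid_size))


def _scott_bandwidth(values: np.ndarray) -> float:
    # Scott's rule for 1-D data: sigma * n**(-1/5)
    return float(np.std(values, ddof=1) * values.size ** (-1 / 5))


def cohort_grid_bounds(
    parcellations: list[SubjectParcellation], pad_bandwidths: float = 3.0
) -> tuple[float, float]:
    """Common grid bounds: pooled [min, max] padded by ``pad_bandwidths``
    pooled Scott bandwidths, so every subject's density tails fit on the grid.
    """
    pooled = np.concatenate([p.pooled_values() for p in parcellations])
    pad = pad_bandwidths * _scott_bandwidth(pooled)
    return float(pooled.min() - pad), float(pooled.max() + pad)


def estimate_pdf(
    values: np.ndarray,
    grid_size: int = DEFAULT_GRID_SIZE,
    grid_bounds: tuple[float, float] | None = None,
    *,
    grid: np.ndarray | None = None,
    bw_method: str = "scott",
    eps: float = DEFAULT_EPS,
) -> RegionPDF:
    """Gaussian-KDE density of ``values`` discretised on a common grid.

    The continuous density is evaluated at the grid points, renormalised to a
    discrete probability vector, floored at ``eps`` and renormalised again.

    Raises
    ------
    DegenerateDistributionError
        If ``values`` has zero variance (KDE bandwidth undefined).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("need at least two values for a density estimate")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if np.ptp(values) == 0:
        raise DegenerateDistributionError(
            "constant value vector: density estimate is degenerate"
        )
    if grid is None:
        if grid_bounds is None:
            raise ValueError("either grid or grid_bounds must be given")
        grid = make_grid(grid_bounds, grid_size)
    kde = stats.gaussian_kde(values, bw_method=bw_method)
    density = kde(grid)
    total = density.sum()
    if total <= 0:
        raise DegenerateDistributionError("density vanished on the grid")
    probs = density / total
    probs = np.maximum(probs, eps)
    probs = probs / probs.sum()
    bandwidth = float(kde.factor * np.std(values, ddof=1))
    return RegionPDF(grid=grid, probs=probs, bandwidth=bandwidth)


def _check_pair(P: RegionPDF, Q: RegionPDF) -> None:
    if not P.same_grid(Q):
        raise ValueError("P and Q must be discretised on the identical grid")


def kl_divergence(P: RegionPDF, Q: RegionPDF) -> float:
    """Directed KL divergence sum_i P(i) ln(P(i)/Q(i)) (natural log)."""
    _check_pair(P, Q)
    return float(np.sum(P.probs * (np.log(P.probs) - np.log(Q.probs))))


def symmetric_kl(P: RegionPDF, Q: RegionPDF) -> float:
    """Symmetric KL divergence: the sum of both directed divergences."""
    _check_pair(P, Q)
    dp = np.log(P.probs) - np.log(Q.probs)
    return float(np.sum((P.probs - Q.probs) * dp))


def kls(P: RegionPDF, Q: RegionPDF) -> float:
    """KL-based similarity exp(-symmetric_kl); in (0, 1], 1 iff P == Q."""
    return float(np.exp(-symmetric_kl(P, Q)))


def build_similarity_matrix(
    parc: SubjectParcellation,
    grid_size: int = DEFAULT_GRID_SIZE,
    grid_bounds: tuple[float, float] | None = None,
    *,
    grid: np.ndarray | None = None,
    bw_method: str = "scott",
    eps: float = DEFAULT_EPS,
) -> SimilarityMatrix:
    """All-pairs KLS matrix for one subject.

    Every region's PDF is estimated on the same grid; pairwise symmetric KL
    divergences are computed in one vectorised pass using the identity
    D_KL(P, Q) = sum_i (P(i) - Q(i)) (ln P(i) - ln Q(i)).
    """
    if grid is None:
        if grid_bounds is None:
            raise ValueError("either grid or grid_bounds must be given")
        grid = make_grid(grid_bounds, grid_size)
    node_ids = parc.region_ids
    pdfs = []
    for rid in node_ids:
        try:
            pdfs.append(
                estimate_pdf(parc.values[rid], grid=grid, bw_method=bw_method, eps=eps)
            )
        except DegenerateDistributionError as exc:
            raise DegenerateDistributionError(
                f"subject {parc.subject_id}, region {rid}: {exc}"
            ) from exc

    P = np.stack([p.probs for p in pdfs])          # (n, m)
    L = np.log(P)
    self_term = np.sum(P * L, axis=1)              # sum_i P ln P per region
    cross = P @ L.T                                # cross[a, b] = sum_i P_a ln P_b
    D = self_term[:, None] + self_term[None, :] - cross - cross.T
    np.maximum(D, 0.0, out=D)                      # clip tiny negative round-off
    W = np.exp(-D)
    np.fill_diagonal(W, 0.0)
    W = 0.5 * (W + W.T)
    meta = {
        "kernel": "gaussian",
        "bw_method": bw_method,
        "grid_size": int(grid.size),
        "grid_bounds": (float(grid[0]), float(grid[-1])),
        "eps": eps,
        "log_base": "e",
        "bandwidths": {int(r): p.bandwidth for r, p in zip(node_ids, pdfs)},
    }
    return SimilarityMatrix(parc.subject_id, node_ids, W, meta)
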