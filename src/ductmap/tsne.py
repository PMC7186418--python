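"""t-distributed stochastic neighbor embedding (tSNE) of expression matrices.

The high-dimensional similarity between cells i and j is the probability of
the two being neighbors under a Gaussian kernel whose per-cell bandwidth
sigma_i is calibrated so the Shannon perplexity 2^H(p_.|i) of each
conditional distribution equals the target perplexity.  Conditionals are
symmetrized into a joint P, and a 2-D map Y is found by gradient descent on
KL(P || Q), where Q is the Student-t (1 df) kernel over map distances.

Two gradient engines are provided:

* exact (theta = 0): the full O(n^2) gradient — the reference path, entirely
  adequate at cohort scale (~1100 cells);
* Barnes-Hut (theta > 0): quadtree approximation of the repulsive term with
  the usual cell-opening criterion (cell diameter / distance < theta),
  matching the published run parameters (theta = 0.5).

Optimization follows the canonical schedule: random Gaussian init (sd 1e-4),
learning rate 200 with adaptive per-coordinate gains, early exaggeration 12
for the first 250 iterations, momentum 0.5 switching to 0.8 at iteration
250, 2000 iterations total by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .ct_io import ExpressionMatrix

__all__ = [
    "TsneParams",
    "EmbeddingResult",
    "conditional_affinities",
    "symmetrize",
    "tsne_embed",
]

_P_MIN = 1e-12


@dataclass(frozen=True)
class TsneParams:
    """Run parameters; defaults are the study's published settings."""

    iterations: int = 2000
    perplexity: float = 10.0
    theta: float = 0.5
    seed: int = 0
    learning_rate: float = 200.0
    early_exaggeration: float = 12.0
    exaggeration_iters: int = 250
    momentum_start: float = 0.5
    momentum_final: float = 0.8
    momentum_switch: int = 250
    init: str = "random"  # or "pca"
    trace_every: int = 50
    #: independent optimizations; the run with the lowest final KL is kept
    restarts: int = 1

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.perplexity <= 1:
            raise ValueError("perplexity must be > 1")
        if not (0.0 <= self.theta <= 1.0):
            raise ValueError("theta must be in [0, 1]")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.init not in ("random", "pca"):
            raise ValueError("init must be 'random' or 'pca'")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass(frozen=True)
class EmbeddingResult:
    """2-D coordinates plus the KL-divergence trace of the optimization."""

    coords: np.ndarray            # [n_cells x 2]
    kl_trace: np.ndarray          # [(iteration, kl), ...]
    params: TsneParams
    cell_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be [n x 2]")
        if not np.isfinite(coords).all():
            raise ValueError("coords must be finite")
        trace = np.asarray(self.kl_trace, dtype=float).reshape(-1, 2)
        if (trace[:, 1] < 0).any():
            raise ValueError("KL trace must be non-negative")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "kl_trace", trace)

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


def _as_matrix(et: ExpressionMatrix | np.ndarray) -> np.ndarray:
    if isinstance(et, ExpressionMatrix):
        return np.asarray(et.et, dtype=float)
    return np.asarray(et, dtype=float)


# ---------------------------------------------------------------------------
# Affinities
# ---------------------------------------------------------------------------

def conditional_affinities(
    et: ExpressionMatrix | np.ndarray,
    perplexity: float,
    tol: float = 1e-6,
    max_steps: int = 200,
) -> np.ndarray:
    """Row-stochastic Gaussian conditional affinities P[j|i].

    For each cell i, the bandwidth is found by binary search on the
    precision beta_i = 1/(2 sigma_i^2) so that the Shannon perplexity of
    p_.|i matches ``perplexity`` (to well within 1e-4).  Euclidean distances
    over all genes; the diagonal is zero.
    """
    X = _as_matrix(et)
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 cells, got {n}")
    if not (1 < perplexity < n):
        raise ValueError(f"perplexity {perplexity} must be in (1, n_cells)")
    D = squareform(pdist(X, metric="sqeuclidean"))
    log_target = np.log(perplexity)

    P = np.zeros((n, n))
    for i in range(n):
        d = np.delete(D[i], i)
        beta, beta_lo, beta_hi = 1.0, 0.0, np.inf
        p = None
        for _ in range(max_steps):
            # shifted exponentials for numerical stability
            logits = -beta * d
            logits -= logits.max()
            w = np.exp(logits)
            sw = w.sum()
            p = w / sw
            # Shannon entropy in nats; perplexity = exp(H)
            h = -np.sum(p * np.log(np.maximum(p, _P_MIN)))
            diff = h - log_target
            if abs(diff) < tol:
                break
            if diff > 0:  # too flat -> narrow the kernel
                beta_lo = beta
                beta = beta * 2.0 if not np.isfinite(beta_hi) else (beta + beta_hi) / 2.0
            else:
                beta_hi = beta
                beta = beta / 2.0 if beta_lo == 0.0 else (beta + beta_lo) / 2.0
        else:
            raise FloatingPointError(
                f"perplexity calibration did not converge for row {i} "
                f"(entropy gap {diff:.2e} after {max_steps} steps)"
            )
        P[i, np.arange(n) != i] = p
    return P


def symmetrize(conditional: np.ndarray) -> np.ndarray:
    """Joint affinities p_ij = (p_j|i + p_i|j) / (2n); entries sum to 1."""
    P = np.asarray(conditional, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("conditional affinity matrix must be square")
    rows = P.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-6):
        raise ValueError("input must be row-stochastic")
    n = P.shape[0]
    return (P + P.T) / (2.0 * n)


# ---------------------------------------------------------------------------
# Gradient engines
# ---------------------------------------------------------------------------

def _student_t_kernel(Y: np.ndarray) -> np.ndarray:
    """Unnormalized t-kernel E_ij = 1/(1 + ||y_i - y_j||^2), zero diagonal."""
    E = 1.0 / (1.0 + squareform(pdist(Y, metric="sqeuclidean")))
    np.fill_diagonal(E, 0.0)
    return E


def _kl_divergence(P: np.ndarray, Y: np.ndarray) -> float:
    E = _student_t_kernel(Y)
    Q = np.maximum(E / E.sum(), _P_MIN)
    Pc = np.maximum(P, _P_MIN)
    mask = P > 0
    return float(np.sum(P[mask] * (np.log(Pc[mask]) - np.log(Q[mask]))))


def _gradient_exact(P_eff: np.ndarray, Y: np.ndarray) -> np.ndarray:
    E = _student_t_kernel(Y)
    Q = E / E.sum()
    M = (P_eff - Q) * E
    return 4.0 * (M.sum(axis=1)[:, None] * Y - M @ Y)


def _gradient_bh(P_eff: np.ndarray, Y: np.ndarray, theta: float) -> np.ndarray:
    from ._bhtree import repulsive_forces

    # attraction uses the exact kernel (P is dense at cohort scale);
    # repulsion is the quadtree approximation
    E = _student_t_kernel(Y)
    A = P_eff * E
    attr = A.sum(axis=1)[:, None] * Y - A @ Y
    forces, z_sum = repulsive_forces(Y, theta)
    z = max(z_sum - Y.shape[0], _P_MIN)  # remove self terms from the partition sum
    return 4.0 * (attr - forces / z)


# ---------------------------------------------------------------------------
# Embedding
# ---------------------------------------------------------------------------

def _initial_coords(X: np.ndarray, params: TsneParams) -> np.ndarray:
    rng = np.random.default_rng(params.seed)
    n = X.shape[0]
    if params.init == "pca":
        Xc = X - X.mean(axis=0)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        Y = Xc @ vt[:2].T
        Y = Y / max(Y[:, 0].std(), _P_MIN) * 1e-4
        return Y + rng.normal(scale=1e-6, size=(n, 2))
    return rng.normal(scale=1e-4, size=(n, 2))


def tsne_embed(
    et: ExpressionMatrix | np.ndarray,
    params: TsneParams | None = None,
) -> EmbeddingResult:
    """Embed an expression matrix in 2-D by tSNE.

    Deterministic for a fixed seed.  The KL divergence against the
    (unexaggerated) joint P is recorded every ``trace_every`` iterations and
    at the final iteration.
    """
    params = params or TsneParams()
    X = _as_matrix(et)
    n = X.shape[0]
    if n < 10:
        raise ValueError(f"need at least 10 cells to embed, got {n}")
    if params.perplexity >= n / 3:
        raise ValueError(
            f"perplexity {params.perplexity} must be < n_cells/3 = {n / 3:.1f}"
        )

    # jitter exact duplicate rows so bandwidth calibration cannot degenerate
    X = X.copy()
    _, first_idx, inv = np.unique(X, axis=0, return_index=True, return_inverse=True)
    dup = np.ones(n, dtype=bool)
    dup[first_idx[inv] == np.arange(n)] = False
    if dup.any():
        jit = np.random.default_rng(params.seed ^ 0x5EED).normal(
            scale=1e-8, size=(int(dup.sum()), X.shape[1])
        )
        X[dup] += jit

    P = symmetrize(conditional_affinities(X, params.perplexity))
    P = np.maximum(P, _P_MIN)

    def optimize(seed: int) -> tuple[np.ndarray, np.ndarray]:
        Y = _initial_coords(X, replace(params, seed=seed))
        update = np.zeros_like(Y)
        gains = np.ones_like(Y)
        trace: list[tuple[int, float]] = []
        for t in range(1, params.iterations + 1):
            exag = params.early_exaggeration if t <= params.exaggeration_iters else 1.0
            if t == params.exaggeration_iters + 1:
                # leaving the exaggerated phase: drop its momentum and gains
                update[:] = 0.0
                gains[:] = 1.0
            P_eff = P * exag if exag != 1.0 else P
            if params.theta == 0.0:
                grad = _gradient_exact(P_eff, Y)
            else:
                grad = _gradient_bh(P_eff, Y, params.theta)
            if not np.isfinite(grad).all():
                raise FloatingPointError(f"non-finite gradient at iteration {t}")

            momentum = (
                params.momentum_start if t <= params.momentum_switch else params.momentum_final
            )
            same_sign = np.sign(grad) == np.sign(update)
            gains = np.where(same_sign, gains * 0.8, gains + 0.2)
            np.clip(gains, 0.01, None, out=gains)
            update = momentum * update - params.learning_rate * gains * grad
            Y = Y + update
            Y = Y - Y.mean(axis=0)

            if t % params.trace_every == 0 or t == params.iterations:
                trace.append((t, _kl_divergence(P, Y)))
        return Y, np.array(trace)

    best: tuple[np.ndarray, np.ndarray] | None = None
    for r in range(params.restarts):
        seed_r = params.seed if r == 0 else (params.seed + 1000003 * r) % (2**31)
        Y, trace = optimize(seed_r)
        if best is None or trace[-1, 1] < best[1][-1, 1]:
            best = (Y, trace)

    cell_ids = tuple(et.cell_ids) if isinstance(et, ExpressionMatrix) else None
    return EmbeddingResult(
        coords=best[0], kl_trace=best[1], params=params, cell_ids=cell_ids
    )
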