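"""Nonnegative CPD (ALS/HALS) and orthogonal Tucker (HOOI) with rank selection.

The canonical polyadic decomposition approximates an N-way tensor X as a sum
of R rank-1 outer products, X ~ sum_r lambda_r u_r^(1) o ... o u_r^(N), with
all factor entries constrained nonnegative; it is fit by block-coordinate
nonnegative least squares with HALS-style column updates, which makes every
block update an exact coordinate minimizer and the objective monotone
nonincreasing. The orthogonal Tucker decomposition Y ~ G x_1 A1 x_2 A2 x_3 A3
(orthonormal factor columns) is initialized by truncated higher-order SVD and
refined by higher-order orthogonal iteration.

Rank selection follows the relative-reconstruction-error rule: the smallest
rank whose relative Frobenius error falls below a threshold (default 10%).

Normalization convention: CPD factor columns carry unit L2 norm with the
scale in ``weights``; Tucker scale lives in the core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce

import numpy as np
from scipy.linalg import khatri_rao

from .core_io import ConfigurationError, DataError

__all__ = [
    "CPDModel",
    "TuckerModel",
    "relative_error",
    "nn_cpd",
    "run_cpd_ensemble",
    "select_rank_cpd",
    "orthogonal_tucker",
    "select_ranks_td",
    "factor_congruence",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# tensor algebra helpers
# ---------------------------------------------------------------------------


def unfold(tensor: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` unfolding; remaining axes keep their original order."""
    return np.moveaxis(tensor, mode, 0).reshape(tensor.shape[mode], -1)


def _khatri_rao_except(factors: list[np.ndarray], skip: int) -> np.ndarray:
    mats = [factors[k] for k in range(len(factors)) if k != skip]
    return reduce(khatri_rao, mats)


def mode_dot(tensor: np.ndarray, matrix: np.ndarray, mode: int) -> np.ndarray:
    """Multiply ``tensor`` by ``matrix`` along ``mode`` (matrix is applied as rows x mode-dim)."""
    moved = np.moveaxis(tensor, mode, -1)
    out = moved @ matrix.T
    return np.moveaxis(out, -1, mode)


def _cp_reconstruct(factors: list[np.ndarray], weights: np.ndarray) -> np.ndarray:
    subs = []
    letters = "ijklmn"
    for n, U in enumerate(factors):
        subs.append(f"{letters[n]}r")
    expr = ",".join(subs) + ",r->" + letters[: len(factors)]
    return np.einsum(expr, *factors, weights, optimize=True)


def _tucker_reconstruct(core: np.ndarray, factors: list[np.ndarray]) -> np.ndarray:
    out = core
    for n, U in enumerate(factors):
        out = mode_dot(out, U, n)
    return out


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


@dataclass
class CPDModel:
    """A fitted nonnegative CPD: per-mode factors (unit-L2 columns) + weights."""

    factors: list[np.ndarray]
    weights: np.ndarray
    rank: int
    rel_error: float
    run_seed: int
    n_iter: int = 0
    error_history: list[float] = field(default_factory=list)

    def reconstruct(self) -> np.ndarray:
        return _cp_reconstruct(self.factors, self.weights)


@dataclass
class TuckerModel:
    """A fitted orthogonal Tucker model: core + orthonormal factor matrices."""

    core: np.ndarray
    factors: list[np.ndarray]
    ranks: tuple[int, ...]
    rel_error: float
    n_iter: int = 0
    fit_history: list[float] = field(default_factory=list)

    def reconstruct(self) -> np.ndarray:
        return _tucker_reconstruct(self.core, self.factors)


def relative_error(model: CPDModel | TuckerModel, tensor: np.ndarray) -> float:
    """Frobenius norm of (tensor - reconstruction) over Frobenius norm of tensor."""
    tensor = np.asarray(tensor, dtype=float)
    norm = np.linalg.norm(tensor)
    if norm == 0:
        raise DataError("relative error undefined for an all-zero tensor")
    return float(np.linalg.norm(tensor - model.reconstruct()) / norm)


# ---------------------------------------------------------------------------
# nonnegative CPD
# ---------------------------------------------------------------------------


def nn_cpd(
    tensor: np.ndarray,
    rank: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> CPDModel:
    """Fit a rank-``rank`` nonnegative CPD by HALS alternating least squares.

    Each sweep updates every mode by exact nonnegative coordinate
    minimization column by column, so the squared reconstruction error is
    nonincreasing across iterations; the sweep loop stops when the relative
    change of the error drops below ``tol`` or after ``max_iter`` sweeps.
    Deterministic given ``seed`` (uniform random initialization).
    """
    X = np.asarray(tensor, dtype=float)
    if not np.all(np.isfinite(X)):
        raise DataError("tensor contains non-finite entries")
    if np.any(X < 0):
        raise DataError("nonnegative CPD requires a nonnegative tensor")
    if rank < 1:
        raise ConfigurationError("rank must be >= 1")
    norm_x = np.linalg.norm(X)
    if norm_x == 0:
        raise DataError("cannot decompose an all-zero tensor")

    rng = np.random.default_rng(seed)
    ndim = X.ndim
    # scale the random init so the initial reconstruction has the tensor's norm
    scale = (norm_x / np.sqrt(rank)) ** (1.0 / ndim)
    factors = [
        rng.uniform(0.1, 1.0, size=(X.shape[n], rank)) * scale / np.sqrt(X.shape[n])
        for n in range(ndim)
    ]
    unfoldings = [unfold(X, n) for n in range(ndim)]
    grams = [U.T @ U for U in factors]

    history: list[float] = []
    prev_err = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for n in range(ndim):
            kr = _khatri_rao_except(factors, n)
            W = unfoldings[n] @ kr                      # I_n x R  (MTTKRP)
            G = reduce(np.multiply, [grams[k] for k in range(ndim) if k != n])
            U = factors[n]
            for r in range(U.shape[1]):
                denom = G[r, r]
                if denom < _EPS:
                    denom = _EPS
                col = U[:, r] + (W[:, r] - U @ G[:, r]) / denom
                np.maximum(col, 0.0, out=col)
                if not np.any(col):
                    # dead component: reseed tiny to keep the update well posed
                    col = rng.uniform(0.0, 1.0, size=col.shape) * _EPS
                U[:, r] = col
            grams[n] = U.T @ U
            last_W, last_G, last_n = W, G, n
        # err^2 = ||X||^2 - 2<U_n, W> + <U_n^T U_n, G> using the last-updated mode
        Un = factors[last_n]
        err_sq = norm_x**2 - 2.0 * float(np.sum(Un * last_W)) + float(
            np.sum(grams[last_n] * last_G)
        )
        err = np.sqrt(max(err_sq, 0.0)) / norm_x
        history.append(err)
        if prev_err - err < tol * max(prev_err, _EPS):
            prev_err = err
            break
        prev_err = err

    # normalize columns to unit L2, collecting scales into the weights
    weights = np.ones(rank)
    for n in range(ndim):
        norms = np.linalg.norm(factors[n], axis=0)
        norms_safe = np.where(norms > 0, norms, 1.0)
        factors[n] = factors[n] / norms_safe
        weights *= norms
    model = CPDModel(
        factors=factors,
        weights=weights,
        rank=rank,
        rel_error=float(prev_err),
        run_seed=seed,
        n_iter=n_iter,
        error_history=history,
    )
    # report the exact reconstruction error (self-consistency with relative_error)
    model.rel_error = relative_error(model, X)
    return model


def ensemble_seeds(master_seed: int, n_runs: int) -> list[int]:
    """Distinct deterministic per-run seeds derived from the master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n_runs, dtype=np.uint32)
    return [int(s % (2**31 - 1)) for s in state]


def run_cpd_ensemble(
    tensor: np.ndarray,
    rank: int,
    n_runs: int = 10,
    master_seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> list[CPDModel]:
    """Run the nonnegative CPD ``n_runs`` times from distinct random starts.

    The CPD is not unique, so multiple runs expose the variation that the
    cross-run consensus screening later consolidates.
    """
    if n_runs < 1:
        raise ConfigurationError("n_runs must be >= 1")
    return [
        nn_cpd(tensor, rank, seed=s, max_iter=max_iter, tol=tol)
        for s in ensemble_seeds(master_seed, n_runs)
    ]


AUDIT_SEED = 20231109  # fixed seed for rank-selection fits, distinct from runs


def select_rank_cpd(
    tensor: np.ndarray,
    r_max: int = 15,
    error_threshold: float = 0.10,
    seed: int = AUDIT_SEED,
    max_iter: int = 200,
    tol: float = 1e-7,
) -> tuple[int, np.ndarray, bool]:
    """Pick the smallest rank whose relative error falls below the threshold.

    Fits ranks ``1..r_max`` once each from a fixed audit seed and returns
    ``(selected_rank, error_curve, threshold_met)``; when no rank qualifies,
    ``r_max`` is returned with ``threshold_met=False``. The full curve is
    kept so the error-versus-rank elbow can be audited.
    """
    if r_max < 1:
        raise ConfigurationError("r_max must be >= 1")
    errors = np.empty(r_max)
    for r in range(1, r_max + 1):
        model = nn_cpd(tensor, r, seed=seed + r, max_iter=max_iter, tol=tol)
        errors[r - 1] = model.rel_error
    below = np.nonzero(errors < error_threshold)[0]
    if below.size:
        return int(below[0]) + 1, errors, True
    return r_max, errors, False


# ---------------------------------------------------------------------------
# orthogonal Tucker
# ---------------------------------------------------------------------------


def _truncated_left_sv(mat: np.ndarray, rank: int) -> np.ndarray:
    U, _, _ = np.linalg.svd(mat, full_matrices=False)
    return U[:, :rank]


def hosvd(tensor: np.ndarray, ranks: tuple[int, ...]) -> TuckerModel:
    """Truncated higher-order SVD (the HOOI initializer)."""
    X = np.asarray(tensor, dtype=float)
    factors = [_truncated_left_sv(unfold(X, n), ranks[n]) for n in range(X.ndim)]
    core = X
    for n, U in enumerate(factors):
        core = mode_dot(core, U.T, n)
    model = TuckerModel(core=core, factors=factors, ranks=tuple(ranks), rel_error=np.nan)
    model.rel_error = relative_error(model, X)
    return model


def orthogonal_tucker(
    tensor: np.ndarray,
    ranks: tuple[int, ...],
    tol: float = 1e-8,
    max_iter: int = 200,
) -> TuckerModel:
    """Orthogonal Tucker via HOSVD initialization + higher-order orthogonal iteration.

    Every sweep re-solves each factor as the dominant subspace of the tensor
    projected through the other modes' current factors, so the captured core
    norm (the fit) is nondecreasing across sweeps. Factors are orthonormal to
    machine precision by construction.
    """
    X = np.asarray(tensor, dtype=float)
    if not np.all(np.isfinite(X)):
        raise DataError("tensor contains non-finite entries")
    if len(ranks) != X.ndim:
        raise ConfigurationError("one rank per tensor mode required")
    for n, r in enumerate(ranks):
        if not (1 <= r <= X.shape[n]):
            raise ConfigurationError(
                f"mode-{n} rank {r} outside [1, {X.shape[n]}]"
            )
    norm_x = np.linalg.norm(X)
    if norm_x == 0:
        raise DataError("cannot decompose an all-zero tensor")

    model = hosvd(X, tuple(ranks))
    factors = model.factors
    fit_history: list[float] = []
    prev_fit = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for n in range(X.ndim):
            Y = X
            for k in range(X.ndim):
                if k != n:
                    Y = mode_dot(Y, factors[k].T, k)
            factors[n] = _truncated_left_sv(unfold(Y, n), ranks[n])
        core = X
        for k in range(X.ndim):
            core = mode_dot(core, factors[k].T, k)
        fit = float(np.linalg.norm(core))  # captured energy; monotone under HOOI
        fit_history.append(fit)
        if fit - prev_fit < tol * max(abs(prev_fit), _EPS):
            prev_fit = fit
            break
        prev_fit = fit
    core = X
    for k in range(X.ndim):
        core = mode_dot(core, factors[k].T, k)
    err = np.sqrt(max(norm_x**2 - float(np.linalg.norm(core)) ** 2, 0.0)) / norm_x
    return TuckerModel(
        core=core,
        factors=factors,
        ranks=tuple(ranks),
        rel_error=float(err),
        n_iter=n_iter,
        fit_history=fit_history,
    )


def select_ranks_td(
    tensor: np.ndarray,
    rt_max: int | None = None,
    rc_max: int | None = None,
    error_threshold: float = 0.10,
) -> tuple[tuple[int, int], np.ndarray, bool]:
    """Choose (Rt, Rc) for a 3-way tensor with uncompressed subject mode.

    Scans candidate rank pairs using the HOSVD error estimate
    ``sqrt(sum of discarded mode-0 sv^2 + discarded mode-1 sv^2) / ||Y||``
    (an upper bound on the truncated-HOSVD — hence HOOI — error), in the
    total order smallest ``Rt+Rc`` first, then smallest ``Rt``; the first
    pair whose estimate falls below the threshold wins. Falls back to
    ``(rt_max, rc_max)`` with ``met=False`` if none qualifies.
    """
    Y = np.asarray(tensor, dtype=float)
    if Y.ndim != 3:
        raise ConfigurationError("select_ranks_td expects a 3-way tensor")
    it, ic, _ = Y.shape
    rt_max = min(rt_max or it, it)
    rc_max = min(rc_max or ic, ic)
    norm_y = np.linalg.norm(Y)
    if norm_y == 0:
        raise DataError("cannot select ranks for an all-zero tensor")
    sv_t = np.linalg.svd(unfold(Y, 0), compute_uv=False)
    sv_c = np.linalg.svd(unfold(Y, 1), compute_uv=False)
    tail_t = np.concatenate([np.cumsum(sv_t[::-1] ** 2)[::-1], [0.0]])  # tail_t[r] = sum_{i>=r}
    tail_c = np.concatenate([np.cumsum(sv_c[::-1] ** 2)[::-1], [0.0]])
    surface = np.empty((rt_max, rc_max))
    for rt in range(1, rt_max + 1):
        for rc in range(1, rc_max + 1):
            est_sq = tail_t[min(rt, len(sv_t))] + tail_c[min(rc, len(sv_c))]
            surface[rt - 1, rc - 1] = np.sqrt(max(est_sq, 0.0)) / norm_y
    candidates = sorted(
        ((rt, rc) for rt in range(1, rt_max + 1) for rc in range(1, rc_max + 1)),
        key=lambda p: (p[0] + p[1], p[0]),
    )
    for rt, rc in candidates:
        if surface[rt - 1, rc - 1] < error_threshold:
            return (rt, rc), surface, True
    return (rt_max, rc_max), surface, False


# ---------------------------------------------------------------------------
# factor matching (recovery scoring)
# ---------------------------------------------------------------------------


def factor_congruence(
    estimated: list[np.ndarray], truth: list[np.ndarray]
) -> tuple[np.ndarray, list[int]]:
    """Greedy permutation matching of estimated to true components.

    The congruence of a component pair is the product over modes of the
    cosine similarity between the corresponding factor columns (invariant to
    per-mode scaling). Returns per-true-component congruences after greedy
    assignment, plus the permutation.
    """
    r_true = truth[0].shape[1]
    r_est = estimated[0].shape[1]
    sim = np.ones((r_true, r_est))
    for U_t, U_e in zip(truth, estimated):
        a = U_t / np.maximum(np.linalg.norm(U_t, axis=0), _EPS)
        b = U_e / np.maximum(np.linalg.norm(U_e, axis=0), _EPS)
        sim *= np.abs(a.T @ b)
    perm: list[int] = [-1] * r_true
    scores = np.zeros(r_true)
    available = set(range(r_est))
    for _ in range(min(r_true, r_est)):
        masked = sim.copy()
        masked[[i for i in range(r_true) if perm[i] >= 0], :] = -np.inf
        masked[:, [j for j in range(r_est) if j not in available]] = -np.inf
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        perm[i] = int(j)
        scores[i] = sim[i, j]
        available.discard(int(j))
    return scores, perm
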