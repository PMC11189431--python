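"""Sparse coding: coefficient inference, cost, dictionary learning, metrics.

A preprocessed patch x (frame flattened to N pixels) is approximated as a
linear combination of P dictionary atoms g_i,

    x  ~=  sum_i b_i g_i,

with the coefficients chosen to minimize the cost

    C(b) = sum_pixels [x - sum_i b_i g_i]^2 + lambda * sum_i S(b_i / sigma).

The first term preserves the image content; the second charges the code for
spreading activity over many coefficients.  S is an even, non-decreasing
neural-activation-style penalty — log(1 + x^2) by default, with 1 - e^{-x^2}
and |x| as alternatives — sigma a scaling constant (by default the pooled
pixel variance of the preprocessed training patches) and lambda = 0.15 sigma.
With lambda = 0 the cost reduces to plain least squares, and with a complete
linearly independent basis it is driven exactly to zero.

Dictionary learning is stochastic gradient descent on the batch-mean cost
with respect to the atoms at fixed inferred coefficients: after coding a
batch (default 100 patches), each atom moves along the mean of
(coefficient x residual), and atom gains are then rescaled so the running
variance of every coefficient matches the common mean — the variance
equalization that keeps atoms from collapsing or monopolizing the code.
Training stops once the variance of the batch-mean cost over a sliding
window falls to 1% of its mean.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np

from .dictionary_init import Dictionary
from .exceptions import ConfigError, DegenerateError, DomainError, ShapeError
from .image_prep import PatchSet

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Sparsity penalties (value, derivative).  The |x| option uses a
# Huber-smoothed derivative near 0 (half-width 1e-6) so that conjugate
# gradients stays well-defined.
# ---------------------------------------------------------------------------

_HUBER_DELTA = 1e-6


def _abs_value(x):
    ax = np.abs(x)
    small = ax < _HUBER_DELTA
    return np.where(small, x * x / (2 * _HUBER_DELTA) + _HUBER_DELTA / 2, ax)


def _abs_deriv(x):
    return np.clip(x / _HUBER_DELTA, -1.0, 1.0)


SPARSITY_FUNCTIONS = {
    "log1px2": (lambda x: np.log1p(x * x), lambda x: 2 * x / (1 + x * x)),
    "one_minus_exp": (lambda x: -np.expm1(-(x * x)), lambda x: 2 * x * np.exp(-(x * x))),
    "abs": (_abs_value, _abs_deriv),
}


# ---------------------------------------------------------------------------
# Configuration and code containers
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CostConfig:
    """Cost-function configuration.

    ``sigma``/``lam`` may be left as None and resolved against training data:
    sigma becomes the pooled population pixel variance of the patches
    (``sigma_mode='std'`` uses the standard deviation instead) and
    lam = lam_scale * sigma.
    """

    s_fn: str = "log1px2"
    sigma: float | None = None
    lam: float | None = None
    lam_scale: float = 0.15
    sigma_mode: str = "variance"  # or "std"

    def __post_init__(self) -> None:
        if self.s_fn not in SPARSITY_FUNCTIONS:
            raise ConfigError(
                f"unknown sparsity function {self.s_fn!r}; "
                f"choose from {sorted(SPARSITY_FUNCTIONS)}"
            )
        if self.sigma is not None and self.sigma <= 0:
            raise ConfigError("sigma must be positive")
        if self.lam is not None and self.lam < 0:
            raise ConfigError("lambda must be non-negative")

    def resolve(self, patches: np.ndarray) -> "CostConfig":
        """Freeze sigma/lambda against a pool of preprocessed patches."""
        var = float(np.var(patches))
        if var <= 0:
            raise ConfigError("patch pool has zero pixel variance")
        sigma = self.sigma
        if sigma is None:
            sigma = var if self.sigma_mode == "variance" else float(np.sqrt(var))
        lam = self.lam if self.lam is not None else self.lam_scale * sigma
        return dataclasses.replace(self, sigma=sigma, lam=lam)

    def _concrete(self) -> tuple[float, float]:
        if self.sigma is None or self.lam is None:
            raise ConfigError(
                "sigma/lambda unresolved; call resolve() or set them explicitly"
            )
        return self.sigma, self.lam


@dataclasses.dataclass
class SparseCode:
    """Coefficient vector for one patch, with optional top-k support."""

    coefficients: np.ndarray
    support: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)


# ---------------------------------------------------------------------------
# Cost and inference
# ---------------------------------------------------------------------------


def _patch_vector(patch, n_pixels: int) -> np.ndarray:
    x = np.asarray(patch, dtype=float).ravel()
    if x.size != n_pixels:
        raise ShapeError(f"patch has {x.size} pixels, dictionary expects {n_pixels}")
    return x


def evaluate_cost(
    patch, code: SparseCode | np.ndarray, dictionary: Dictionary, cfg: CostConfig
) -> float:
    """Evaluate the sparse-coding cost of a (patch, code) pair."""
    sigma, lam = cfg._concrete()
    b = code.coefficients if isinstance(code, SparseCode) else np.asarray(code, float)
    G = dictionary.as_matrix()
    if b.size != G.shape[1]:
        raise ShapeError(f"code length {b.size} != atom count {G.shape[1]}")
    x = _patch_vector(patch, G.shape[0])
    residual = x - G @ b
    s_value = SPARSITY_FUNCTIONS[cfg.s_fn][0]
    return float(residual @ residual + lam * s_value(b / sigma).sum())


def _batch_cg(G, X, lam, sigma, s_fn, gtol, maxiter):
    """Minimize sum-over-columns of the coding cost with Polak-Ribiere+ CG.

    G: (N, P) synthesis matrix; X: (N, nb) patches.  Returns B (P, nb) and
    the per-column final cost.  Zero initialization; the line search starts
    from the exact minimizer of the quadratic term along the direction and
    backtracks on the full objective, so every iterate is a descent step and
    for lam = 0 the scheme is exact linear CG.
    """
    s_value, s_deriv = SPARSITY_FUNCTIONS[s_fn]
    P, nb = G.shape[1], X.shape[1]
    B = np.zeros((P, nb))
    R = X.copy()  # residual X - G B

    def cost(Bc, Rc):
        return np.sum(Rc * Rc) + lam * np.sum(s_value(Bc / sigma))

    def grad(Bc, Rc):
        g = -2.0 * (G.T @ Rc)
        if lam > 0:
            g = g + (lam / sigma) * s_deriv(Bc / sigma)
        return g

    f = cost(B, R)
    g = grad(B, R)
    d = -g
    g_dot = np.sum(g * g)
    for _ in range(maxiter):
        if np.sqrt(g_dot) <= gtol:
            break
        slope = np.sum(g * d)
        if slope >= 0:  # not a descent direction: restart
            d = -g
            slope = -g_dot
        Gd = G @ d
        denom = np.sum(Gd * Gd)
        # Exact step for the quadratic part (exact line search when lam = 0).
        alpha = np.sum(R * Gd) / denom if denom > 0 else 1.0
        if alpha <= 0:
            alpha = 1e-3
        # Backtracking Armijo on the full objective.
        for _ in range(40):
            B_new = B + alpha * d
            R_new = R - alpha * Gd
            f_new = cost(B_new, R_new)
            if f_new <= f + 1e-4 * alpha * slope:
                break
            alpha *= 0.5
        else:
            break  # line search failed: gradient numerically flat
        B, R, f = B_new, R_new, f_new
        g_new = grad(B, R)
        g_new_dot = np.sum(g_new * g_new)
        beta = max(0.0, np.sum(g_new * (g_new - g)) / g_dot)  # PR+
        d = -g_new + beta * d
        g, g_dot = g_new, g_new_dot
    costs = np.sum(R * R, axis=0) + lam * np.sum(s_value(B / sigma), axis=0)
    return B, costs


def batch_infer_coefficients(
    patches,
    dictionary: Dictionary,
    cfg: CostConfig,
    gtol: float | None = None,
    maxiter: int = 500,
) -> np.ndarray:
    """Infer coefficients for many patches sharing one dictionary.

    Returns a (P, n_patches) array.  ``patches`` may be a PatchSet or an
    array of shape (n, frame, frame) or (n, N).
    """
    sigma, lam = cfg._concrete()
    G = dictionary.as_matrix()
    if isinstance(patches, PatchSet):
        X = patches.as_matrix().T
    else:
        arr = np.asarray(patches, dtype=float)
        X = arr.reshape(arr.shape[0], -1).T
    if X.shape[0] != G.shape[0]:
        raise ShapeError("patch size does not match dictionary frame size")
    if gtol is None:
        gtol = 1e-6 * G.shape[1] * np.sqrt(X.shape[1])
    B, _ = _batch_cg(G, X, lam, sigma, cfg.s_fn, gtol, maxiter)
    return B


def infer_coefficients(
    patch,
    dictionary: Dictionary,
    cfg: CostConfig,
    gtol: float | None = None,
    maxiter: int = 500,
) -> SparseCode:
    """Minimize the coding cost for one patch (nonlinear conjugate gradient).

    Zero-initialized Polak-Ribiere+ CG with monotone line search; the
    returned cost never exceeds the cost of the all-zero code.  Default
    gradient-norm tolerance is 1e-6 * P.  Non-convergence within the
    iteration cap emits a warning and returns the best iterate.
    """
    sigma, lam = cfg._concrete()
    G = dictionary.as_matrix()
    x = _patch_vector(patch, G.shape[0])
    if gtol is None:
        gtol = 1e-6 * G.shape[1]
    B, costs = _batch_cg(G, x[:, None], lam, sigma, cfg.s_fn, gtol, maxiter)
    b = B[:, 0]
    # Descent guarantee relative to the all-zero code.
    if costs[0] > x @ x:
        warnings.warn("inference did not improve on the zero code; returning zeros")
        b = np.zeros_like(b)
    grad_norm = np.linalg.norm(
        -2.0 * G.T @ (x - G @ b)
        + (lam / sigma) * SPARSITY_FUNCTIONS[cfg.s_fn][1](b / sigma)
    )
    if grad_norm > gtol * (1 + np.linalg.norm(x)):
        warnings.warn(
            f"coefficient inference stopped at gradient norm {grad_norm:.3g} "
            f"(tolerance {gtol:.3g}); returning best iterate"
        )
    return SparseCode(coefficients=b)


# ---------------------------------------------------------------------------
# Sparsification, synthesis, metrics
# ---------------------------------------------------------------------------


def sparsify(code: SparseCode, k: int) -> SparseCode:
    """Keep the k largest-magnitude coefficients (ties: lower index wins)."""
    b = code.coefficients
    if not 0 <= k <= b.size:
        raise DomainError(f"k must lie in [0, {b.size}]")
    # Stable sort on -|b| keeps the lower index first among ties.
    order = np.argsort(-np.abs(b), kind="stable")
    support = np.sort(order[:k])
    out = np.zeros_like(b)
    out[support] = b[support]
    return SparseCode(coefficients=out, support=support)


def reconstruct(code: SparseCode | np.ndarray, dictionary: Dictionary) -> np.ndarray:
    """Linear synthesis sum_i b_i g_i, returned in patch shape."""
    b = code.coefficients if isinstance(code, SparseCode) else np.asarray(code, float)
    G = dictionary.as_matrix()
    if b.size != G.shape[1]:
        raise ShapeError(f"code length {b.size} != atom count {G.shape[1]}")
    f = dictionary.frame_size
    return (G @ b).reshape(f, f)


def reconstruction_metrics(original, reconstructed) -> dict:
    """Pearson correlation and relative MSE (percent of pixel variance)."""
    x = np.asarray(original, float).ravel()
    y = np.asarray(reconstructed, float).ravel()
    if x.shape != y.shape:
        raise ShapeError("original and reconstruction must have the same shape")
    var = np.var(x)  # population variance
    if var == 0:
        raise DegenerateError("metrics undefined for a constant original")
    mse = np.mean((x - y) ** 2)
    if np.var(y) == 0:
        correlation = 0.0
    else:
        correlation = float(np.corrcoef(x, y)[0, 1])
    return {"correlation": correlation, "relative_mse": float(100.0 * mse / var)}


def coefficients_for_correlation(
    patch, code: SparseCode, dictionary: Dictionary, target: float = 0.97
) -> int:
    """Smallest k whose top-k reconstruction reaches the target correlation.

    Scans k = 1..P over the magnitude ordering of the full code; returns P
    if the target is never reached.
    """
    b = code.coefficients
    G = dictionary.as_matrix()
    x = _patch_vector(patch, G.shape[0])
    if np.var(x) == 0:
        raise DegenerateError("correlation undefined for a constant patch")
    order = np.argsort(-np.abs(b), kind="stable")
    recon = np.zeros_like(x)
    for k, idx in enumerate(order, start=1):
        recon = recon + b[idx] * G[:, idx]
        if np.var(recon) == 0:
            continue
        if np.corrcoef(x, recon)[0, 1] >= target:
            return k
    return b.size


# ---------------------------------------------------------------------------
# Dictionary learning
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TrainingSchedule:
    """Batching, stopping and step-size settings for training."""

    batch_size: int = 100
    max_batches: int = 3000
    window: int = 20  # sliding window (batches) for the 1%-variance stop rule
    learning_rate: float = 0.1  # scaled by 1 / batch-mean coefficient energy
    seed: int = 0
    infer_maxiter: int = 500
    # Atom maintenance: every `replace_every` batches (during the first
    # `replace_phase` fraction of the budget), one atom of any pair with
    # mutual |cos| above `coherence_threshold`, and any dead atom, is
    # re-seeded from the worst-reconstructed residual direction.
    replace_every: int = 10
    coherence_threshold: float = 0.92
    replace_phase: float = 0.75


@dataclasses.dataclass
class TrainingState:
    """Mutable training bookkeeping around a dictionary."""

    dictionary: Dictionary
    batch_count: int = 0
    cost_history: list = dataclasses.field(default_factory=list)
    coeff_var: np.ndarray | None = None  # running per-atom coefficient variance
    coeff_var_target: float | None = None  # frozen common variance target
    var_decay: float = 0.3
    learning_rate: float = 0.1
    converged: bool = False
    # Last-batch artifacts for atom maintenance (set by update_dictionary).
    _last_residual: np.ndarray | None = dataclasses.field(
        default=None, repr=False, compare=False
    )
    _last_patches: np.ndarray | None = dataclasses.field(
        default=None, repr=False, compare=False
    )

    @property
    def iterations_to_convergence(self) -> int | None:
        return self.batch_count if self.converged else None


def _as_patch_array(batch) -> np.ndarray:
    if isinstance(batch, PatchSet):
        return batch.as_matrix()
    arr = np.asarray(batch, dtype=float)
    return arr.reshape(arr.shape[0], -1)


def update_dictionary(batch, state: TrainingState, cfg: CostConfig) -> TrainingState:
    """One learning step on a batch of preprocessed patches (in place).

    Coefficients are inferred for every patch; each atom then moves along
    the negative cost gradient, Delta g_i ∝ mean_batch(b_i * residual), with
    step 'learning_rate / batch-mean coefficient energy'; finally atom gains
    are rescaled so the running coefficient variances are all equal to their
    common mean.
    """
    if len(batch) == 0:
        warnings.warn("empty batch: dictionary update skipped")
        return state
    X = _as_patch_array(batch).T
    sigma, lam = cfg._concrete()
    G = state.dictionary.as_matrix()
    nb = X.shape[1]
    gtol = 1e-6 * G.shape[1] * np.sqrt(nb)
    B, costs = _batch_cg(G, X, lam, sigma, cfg.s_fn, gtol, maxiter=500)
    state.cost_history.append(float(costs.mean()))

    R = X - G @ B
    delta = R @ B.T / nb  # (N, P): mean over batch of residual * coefficient
    coeff_energy = float(np.mean(B * B))
    step = state.learning_rate / max(coeff_energy, 1e-12)
    G = G + step * delta

    # Variance-equalizing gain rescale.  Coefficients are zero-mean by
    # symmetry, so the running second moment serves as the variance.  The
    # common target is frozen after the first batch: rescaling to a moving
    # mean would leave a global scale ambiguity that lets atoms grow until
    # the sparsity penalty is voided.
    batch_var = np.mean(B * B, axis=1)
    if state.coeff_var is None:
        state.coeff_var = batch_var.copy()
    else:
        rho = state.var_decay
        state.coeff_var = (1 - rho) * state.coeff_var + rho * batch_var
    if state.coeff_var_target is None:
        state.coeff_var_target = float(state.coeff_var.mean())
    active = state.coeff_var > 1e-14
    if active.any():
        target = state.coeff_var_target
        scale = np.ones_like(state.coeff_var)
        scale[active] = np.sqrt(state.coeff_var[active] / target)
        G = G * scale[None, :]
        # Scaling an atom by s scales its future coefficients by 1/s.
        state.coeff_var[active] = target

    state.dictionary = state.dictionary.with_matrix(G)
    state.batch_count += 1
    # Gain rescaling leaves the reconstruction (and hence the residual)
    # unchanged, so R is still the current residual.
    state._last_residual = R
    state._last_patches = X
    return state


def _maintain_atoms(state: TrainingState, threshold: float) -> int:
    """Replace coherent-duplicate and dead atoms (in place).

    For every atom pair with mutual |cosine| above ``threshold`` (and every
    atom whose running coefficient variance has collapsed), one member is
    re-seeded from the worst-reconstructed residual direction of the last
    batch — the standard duplicate-pruning step of dictionary learners.
    Returns the number of replacements.
    """
    if state._last_residual is None or state.coeff_var is None:
        return 0
    G = state.dictionary.as_matrix()
    R, X = state._last_residual, state._last_patches
    norms = np.linalg.norm(G, axis=0)
    unit = G / np.where(norms > 0, norms, 1.0)
    coherence = np.abs(unit.T @ unit)
    np.fill_diagonal(coherence, 0.0)
    residual_norm = np.sum(R * R, axis=0)
    median_norm = float(np.median(norms))
    target = state.coeff_var_target or 1.0
    dead = state.coeff_var <= 1e-10 * target
    to_replace: list[int] = [int(i) for i in np.flatnonzero(dead)]
    taken = set(to_replace)
    P = G.shape[1]
    for i in range(P):
        if i in taken:
            continue
        for j in range(i + 1, P):
            if j in taken:
                continue
            if coherence[i, j] > threshold:
                to_replace.append(j)
                taken.add(j)
    for j in to_replace:
        k = int(np.argmax(residual_norm))
        new_atom = R[:, k]
        if np.linalg.norm(new_atom) < 1e-9:
            new_atom = X[:, k]
        residual_norm[k] = 0.0
        G[:, j] = new_atom / max(np.linalg.norm(new_atom), 1e-12) * median_norm
        state.coeff_var[j] = target
    if to_replace:
        state.dictionary = state.dictionary.with_matrix(G)
    return len(to_replace)


def _stopping_predicate(history, window: int) -> bool:
    if len(history) < window:
        return False
    recent = np.asarray(history[-window:])
    return bool(np.var(recent) <= 0.01 * np.mean(recent))


def train(
    patches,
    init: Dictionary,
    cfg: CostConfig,
    schedule: TrainingSchedule | None = None,
) -> TrainingState:
    """Iterative dictionary learning over a pool of preprocessed patches.

    Batches are drawn by cycling the seeded-shuffled patch pool.  Training
    stops when the variance of the batch-mean cost over the last ``window``
    batches drops to 1% of its mean, or at ``max_batches`` (in which case
    ``converged`` stays False).
    """
    if schedule is None:
        schedule = TrainingSchedule()
    pool = _as_patch_array(patches)
    if len(pool) == 0:
        raise DomainError("training requires at least one patch")
    if pool.shape[1] != init.n_pixels:
        raise ShapeError("patch size does not match the initial dictionary")
    cfg = cfg.resolve(pool)
    rng = np.random.default_rng(schedule.seed)
    order = rng.permutation(len(pool))
    state = TrainingState(
        dictionary=Dictionary(atoms=list(init.atoms), frame_size=init.frame_size),
        learning_rate=schedule.learning_rate,
    )
    cursor = 0
    replace_until = int(schedule.max_batches * schedule.replace_phase)
    for batch_no in range(schedule.max_batches):
        idx = order[np.arange(cursor, cursor + schedule.batch_size) % len(pool)]
        cursor = (cursor + schedule.batch_size) % len(pool)
        update_dictionary(pool[idx], state, cfg)
        if (
            schedule.replace_every > 0
            and (batch_no + 1) % schedule.replace_every == 0
            and batch_no < replace_until
        ):
            _maintain_atoms(state, schedule.coherence_threshold)
        if _stopping_predicate(state.cost_history, schedule.window):
            state.converged = True
            break
    logger.info(
        "training %s after %d batches (final cost %.4g)",
        "converged" if state.converged else "stopped",
        state.batch_count,
        state.cost_history[-1] if state.cost_history else float("nan"),
    )
    return state


def match_atoms(learned: Dictionary, truth: Dictionary) -> np.ndarray:
    """Greedy bipartite matching of learned to ground-truth atoms.

    Returns the |cosine| similarity of each matched pair (length = number of
    truth atoms), pairing the globally most similar unmatched pair first.
    """
    A = learned.as_matrix()
    T = truth.as_matrix()
    A = A / np.linalg.norm(A, axis=0, keepdims=True)
    T = T / np.linalg.norm(T, axis=0, keepdims=True)
    sim = np.abs(A.T @ T)  # (P_learned, P_truth)
    sim = sim.copy()
    out = np.zeros(T.shape[1])
    for _ in range(min(sim.shape)):
        i, j = np.unravel_index(np.argmax(sim), sim.shape)
        out[j] = sim[i, j]
        sim[i, :] = -1
        sim[:, j] = -1
    return out
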