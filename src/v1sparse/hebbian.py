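"""Hebbian weight dynamics, the log-normal steady state, and identity structure.

The synaptic weight w_ij between a pre-synaptic neuron i (mean firing rate
fbar_i) and a post-synaptic neuron j evolves under a Hebbian growth term and
a linear decay,

    dw_ij/dt = c1 * fbar_i^alpha * w_ij^beta * fbar_j^gamma - c2 * w_ij,

with adjustable positive rate constants c1, c2 and exponents alpha, beta,
gamma.  For beta < 1 (and c1, c2 > 0) every positive weight is attracted to
the closed-form steady state

    w_ij = c * fbar_i^(alpha/(1-beta)) * fbar_j^(gamma/(1-beta)),
    c    = (c1/c2)^(1/(1-beta)).

Cortical firing rates are empirically log-normal; powers and products of
log-normal variables are log-normal, so the steady-state weights inherit a
log-normal law.  Because strong weights link neurons with strong (and
correlated) rates on both sides, the weight matrix carries its dominant mass
on correctly-paired pre/post combinations — after ordering neurons by
response similarity it is first-order approximated by a scaled identity,
the structural bridge to direct-shortcut residual networks.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from statsmodels.stats.diagnostic import lilliefors

from .exceptions import (
    DegenerateError,
    DomainError,
    InstabilityError,
    RegularityError,
    ShapeError,
)

_OVERFLOW_GUARD = 1e12


# ---------------------------------------------------------------------------
# Populations and parameters
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class NeuronPopulation:
    """Mean firing rates (and optional response traces) of n neurons."""

    mean_rates: np.ndarray
    mu: float | None = None  # parameters of the underlying normal law
    sd: float | None = None
    traces: np.ndarray | None = None  # optional (n, T) responses

    def __post_init__(self) -> None:
        self.mean_rates = np.asarray(self.mean_rates, dtype=float)
        if np.any(self.mean_rates <= 0):
            raise DomainError("all mean rates must be positive")

    @property
    def n(self) -> int:
        return self.mean_rates.size


@dataclasses.dataclass
class PlasticityParams:
    """Rate constants and exponents of the Hebbian rule.

    Regularity (a finite attracting steady state for positive weights)
    requires c1 > 0, c2 > 0 and beta < 1.
    """

    c1: float = 1.0
    c2: float = 1.0
    alpha: float = 1.0
    beta: float = 0.5
    gamma: float = 1.0

    def __post_init__(self) -> None:
        # c1 = 0 is admitted as the pure-decay limit (all weights -> 0).
        if self.c1 < 0 or self.c2 <= 0:
            raise RegularityError("c1 must be >= 0 and c2 > 0")
        if self.beta >= 1:
            raise RegularityError("beta must be < 1 for a finite steady state")

    @property
    def pre_exponent(self) -> float:
        return self.alpha / (1.0 - self.beta)

    @property
    def post_exponent(self) -> float:
        return self.gamma / (1.0 - self.beta)

    @property
    def c(self) -> float:
        return (self.c1 / self.c2) ** (1.0 / (1.0 - self.beta))


@dataclasses.dataclass
class WeightMatrix:
    """n x n non-negative weights, w[i, j] = pre i -> post j."""

    w: np.ndarray
    t: float | None = None
    steady_state: bool = False

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 2 or self.w.shape[0] != self.w.shape[1]:
            raise ShapeError("weight matrix must be square")

    @property
    def n(self) -> int:
        return self.w.shape[0]


# ---------------------------------------------------------------------------
# Sampling and dynamics
# ---------------------------------------------------------------------------


def sample_lognormal_rates(
    n: int, mu: float = 0.0, sd: float = 1.0, seed: int = 0
) -> NeuronPopulation:
    """Draw i.i.d. log-normal mean rates exp(Normal(mu, sd))."""
    if sd <= 0:
        raise DomainError("sd must be positive")
    if n < 1:
        raise DomainError("n must be at least 1")
    rng = np.random.default_rng(seed)
    rates = np.exp(rng.normal(mu, sd, size=n))
    return NeuronPopulation(mean_rates=rates, mu=mu, sd=sd)


def steady_state_weights(
    pop: NeuronPopulation, params: PlasticityParams
) -> WeightMatrix:
    """Closed-form steady state c * fbar_i^(a/(1-b)) * fbar_j^(g/(1-b))."""
    pre = pop.mean_rates**params.pre_exponent
    post = pop.mean_rates**params.post_exponent
    return WeightMatrix(w=params.c * np.outer(pre, post), steady_state=True)


def steady_state_pair_sample(
    pop: NeuronPopulation, params: PlasticityParams
) -> np.ndarray:
    """Steady-state weights over disjoint neuron pairs, w[i, m+i] for i < m.

    These floor(n/2) entries involve each neuron at most once, so they are
    independent draws of the weight-entry marginal — the correct sample for
    distributional tests, which entries sharing a neuron (a full row or the
    whole matrix) are not.  Computed from the closed form without
    materializing the n x n matrix.
    """
    m = pop.n // 2
    if m < 1:
        raise DomainError("need at least two neurons")
    pre = pop.mean_rates[:m] ** params.pre_exponent
    post = pop.mean_rates[m : 2 * m] ** params.post_exponent
    return params.c * pre * post


@dataclasses.dataclass
class HebbianTrajectory:
    """Stored snapshots of a simulated weight trajectory."""

    times: np.ndarray
    weights: np.ndarray  # (snapshots, n, n)

    @property
    def final(self) -> WeightMatrix:
        return WeightMatrix(w=self.weights[-1], t=float(self.times[-1]))


def simulate_hebbian(
    pop: NeuronPopulation,
    params: PlasticityParams,
    w0: WeightMatrix | np.ndarray,
    dt: float | None = None,
    t_end: float | None = None,
    store_every: int | None = None,
) -> HebbianTrajectory:
    """Integrate the Hebbian ODE by explicit Euler, entry-wise.

    Defaults: dt = 0.01/c2 and t_end = 50/c2, after which the state is well
    inside the integrator tolerance of the closed-form steady state (the
    slowest linearized decay rate is c2*(1-beta)).  Initial weights must be
    strictly positive (fractional powers of 0 are undefined for beta < 0);
    any entry exceeding an overflow guard aborts with an instability error.
    """
    w = np.asarray(w0.w if isinstance(w0, WeightMatrix) else w0, dtype=float).copy()
    if np.any(w <= 0):
        raise DomainError("initial weights must be strictly positive")
    if dt is None:
        dt = 0.01 / params.c2
    if t_end is None:
        t_end = 50.0 / params.c2
    if dt <= 0 or t_end <= 0:
        raise DomainError("dt and t_end must be positive")
    n_steps = int(np.ceil(t_end / dt))
    if store_every is None:
        store_every = max(n_steps // 50, 1)
    hebb_gain = params.c1 * np.outer(
        pop.mean_rates**params.alpha, pop.mean_rates**params.gamma
    )
    if hebb_gain.shape != w.shape:
        raise ShapeError("initial weight matrix does not match the population size")
    times = [0.0]
    snaps = [w.copy()]
    for step in range(1, n_steps + 1):
        w = w + dt * (hebb_gain * w**params.beta - params.c2 * w)
        if not np.all(np.isfinite(w)) or np.any(w > _OVERFLOW_GUARD):
            raise InstabilityError(
                "weight trajectory diverged; regularity requires beta < 1 "
                "and c1, c2 > 0 with finite mean rates"
            )
        if np.any(w <= 0):
            raise InstabilityError(
                "a weight left the positive orthant; reduce dt (stability "
                "needs dt * c2 * (1 - beta) < 2)"
            )
        if step % store_every == 0 or step == n_steps:
            times.append(step * dt)
            snaps.append(w.copy())
    return HebbianTrajectory(times=np.asarray(times), weights=np.stack(snaps))


# ---------------------------------------------------------------------------
# Analysis
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ExponentFit:
    """Log-linear regression estimates of the steady-state structure."""

    pre_exponent: float  # alpha / (1 - beta)
    post_exponent: float  # gamma / (1 - beta)
    log_c: float
    residual_rms: float


def fit_exponents(W: WeightMatrix | np.ndarray, pop: NeuronPopulation) -> ExponentFit:
    """Least-squares fit of log w_ij on (log fbar_i, log fbar_j).

    The steady state is exactly log-linear, so a noiseless matrix recovers
    both exponents with zero residual.
    """
    w = np.asarray(W.w if isinstance(W, WeightMatrix) else W, dtype=float)
    if np.any(w <= 0):
        raise DomainError("all weights must be positive for the log-linear fit")
    logf = np.log(pop.mean_rates)
    n = pop.n
    if w.shape != (n, n):
        raise ShapeError("weight matrix does not match the population size")
    li = np.repeat(logf, n)
    lj = np.tile(logf, n)
    design = np.column_stack([np.ones(n * n), li, lj])
    coef, *_ = np.linalg.lstsq(design, np.log(w).ravel(), rcond=None)
    resid = np.log(w).ravel() - design @ coef
    return ExponentFit(
        pre_exponent=float(coef[1]),
        post_exponent=float(coef[2]),
        log_c=float(coef[0]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


@dataclasses.dataclass
class LognormalityResult:
    statistic: float
    pvalue: float
    passed: bool  # True when log-normality is NOT rejected


def lognormality_test(values, alpha_level: float = 0.01) -> LognormalityResult:
    """Lilliefors-corrected KS test of normality applied to log(values).

    The test assumes independent samples: when applied to entries of a
    steady-state weight matrix, use entries over disjoint neuron pairs
    (entries sharing a neuron are dependent).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 50:
        raise DomainError("need at least 50 values")
    if np.any(v <= 0):
        raise DomainError("values must be positive")
    stat, p = lilliefors(np.log(v), dist="norm")
    return LognormalityResult(
        statistic=float(stat), pvalue=float(p), passed=bool(p > alpha_level)
    )


def linear_response(W: WeightMatrix | np.ndarray, rates) -> np.ndarray:
    """Linear post-synaptic response f_j = sum_i w_ij f_i."""
    w = np.asarray(W.w if isinstance(W, WeightMatrix) else W, dtype=float)
    f = np.asarray(rates, dtype=float)
    if f.ndim != 1 or f.size != w.shape[0]:
        raise ShapeError("rate vector length must equal the number of neurons")
    return f @ w


def identity_approximation_score(
    W: WeightMatrix | np.ndarray,
) -> tuple[float, float]:
    """How well a scaled identity approximates W, and the best scale.

    c_fit minimizes ||W - c I||_F (closed form: the mean diagonal entry);
    score = 1 - ||W - c_fit I||_F^2 / ||W||_F^2, floored at 0.  A score of 1
    means W is an exact multiple of the identity; 0 means the identity
    component explains none of the matrix energy.
    """
    w = np.asarray(W.w if isinstance(W, WeightMatrix) else W, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ShapeError("W must be square")
    total = np.sum(w * w)
    if total == 0:
        raise DegenerateError("identity score undefined for an all-zero matrix")
    c_fit = float(np.mean(np.diag(w)))
    resid = w - c_fit * np.eye(w.shape[0])
    score = 1.0 - np.sum(resid * resid) / total
    return max(0.0, float(score)), c_fit


def identity_permutation_pvalue(
    W: WeightMatrix | np.ndarray,
    n_permutations: int = 100,
    seed: int = 0,
) -> tuple[float, np.ndarray, float]:
    """Empirical p-value of the identity score against scrambled pairings.

    The null scrambles the pre/post pairing by permuting rows and columns
    independently (a *symmetric* permutation P^T W P leaves the score
    invariant — it only relabels neurons — so it cannot serve as a null).
    Returns (observed score, null scores, one-sided empirical p).
    """
    w = np.asarray(W.w if isinstance(W, WeightMatrix) else W, dtype=float)
    score, _ = identity_approximation_score(w)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for k in range(n_permutations):
        pr = rng.permutation(w.shape[0])
        pc = rng.permutation(w.shape[0])
        null[k], _ = identity_approximation_score(w[pr][:, pc])
    p = (1.0 + np.sum(null >= score)) / (n_permutations + 1.0)
    return score, null, float(p)


# ---------------------------------------------------------------------------
# Response-similarity ordering
# ---------------------------------------------------------------------------


def synthesize_response_traces(
    n: int,
    n_groups: int = 4,
    n_samples: int = 200,
    seed: int = 0,
    coupling: float = 0.9,
) -> tuple[np.ndarray, np.ndarray]:
    """Shared-latent-factor log-normal response traces.

    Each neuron loads on one of ``n_groups`` latent factors with weight
    ``coupling``; within-group responses are strongly correlated, across
    groups uncorrelated.  Returns (traces (n, n_samples), group labels).
    """
    if not 0 <= coupling <= 1:
        raise DomainError("coupling must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    groups = rng.integers(0, n_groups, size=n)
    latent = rng.standard_normal((n_groups, n_samples))
    noise = rng.standard_normal((n, n_samples))
    log_traces = coupling * latent[groups] + np.sqrt(1 - coupling**2) * noise
    return np.exp(log_traces), groups


def sort_by_response_similarity(
    W: WeightMatrix | np.ndarray, traces: np.ndarray
) -> tuple[WeightMatrix, np.ndarray]:
    """Reorder neurons so that highly correlated responses become adjacent.

    Greedy seriation on the response-correlation matrix: start from the most
    correlated pair and repeatedly extend whichever chain end has the most
    correlated unused neighbour.  W is permuted symmetrically (rows and
    columns alike), which leaves its identity score unchanged but makes the
    block structure visible.
    """
    w = np.asarray(W.w if isinstance(W, WeightMatrix) else W, dtype=float)
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] != w.shape[0]:
        raise ShapeError("need one response trace per neuron")
    if traces.shape[1] < 10:
        raise DomainError("traces must have at least 10 samples")
    if np.any(traces.std(axis=1) == 0):
        raise DegenerateError("correlation undefined for a constant trace")
    corr = np.corrcoef(traces)
    n = w.shape[0]
    masked = corr.copy()
    np.fill_diagonal(masked, -np.inf)
    i, j = np.unravel_index(np.argmax(masked), masked.shape)
    chain = [int(i), int(j)]
    used = set(chain)
    while len(chain) < n:
        best = None  # (corr, end_index, neuron)
        for end, pos in ((chain[0], 0), (chain[-1], len(chain))):
            for k in range(n):
                if k in used:
                    continue
                if best is None or corr[end, k] > best[0]:
                    best = (corr[end, k], pos, k)
        _, pos, k = best
        chain.insert(pos, k)
        used.add(k)
    perm = np.asarray(chain)
    return WeightMatrix(w=w[perm][:, perm]), perm
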