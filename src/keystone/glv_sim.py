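"""Generalized Lotka-Volterra (GLV) community simulation.

Communities of N interacting taxa follow

    dx_i/dt = r_i x_i + sum_j a_ij x_i x_j,

with intrinsic growth rates r_i ~ U(0, 1), self-regulation a_ii = -1
(logistic term), and off-diagonal interactions drawn U(-sigma_A, sigma_A)
on a random interaction network. A microbial "sample" is a steady state
of this system reached from a random initial condition: each taxon is
initially present with probability ``presence_prob`` (default 0.8) and
present taxa start at abundances U(0, 1). Different initial conditions
reach alternative steady states, which is the source of natural
presence/absence variation across a simulated cohort.

Two topologies are supported:

* Erdos-Renyi (ER): each directed off-diagonal interaction exists
  independently with probability mean_degree / (N - 1). Structurally
  homogeneous, so keystones must be created explicitly by *boosting*:
  multiplying all outgoing interactions a_ji of a chosen taxon i by a
  factor K > 1 (strength-based keystones). K can also be drawn per taxon
  from a log-normal distribution to create a few influential taxa.
* Barabasi-Albert (BA): n_0 fully connected seed nodes, then
  degree-proportional preferential attachment; each undirected edge is
  oriented out of its higher-degree endpoint with probability d
  (directionality), else uniformly. Hubs arise naturally and act as
  structure-based keystones without any boosting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import odeint

from ._exceptions import InstabilityError
from .abundance_data import Cohort, PairedCohort

__all__ = [
    "GLVModel",
    "KeystoneSpec",
    "SteadyState",
    "make_er_model",
    "make_ba_model",
    "boost_species",
    "lognormal_boosts",
    "apply_boosts",
    "simulate_steady_state",
    "generate_cohort",
    "generate_paired_cohort",
    "default_sigma_a",
]

#: abundances below this are treated as extinct (exact zeros downstream)
EXTINCTION_EPS = 1e-8
#: integration aborts when any abundance exceeds this
BLOWUP_CAP = 1e6
#: steady-state criterion: ||dx/dt||_inf / max(||x||_inf, 1e-12) < TOL_SS
TOL_SS = 1e-8
T_MAX = 1000.0


@dataclass
class GLVModel:
    """A GLV system: growth rates, interaction matrix, topology metadata."""

    r: np.ndarray
    A: np.ndarray
    topology: str = "custom"
    params: dict = field(default_factory=dict)
    sigma_A: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        n = self.r.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("A must be N x N matching r")

    @property
    def n_taxa(self) -> int:
        return self.r.shape[0]

    def to_dict(self) -> dict:
        return {
            "r": self.r.tolist(),
            "A": self.A.tolist(),
            "topology": self.topology,
            "params": self.params,
            "sigma_A": self.sigma_A,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GLVModel":
        return cls(np.array(d["r"]), np.array(d["A"]), d.get("topology", "custom"),
                   d.get("params", {}), d.get("sigma_A", 0.0), d.get("seed"))


@dataclass
class KeystoneSpec:
    """A designated strength-based keystone: taxon index and boost K > 0."""

    taxon: int
    K: float = 10.0

    def __post_init__(self):
        if self.K <= 0:
            raise ValueError(f"boost factor K must be positive, got {self.K}")


def default_sigma_a(mean_degree: float) -> float:
    """Interaction scale 0.5 / sqrt(mean degree), small enough that almost
    all random communities reach a stable steady state."""
    return 0.5 / np.sqrt(mean_degree)


def _draw_growth_rates(N: int, growth: str, rng: np.random.Generator) -> np.ndarray:
    if growth == "uniform":
        return rng.uniform(0.0, 1.0, N)
    if growth == "unit":
        return np.ones(N)
    raise ValueError(f"unknown growth-rate scheme {growth!r}")


def make_er_model(N: int, mean_degree: float, sigma_A: float, seed: int,
                  growth: str = "uniform") -> GLVModel:
    """GLV model on a directed Erdos-Renyi interaction network.

    Each off-diagonal a_ij is nonzero independently with probability
    ``mean_degree / (N - 1)``; nonzero values are U(-sigma_A, sigma_A),
    the diagonal is -1. Growth rates are r_i ~ U(0, 1) by default;
    ``growth='unit'`` sets every r_i = 1, the convention used in
    designated-keystone demonstration cohorts so that the keystone's
    influence is not confounded with a randomly tiny intrinsic growth
    rate.
    """
    if not 0 < mean_degree < N:
        raise ValueError("mean_degree must lie in (0, N)")
    rng = np.random.default_rng(seed)
    p = mean_degree / (N - 1)
    mask = rng.random((N, N)) < p
    np.fill_diagonal(mask, False)
    A = np.where(mask, rng.uniform(-sigma_A, sigma_A, (N, N)), 0.0)
    np.fill_diagonal(A, -1.0)
    r = _draw_growth_rates(N, growth, rng)
    return GLVModel(r, A, "er",
                    {"mean_degree": mean_degree, "p_er": p, "growth": growth},
                    sigma_A, seed)


def _ba_edges(N: int, n_0: int, rng: np.random.Generator) -> list:
    """Undirected BA skeleton: complete core of n_0 seed nodes, then each
    new node attaches to n_0 distinct existing nodes with probability
    proportional to degree."""
    degree = np.zeros(N, dtype=float)
    edges = []
    for u in range(n_0):
        for v in range(u + 1, n_0):
            edges.append((u, v))
            degree[u] += 1
            degree[v] += 1
    if n_0 == 1:
        degree[0] = 1.0  # lone seed: give it unit weight so attachment works
    for new in range(n_0, N):
        w = degree[:new].copy()
        if w.sum() == 0:
            w[:] = 1.0
        m = min(n_0, new)
        targets = rng.choice(new, size=m, replace=False, p=w / w.sum())
        for t in targets:
            edges.append((int(t), new))
            degree[t] += 1
            degree[new] += 1
    return edges


def make_ba_model(N: int, n_0: int, d: float, sigma_A: float, seed: int,
                  growth: str = "uniform") -> GLVModel:
    """GLV model on a directed Barabasi-Albert interaction network.

    The undirected scale-free skeleton is built by preferential
    attachment from a fully connected core of ``n_0`` seed nodes. Each
    undirected edge {u, v} then becomes one directed interaction: with
    probability ``d`` it is oriented *out of* the higher-degree endpoint
    (so hubs preferentially influence their neighbors), otherwise the
    orientation is uniform. Interaction values and growth rates are
    drawn as in :func:`make_er_model`.
    """
    if not 1 <= n_0 <= N:
        raise ValueError("require 1 <= n_0 <= N")
    if not 0 <= d <= 1:
        raise ValueError("directionality d must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    edges = _ba_edges(N, n_0, rng)
    degree = np.zeros(N, dtype=int)
    for u, v in edges:
        degree[u] += 1
        degree[v] += 1
    A = np.zeros((N, N))
    for u, v in edges:
        if rng.random() < d:
            # orient out of the higher-degree endpoint (ties: uniform)
            if degree[u] > degree[v]:
                src, dst = u, v
            elif degree[v] > degree[u]:
                src, dst = v, u
            else:
                src, dst = (u, v) if rng.random() < 0.5 else (v, u)
        else:
            src, dst = (u, v) if rng.random() < 0.5 else (v, u)
        # source influences destination: a_{dst, src} nonzero
        A[dst, src] = rng.uniform(-sigma_A, sigma_A)
    np.fill_diagonal(A, -1.0)
    r = _draw_growth_rates(N, growth, rng)
    return GLVModel(r, A, "ba",
                    {"n_0": n_0, "directionality": d, "growth": growth},
                    sigma_A, seed)


def boost_species(model: GLVModel, spec: KeystoneSpec) -> GLVModel:
    """Multiply the outgoing interactions of one taxon by K.

    Sets a~_ji = K * a_ji for all j != i, leaving the self-regulation
    a_ii = -1 and every other entry untouched. K = 1 is the identity.
    """
    i = spec.taxon
    if not 0 <= i < model.n_taxa:
        raise ValueError(f"taxon index {i} out of range")
    A = model.A.copy()
    col = A[:, i] * spec.K
    col[i] = A[i, i]
    A[:, i] = col
    params = dict(model.params, keystone={"taxon": int(i), "K": float(spec.K)})
    return replace(model, A=A, params=params)


def lognormal_boosts(N: int, mu: float = 0.5, sigma: float = 1.0,
                     seed: int = 0) -> np.ndarray:
    """Per-taxon boost factors K_i ~ log-normal(mu, sigma).

    The long tail makes a few taxa highly influential while most have
    modest interaction strength.
    """
    rng = np.random.default_rng(seed)
    return rng.lognormal(mu, sigma, N)


def apply_boosts(model: GLVModel, K: Sequence[float]) -> GLVModel:
    """Boost every taxon's outgoing interactions by its own factor K_i."""
    K = np.asarray(K, dtype=float)
    if K.shape != (model.n_taxa,):
        raise ValueError("K must have one factor per taxon")
    if np.any(K <= 0):
        raise ValueError("boost factors must be positive")
    A = model.A * K[np.newaxis, :]
    np.fill_diagonal(A, np.diag(model.A))
    params = dict(model.params, boosts="lognormal-vector")
    return replace(model, A=A, params=params)


@dataclass
class SteadyState:
    """Result of integrating a GLV system to equilibrium."""

    x: np.ndarray
    converged: bool
    t_final: float
    residual: float  # relative derivative norm at the end


def _polish_fixed_point(r, A, x, tol):
    """Fixed-point polish: solve the interior equilibrium of a candidate
    surviving subsystem exactly (x_s = -A_ss^{-1} r_s).

    Candidate survivor sets are tried at increasing extinction cutoffs,
    which also resolves trajectories still carrying slowly dying taxa.
    A solution is accepted only when it is positive, stays close to the
    integrated endpoint, and every excluded taxon has a negative
    invasion growth rate at the polished point (so the trajectory's
    limit really drops it). At an accepted point the derivative of the
    full system is exactly zero.
    """
    if not (x > 1e-6).any():
        return np.zeros_like(x), True
    scale = max(np.max(np.abs(x)), 1.0)
    for cut in (1e-6, 1e-4, 1e-3, 1e-2):
        alive = x > cut
        if not alive.any():
            continue
        idx = np.flatnonzero(alive)
        try:
            xs = np.linalg.solve(A[np.ix_(idx, idx)], -r[idx])
        except np.linalg.LinAlgError:
            continue
        if np.any(xs <= 0) or not np.all(np.isfinite(xs)):
            continue
        if np.max(np.abs(xs - x[idx])) > max(0.05 * scale, 10 * cut):
            continue
        dead = np.flatnonzero(~alive)
        if dead.size:
            invasion = r[dead] + A[np.ix_(dead, idx)] @ xs
            if np.any(invasion >= 0):
                continue
        full = np.zeros_like(x)
        full[idx] = xs
        return full, True
    return None, False


def simulate_steady_state(model: GLVModel, initial, *, t_max: float = T_MAX,
                          tol_ss: float = TOL_SS,
                          extinction_eps: float = EXTINCTION_EPS,
                          blowup_cap: float = BLOWUP_CAP,
                          full_output: bool = False):
    """Integrate the GLV equations from ``initial`` to a steady state.

    Taxa starting at zero are removed from the system up front (zero
    abundance is an invariant manifold of the dynamics), the remaining
    subsystem is integrated with LSODA (analytic Jacobian supplied), and
    the surviving-species fixed point is polished by a direct linear
    solve when the integrated trajectory has settled near it. Abundances
    below ``extinction_eps`` are clipped to exactly zero.

    Returns the steady abundance vector, or a :class:`SteadyState` when
    ``full_output`` is true. Raises :class:`InstabilityError` if any
    abundance exceeds ``blowup_cap``; issues a warning (and sets
    ``converged=False``) if the criterion is not met by ``t_max``.
    """
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (model.n_taxa,):
        raise ValueError("initial condition must have one entry per taxon")
    if np.any(initial < 0):
        raise ValueError("initial abundances must be non-negative")
    present = initial > 0
    x_full = np.zeros(model.n_taxa)
    if not present.any():
        res = SteadyState(x_full, True, 0.0, 0.0)
        return res if full_output else res.x
    idx = np.flatnonzero(present)
    r = model.r[idx]
    A = model.A[np.ix_(idx, idx)]

    def rhs(x, t):
        return x * (r + A @ x)

    def jac(x, t):
        J = x[:, None] * A
        J[np.diag_indices_from(J)] += r + A @ x
        return J

    x = initial[idx].copy()
    t_done = 0.0
    converged = False
    residual = np.inf
    for t_next in (min(200.0, t_max), t_max):
        if t_next <= t_done:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = odeint(rhs, x, [0.0, t_next - t_done], Dfun=jac,
                         rtol=1e-8, atol=1e-10, mxstep=10_000)
        x = np.maximum(sol[-1], 0.0)
        t_done = t_next
        if not np.all(np.isfinite(x)) or np.max(x) > blowup_cap:
            raise InstabilityError(
                "GLV integration diverged (abundance exceeded "
                f"{blowup_cap:g})", seed=model.seed)
        polished, ok = _polish_fixed_point(r, A, x, tol_ss)
        if ok:
            x = polished
            converged = True
            residual = 0.0
            break
        dx = rhs(x, t_done)
        residual = np.max(np.abs(dx)) / max(np.max(np.abs(x)), 1e-12)
        if residual < tol_ss:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"steady state not reached by t={t_max:g} "
            f"(relative derivative norm {residual:.2e})")
    x[x < extinction_eps] = 0.0
    x_full[idx] = x
    res = SteadyState(x_full, converged, t_done, float(residual))
    return res if full_output else res.x


def _draw_initial(n, presence_prob, rng):
    mask = rng.random(n) < presence_prob
    return np.where(mask, rng.uniform(0.0, 1.0, n), 0.0)


def generate_cohort(model: GLVModel, M: int, presence_prob: float = 0.8,
                    seed: int = 0, **integrate_kw) -> Cohort:
    """Generate a cross-sectional cohort of M samples from one GLV model.

    Each sample starts from an independent random initial condition
    (every taxon present with probability ``presence_prob``, abundances
    U(0, 1)), is integrated to steady state, and is normalized to
    relative abundances. The absolute steady states and per-sample
    convergence flags are retained for perturbation experiments.
    """
    if M < 2:
        raise ValueError("a cohort needs at least two samples")
    rng = np.random.default_rng(seed)
    n = model.n_taxa
    absolute = np.zeros((n, M))
    converged = np.zeros(M, dtype=bool)
    for k in range(M):
        init = _draw_initial(n, presence_prob, rng)
        try:
            ss = simulate_steady_state(model, init, full_output=True,
                                       **integrate_kw)
        except InstabilityError as exc:
            exc.sample = k
            raise
        absolute[:, k] = ss.x
        converged[k] = ss.converged
    taxon_ids = [f"T{i:04d}" for i in range(n)]
    sample_ids = [f"S{k:04d}" for k in range(M)]
    meta = {"generator": "glv", "topology": model.topology,
            "model_seed": model.seed, "cohort_seed": seed,
            "M": M, "presence_prob": presence_prob,
            "sigma_A": model.sigma_A, **model.params}
    return Cohort.from_counts(absolute, taxon_ids, sample_ids,
                              absolute=absolute, converged=converged, meta=meta)


def generate_paired_cohort(model: GLVModel, H: int, presence_prob: float = 0.8,
                           seed: int = 0, **integrate_kw) -> PairedCohort:
    """Two-collection cohort for the longitudinal analysis.

    Each subject's second sample is generated by re-integrating the
    model from a freshly perturbed initial condition (presence resampled
    with the same probability, abundances redrawn), emulating the
    community reassembly that occurs over the months between two
    collections.
    """
    first = generate_cohort(model, H, presence_prob, seed=seed, **integrate_kw)
    second = generate_cohort(model, H, presence_prob, seed=seed + 1,
                             **integrate_kw)
    second.meta["collection"] = "second"
    return PairedCohort(first, second)
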