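"""Hill-function ODE model of gene-regulatory dynamics and its fitting.

The model for m genes is

    tau * dx_i/dt = -x_i + H_i(x, W_in, u),

    H_i = (u_i + sum_{W_ji > 0} W_ji x_j^3)
          / (1 + u_i + sum_{W_ji > 0} W_ji x_j^3 + sum_{W_ji < 0} (-W_ji) x_j^3),

a saturating activator/repressor competition with Hill exponent 3, a per-gene
basal drive u_i >= 0 and a single global timescale tau. H_i lies in [0, 1) for
nonnegative states, which makes the unit box [0, 1]^m forward invariant.

Parameters are *compatible* with a network when W_in is nonzero exactly on its
edges; fitting only ever introduces weights on the allowed edge set. The fit
minimizes summed squared error to binned trajectories plus an L1 penalty on
(W_in, u, tau) and a branch-wise initial-condition anchor, using self-adaptive
differential evolution (jDE, DE/rand/1/bin) with the whole population
integrated in one vectorized fixed-step RK4 pass per generation.

In-silico knockdown of gene i replaces its decay term by -(k+1) x_i; k = 2 is
the conventional strength.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .network import GeneNetwork
from .prep import BinnedTimeSeries

__all__ = [
    "HillParameters",
    "KnockdownSpec",
    "FitConfig",
    "FitResult",
    "hill_rhs",
    "hill_nonlinearity",
    "simulate",
    "knockdown_simulate",
    "total_loss",
    "fit",
    "classify_fit",
    "FIT_LABELS",
]

FIT_LABELS = ("damaged_like", "mechanism_recovered", "no_bistability", "decoupled")


@dataclass(frozen=True)
class HillParameters:
    """Model parameters (W_in, u, tau) plus per-branch initial states.

    ``W_in[j, i]`` is the signed influence of gene j on gene i.
    """

    gene_names: tuple[str, ...]
    W_in: np.ndarray
    u: np.ndarray
    tau: float
    x0_per_branch: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = len(self.gene_names)
        if self.W_in.shape != (m, m):
            raise ValueError("W_in must be m x m")
        if self.u.shape != (m,):
            raise ValueError("u must have one entry per gene")
        if np.any(self.u < 0):
            raise ValueError("basal drive u must be nonnegative")
        if self.tau <= 0:
            raise ValueError("timescale tau must be positive")
        for b, x0 in self.x0_per_branch.items():
            if np.any((x0 < 0) | (x0 > 1)):
                raise ValueError(f"x0 for branch {b!r} must lie in [0, 1]^m")

    @property
    def m(self) -> int:
        return len(self.gene_names)

    def weight(self, source: str, target: str) -> float:
        j = self.gene_names.index(source)
        i = self.gene_names.index(target)
        return float(self.W_in[j, i])

    def compatible_with(self, net: GeneNetwork) -> bool:
        """True if W_in is nonzero only on the network's edges."""
        allowed = net.adjacency().astype(bool)
        return bool(np.all((self.W_in != 0) <= allowed))

    def to_dict(self) -> dict:
        return {
            "genes": list(self.gene_names),
            "W_in": self.W_in.tolist(),
            "u": self.u.tolist(),
            "tau": self.tau,
            "x0_per_branch": {b: x.tolist() for b, x in self.x0_per_branch.items()},
        }

    @staticmethod
    def from_dict(d: dict) -> "HillParameters":
        return HillParameters(
            gene_names=tuple(d["genes"]),
            W_in=np.asarray(d["W_in"], dtype=float),
            u=np.asarray(d["u"], dtype=float),
            tau=float(d["tau"]),
            x0_per_branch={
                b: np.asarray(x, dtype=float) for b, x in d["x0_per_branch"].items()
            },
        )


@dataclass(frozen=True)
class KnockdownSpec:
    gene: str
    k: float = 2.0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("knockdown strength k must be >= 0")


@dataclass(frozen=True)
class FitConfig:
    """Differential-evolution fit settings.

    ``lambda_p`` scales the L1 sparsity penalty and ``lambda_ic`` the
    initial-condition anchor; their defaults set the intended hierarchy
    (trajectory fit and initial conditions first, sparsity last).
    """

    lambda_p: float = 0.001
    lambda_ic: float = 10.0
    w_bound: float = 5.0
    u_max: float = 5.0
    tau_bounds: tuple[float, float] = (0.01, 10.0)
    population_multiplier: int = 15
    max_generations: int = 300
    stagnation_generations: int = 50
    seed: int = 0
    ode_rtol: float = 1e-6
    ode_atol: float = 1e-8
    rk4_max_step: float = 0.02

    def __post_init__(self) -> None:
        if self.lambda_p < 0 or self.lambda_ic < 0:
            raise ValueError("loss weights must be nonnegative")
        if not (0 < self.tau_bounds[0] < self.tau_bounds[1]):
            raise ValueError("tau bounds must be positive and increasing")


@dataclass
class FitResult:
    params: HillParameters
    loss_components: dict
    generations_run: int
    classification: str | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "params": self.params.to_dict(),
                "loss_components": self.loss_components,
                "generations_run": self.generations_run,
                "classification": self.classification,
            },
            indent=2,
        )

    @staticmethod
    def from_json(text: str) -> "FitResult":
        d = json.loads(text)
        return FitResult(
            params=HillParameters.from_dict(d["params"]),
            loss_components=d["loss_components"],
            generations_run=d["generations_run"],
            classification=d.get("classification"),
        )


def hill_nonlinearity(x: np.ndarray, W_in: np.ndarray, u: np.ndarray) -> np.ndarray:
    """H(x, W_in, u); supports a batch leading axis on x/W_in/u.

    For a single system: x (m,), W_in (m, m), u (m,). For a population:
    x (..., m), W_in (..., m, m), u (..., m) with matching leading axes.
    """
    x3 = x**3
    pos = np.maximum(W_in, 0.0)
    neg = np.maximum(-W_in, 0.0)
    if W_in.ndim == 2:
        a = x3 @ pos
        r = x3 @ neg
    else:
        a = np.einsum("...ji,...j->...i", pos, x3)
        r = np.einsum("...ji,...j->...i", neg, x3)
    num = u + a
    return num / (1.0 + num + r)


def hill_rhs(x: np.ndarray, params: HillParameters) -> np.ndarray:
    """dx/dt = (-x + H(x)) / tau."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("state must be finite")
    H = hill_nonlinearity(x, params.W_in, params.u)
    return (-x + H) / params.tau


def simulate(
    params: HillParameters,
    x0: np.ndarray,
    t_grid: Sequence[float],
    rtol: float = 1e-6,
    atol: float = 1e-8,
    knockdown: KnockdownSpec | None = None,
) -> np.ndarray:
    """Integrate the model, returning the genes x times trajectory.

    Adaptive Runge--Kutta (4,5). The unit box is forward invariant for the
    exact flow; the output is clipped to [0, 1] to remove solver roundoff
    excursions of order the tolerances.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if len(t_grid) > 1 and not np.all(np.diff(t_grid) > 0):
        raise ValueError("t_grid must be strictly increasing")
    x0 = np.asarray(x0, dtype=float)
    if np.any((x0 < 0) | (x0 > 1)):
        raise ValueError("x0 must lie in [0, 1]^m")
    decay = np.ones(params.m)
    if knockdown is not None:
        decay[params.gene_names.index(knockdown.gene)] = knockdown.k + 1.0

    def rhs(_t, x):
        H = hill_nonlinearity(x, params.W_in, params.u)
        return (-decay * x + H) / params.tau

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        x0,
        t_eval=t_grid,
        method="RK45",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    return np.clip(sol.y, 0.0, 1.0)


def knockdown_simulate(
    params: HillParameters,
    spec: KnockdownSpec,
    x0: np.ndarray,
    t_grid: Sequence[float],
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> np.ndarray:
    """Simulate with gene ``spec.gene`` decaying at rate (k+1) instead of 1."""
    if spec.gene not in params.gene_names:
        raise KeyError(f"unknown gene {spec.gene!r}")
    return simulate(params, x0, t_grid, rtol=rtol, atol=atol, knockdown=spec)


# ---------------------------------------------------------------------------
# batched fixed-step integration (used by the DE objective and total_loss)
# ---------------------------------------------------------------------------


def _batch_rhs(x, W, u, tau):
    H = hill_nonlinearity(x, W, u)
    return (-x + H) / tau


def _batch_trajectory(x0, W, u, tau, times, max_step):
    """RK4 along ``times`` for a population; returns (pop, n_times, m).

    States are clipped to the invariant unit box after every step.
    """
    P, m = x0.shape
    out = np.empty((P, len(times), m))
    out[:, 0] = x0
    x = x0.copy()
    tau = tau[:, None]
    for k in range(1, len(times)):
        span = times[k] - times[k - 1]
        n_sub = max(1, int(np.ceil(span / max_step)))
        h = span / n_sub
        for _ in range(n_sub):
            k1 = _batch_rhs(x, W, u, tau)
            k2 = _batch_rhs(np.clip(x + 0.5 * h * k1, 0, 1), W, u, tau)
            k3 = _batch_rhs(np.clip(x + 0.5 * h * k2, 0, 1), W, u, tau)
            k4 = _batch_rhs(np.clip(x + h * k3, 0, 1), W, u, tau)
            x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            np.clip(x, 0.0, 1.0, out=x)
        out[:, k] = x
    return out


def _batch_losses(W, u, tau, x0_branches, series_list, lambda_p, lambda_ic, max_step,
                  edge_index):
    """Vectorized loss components for a population of parameter vectors."""
    P = W.shape[0]
    L_model = np.zeros(P)
    L_ic = np.zeros(P)
    for bi, series in enumerate(series_list):
        x0 = x0_branches[:, bi, :]
        traj = _batch_trajectory(x0, W, u, tau, series.times, max_step)
        D = series.values.T[None, :, :]  # 1 x bins x genes
        L_model += np.sum((D - traj) ** 2, axis=(1, 2))
        L_ic += np.max(np.abs(series.values[:, 0][None, :] - x0), axis=1)
    j, i = edge_index
    L_p = np.sum(np.abs(W[:, j, i]), axis=1) + np.sum(np.abs(u), axis=1) + np.abs(tau)
    L_total = L_model + lambda_p * L_p + lambda_ic * L_ic
    return L_total, L_model, L_p, L_ic


def _check_series(params_genes, series_list, x0_keys):
    for s in series_list:
        if s.branch_id not in x0_keys:
            raise ValueError(f"no initial condition for branch {s.branch_id!r}")
        if s.gene_names and tuple(s.gene_names) != tuple(params_genes):
            raise ValueError("series gene order does not match the parameters")


def total_loss(
    params: HillParameters,
    series_list: Sequence[BinnedTimeSeries],
    config: FitConfig,
) -> tuple[float, dict]:
    """Composite loss L_model + lambda_p L_p + lambda_ic L_IC for one model.

    L_model sums squared trajectory error over branches, genes and bins; L_p
    is the L1 norm of (W_in edge weights, u, tau); L_IC sums, over branches,
    the max-norm gap between the first data point and the branch's initial
    state. Uses the same fixed-step integrator as the fit so reported
    components are exactly the ones optimized.
    """
    if not series_list:
        raise ValueError("series_list is empty")
    _check_series(params.gene_names, series_list, set(params.x0_per_branch))
    j, i = np.nonzero(params.W_in)
    if len(j) == 0:  # allow all-zero W: L_p then counts u and tau only
        j = i = np.array([], dtype=int)
    x0b = np.stack(
        [params.x0_per_branch[s.branch_id] for s in series_list], axis=0
    )[None, :, :]
    L_total, L_model, L_p, L_ic = _batch_losses(
        params.W_in[None],
        params.u[None],
        np.array([params.tau]),
        x0b,
        series_list,
        config.lambda_p,
        config.lambda_ic,
        config.rk4_max_step,
        (j, i),
    )
    components = {
        "L_model": float(L_model[0]),
        "L_p": float(L_p[0]),
        "L_IC": float(L_ic[0]),
        "L_total": float(L_total[0]),
    }
    return components["L_total"], components


def _unpack(pop, m, n_edges, n_branches, edge_index):
    """Decision vectors (P, D) -> (W, u, tau, x0_branches)."""
    P = pop.shape[0]
    W = np.zeros((P, m, m))
    j, i = edge_index
    W[:, j, i] = pop[:, :n_edges]
    o = n_edges
    u = pop[:, o : o + m]
    tau = pop[:, o + m]
    x0 = pop[:, o + m + 1 :].reshape(P, n_branches, m)
    return W, u, tau, x0


def fit(
    net: GeneNetwork,
    series_list: Sequence[BinnedTimeSeries],
    config: FitConfig | None = None,
) -> FitResult:
    """Fit graph-compatible Hill-ODE parameters with self-adaptive DE (jDE).

    The decision vector holds one signed weight per network edge, the basal
    drives u, the timescale tau and one initial state per branch. DE/rand/1/bin
    with per-member self-adapted F and CR minimizes :func:`total_loss`;
    members whose loss evaluates non-finite receive a large penalty. The run
    stops at ``max_generations`` or after ``stagnation_generations`` without
    improvement of the best loss. Fixed seed gives a reproducible result.
    """
    if config is None:
        config = FitConfig()
    if not series_list:
        raise ValueError("series_list is empty")
    if net.m == 0:
        raise ValueError("network has no genes")
    for s in series_list:
        if s.gene_names and tuple(s.gene_names) != net.genes:
            raise ValueError("series gene order does not match the network")

    m = net.m
    idx = {g: k for k, g in enumerate(net.genes)}
    edges = sorted(net.edges, key=lambda e: (idx[e[0]], idx[e[1]]))
    n_edges = len(edges)
    edge_index = (
        np.array([idx[s] for s, _ in edges], dtype=int),
        np.array([idx[t] for _, t in edges], dtype=int),
    )
    branches = [s.branch_id for s in series_list]
    B = len(branches)
    D = n_edges + m + 1 + B * m

    lo = np.concatenate(
        [
            np.full(n_edges, -config.w_bound),
            np.zeros(m),
            [config.tau_bounds[0]],
            np.zeros(B * m),
        ]
    )
    hi = np.concatenate(
        [
            np.full(n_edges, config.w_bound),
            np.full(m, config.u_max),
            [config.tau_bounds[1]],
            np.ones(B * m),
        ]
    )

    rng = np.random.default_rng(config.seed)
    NP = max(config.population_multiplier * D, 8)
    pop = rng.uniform(lo, hi, size=(NP, D))
    F = np.full(NP, 0.5)
    CR = np.full(NP, 0.9)

    def evaluate(vectors):
        W, u, tau, x0 = _unpack(vectors, m, n_edges, B, edge_index)
        L_total, L_model, L_p, L_ic = _batch_losses(
            W, u, tau, x0, series_list,
            config.lambda_p, config.lambda_ic, config.rk4_max_step, edge_index,
        )
        bad = ~np.isfinite(L_total)
        L_total[bad] = 1e12
        return L_total, L_model, L_p, L_ic

    loss, L_model, L_p, L_ic = evaluate(pop)
    if not np.any(np.isfinite(loss)):
        raise RuntimeError("initial population produced no finite loss")
    best_loss = float(loss.min())
    stagnant = 0
    gens = 0

    for gen in range(config.max_generations):
        gens = gen + 1
        # jDE self-adaptation of F and CR (tau1 = tau2 = 0.1)
        F_trial = np.where(rng.random(NP) < 0.1, 0.1 + 0.9 * rng.random(NP), F)
        CR_trial = np.where(rng.random(NP) < 0.1, rng.random(NP), CR)

        # DE/rand/1: three distinct partners, none equal to the target index
        r = np.empty((NP, 3), dtype=int)
        for k in range(NP):
            r[k] = rng.choice(NP - 1, size=3, replace=False)
        r[r >= np.arange(NP)[:, None]] += 1
        mutant = pop[r[:, 0]] + F_trial[:, None] * (pop[r[:, 1]] - pop[r[:, 2]])
        np.clip(mutant, lo, hi, out=mutant)

        cross = rng.random((NP, D)) < CR_trial[:, None]
        cross[np.arange(NP), rng.integers(0, D, size=NP)] = True
        trial = np.where(cross, mutant, pop)

        t_loss, t_model, t_p, t_ic = evaluate(trial)
        better = t_loss <= loss
        pop[better] = trial[better]
        loss[better] = t_loss[better]
        L_model[better] = t_model[better]
        L_p[better] = t_p[better]
        L_ic[better] = t_ic[better]
        F[better] = F_trial[better]
        CR[better] = CR_trial[better]

        new_best = float(loss.min())
        if new_best < best_loss - 1e-12:
            best_loss = new_best
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= config.stagnation_generations:
                break

    b = int(np.argmin(loss))
    W, u, tau, x0 = _unpack(pop[b : b + 1], m, n_edges, B, edge_index)
    params = HillParameters(
        gene_names=net.genes,
        W_in=W[0],
        u=u[0],
        tau=float(tau[0]),
        x0_per_branch={br: x0[0, bi].copy() for bi, br in enumerate(branches)},
    )
    components = {
        "L_model": float(L_model[b]),
        "L_p": float(L_p[b]),
        "L_IC": float(L_ic[b]),
        "L_total": float(loss[b]),
    }
    return FitResult(params=params, loss_components=components, generations_run=gens)


def classify_fit(
    result: FitResult,
    net: GeneNetwork,
    focus: tuple[str, tuple[str, str]],
    t_grid: Sequence[float] | None = None,
    delta: float = 0.1,
    k: float = 2.0,
) -> str:
    """Classify the mechanism encoded by a fitted model.

    ``focus = (source, (arm_other, arm_reporter))`` names the upstream gene
    whose influence is under scrutiny and the two competing arm genes, with
    ``arm_reporter`` the one whose incoming edge was damaged. Labels:

    - ``no_bistability``: simulations from the branch initial states end
      within ``delta`` (max-norm) of each other — the branches collapsed;
    - ``mechanism_recovered``: the reporter arm receives the stronger drive
      from the source (|W(source->reporter)| > |W(source->other)|) and an
      in-silico knockdown of the source lowers the reporter's late-time
      expression;
    - ``decoupled``: both source->arm weights are below 5% of the largest
      fitted weight — the arms run on their basal drives;
    - ``damaged_like`` otherwise (the fit leans on the remaining edge, giving
      the wrong knockdown prediction).
    """
    source, (arm_other, arm_reporter) = focus
    for g in (source, arm_other, arm_reporter):
        if g not in net.genes:
            raise KeyError(f"focus gene {g!r} not in the network")
    params = result.params
    branches = list(params.x0_per_branch)
    if len(branches) < 2:
        raise ValueError("classification needs at least two branch initial states")
    if t_grid is None:
        t_grid = np.linspace(0.0, 1.0, 101)
    t_grid = np.asarray(t_grid, dtype=float)

    trajs = {b: simulate(params, params.x0_per_branch[b], t_grid) for b in branches}
    ends = np.stack([trajs[b][:, -1] for b in branches])
    spread = max(
        np.max(np.abs(ends[a] - ends[b]))
        for a in range(len(branches))
        for b in range(a + 1, len(branches))
    )
    if spread < delta:
        return "no_bistability"

    w_rep = abs(params.weight(source, arm_reporter))
    w_oth = abs(params.weight(source, arm_other))
    if w_rep > w_oth:
        rep_i = params.gene_names.index(arm_reporter)
        late = t_grid >= t_grid[0] + 0.8 * (t_grid[-1] - t_grid[0])
        spec = KnockdownSpec(gene=source, k=k)
        base = np.mean([trajs[b][rep_i, late].mean() for b in branches])
        kd = np.mean(
            [
                knockdown_simulate(params, spec, params.x0_per_branch[b], t_grid)[
                    rep_i, late
                ].mean()
                for b in branches
            ]
        )
        if kd < base:
            return "mechanism_recovered"

    w_max = float(np.max(np.abs(params.W_in))) if np.any(params.W_in) else 0.0
    if w_max == 0.0 or (w_rep < 0.05 * w_max and w_oth < 0.05 * w_max):
        return "decoupled"
    return "damaged_like"
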