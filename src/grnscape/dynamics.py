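"""Sigmoidal rate-equation dynamics: integration, steady states, fitting, sweeps.

The reference integrator is forward Euler on

    eta * dv_i/dt = g(h_i / Theta) - gamma * v_i,

where ``g`` is the logistic function, ``h_i`` the regulatory force on gene
*i* and ``Theta = 2 T``.  The degradation rate ``gamma`` generalises the
plain ``-v_i`` decay; the free-energy landscape assumes ``gamma = 1`` (the
thermodynamic derivation has no degradation parameter), so sweeps over
``gamma`` report dynamics-derived summaries only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize
from scipy.special import expit
from scipy.stats import qmc

from .model import GeneNetwork, NoiseModel, as_state, force

__all__ = [
    "DynamicsSettings",
    "TimeSeries",
    "FitResult",
    "UnderdeterminedError",
    "FitInfeasibleError",
    "integrate",
    "steady_states",
    "fit_to_timeseries",
    "fit_to_attractors",
    "fixed_point_jacobian",
    "sensitivity_sweep",
]

log = logging.getLogger(__name__)

_CLAMP_EPS = 1e-9


class UnderdeterminedError(ValueError):
    """Raised when a fit has more free parameters than residuals."""


class FitInfeasibleError(RuntimeError):
    """Raised when no parameter set makes all targets stable fixed points."""


@dataclass(frozen=True)
class DynamicsSettings:
    """Integration controls.

    eta : step parameter of the rate equation (time-scale).
    gamma : degradation rate (1 recovers the thermodynamic form).
    dt : forward-Euler step; ``dt * gamma / eta < 1`` is required for
        stability of the linear decay part.
    t_max : integration horizon.
    convergence_tol : max-norm threshold on the rate at which a trajectory
        is declared converged.
    """

    eta: float = 1.0
    gamma: float = 1.0
    dt: float = 0.1
    t_max: float = 400.0
    convergence_tol: float = 1e-9

    def __post_init__(self):
        for name in ("eta", "gamma", "dt", "t_max", "convergence_tol"):
            val = getattr(self, name)
            if not (np.isfinite(val) and val > 0):
                raise ValueError(f"{name} must be positive and finite, got {val}")
        if self.dt * self.gamma / self.eta >= 1.0:
            raise ValueError(
                f"unstable Euler step: dt*gamma/eta = {self.dt * self.gamma / self.eta:g} >= 1"
            )


@dataclass(frozen=True)
class TimeSeries:
    """Expression trajectory: strictly increasing times, values in (0, 1)."""

    times: np.ndarray
    values: np.ndarray
    gene_names: tuple = ()

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be a strictly increasing 1-D vector")
        if v.ndim != 2 or v.shape[0] != t.shape[0]:
            raise ValueError(
                f"values must be (timepoints x genes), got {v.shape} for {t.shape[0]} times"
            )
        if not np.all(np.isfinite(v)) or np.any(v <= 0) or np.any(v >= 1):
            raise ValueError("expression values must lie strictly inside (0, 1)")
        names = tuple(self.gene_names) or tuple(f"g{i}" for i in range(v.shape[1]))
        if len(names) != v.shape[1]:
            raise ValueError("gene_names length does not match value columns")
        t = t.copy()
        v = v.copy()
        t.flags.writeable = False
        v.flags.writeable = False
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "gene_names", names)

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.gene_names))
        df.insert(0, "time", self.times)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TimeSeries":
        if "time" not in df.columns:
            raise ValueError("time-series table needs a 'time' column")
        genes = [c for c in df.columns if c != "time"]
        return cls(df["time"].to_numpy(), df[genes].to_numpy(), tuple(genes))


@dataclass(frozen=True)
class FitResult:
    """Outcome of a parameter fit."""

    network: GeneNetwork
    residual: float
    converged: bool
    w_bounds: tuple
    l_bounds: tuple
    n_free: int
    message: str = ""

    def __post_init__(self):
        if self.residual < 0:
            raise ValueError("residual sum of squares cannot be negative")


def _rate(net: GeneNetwork, v: np.ndarray, noise: NoiseModel, s: DynamicsSettings):
    return (expit(force(net, v) / noise.theta) - s.gamma * v) / s.eta


def integrate(
    net: GeneNetwork,
    noise: NoiseModel,
    v0,
    settings: DynamicsSettings | None = None,
) -> TimeSeries:
    """Forward-Euler trajectory of the sigmoidal rate equations.

    The full trajectory (including the initial state) is returned; iterates
    are clamped to [1e-9, 1 - 1e-9] so entropy-based post-processing stays
    finite.  A non-finite state aborts with a diagnostic.
    """
    s = settings or DynamicsSettings()
    v = as_state(v0, net.n)
    n_steps = int(np.ceil(s.t_max / s.dt))
    out = np.empty((n_steps + 1, net.n))
    out[0] = v
    for k in range(n_steps):
        v = v + s.dt * _rate(net, v, noise, s)
        if not np.all(np.isfinite(v)):
            raise FloatingPointError(
                f"non-finite state at step {k + 1} (t={(k + 1) * s.dt:g}); "
                "reduce dt or check parameters"
            )
        np.clip(v, _CLAMP_EPS, 1.0 - _CLAMP_EPS, out=v)
        out[k + 1] = v
    times = np.arange(n_steps + 1) * s.dt
    return TimeSeries(times, out, net.gene_names)


def _evolve_to_limit(net, noise, v, s):
    """Integrate without storing the trajectory until the rate stalls."""
    n_steps = int(np.ceil(s.t_max / s.dt))
    for _ in range(n_steps):
        dv = s.dt * _rate(net, v, noise, s)
        v = np.clip(v + dv, _CLAMP_EPS, 1.0 - _CLAMP_EPS)
        if not np.all(np.isfinite(v)):
            raise FloatingPointError("non-finite state during integration")
        if np.max(np.abs(dv)) < s.dt * s.convergence_tol:
            break
    return v


def _refine_fixed_point(net, noise, v, s, tol=1e-10, damping=0.5, max_iter=20000):
    """Damped Picard iteration of v <- g(h/Theta)/gamma from a near-limit."""
    for _ in range(max_iter):
        target = expit(force(net, v) / noise.theta) / s.gamma
        new = (1.0 - damping) * v + damping * target
        new = np.clip(new, _CLAMP_EPS, 1.0 - _CLAMP_EPS)
        if np.max(np.abs(new - v)) < tol:
            return new, True
        v = new
    return v, False


def steady_states(
    net: GeneNetwork,
    noise: NoiseModel,
    settings: DynamicsSettings | None = None,
    n_starts: int = 50,
    seed: int = 0,
    dedup_tol: float = 1e-4,
) -> list:
    """Stable fixed points located from many quasi-random starts.

    Starts are a seeded Halton sequence over (0.02, 0.98)^N; each is
    integrated to its limit, refined by damped Picard iteration of
    ``v <- g(h/Theta)/gamma`` to 1e-10, deduplicated at ``dedup_tol`` in
    max-norm and returned sorted lexicographically.  Non-convergent starts
    are logged, not fatal.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    s = settings or DynamicsSettings()
    sampler = qmc.Halton(d=net.n, seed=seed)
    starts = 0.02 + 0.96 * sampler.random(n_starts)
    found: list[np.ndarray] = []
    n_failed = 0
    for v0 in starts:
        try:
            v = _evolve_to_limit(net, noise, v0.copy(), s)
            v, ok = _refine_fixed_point(net, noise, v, s)
        except FloatingPointError:
            n_failed += 1
            continue
        if not ok:
            n_failed += 1
            continue
        if not any(np.max(np.abs(v - u)) < dedup_tol for u in found):
            found.append(v)
    if n_failed:
        log.warning("steady_states: %d of %d starts did not converge", n_failed, n_starts)
    found.sort(key=lambda u: tuple(u))
    return found


def _pack_masks(w_mask, l_mask, n):
    w_mask = np.asarray(w_mask, dtype=bool)
    l_mask = np.asarray(l_mask, dtype=bool)
    if w_mask.shape != (n, n):
        raise ValueError(f"W mask must be {n}x{n}, got {w_mask.shape}")
    if l_mask.shape != (n,):
        raise ValueError(f"l mask must have length {n}, got {l_mask.shape}")
    return w_mask, l_mask


def _build_net(theta_vec, template, w_mask, l_mask):
    W = np.array(template.W)
    l = np.array(template.l)
    nw = int(w_mask.sum())
    W[w_mask] = theta_vec[:nw]
    l[l_mask] = theta_vec[nw:]
    return template.with_updates(W=W, l=l)


def fit_to_timeseries(
    data,
    w_mask,
    l_mask,
    noise: NoiseModel,
    settings: DynamicsSettings | None = None,
    seed: int = 0,
    n_starts: int = 5,
    w_bounds: tuple = (-20.0, 20.0),
    l_bounds: tuple = (-10.0, 10.0),
    base: GeneNetwork | None = None,
) -> FitResult:
    """Least-squares fit of free W and l entries to observed increments.

    ``data`` is one :class:`TimeSeries` or a sequence of them (several
    trajectories improve identifiability).  For each consecutive pair of
    observations the Euler-predicted increment is compared with the
    observed one; the summed squared discrepancy is minimised over the
    masked entries with bounded trust-region least squares, restarted from
    ``n_starts`` seeded initial guesses.
    """
    if isinstance(data, TimeSeries):
        series = [data]
    else:
        series = list(data)
    if not series:
        raise ValueError("no time series supplied")
    for ts in series:
        if len(ts.times) < 2:
            raise ValueError("each time series needs at least 2 timepoints")
    n = series[0].n_genes
    w_mask, l_mask = _pack_masks(w_mask, l_mask, n)
    s = settings or DynamicsSettings()
    template = base or GeneNetwork(series[0].gene_names, np.zeros((n, n)), np.zeros(n))
    n_free = int(w_mask.sum() + l_mask.sum())
    n_resid = sum((len(ts.times) - 1) * n for ts in series)
    if n_free > n_resid:
        raise UnderdeterminedError(
            f"{n_free} free parameters but only {n_resid} increment residuals; "
            "supply more data or freeze parameters"
        )
    if n_free == 0:
        raise ValueError("no free parameters selected by the masks")

    def residuals(theta_vec):
        net = _build_net(theta_vec, template, w_mask, l_mask)
        out = []
        for ts in series:
            v = ts.values[:-1]
            dt = np.diff(ts.times)[:, None]
            pred = v + dt / s.eta * (expit(force(net, v) / noise.theta) - s.gamma * v)
            out.append((ts.values[1:] - pred).ravel())
        return np.concatenate(out)

    lo = np.concatenate([np.full(int(w_mask.sum()), w_bounds[0]), np.full(int(l_mask.sum()), l_bounds[0])])
    hi = np.concatenate([np.full(int(w_mask.sum()), w_bounds[1]), np.full(int(l_mask.sum()), l_bounds[1])])
    rng = np.random.default_rng(seed)
    best = None
    for k in range(n_starts):
        if k == 0:
            x0 = np.zeros(n_free)
        else:
            x0 = rng.uniform(np.maximum(lo, -3.0), np.minimum(hi, 3.0))
        sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
        if best is None or sol.cost < best.cost:
            best = sol
    rss = float(2.0 * best.cost)
    net = _build_net(best.x, template, w_mask, l_mask)
    return FitResult(
        network=net,
        residual=rss,
        converged=bool(best.status > 0),
        w_bounds=tuple(w_bounds),
        l_bounds=tuple(l_bounds),
        n_free=n_free,
        message=best.message,
    )


def fixed_point_jacobian(net: GeneNetwork, v, noise: NoiseModel) -> np.ndarray:
    """Jacobian of the fixed-point map G_i(v) = g(h_i / Theta) at v.

    ``J[i, j] = g'(h_i/Theta) W[j, i] / Theta``; a fixed point is locally
    stable under Picard iteration (and under the Euler flow with gamma = 1)
    when the spectral radius of J is below 1.
    """
    v = as_state(v, net.n)
    g = expit(force(net, v) / noise.theta)
    return (g * (1.0 - g) / noise.theta)[:, None] * net.W.T


def fit_to_attractors(
    targets: Sequence,
    w_mask,
    l_mask,
    noise: NoiseModel,
    seed: int = 0,
    n_starts: int = 8,
    w_bounds: tuple = (-20.0, 20.0),
    l_bounds: tuple = (-10.0, 10.0),
    base: GeneNetwork | None = None,
    gene_names: Sequence[str] | None = None,
    stability_margin: float = 0.95,
    penalty_weight: float = 10.0,
    tol: float = 1e-6,
) -> FitResult:
    """Find parameters under which every target is a stable fixed point.

    Minimises the summed squared fixed-point defect ``g(h/Theta) - v*``
    over the masked parameters, with a hinge penalty keeping the spectral
    radius of the fixed-point Jacobian below ``stability_margin`` at every
    target.  Derivative-free bounded Powell search with seeded multistart.
    Raises :class:`FitInfeasibleError`, naming the violating target, when
    no start achieves defect < ``tol`` with all targets stable.
    """
    if not targets:
        raise ValueError("at least one target state is required")
    targets = [as_state(t) for t in targets]
    n = targets[0].shape[0]
    for t in targets:
        if t.shape[0] != n:
            raise ValueError("all targets must have the same length")
    w_mask, l_mask = _pack_masks(w_mask, l_mask, n)
    names = tuple(gene_names) if gene_names else (base.gene_names if base else tuple(f"g{i}" for i in range(n)))
    template = base or GeneNetwork(names, np.zeros((n, n)), np.zeros(n))
    n_free = int(w_mask.sum() + l_mask.sum())
    if n_free == 0:
        raise ValueError("no free parameters selected by the masks")

    def defect_and_rho(net):
        sq = 0.0
        rhos = []
        for t in targets:
            r = expit(force(net, t) / noise.theta) - t
            sq += float(r @ r)
            rhos.append(float(np.max(np.abs(np.linalg.eigvals(fixed_point_jacobian(net, t, noise))))))
        return sq, rhos

    def objective(theta_vec):
        net = _build_net(theta_vec, template, w_mask, l_mask)
        sq, rhos = defect_and_rho(net)
        pen = sum(max(0.0, r - stability_margin) ** 2 for r in rhos)
        return sq + penalty_weight * pen

    lo = np.concatenate([np.full(int(w_mask.sum()), w_bounds[0]), np.full(int(l_mask.sum()), l_bounds[0])])
    hi = np.concatenate([np.full(int(w_mask.sum()), w_bounds[1]), np.full(int(l_mask.sum()), l_bounds[1])])
    rng = np.random.default_rng(seed)
    x_base = np.concatenate([np.asarray(template.W)[w_mask], np.asarray(template.l)[l_mask]])
    best_x, best_f = None, np.inf
    for k in range(n_starts):
        x0 = x_base if k == 0 else rng.uniform(np.maximum(lo, -5.0), np.minimum(hi, 5.0))
        sol = minimize(objective, x0, method="Powell", bounds=list(zip(lo, hi)))
        if sol.fun < best_f:
            best_x, best_f = sol.x, sol.fun
        if best_f < tol**2:
            break
    net = _build_net(best_x, template, w_mask, l_mask)
    sq, rhos = defect_and_rho(net)
    bad = [i for i, r in enumerate(rhos) if r >= 1.0]
    if sq > tol or bad:
        worst = bad[0] if bad else int(np.argmax([
            float(np.sum((expit(force(net, t) / noise.theta) - t) ** 2)) for t in targets
        ]))
        raise FitInfeasibleError(
            f"could not make all targets stable fixed points; worst target index {worst} "
            f"(state {np.round(targets[worst], 3)}), defect {sq:.2e}, "
            f"spectral radii {np.round(rhos, 3)}"
        )
    return FitResult(
        network=net,
        residual=sq,
        converged=True,
        w_bounds=tuple(w_bounds),
        l_bounds=tuple(l_bounds),
        n_free=n_free,
    )


def _parse_parameter(net: GeneNetwork, parameter: str):
    """Parse 'T', 'gamma', 'W[src,tgt]' or 'l[gene]' (names or indices)."""
    p = parameter.strip()
    if p in ("T", "gamma"):
        return p, None
    if p.startswith("W[") and p.endswith("]"):
        inner = p[2:-1].split(",")
        if len(inner) == 2:
            j = net.index(inner[0].strip())
            i = net.index(inner[1].strip())
            return "W", (j, i)
    if p.startswith("l[") and p.endswith("]"):
        return "l", net.index(p[2:-1].strip())
    raise ValueError(
        f"unknown parameter {parameter!r}; expected 'T', 'gamma', 'W[src,tgt]' or 'l[gene]'"
    )


def sensitivity_sweep(
    net: GeneNetwork,
    noise: NoiseModel,
    parameter: str,
    values: Sequence[float],
    summaries: Sequence[str] = ("n_attractors", "barrier_height"),
    d: int | None = None,
    settings: DynamicsSettings | None = None,
    seed: int = 0,
    weight_mode: str = "abs",
) -> pd.DataFrame:
    """Recompute landscape summaries while one parameter is varied.

    For ``T`` and any ``W``/``l`` entry the summaries are taken from the
    landscape route (grid attractors; barrier of the path between the two
    lowest-F attractors, NaN when fewer than two exist).  ``gamma`` has no
    landscape counterpart, so its rows use the dynamics route
    (``steady_states`` counts) and report NaN barriers.  Returns one tidy
    row per value.
    """
    from . import landscape as _landscape
    from . import paths as _paths

    kind, idx = _parse_parameter(net, parameter)
    allowed = {"n_attractors", "barrier_height"}
    bad = set(summaries) - allowed
    if bad:
        raise ValueError(f"unknown summaries {sorted(bad)}; choose from {sorted(allowed)}")
    values = [float(v) for v in values]
    if not all(np.isfinite(values)):
        raise ValueError("sweep values must be finite")

    rows = []
    for val in values:
        cur_net, cur_noise, cur_settings = net, noise, settings or DynamicsSettings()
        if kind == "T":
            cur_noise = NoiseModel(T=val)
        elif kind == "gamma":
            cur_settings = replace(cur_settings, gamma=val)
        elif kind == "W":
            W = np.array(net.W)
            W[idx] = val
            cur_net = net.with_updates(W=W)
        else:
            l = np.array(net.l)
            l[idx] = val
            cur_net = net.with_updates(l=l)

        row = {"parameter": parameter, "value": val}
        if kind == "gamma":
            states = steady_states(cur_net, cur_noise, cur_settings, seed=seed)
            if "n_attractors" in summaries:
                row["n_attractors"] = len(states)
            if "barrier_height" in summaries:
                row["barrier_height"] = np.nan
        else:
            grid = _landscape.evaluate_grid(cur_net, cur_noise, d=d)
            graph = _landscape.build_graph(grid)
            attrs = _landscape.find_attractors(graph, grid)
            if "n_attractors" in summaries:
                row["n_attractors"] = len(attrs.attractors)
            if "barrier_height" in summaries:
                if len(attrs.attractors) >= 2:
                    p = _paths.shortest_path(graph, grid, attrs, 0, 1, weight_mode=weight_mode)
                    row["barrier_height"] = p.barrier
                else:
                    row["barrier_height"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
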