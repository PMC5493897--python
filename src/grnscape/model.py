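"""Network data model and closed-form thermodynamic quantities.

A regulatory circuit of ``N`` genes is summarised by an interaction matrix
``W`` — entry ``W[j, i]`` is the force gene *j* exerts on gene *i*, with
self-interactions on the diagonal — a vector ``l`` of constant external
inputs, and a noise level (temperature) ``T``.  Continuous expression levels
``v`` in the open cube (0, 1)^N are mean-field averages of underlying on/off
gene states, which yields an approximate free-energy landscape

    F(v) = E(v) - Theta * S(v),        Theta = 2 * T,

with a quadratic internal energy ``E`` and the per-gene binary mixing
entropy ``S``.  Because ``W`` is in general asymmetric, ``E`` is defined
through a per-gene decomposition ``E = sum_i E_i`` in which only gene *i*'s
own activity is treated as the dynamical variable; the stationary points of
each decomposed part then coincide *exactly* with the sigmoidal fixed
points ``v_i = g(h_i / Theta)``, where ``h_i = sum_j W[j, i] v_j + l_i`` is
the total regulatory force on gene *i*.

The entropy weight is ``Theta = 2 T`` rather than ``T`` so that landscape
minima and dynamical fixed points agree exactly (see ``docs/methods.md``);
``T`` remains the user-facing noise parameter everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit, logit as _logit, xlogy

__all__ = [
    "GeneNetwork",
    "NoiseModel",
    "HillParams",
    "SigmoidGainParams",
    "as_state",
    "sigmoid",
    "logit",
    "hill",
    "sigmoid_from_hill",
    "force",
    "internal_energy",
    "landscape_energy",
    "entropy",
    "free_energy",
]


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass(frozen=True)
class GeneNetwork:
    """Topology, interaction weights and external inputs of one circuit.

    ``W[j, i]`` is the signed force that source gene *j* exerts on target
    gene *i*; the diagonal holds self-interactions.  ``l[i]`` is a constant
    external force on gene *i* (same dimensionless units as ``W @ v``).
    ``triplet`` may hold cooperative three-gene couplings ``(i, j, k, w)``;
    they are stored for completeness but no computation consumes them.
    """

    gene_names: tuple
    W: np.ndarray
    l: np.ndarray
    triplet: tuple = ()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        names = tuple(str(g) for g in self.gene_names)
        if len(names) < 1:
            raise ValueError("a network needs at least one gene")
        if len(set(names)) != len(names):
            raise ValueError("gene names must be unique")
        W = _as_float_array(self.W, "W")
        l = _as_float_array(self.l, "l")
        n = len(names)
        if W.shape != (n, n):
            raise ValueError(
                f"W must be {n}x{n} to match {n} gene names, got {W.shape}"
            )
        if l.shape != (n,):
            raise ValueError(f"l must have length {n}, got shape {l.shape}")
        W = W.copy()
        l = l.copy()
        W.flags.writeable = False
        l.flags.writeable = False
        object.__setattr__(self, "gene_names", names)
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "l", l)
        object.__setattr__(self, "triplet", tuple(self.triplet))

    @property
    def n(self) -> int:
        return len(self.gene_names)

    def index(self, gene) -> int:
        """Resolve a gene name or integer index to an integer index."""
        if isinstance(gene, (int, np.integer)):
            i = int(gene)
            if not 0 <= i < self.n:
                raise IndexError(f"gene index {i} out of range for N={self.n}")
            return i
        try:
            return self.gene_names.index(str(gene))
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}; genes are {self.gene_names}")

    def with_updates(self, W=None, l=None, metadata=None) -> "GeneNetwork":
        return GeneNetwork(
            self.gene_names,
            self.W if W is None else W,
            self.l if l is None else l,
            self.triplet,
            dict(self.metadata) if metadata is None else metadata,
        )


@dataclass(frozen=True)
class NoiseModel:
    """Noise level of the dynamics; ``theta = 2 T`` is the entropy weight."""

    T: float

    def __post_init__(self):
        if not (np.isfinite(self.T) and self.T > 0):
            raise ValueError(f"temperature must be positive and finite, got {self.T}")
        object.__setattr__(self, "T", float(self.T))

    @property
    def theta(self) -> float:
        return 2.0 * self.T


def as_state(v, n: int | None = None) -> np.ndarray:
    """Validate an expression state: a finite vector strictly inside (0, 1)^N.

    The open interval is required because the mixing entropy diverges
    (has infinite slope) at 0 and 1.
    """
    arr = np.atleast_1d(_as_float_array(v, "state"))
    if arr.ndim != 1:
        raise ValueError(f"state must be a vector, got shape {arr.shape}")
    if n is not None and arr.shape != (n,):
        raise ValueError(f"state must have length {n}, got {arr.shape[0]}")
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise ValueError("state components must lie strictly inside (0, 1)")
    return arr


@dataclass(frozen=True)
class HillParams:
    """Hill gain h(x) = x^n / (k^n + x^n); h(k) = 1/2 by construction."""

    k: float
    n: float

    def __post_init__(self):
        if not (np.isfinite(self.k) and self.k > 0):
            raise ValueError(f"half-saturation k must be > 0, got {self.k}")
        if not (np.isfinite(self.n) and self.n >= 1):
            raise ValueError(f"Hill coefficient n must be >= 1, got {self.n}")


@dataclass(frozen=True)
class SigmoidGainParams:
    """Shifted sigmoid gain g(x) = 1 / (1 + exp(-a (x - c))); g(c) = 1/2."""

    a: float
    c: float

    def __post_init__(self):
        if not (np.isfinite(self.a) and self.a > 0):
            raise ValueError(f"steepness a must be > 0, got {self.a}")
        if not np.isfinite(self.c):
            raise ValueError("midpoint c must be finite")

    def __call__(self, x):
        return expit(self.a * (np.asarray(x, dtype=float) - self.c))


def sigmoid(x):
    """Logistic function 1 / (1 + exp(-x)); overflow-safe for any finite x."""
    return expit(x)


def logit(p):
    """Inverse sigmoid, log(p / (1 - p))."""
    return _logit(p)


def hill(x, p: HillParams):
    """Hill gain x^n / (k^n + x^n) for x >= 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("Hill gain is defined for non-negative arguments only")
    xn = (x / p.k) ** p.n
    return xn / (1.0 + xn)


def sigmoid_from_hill(
    p: HillParams,
    method: str = "slope_match",
    x_max: float | None = None,
    n_points: int = 601,
) -> SigmoidGainParams:
    """Convert a Hill gain to the sigmoid that best mimics it.

    ``slope_match`` matches value (1/2) and derivative (n / 4k) at the Hill
    midpoint, giving ``c = k`` and ``a = n / k`` in closed form.
    ``least_squares`` minimises the sum of squared differences between the
    two gains on an even grid of ``n_points`` points over ``[0, x_max]``
    (default ``x_max = 2.5 k``), starting from the slope-matched values.
    """
    if method == "slope_match":
        return SigmoidGainParams(a=p.n / p.k, c=p.k)
    if method != "least_squares":
        raise ValueError(f"unknown method {method!r}; use 'slope_match' or 'least_squares'")
    if x_max is None:
        x_max = 2.5 * p.k
    if x_max <= p.k:
        raise ValueError(f"least-squares fitting range [0, x_max] needs x_max > k, got {x_max}")
    grid = np.linspace(0.0, x_max, n_points)
    target = hill(grid, p)

    def resid(ac):
        a, c = ac
        return expit(a * (grid - c)) - target

    start = np.array([p.n / p.k, p.k])
    sol = least_squares(resid, start, bounds=([1e-8, -np.inf], [np.inf, np.inf]))
    return SigmoidGainParams(a=float(sol.x[0]), c=float(sol.x[1]))


def force(net: GeneNetwork, v, i=None):
    """Total regulatory force h_i = sum_j W[j, i] v_j + l_i.

    ``v`` may be a single state (length-N) or a batch with shape (..., N);
    broadcasting applies over leading axes.  With ``i`` given (name or
    index), the scalar force on that gene is returned.
    """
    v = np.asarray(v, dtype=float)
    h = v @ net.W + net.l
    if i is None:
        return h
    return h[..., net.index(i)]


def internal_energy(net: GeneNetwork, v, per_gene: bool = False):
    """Per-gene decomposed internal energy; summed by default.

    Each gene contributes

        E_i = -1/2 [ sum_{j != i} W[j, i] v_j v_i
                     + 1/2 W[i, i] v_i^2 + l_i v_i ],

    so that dE_i/dv_i = -h_i / 2 exactly — the decomposed parts are the
    objects whose own-gene gradients generate the sigmoidal dynamics (the
    diagonal carries 1/4 in E_i because a self-interaction appears once,
    not twice, in gene i's own force).  The sum equals the merged
    quadratic form -1/2 [sum_{i != j} W[j, i] v_i v_j + sum_i l_i v_i]
    - 1/4 sum_i W[i, i] v_i^2 for any (asymmetric) W, which counts every
    reciprocal coupling twice, once per direction.  The single-valued
    landscape potential counts each pair once instead; see
    :func:`landscape_energy`.  ``v`` broadcasts over leading axes.
    """
    v = np.asarray(v, dtype=float)
    diag = np.diagonal(net.W)
    cross = v @ net.W - diag * v  # sum_{j != i} W[j, i] v_j
    e = -0.5 * (cross * v + 0.5 * diag * v**2 + net.l * v)
    if per_gene:
        return e
    return e.sum(axis=-1)


def landscape_energy(net: GeneNetwork, v):
    """Quadratic landscape potential E(v) = -1/4 v'Wv - 1/2 l'v.

    The unique single-valued quadratic whose partial derivatives reproduce
    the per-gene decomposed gradients ``-h_i / 2`` exactly whenever the
    couplings are reciprocal (symmetric W): each unordered gene pair
    enters once at the mean of its two directed strengths, and each
    self-interaction at the same 1/4 coefficient as in the decomposition.
    For non-reciprocal couplings this mean-coupling form is the
    approximation that makes a landscape exist at all; its minima then
    track the dynamical fixed points only approximately.  ``v`` broadcasts
    over leading axes.
    """
    v = np.asarray(v, dtype=float)
    quad = np.einsum("...j,ji,...i->...", v, net.W, v)
    return -0.25 * quad - 0.5 * (v @ net.l)


def entropy(v, per_gene: bool = False):
    """Binary mixing entropy S = -1/2 sum_i [v ln v + (1-v) ln(1-v)].

    Natural logarithm; non-negative, maximal at v = 1/2, and vanishing in
    the limits v -> 0+ or 1-.  Components must lie strictly inside (0, 1).
    ``v`` broadcasts over leading axes.
    """
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0.0) or np.any(v >= 1.0):
        raise ValueError("entropy requires components strictly inside (0, 1)")
    s = -0.5 * (xlogy(v, v) + xlogy(1.0 - v, 1.0 - v))
    if per_gene:
        return s
    return s.sum(axis=-1)


def free_energy(net: GeneNetwork, v, noise: NoiseModel):
    """Landscape value F(v) = E(v) - Theta * S(v) with Theta = 2 T.

    ``E`` is the mean-coupling quadratic of :func:`landscape_energy`, so
    for symmetric W every interior stationary point of F is exactly a
    fixed point ``v_i = sigmoid(h_i / Theta)`` of the dynamics and vice
    versa.  Gene-by-gene (partners frozen) the same equivalence holds for
    *any* W through the decomposed parts ``internal_energy(...,
    per_gene=True)``.  ``v`` broadcasts over leading axes.
    """
    return landscape_energy(net, v) - noise.theta * entropy(v)
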