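"""Ready-made example networks with verified attractor structure.

Five circuits, from toy switches to published developmental motifs:

* a single self-activating gene (the minimal bistable switch),
* the toggle switch (two mutually repressing, self-activating genes),
* GATA2-GFI1B-GFI1 (haematopoietic stem cell vs myelo-lymphoid commitment),
* GATA1-GATA2-PU.1 (erythroid vs myeloid lineage choice),
* the embryonic stem cell core circuit NANOG / OCT4-SOX2 / FGF4 / G,
  where G stands for a differentiation programme (e.g. GATA6, SOX17) and
  the culture signals LIF and 2i enter as external-input knobs.

Only the sign patterns of the interaction matrices are taken from the
literature; the default magnitudes are re-derived in this package so that
each circuit's documented pair of cell states is a stable fixed point of
the dynamics *and* a grid attractor of the free-energy landscape, with the
two routes agreeing to within one grid cell.  Because the landscape
effectively symmetrises the interaction matrix, that joint requirement is
only approximately satisfiable for asymmetric topologies; the defaults
push both attractors into deeply saturated (near-corner) expression states
where the residual disagreement is smaller than a grid cell.  The
constants below are frozen output of ``scripts/derive_zoo_params.py``,
which re-derives and re-verifies them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import DynamicsSettings, TimeSeries, integrate
from .model import GeneNetwork, NoiseModel

__all__ = [
    "ZooEntry",
    "make_single_gene",
    "make_toggle",
    "make_gata2_gfi1_gfi1b",
    "make_gata1_gata2_pu1",
    "make_escell",
    "get",
    "names",
    "generate_synthetic_timeseries",
]


@dataclass(frozen=True)
class ZooEntry:
    """A zoo network with its default noise level and extra presets.

    ``attractor_patterns`` lists the documented cell states as high/low
    (1/0) signatures, in no particular order.  ``presets`` holds named
    :class:`NoiseModel` alternatives (for the 1- and 2-gene models a
    ``high_T`` preset in which the barrier is much lower or bistability is
    lost).  ``grid_d`` is the default landscape resolution for this N.
    """

    name: str
    network: GeneNetwork
    noise: NoiseModel
    presets: dict = field(default_factory=dict)
    attractor_patterns: tuple = ()
    grid_d: int = 50
    note: str = ""


def make_single_gene() -> ZooEntry:
    """One positively self-interacting gene: the minimal bistable switch.

    With ``w = 4`` and ``l = -2`` the force is antisymmetric about
    ``v = 1/2``; the switch is bistable for ``T < 0.5`` (the ``low_T``
    default ``T = 0.2``) and monostable at the ``high_T`` preset
    ``T = 0.6``.  Raising T within the bistable range pulls both
    attractors towards 1/2 and lowers the barrier between them.
    """
    net = GeneNetwork(
        ["A"],
        [[4.0]],
        [-2.0],
        metadata={"description": "single self-activating gene switch"},
    )
    return ZooEntry(
        name="single_gene",
        network=net,
        noise=NoiseModel(0.2),
        presets={"low_T": NoiseModel(0.2), "high_T": NoiseModel(0.6)},
        attractor_patterns=((0,), (1,)),
        grid_d=200,
        note="positive auto-regulation; bistable below T=0.5",
    )


def make_toggle() -> ZooEntry:
    """Two mutually repressing, self-activating genes (the toggle switch).

    Symmetric defaults, so the free energy is invariant under gene swap
    and the two attractors (X-high/Y-low and X-low/Y-high) are mirror
    images.  Bistable for ``T < 0.75``; the ``high_T`` preset ``T = 0.65``
    stays bistable with a much smaller barrier.
    """
    net = GeneNetwork(
        ["X", "Y"],
        [[2.0, -4.0], [-4.0, 2.0]],
        [1.0, 1.0],
        metadata={"description": "mutual-inhibition toggle with auto-activation"},
    )
    return ZooEntry(
        name="toggle",
        network=net,
        noise=NoiseModel(0.4),
        presets={"low_T": NoiseModel(0.4), "high_T": NoiseModel(0.65)},
        attractor_patterns=((1, 0), (0, 1)),
        grid_d=50,
        note="paradigmatic bistable motif; symmetric parameters",
    )


def make_gata2_gfi1_gfi1b() -> ZooEntry:
    """GATA2-GFI1B-GFI1 circuit of myelo-lymphoid lineage entry.

    Sign structure: GFI1B and GFI1 mutually inhibit; GFI1 represses GATA2;
    GATA2 induces GFI1B; GATA2 and GFI1 are auto-repressive while GFI1B is
    auto-activating.  The two cell states are the haematopoietic stem cell
    state (GATA2/GFI1B high, GFI1 low) and the myelo-lymphoid committed
    state (GFI1 high, GATA2/GFI1B low).
    """
    genes = ["GATA2", "GFI1B", "GFI1"]
    W = [
        [-0.500, 1.047, 0.000],  # GATA2: auto-repression, induces GFI1B
        [0.000, 1.786, -5.129],  # GFI1B: auto-activation, represses GFI1
        [-10.290, -2.302, -0.500],  # GFI1: represses GATA2+GFI1B, auto-repression
    ]
    l = [2.845, 0.001, 2.833]
    net = GeneNetwork(genes, W, l, metadata={"description": "myelo-lymphoid entry circuit"})
    return ZooEntry(
        name="gata2_gfi1_gfi1b",
        network=net,
        noise=NoiseModel(0.25),
        presets={"low_T": NoiseModel(0.25)},
        attractor_patterns=((1, 1, 0), (0, 0, 1)),
        grid_d=40,
        note="HSC (GATA2/GFI1B high) vs myelo-lymphoid (GFI1 high)",
    )


def make_gata1_gata2_pu1() -> ZooEntry:
    """GATA1-GATA2-PU.1 circuit of the erythroid/myeloid decision.

    Sign structure: GATA1 and PU.1 mutually inhibit and self-activate;
    GATA2 and PU.1 mutually inhibit; GATA1 represses GATA2 while GATA2
    induces GATA1; GATA2 is auto-repressive.  The two cell states are
    erythroid (GATA1/GATA2 high, PU.1 low) and myeloid (PU.1 high).  The
    defaults place the landscape saddle at high GATA2 *and* high PU.1, so
    the optimal myeloid-to-erythroid route raises GATA2 before PU.1 falls.
    """
    genes = ["GATA1", "GATA2", "PU1"]
    W = [
        [1.785, -0.500, -3.633],  # GATA1: auto-activation, represses GATA2 & PU1
        [3.185, -0.500, -5.623],  # GATA2: induces GATA1, auto-repression, represses PU1
        [-3.633, -5.590, 1.440],  # PU1: represses GATAs, auto-activation
    ]
    l = [-0.811, 3.294, 2.881]
    net = GeneNetwork(genes, W, l, metadata={"description": "erythroid/myeloid decision circuit"})
    return ZooEntry(
        name="gata1_gata2_pu1",
        network=net,
        noise=NoiseModel(0.25),
        presets={"low_T": NoiseModel(0.25)},
        attractor_patterns=((1, 1, 0), (0, 0, 1)),
        grid_d=40,
        note="erythroid (GATA1/GATA2 high) vs myeloid (PU.1 high)",
    )


# Embryonic stem cell circuit: the external inputs decompose into a basal
# part plus the named culture-signal knobs (LIF induces NANOG; the 2i
# medium suppresses FGF4).  Defaults below reproduce the frozen l vector.
_ESCELL_L_BASAL = np.array([0.492, 2.312, -2.311, 0.712])
_ESCELL_LIF_DEFAULT = 0.75
_ESCELL_TWO_I_DEFAULT = 0.0


def make_escell(lif: float = _ESCELL_LIF_DEFAULT, two_i: float = _ESCELL_TWO_I_DEFAULT) -> ZooEntry:
    """Embryonic stem cell core circuit NANOG / OCT4-SOX2 / FGF4 / G.

    Sign structure: OCT4-SOX2 (one heterodimer node) induces NANOG, FGF4
    and the differentiation gene G; NANOG is auto-repressive and represses
    G; FGF4 represses NANOG; G is auto-activating and represses NANOG and
    OCT4-SOX2.  ``lif`` (>= 0) adds to NANOG's external input; ``two_i``
    (>= 0) subtracts from FGF4's.  The two cell states are pluripotent
    (NANOG, OCT4-SOX2, FGF4 high; G low) and committed (G high, rest low).
    """
    if lif < 0 or two_i < 0:
        raise ValueError("lif and two_i are signal strengths and must be >= 0")
    genes = ["NANOG", "OCT4-SOX2", "FGF4", "G"]
    W = [
        [-0.500, 0.000, 0.000, -3.507],  # NANOG: auto-repression, represses G
        [3.583, 0.000, 9.648, 0.500],  # OCT4-SOX2: induces NANOG, FGF4, G
        [-0.500, 0.000, 0.000, 0.000],  # FGF4: represses NANOG
        [-3.552, -9.784, 0.000, 1.634],  # G: represses NANOG & OCT4-SOX2, auto-activation
    ]
    l = _ESCELL_L_BASAL + np.array([lif, 0.0, -two_i, 0.0])
    net = GeneNetwork(
        genes,
        W,
        l,
        metadata={"description": "ES-cell pluripotency/commitment circuit", "lif": lif, "two_i": two_i},
    )
    return ZooEntry(
        name="escell",
        network=net,
        noise=NoiseModel(0.25),
        presets={"low_T": NoiseModel(0.25)},
        attractor_patterns=((1, 1, 1, 0), (0, 0, 0, 1)),
        grid_d=25,
        note="pluripotent (NANOG/OCT4-SOX2/FGF4 high) vs committed (G high)",
    )


_REGISTRY = {
    "single_gene": make_single_gene,
    "toggle": make_toggle,
    "gata2_gfi1_gfi1b": make_gata2_gfi1_gfi1b,
    "gata1_gata2_pu1": make_gata1_gata2_pu1,
    "escell": make_escell,
}


def names() -> list:
    """Zoo entry names in registry order."""
    return list(_REGISTRY)


def get(name: str) -> ZooEntry:
    """Look up a zoo entry by name."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown zoo network {name!r}; available: {', '.join(_REGISTRY)}")
    return factory()


def generate_synthetic_timeseries(
    entry: ZooEntry,
    v0,
    observation_noise_sd: float = 0.0,
    seed: int = 0,
    n_points: int = 50,
    dt: float = 0.2,
    settings: DynamicsSettings | None = None,
) -> TimeSeries:
    """Simulated expression data for parameter-recovery experiments.

    Integrates the entry's dynamics with the Euler step equal to the
    output spacing ``dt`` over ``n_points`` observations, then adds seeded
    Gaussian observation noise (sd ``observation_noise_sd``), clipped back
    into (0, 1).  With zero noise the output is exactly the integrator's
    trajectory, so the ground-truth parameters are recoverable.
    """
    if observation_noise_sd < 0:
        raise ValueError("observation noise sd must be >= 0")
    s = settings or DynamicsSettings(dt=dt, t_max=dt * (n_points - 1))
    traj = integrate(entry.network, entry.noise, v0, s)
    take = slice(0, n_points)
    times = traj.times[take]
    values = np.array(traj.values[take])
    if observation_noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, observation_noise_sd, size=values.shape)
        values = np.clip(values, 1e-6, 1.0 - 1e-6)
    return TimeSeries(times, values, entry.network.gene_names)
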