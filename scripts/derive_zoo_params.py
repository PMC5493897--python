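"""Re-derive the frozen default parameters of the multi-gene zoo networks.

The zoo circuits have literature-derived *sign patterns* but no published
magnitudes, so the defaults must be chosen.  The requirement is that the
documented pair of cell states shows up as exactly two attractors by both
routes — stable fixed points of the sigmoidal dynamics and sinks of the
discretized free-energy landscape — agreeing within one grid cell, and
that the optimal inter-attractor routes show the documented gene ordering.

Because the merged landscape effectively symmetrises the interaction
matrix while the dynamics uses it one-sidedly, those requirements cannot
be met exactly for asymmetric topologies.  The design used here drives
both routes' attractors into the same deeply saturated corner cells:
bounded least squares over (W, l) with hinge residuals demanding

* a strong self-consistent force (|h|/Theta >= m) at both wanted corner
  states, for the dynamics matrix and for its symmetrisation;
* rejection of every unwanted corner pattern (some gene's force pushes
  away from the corner), again for both routes;
* where a route ordering is documented, a free-energy ordering between
  candidate saddle corners (e.g. the GATA2-high/PU.1-high pass must be
  cheaper than the PU.1-down-first pass).

Run:  python scripts/derive_zoo_params.py
Prints the derived (W, l) per network and the verification summary; the
values frozen in grnscape.zoo are the rounded output of this script.
"""

import numpy as np
from scipy.optimize import least_squares

from grnscape import (
    GeneNetwork,
    NoiseModel,
    build_graph,
    evaluate_grid,
    find_attractors,
    free_energy,
    shortest_path,
    steady_states,
)

EPS = 0.01  # corner evaluation level
T = 0.25
M_WANT = 4.5  # saturation margin (logit units) at wanted corners
M_AVOID = 1.0  # rejection margin at unwanted corners


def corner(pattern):
    return np.where(np.array(pattern) == 1, 1 - EPS, EPS)


def design(genes, edges, signs, want, avoid, f_order=(), w_cap=20.0, l_cap=12.0,
           w_min=0.5, reg=0.02, seed=0, n_starts=6):
    n = len(genes)
    theta = 2 * T
    nW = len(edges)
    noise = NoiseModel(T)

    def unpack(x):
        W = np.zeros((n, n))
        for e, (j, i) in enumerate(edges):
            W[j, i] = x[e]
        return W, x[nW:]

    def route_h(W, l, t, route):
        if route == "dyn":
            return t @ W + l
        Wsym = 0.5 * (W + W.T)
        np.fill_diagonal(Wsym, np.diagonal(W))
        return t @ Wsym + l

    def resid(x):
        W, l = unpack(x)
        out = []
        for pat in want:
            t = corner(pat)
            sgn = np.where(np.array(pat) == 1, 1.0, -1.0)
            for route in ("dyn", "land"):
                out.append(np.maximum(0.0, M_WANT - sgn * route_h(W, l, t, route) / theta))
        for pat in avoid:
            t = corner(pat)
            sgn = np.where(np.array(pat) == 1, 1.0, -1.0)
            for route in ("dyn", "land"):
                z = sgn * route_h(W, l, t, route) / theta
                softmin = -np.log(np.sum(np.exp(-4.0 * z))) / 4.0
                out.append(np.array([np.maximum(0.0, M_AVOID + softmin)]))
        if f_order:
            net = GeneNetwork(genes, W, l)
            for lo_pat, hi_pat, margin in f_order:
                f_lo = free_energy(net, corner(lo_pat), noise)
                f_hi = free_energy(net, corner(hi_pat), noise)
                out.append(np.array([np.maximum(0.0, f_lo + margin - f_hi)]))
        out.append(reg * x)
        return np.concatenate(out)

    lo = np.empty(nW + n)
    hi = np.empty(nW + n)
    for e, key in enumerate(edges):
        lo[e], hi[e] = (w_min, w_cap) if signs[key] > 0 else (-w_cap, -w_min)
    lo[nW:], hi[nW:] = -l_cap, l_cap
    rng = np.random.default_rng(seed)
    lo_c, hi_c = np.clip(lo, -6, 6), np.clip(hi, -6, 6)
    best = None
    for k in range(n_starts):
        x0 = rng.uniform(lo_c, hi_c) if k else np.clip(np.zeros(nW + n), lo, hi)
        sol = least_squares(resid, x0, bounds=(lo, hi))
        if best is None or sol.cost < best.cost:
            best = sol
    W, l = unpack(best.x)
    return GeneNetwork(genes, W, l), NoiseModel(T)


def first_cross(states, col, up):
    idx = np.flatnonzero(states[:, col] > 0.5 if up else states[:, col] < 0.5)
    return int(idx[0]) if idx.size else None


def verify(name, net, noise, d, orders=()):
    print(f"\n=== {name} (T={noise.T}) ===")
    print("W =\n", np.array2string(net.W, precision=3, suppress_small=True))
    print("l =", np.array2string(net.l, precision=3))
    ss = steady_states(net, noise, n_starts=100, seed=1)
    grid = evaluate_grid(net, noise, d=d)
    graph = build_graph(grid)
    attrs = find_attractors(graph, grid)
    agree = len(ss) == len(attrs.attractors) == 2 and all(
        any(np.max(np.abs(v - a.state)) <= 1.0 / d + 1e-9 for a in attrs.attractors)
        for v in ss
    )
    print(f"dynamics states: {len(ss)}, landscape attractors: {len(attrs.attractors)}, "
          f"one-cell agreement: {agree}")
    for src_pat, tgt_pat, checks in orders:
        def find(pat):
            for k, a in enumerate(attrs.attractors):
                if tuple(1 if x > 0.5 else 0 for x in a.state) == tuple(pat):
                    return k
            raise RuntimeError(f"no attractor with pattern {pat}")

        p = shortest_path(graph, grid, attrs, find(src_pat), find(tgt_pat))
        steps = {
            label: first_cross(p.states, col, up) for label, col, up in checks
        }
        print(f"path {src_pat} -> {tgt_pat}: {len(p)} cells; crossings {steps}")


def main():
    genes = ["GATA2", "GFI1B", "GFI1"]
    edges = [(0, 0), (1, 1), (2, 2), (2, 0), (0, 1), (2, 1), (1, 2)]
    signs = {(0, 0): -1, (1, 1): +1, (2, 2): -1, (2, 0): -1, (0, 1): +1,
             (2, 1): -1, (1, 2): -1}
    net, noise = design(
        genes, edges, signs,
        want=[(1, 1, 0), (0, 0, 1)],
        avoid=[(0, 0, 0), (1, 1, 1), (1, 0, 0), (0, 1, 0)],
    )
    verify("gata2_gfi1_gfi1b", net, noise, 40, orders=[
        ((0, 0, 1), (1, 1, 0), [("GFI1 down", 2, False), ("GFI1B up", 1, True),
                                ("GATA2 up", 0, True)]),
    ])

    genes = ["GATA1", "GATA2", "PU1"]
    edges = [(0, 0), (1, 1), (2, 2), (2, 0), (0, 2), (1, 0), (0, 1), (1, 2), (2, 1)]
    signs = {(0, 0): +1, (1, 1): -1, (2, 2): +1, (2, 0): -1, (0, 2): -1,
             (1, 0): +1, (0, 1): -1, (1, 2): -1, (2, 1): -1}
    net, noise = design(
        genes, edges, signs,
        want=[(1, 1, 0), (0, 0, 1)],
        avoid=[(0, 0, 0), (1, 1, 1), (1, 0, 1), (0, 1, 1), (1, 0, 0), (0, 1, 0)],
        f_order=[((0, 1, 1), (0, 0, 0), 0.5), ((0, 1, 1), (1, 0, 1), 0.5)],
    )
    verify("gata1_gata2_pu1", net, noise, 40, orders=[
        ((0, 0, 1), (1, 1, 0), [("GATA2 up", 1, True), ("PU1 down", 2, False),
                                ("GATA1 up", 0, True)]),
    ])

    genes = ["NANOG", "OCT4-SOX2", "FGF4", "G"]
    edges = [(1, 0), (0, 0), (2, 0), (3, 0), (3, 1), (1, 2), (0, 3), (1, 3), (3, 3)]
    signs = {(1, 0): +1, (0, 0): -1, (2, 0): -1, (3, 0): -1, (3, 1): -1,
             (1, 2): +1, (0, 3): -1, (1, 3): +1, (3, 3): +1}
    # Tighter cap and stronger shrinkage keep the mean-coupling landscape
    # smooth enough that no spurious intermediate minimum appears.
    net, noise = design(
        genes, edges, signs,
        want=[(1, 1, 1, 0), (0, 0, 0, 1)],
        avoid=[(0, 0, 0, 0), (1, 1, 1, 1), (1, 1, 0, 0), (0, 0, 1, 1),
               (1, 0, 1, 0), (0, 1, 0, 1), (0, 1, 1, 0), (1, 0, 0, 1)],
        w_cap=12.0, reg=0.08,
    )
    verify("escell", net, noise, 25, orders=[
        ((0, 0, 0, 1), (1, 1, 1, 0), [("OCT4-SOX2 up", 1, True), ("NANOG up", 0, True),
                                      ("G down", 3, False)]),
    ])


if __name__ == "__main__":
    main()
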