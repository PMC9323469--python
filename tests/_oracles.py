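"""Independent reference implementations used as test oracles.

Everything in this module deliberately avoids the package's own code paths
for the quantity it checks: the MBAR reference minimises the convex MBAR
objective with scipy's BFGS, the common-subgraph reference enumerates
subsets exhaustively with networkx's isomorphism matcher, and the PSF
reader is a from-scratch minimal parser.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from scipy.optimize import minimize as scipy_minimize
from scipy.special import logsumexp


def reference_mbar(u: np.ndarray, counts) -> np.ndarray:
    """Dimensionless free energies by direct minimisation of the MBAR
    objective (BFGS with analytic gradient), anchored at f_0 = 0."""
    u = np.asarray(u, dtype=float)
    counts = np.asarray(counts, dtype=float)
    log_n = np.log(counts)

    def split(fr):
        return np.concatenate([[0.0], fr])

    def objective(fr):
        f = split(fr)
        log_d = logsumexp(log_n[:, None] + f[:, None] - u, axis=0)
        return float(np.sum(log_d) - counts @ f)

    def gradient(fr):
        f = split(fr)
        log_d = logsumexp(log_n[:, None] + f[:, None] - u, axis=0)
        w = np.exp(f[:, None] - u - log_d[None, :])
        return (counts * w.sum(axis=1) - counts)[1:]

    res = scipy_minimize(objective, np.zeros(u.shape[0] - 1), jac=gradient,
                         method="BFGS", options={"gtol": 1e-12, "maxiter": 5000})
    return split(res.x)


def _as_graph(system) -> nx.Graph:
    g = nx.Graph()
    for a in system.atoms:
        g.add_node(a.index, element=a.element)
    g.add_edges_from(system.bonds)
    return g


def _ring_preserving(rings, subset) -> bool:
    for ring in rings:
        hit = len(ring & subset)
        if 0 < hit < len(ring):
            return False
    return True


def brute_force_mcs_size(system_a, system_b) -> int:
    """Size of the maximum connected induced ring-preserving common
    subgraph, by exhaustive enumeration of connected subsets of A."""
    from ccsai.molecular_model import rings as find_rings

    ga, gb = _as_graph(system_a), _as_graph(system_b)
    rings_a = find_rings(system_a)
    rings_b = find_rings(system_b)
    nodes = sorted(ga.nodes)
    best = 0
    for size in range(len(nodes), 0, -1):
        if size <= best:
            break
        for subset in itertools.combinations(nodes, size):
            sset = frozenset(subset)
            sub = ga.subgraph(subset)
            if not nx.is_connected(sub):
                continue
            if not _ring_preserving(rings_a, sset):
                continue
            matcher = nx.algorithms.isomorphism.GraphMatcher(
                gb, sub,
                node_match=lambda n1, n2: n1["element"] == n2["element"])
            for mapping in matcher.subgraph_isomorphisms_iter():
                image = frozenset(mapping)
                if _ring_preserving(rings_b, image):
                    best = size
                    break
            if best == size:
                break
    return best


def parse_psf(path: str):
    """Minimal independent PSF reader: atoms (name, charge, mass) + bonds."""
    with open(path) as fh:
        lines = fh.readlines()
    atoms = []
    bonds = []
    i = 0
    while i < len(lines):
        line = lines[i]
        if "!NATOM" in line:
            n = int(line.split()[0])
            for j in range(1, n + 1):
                parts = lines[i + j].split()
                atoms.append({
                    "index": int(parts[0]),
                    "name": parts[4],
                    "type": parts[5],
                    "charge": float(parts[6]),
                    "mass": float(parts[7]),
                })
            i += n
        elif "!NBOND" in line:
            n = int(line.split()[0])
            flat = []
            j = i + 1
            while len(flat) < 2 * n:
                flat.extend(int(tok) for tok in lines[j].split())
                j += 1
            bonds = [(flat[2 * k], flat[2 * k + 1]) for k in range(n)]
            i = j
        i += 1
    return atoms, bonds
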