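"""Thresholding a connectivity matrix and extracting lipid modules.

Two analytes are linked when their rescaled connectivity score is at least
``epsilon`` in magnitude; a module is a connected component of that graph
with at least ``m`` members.  Components smaller than ``m`` — including
isolated analytes — are module-free.  (The path-connectivity reading of a
module is used; requiring *every* within-module pair to score above the
threshold would make modules cliques, which contradicts the path wording and
the observed network topology, so it is deliberately not implemented.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .connectivity import ConnectivityMatrix
from .io import NetworkEdgeList


@dataclass
class ModuleSet:
    """Disjoint analyte modules of size >= m from one thresholded network."""

    modules: list[frozenset]
    m: int
    epsilon: float
    universe: list  # all analyte ids of the network
    member_of: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        member_of = {}
        for i, mod in enumerate(self.modules):
            if len(mod) < self.m:
                raise ValueError("module smaller than minimum size m")
            for a in mod:
                if a in member_of:
                    raise ValueError("modules are not disjoint")
                member_of[a] = i
        self.member_of = member_of

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def module_of(self, analyte) -> frozenset | None:
        i = self.member_of.get(analyte)
        return None if i is None else self.modules[i]

    def covered(self) -> frozenset:
        """Analytes belonging to some module."""
        return frozenset(self.member_of)


def threshold_network(cm: ConnectivityMatrix, epsilon: float) -> NetworkEdgeList:
    """Edges between analyte pairs with ``|score| >= epsilon`` (sign ignored)."""
    if not cm.rescaled:
        raise ValueError("threshold_network expects a rescaled connectivity matrix")
    if not 0 < epsilon <= 1:
        raise ValueError("epsilon must be in (0, 1]")
    s = cm.scores
    ids = cm.analyte_ids
    jj, kk = np.nonzero(np.triu(np.abs(s) >= epsilon, k=1))
    edges = [(ids[j], ids[k], float(s[j, k])) for j, k in zip(jj, kk)]
    return NetworkEdgeList(edges=edges, epsilon=epsilon, nodes=list(ids))


def extract_modules(net: NetworkEdgeList, m: int = 3) -> ModuleSet:
    """Connected components of the thresholded graph, kept when size >= m."""
    if m < 2:
        raise ValueError("minimum module size m must be >= 2")
    ids = list(net.nodes)
    index = {a: i for i, a in enumerate(ids)}
    p = len(ids)
    if net.edges:
        rows = np.array([index[j] for j, _, _ in net.edges])
        cols = np.array([index[k] for _, k, _ in net.edges])
        data = np.ones(len(net.edges))
        adj = csr_matrix(
            (np.r_[data, data], (np.r_[rows, cols], np.r_[cols, rows])), shape=(p, p)
        )
        _, labels = connected_components(adj, directed=False)
    else:
        labels = np.arange(p)
    comps: dict[int, list] = {}
    for a, lab in zip(ids, labels):
        comps.setdefault(int(lab), []).append(a)
    modules = [frozenset(members) for _, members in sorted(comps.items()) if len(members) >= m]
    return ModuleSet(modules=modules, m=m, epsilon=net.epsilon, universe=ids)
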