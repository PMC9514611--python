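"""High-level facade tying model → graph → transform → bSFS together."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .laplace import ComputationalGraph, evaluate_laplace
from .mc import estimate_bsfs
from .model import BranchTypeSet, DemographicModel
from .mutations import ArrayLayout, ConfigArray, array_layout
from .statespace import StateGraph, build_state_graph
from .taylor import bsfs_probabilities


class GfEvaluator:
    """Caches the state and computational graphs of one model.

    Parameters
    ----------
    model:
        The demographic model.
    phased, rooted:
        Branch-type labelling flags: unphased labels samples by deme of
        origin; unrooted folds complementary types.
    """

    def __init__(self, model: DemographicModel, *, phased: bool = False,
                 rooted: bool = False) -> None:
        self.model = model
        self.bts = BranchTypeSet(model, phased=phased, rooted=rooted)
        self.graph: StateGraph = build_state_graph(model, self.bts)
        self.cgraph = ComputationalGraph(self.graph)

    @property
    def n_branch_types(self) -> int:
        return len(self.bts)

    def laplace(self, omega: Sequence[float], T: Optional[float] = None) -> float:
        """Evaluate the (δ-inverted) Laplace transform at ``ω``."""
        return evaluate_laplace(self.cgraph, omega, T)

    def bsfs(self, theta: float, kmax, T: Optional[float] = None) -> ConfigArray:
        """Exact block-wise mutation-configuration probabilities."""
        return bsfs_probabilities(self.cgraph, theta, kmax, T=T)

    def bsfs_mc(self, theta: float, kmax, reps: int, seed: int,
                T: Optional[float] = None) -> ConfigArray:
        """Monte-Carlo estimate of the same array (with standard errors)."""
        return estimate_bsfs(self.graph, theta, kmax, reps, seed, T=T)

    def layout(self, kmax) -> ArrayLayout:
        return array_layout(kmax, self.graph)

    def graph_stats(self, kmax=None) -> dict:
        """Structural counts: states/edges, computational-graph nodes,
        branch types, path-equation table size, and (given ``kmax``)
        configuration-array sizes."""
        out = {
            "demes": len(self.model.demes),
            "samples": self.model.total_samples,
            "branch_types": len(self.bts),
            "state_graph_states": self.graph.n_states,
            "state_graph_edges": self.graph.n_edges,
            "unique_equations": len(self.graph.equations),
            "computational_graph_nodes": self.cgraph.n_nodes,
        }
        if kmax is not None:
            lay = self.layout(kmax)
            out["bsfs_size"] = lay.n_slots
            out["bsfs_compatible"] = lay.n_compatible
        return out
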