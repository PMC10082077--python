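"""Diffusion-based pathway enrichment over a metabolite-pathway graph.

Significantly changed compounds are placed as heat sources on a typed
(pathway / reaction / compound) knowledge graph; node scores solve the
regularized-Laplacian system (L + lambda I) f = b where b indicates the
input compounds.  Empirical p-scores compare each node's observed score
with a null distribution of scores from random compound sets of the same
size, with add-one smoothing, so a node's p-score is never below
1/(1 + n_permutations).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

DEFAULT_LAMBDA = 0.01


def _node_order(graph: nx.Graph) -> list:
    return sorted(graph.nodes)


def _laplacian_solver(graph: nx.Graph, lam: float):
    nodes = _node_order(graph)
    L = nx.laplacian_matrix(graph, nodelist=nodes, weight="weight").astype(float)
    A = (L + lam * sp.identity(L.shape[0], format="csr")).tocsc()
    return nodes, splu(A)


def compound_nodes(graph: nx.Graph) -> list:
    return sorted(n for n, d in graph.nodes(data=True) if d.get("type") == "compound")


def diffusion_scores(graph: nx.Graph, input_compounds: set,
                     lam: float = DEFAULT_LAMBDA) -> pd.Series:
    """Heat-diffusion score per node for a set of input compounds."""
    nodes, lu, b = _prepare(graph, input_compounds, lam)
    return pd.Series(lu.solve(b), index=nodes)


def _prepare(graph: nx.Graph, input_compounds: set, lam: float):
    if not input_compounds:
        raise ValueError("input compound set is empty")
    comp = set(compound_nodes(graph))
    missing = set(input_compounds) - comp
    if missing:
        raise ValueError(f"input ids not present as compound nodes: {sorted(missing)}")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    nodes, lu = _laplacian_solver(graph, lam)
    idx = {n: i for i, n in enumerate(nodes)}
    b = np.zeros(len(nodes))
    for c in input_compounds:
        b[idx[c]] = 1.0
    return nodes, lu, b


@dataclass
class EnrichmentResult:
    """Diffusion scores with permutation p-scores per node."""

    table: pd.DataFrame  # columns: node_type, score, p_score, sig_0.01, sig_0.05
    n_permutations: int

    def significant_pathways(self, threshold: float = 0.05) -> set:
        t = self.table
        mask = (t["node_type"] == "pathway") & (t["p_score"] < threshold)
        return set(t.index[mask])


def pscore(graph: nx.Graph, input_compounds: set, n_permutations: int = 2000,
           seed: int = 0, lam: float = DEFAULT_LAMBDA) -> EnrichmentResult:
    """Empirical diffusion p-scores from random same-size compound sets.

    p = (1 + #{null scores >= observed}) / (1 + n_permutations) per node.
    """
    if n_permutations < 1000:
        raise ValueError("at least 1000 permutations are required")
    comp = compound_nodes(graph)
    k = len(set(input_compounds))
    if k > len(comp):
        raise ValueError("input set larger than the graph's compound count")
    nodes, lu, b = _prepare(graph, set(input_compounds), lam)
    observed = lu.solve(b)

    rng = np.random.default_rng(seed)
    idx = {n: i for i, n in enumerate(nodes)}
    comp_idx = np.array([idx[c] for c in comp])
    exceed = np.zeros(len(nodes))
    for _ in range(n_permutations):
        pick = rng.choice(comp_idx, size=k, replace=False)
        bb = np.zeros(len(nodes))
        bb[pick] = 1.0
        null = lu.solve(bb)
        exceed += null >= observed
    p = (1.0 + exceed) / (1.0 + n_permutations)
    table = pd.DataFrame({
        "node_type": [graph.nodes[n]["type"] for n in nodes],
        "score": observed,
        "p_score": p,
    }, index=pd.Index(nodes, name="node_id"))
    table["sig_0.01"] = table["p_score"] < 0.01
    table["sig_0.05"] = table["p_score"] < 0.05
    return EnrichmentResult(table=table, n_permutations=n_permutations)


def map_features_to_compounds(feature_meta: pd.DataFrame, diff_table: pd.DataFrame,
                              dictionary: dict, p_threshold: float = 0.1,
                              p_column: str = "p_raw") -> tuple[set, list]:
    """Map significant features to compound ids via identification labels.

    Features with ``p < p_threshold`` whose identification label has a
    dictionary entry contribute their compound id (duplicates collapse to
    a non-redundant set); significant features without an entry are
    returned as unmatched.
    """
    sig = diff_table.index[diff_table[p_column] < p_threshold]
    matched, unmatched = set(), []
    for fid in sig:
        label = feature_meta.loc[fid, "identification"]
        if label in dictionary:
            matched.add(dictionary[label])
        else:
            unmatched.append(fid)
    return matched, unmatched
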