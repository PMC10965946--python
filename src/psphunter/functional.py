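"""Protein-level annotation and PPI-network feature blocks."""

from __future__ import annotations

import networkx as nx
import numpy as np

from .io import PTM_TYPES, AnnotationTables

#: 11-dim annotation layout: PTM frequencies for the four experimentally
#: annotated modification types (sites / length), variant counts
#: (total, pathogenic, neutral), log10(abundance ppm + 1), protein age,
#: essential flag, housekeeping flag.
ANNOTATION_SLOTS = (
    "ptm_phosphorylation", "ptm_acetylation", "ptm_ubiquitination",
    "ptm_methylation", "variants_total", "variants_pathogenic",
    "variants_neutral", "abundance", "age", "essential", "housekeeping",
)


def annotation_block(protein_id: str, length: int,
                     tables: AnnotationTables) -> tuple[np.ndarray, bool]:
    """11-dim protein-annotation block and its availability flag.

    PTM frequency is annotated sites divided by sequence length.  Proteins
    absent from every table get an all-zero block flagged unavailable;
    abundance enters as log10(ppm + 1) since the forest only needs a
    monotone encoding.
    """
    if length <= 0:
        raise ValueError("protein length must be positive")
    out = np.zeros(len(ANNOTATION_SLOTS))
    seen = False
    ptms = tables.ptm_counts.get(protein_id)
    if ptms is not None:
        seen = True
        for i, t in enumerate(PTM_TYPES):
            c = ptms.get(t, 0)
            if c < 0:
                raise ValueError(f"{protein_id}: negative PTM count")
            out[i] = c / length
    variants = tables.variants.get(protein_id)
    if variants is not None:
        seen = True
        n_path = sum(v.clazz == "pathogenic" for v in variants)
        n_neut = sum(v.clazz == "neutral" for v in variants)
        out[4:7] = (n_path + n_neut, n_path, n_neut)
    if protein_id in tables.abundance:
        seen = True
        out[7] = np.log10(tables.abundance[protein_id] + 1.0)
    if protein_id in tables.age:
        seen = True
        out[8] = tables.age[protein_id]
    if tables.is_available("essential"):
        seen = seen or protein_id in tables.essential
        out[9] = float(protein_id in tables.essential)
    if tables.is_available("housekeeping"):
        seen = seen or protein_id in tables.housekeeping
        out[10] = float(protein_id in tables.housekeeping)
    return out, seen


def network_block(protein_id: str, graph: nx.Graph,
                  betweenness: dict | None = None) -> np.ndarray:
    """4-dim network block: degree, betweenness, clustering coefficient,
    average neighbor degree.

    Betweenness is the unnormalized shortest-path count over the full graph;
    pass a precomputed ``betweenness`` dict to avoid recomputing it per
    protein.  Absent or isolated nodes map to all zeros.
    """
    if protein_id not in graph or graph.degree(protein_id) == 0:
        return np.zeros(4)
    if betweenness is None:
        betweenness = nx.betweenness_centrality(graph, normalized=False)
    return np.array([
        graph.degree(protein_id),
        betweenness[protein_id],
        nx.clustering(graph, protein_id),
        nx.average_neighbor_degree(graph, nodes=[protein_id])[protein_id],
    ])
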