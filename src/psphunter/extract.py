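"""Assemble full feature vectors from whatever inputs are available.

The extractor owns the per-protein side inputs (profiles, conservation
tracks, residue tracks), the protein-level annotation tables, the PPI graph
and the trained 3-gram embedding, and produces 122-dim feature vectors under
a consistent availability-mask policy (missing block -> zero fill, mask
False).

For sequence variants (windowed truncations, substitutions, deletions,
fusion constructs) the sequence-derived blocks are recomputed on the variant
sequence, with per-residue side inputs sliced to the retained wild-type
positions; the annotation and network blocks are frozen at their wild-type
values because curated protein-level annotations do not change under an
in-silico edit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .embedding import EmbeddingModel, embed_sequence
from .features import (FeatureVector, composition_block, conservation_block,
                       funcsite_block, profile_block)
from .functional import annotation_block, network_block
from .io import (AnnotationTables, ConservationTrack, HMMProfile, ProteinRecord,
                 PSSMProfile, ResidueTracks)


@dataclass
class FeatureExtractor:
    embedding: EmbeddingModel | None = None
    annotations: AnnotationTables = field(default_factory=AnnotationTables)
    ppi: nx.Graph | None = None
    pssms: dict[str, PSSMProfile] = field(default_factory=dict)
    hmms: dict[str, HMMProfile] = field(default_factory=dict)
    conservation: dict[str, ConservationTrack] = field(default_factory=dict)
    tracks: dict[str, ResidueTracks] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._betweenness: dict | None = None
        if self.ppi is not None and self.ppi.number_of_nodes() > 0:
            self._betweenness = nx.betweenness_centrality(
                self.ppi, normalized=False)

    # -- fixed (protein-level) blocks -------------------------------------

    def _fixed_blocks(self, record: ProteinRecord):
        blocks: dict[str, np.ndarray] = {}
        avail: dict[str, bool] = {}
        ann, seen = annotation_block(record.id, record.length, self.annotations)
        blocks["annotation"] = ann
        avail["annotation"] = seen
        if self.ppi is not None:
            blocks["network"] = network_block(record.id, self.ppi,
                                              self._betweenness)
            avail["network"] = True
        return blocks, avail

    # -- sequence-derived blocks ------------------------------------------

    def _sequence_blocks(self, record_id: str, seq: str,
                         pssm: np.ndarray | None,
                         hmm: np.ndarray | None,
                         cons: np.ndarray | None,
                         tracks: ResidueTracks | None,
                         full_length: int | None = None):
        blocks: dict[str, np.ndarray] = {"composition": composition_block(seq)}
        avail: dict[str, bool] = {"composition": True}
        if pssm is not None:
            blocks["pssm"] = profile_block(pssm)
            avail["pssm"] = True
        if hmm is not None:
            blocks["hmm"] = profile_block(hmm)
            avail["hmm"] = True
        if cons is not None:
            blocks["conservation"] = conservation_block(cons)
            avail["conservation"] = True
        if tracks is not None:
            pseudo = ProteinRecord(record_id, "A" * tracks.length)
            fs = funcsite_block(pseudo, tracks)
            fs[-1] = float(full_length if full_length is not None else len(seq))
            blocks["funcsite"] = fs
            avail["funcsite"] = True
        if self.embedding is not None:
            blocks["word2vec"] = embed_sequence(seq, self.embedding)
            avail["word2vec"] = True
        return blocks, avail

    # -- public API --------------------------------------------------------

    def vector(self, record: ProteinRecord) -> FeatureVector:
        """Full wild-type feature vector for one protein."""
        pssm = self.pssms.get(record.id)
        hmm = self.hmms.get(record.id)
        cons = self.conservation.get(record.id)
        tracks = self.tracks.get(record.id)
        blocks, avail = self._sequence_blocks(
            record.id, record.sequence,
            pssm.matrix if pssm else None,
            hmm.matrix if hmm else None,
            cons.scores if cons else None,
            tracks,
        )
        fixed, favail = self._fixed_blocks(record)
        blocks.update(fixed)
        avail.update(favail)
        return FeatureVector(record.id, blocks, avail)

    def matrix(self, records: list[ProteinRecord]) -> np.ndarray:
        return np.vstack([self.vector(r).concat() for r in records])

    def variant_vector(self, record: ProteinRecord, variant_seq: str,
                       keep: np.ndarray) -> np.ndarray:
        """Feature vector for an edited form of ``record``.

        ``keep`` holds the 0-based wild-type positions retained in the
        variant; per-residue side inputs are sliced to those positions and
        their blocks recomputed, while annotation and network blocks are
        carried over from the wild type.  The funcsite length slot reports
        the variant's length.
        """
        keep = np.asarray(keep, dtype=np.intp)
        pssm = self.pssms.get(record.id)
        hmm = self.hmms.get(record.id)
        cons = self.conservation.get(record.id)
        tracks = self.tracks.get(record.id)
        blocks, avail = self._sequence_blocks(
            record.id, variant_seq,
            pssm.matrix[keep] if pssm else None,
            hmm.matrix[keep] if hmm else None,
            cons.scores[keep] if cons else None,
            tracks.subset(keep) if tracks else None,
            full_length=len(variant_seq),
        )
        fixed, favail = self._fixed_blocks(record)
        blocks.update(fixed)
        avail.update(favail)
        return FeatureVector(record.id, blocks, avail).concat()
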