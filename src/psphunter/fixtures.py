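"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates, at desk scale, the contrasts reported between
phase-separating and background proteins: positives are enriched in glycine
and proline, carry a planted "key block" built from a small shared
vocabulary of aromatic sticky 3-grams interleaved with G/P spacers (so both
the composition and the word2vec channel see it), and receive elevated PTM
densities, abundance and PPI connectivity.  Negatives are drawn from a
background residue distribution with sparse annotations.  Everything is
reproducible from a single seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .io import (PREDICTED_PTM_TYPES, PTM_TYPES, AnnotationTables,
                 ProteinRecord, ResidueTracks, Variant, write_fasta,
                 write_tracks_tsv)

# approximate Swiss-Prot background residue frequencies
_BG = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38, "Q": 3.93,
    "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96, "L": 9.66, "K": 5.84,
    "M": 2.42, "F": 3.86, "P": 4.70, "S": 6.56, "T": 5.34, "W": 1.08,
    "Y": 2.92, "V": 6.87,
}
_BG_LETTERS = np.array(list(_BG))
_BG_P = np.array(list(_BG.values())) / sum(_BG.values())


@dataclass
class FixtureConfig:
    """Study conditions of the synthetic cohort."""

    n_pos: int = 60
    n_neg: int = 60
    length_range: tuple[int, int] = (150, 800)
    gp_enrichment: float = 1.5  # G/P weight multiplier in positives
    sticky_vocab_size: int = 8  # shared aromatic 3-gram vocabulary
    key_block_len: int = 40
    key_block_margin: int = 30  # distance of the block from either terminus
    ptm_rate: float = 0.02      # annotated PTM sites per residue (background)
    ptm_factor: float = 2.0     # positive multiplier
    abundance_factor: float = 2.0
    ppi_p_in_pos: float = 0.08  # edge probability within the positive block
    ppi_p_bg: float = 0.02
    ppi_p_cross: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pos, self.n_neg, self.key_block_len) <= 0:
            raise ValueError("counts and block length must be positive")
        if self.gp_enrichment < 1 or self.ptm_factor < 1:
            raise ValueError("enrichment factors must be >= 1")
        if (self.key_block_len + 2 * self.key_block_margin
                > self.length_range[0]):
            raise ValueError(
                "key block plus margins exceeds the minimum length")


@dataclass
class FixtureBundle:
    config: FixtureConfig
    records: list[ProteinRecord]  # positives first, then negatives
    labels: dict[str, int]
    key_blocks: dict[str, tuple[int, int]]  # 1-based inclusive
    tables: AnnotationTables
    graph: nx.Graph
    tracks: dict[str, ResidueTracks]
    sticky_vocab: list[str] = field(default_factory=list)

    @property
    def positives(self) -> list[ProteinRecord]:
        return [r for r in self.records if self.labels[r.id] == 1]

    @property
    def negatives(self) -> list[ProteinRecord]:
        return [r for r in self.records if self.labels[r.id] == 0]


def _sticky_vocab(rng: np.random.Generator, size: int) -> list[str]:
    """Aromatic-core sticky 3-grams (aromatic, G/S, aromatic) — rare under
    the background distribution, concentrated in planted blocks."""
    vocab: list[str] = []
    while len(vocab) < size:
        gram = (rng.choice(list("FYW")) + rng.choice(list("GS"))
                + rng.choice(list("FYW")))
        if gram not in vocab:
            vocab.append(gram)
    return vocab


def _key_block(rng: np.random.Generator, vocab: list[str],
               length: int) -> str:
    """Sticky 3-grams from the shared vocabulary alternating with G/P
    spacer pairs (5-residue chunks), trimmed to the requested length."""
    parts = []
    while sum(len(p) for p in parts) < length:
        parts.append(str(rng.choice(vocab)))
        parts.append("".join(rng.choice(list("GP"), size=2)))
    return "".join(parts)[:length]


def _draw_sequence(rng: np.random.Generator, length: int,
                   positive: bool, cfg: FixtureConfig) -> np.ndarray:
    p = _BG_P.copy()
    if positive:
        for aa in "GP":
            p[np.flatnonzero(_BG_LETTERS == aa)[0]] *= cfg.gp_enrichment
        p /= p.sum()
    return rng.choice(_BG_LETTERS, size=length, p=p)


def _make_tracks(rng: np.random.Generator, pid: str, length: int,
                 positive: bool, block: tuple[int, int] | None
                 ) -> ResidueTracks:
    ss_p = (0.25, 0.20, 0.55) if positive else (0.30, 0.25, 0.45)
    ss = rng.choice(3, size=length, p=ss_p)
    disordered = rng.random(length) < (0.30 if positive else 0.25)
    if block is not None:
        disordered[block[0] - 1:block[1]] = True
    ptm_p = np.array([0.06, 0.02, 0.02, 0.02]) * (1.0 if positive else 0.7)
    deleterious = rng.binomial(19, 0.25, size=length)
    return ResidueTracks(
        pid,
        helix=ss == 0, sheet=ss == 1, coil=ss == 2,
        accessible=rng.random(length) < 0.5,
        disordered=disordered,
        rna_binding=rng.random(length) < (0.06 if positive else 0.04),
        dna_binding=rng.random(length) < 0.03,
        ptm=rng.random((length, 4)) < ptm_p,
        deleterious=deleterious,
        neutral=19 - deleterious,
    )


def make_fixture_bundle(config: FixtureConfig | None = None,
                        seed: int | None = None) -> FixtureBundle:
    """Generate a full synthetic bundle: sequences with planted key blocks,
    residue tracks, annotation tables and a two-community PPI graph."""
    cfg = config or FixtureConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    vocab = _sticky_vocab(rng, cfg.sticky_vocab_size)

    records: list[ProteinRecord] = []
    labels: dict[str, int] = {}
    key_blocks: dict[str, tuple[int, int]] = {}
    lo, hi = cfg.length_range
    for i in range(cfg.n_pos + cfg.n_neg):
        positive = i < cfg.n_pos
        pid = f"pos{i:03d}" if positive else f"neg{i - cfg.n_pos:03d}"
        length = int(rng.integers(lo, hi + 1))
        seq = _draw_sequence(rng, length, positive, cfg)
        if positive:
            start0 = int(rng.integers(
                cfg.key_block_margin,
                length - cfg.key_block_margin - cfg.key_block_len + 1))
            block = _key_block(rng, vocab, cfg.key_block_len)
            seq[start0:start0 + cfg.key_block_len] = list(block)
            key_blocks[pid] = (start0 + 1, start0 + cfg.key_block_len)
        records.append(ProteinRecord(pid, "".join(seq)))
        labels[pid] = int(positive)

    tables = AnnotationTables()
    tables.available = {k: True for k in ("ptm", "variants", "abundance",
                                          "age", "essential", "housekeeping")}
    base_rates = {"phosphorylation": 1.5, "acetylation": 0.5,
                  "ubiquitination": 0.5, "methylation": 0.5}
    tracks: dict[str, ResidueTracks] = {}
    for rec in records:
        positive = labels[rec.id] == 1
        factor = cfg.ptm_factor if positive else 1.0
        tables.ptm_counts[rec.id] = {
            t: int(rng.poisson(rec.length * cfg.ptm_rate * w * factor))
            for t, w in base_rates.items()
        }
        n_var = int(rng.poisson(4))
        variants = []
        for _ in range(n_var):
            pos = int(rng.integers(1, rec.length + 1))
            variants.append(Variant(
                pos, rec.sequence[pos - 1], str(rng.choice(_BG_LETTERS)),
                "pathogenic" if rng.random() < 0.5 else "neutral"))
        tables.variants[rec.id] = variants
        ppm = float(rng.lognormal(3.0, 1.0))
        tables.abundance[rec.id] = ppm * (cfg.abundance_factor if positive
                                          else 1.0)
        tables.age[rec.id] = float(rng.uniform(50, 1500))
        if rng.random() < (0.30 if positive else 0.10):
            tables.essential.add(rec.id)
        if rng.random() < (0.50 if positive else 0.25):
            tables.housekeeping.add(rec.id)
        tracks[rec.id] = _make_tracks(rng, rec.id, rec.length, positive,
                                      key_blocks.get(rec.id))

    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(r.id for r in records)
    ids = [r.id for r in records]
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            both_pos = labels[ids[i]] + labels[ids[j]]
            p = (cfg.ppi_p_in_pos if both_pos == 2
                 else cfg.ppi_p_cross if both_pos == 1 else cfg.ppi_p_bg)
            if rng.random() < p:
                graph.add_edge(ids[i], ids[j])

    return FixtureBundle(cfg, records, labels, key_blocks, tables, graph,
                         tracks, sticky_vocab=vocab)


def write_bundle(bundle: FixtureBundle, outdir: str | Path) -> None:
    """Write the bundle as plain-text files (FASTA + TSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.positives, outdir / "positives.fasta")
    write_fasta(bundle.negatives, outdir / "negatives.fasta")
    with open(outdir / "labels.tsv", "w") as fh:
        for pid, lab in bundle.labels.items():
            fh.write(f"{pid}\t{lab}\n")
    with open(outdir / "key_blocks.tsv", "w") as fh:
        for pid, (s, e) in bundle.key_blocks.items():
            fh.write(f"{pid}\t{s}\t{e}\n")
    t = bundle.tables
    with open(outdir / "ptm.tsv", "w") as fh:
        for pid, counts in t.ptm_counts.items():
            for typ in PTM_TYPES:
                fh.write(f"{pid}\t{typ}\t{counts.get(typ, 0)}\n")
    with open(outdir / "variants.tsv", "w") as fh:
        for pid, variants in t.variants.items():
            for v in variants:
                fh.write(f"{pid}\t{v.position}\t{v.ref}\t{v.alt}\t{v.clazz}\n")
    with open(outdir / "abundance.tsv", "w") as fh:
        for pid, ppm in t.abundance.items():
            fh.write(f"{pid}\t{ppm:.6f}\n")
    with open(outdir / "age.tsv", "w") as fh:
        for pid, age in t.age.items():
            fh.write(f"{pid}\t{age:.3f}\n")
    (outdir / "essential.txt").write_text(
        "".join(f"{p}\n" for p in sorted(t.essential)))
    (outdir / "housekeeping.txt").write_text(
        "".join(f"{p}\n" for p in sorted(t.housekeeping)))
    with open(outdir / "ppi.tsv", "w") as fh:
        for a, b in sorted(bundle.graph.edges()):
            fh.write(f"{a}\t{b}\n")
    tracks_dir = outdir / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    for pid, tr in bundle.tracks.items():
        write_tracks_tsv(tr, tracks_dir / f"{pid}.tsv")
    (outdir / "config.json").write_text(
        json.dumps(dataclasses.asdict(bundle.config), indent=2) + "\n")
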