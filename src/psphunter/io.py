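"""Readers and writers for the formats the pipeline touches.

Sequences come in as FASTA; evolutionary profiles as PSI-BLAST ASCII PSSMs
and HH-suite ``.hhm`` files; per-residue annotation tracks and protein-level
annotation tables as TSV; protein-protein interaction networks as two-column
TSV edge lists.  Everything user-facing is 1-based inclusive; internally,
per-residue arrays are 0-based numpy arrays of length L.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("psphunter")

#: Canonical internal amino-acid column order for all L x 20 matrices.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

#: Ambiguity codes resolved under the default "map" policy.  X is kept in the
#: sequence (it counts toward length) but is excluded from category counts and
#: from 3-gram vocabularies downstream.
AMBIGUOUS_MAP = {"B": "D", "Z": "E", "J": "L", "U": "C", "O": "K"}

PTM_TYPES = ("phosphorylation", "acetylation", "ubiquitination", "methylation")
#: Predicted (sequence-based) PTM site types carried as per-residue tracks.
PREDICTED_PTM_TYPES = (
    "phosphorylation",
    "methylation",
    "s_nitrosylation",
    "palmitoylation",
)
VARIANT_CLASSES = ("pathogenic", "neutral")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier plus a validated amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        allowed = set(AA_ORDER) | {"X"}
        bad = set(self.sequence) - allowed
        if bad:
            raise ValueError(
                f"{self.id}: invalid residues {sorted(bad)}; normalize first"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


def normalize_sequence(seq: str, policy: str = "map") -> str | None:
    """Uppercase a raw sequence and resolve nonstandard letters.

    Policies: ``map`` substitutes B->D, Z->E, J->L, U->C, O->K and keeps X;
    ``drop`` returns None for any sequence containing a nonstandard letter
    (including X); ``strict`` raises instead.
    """
    seq = seq.upper().replace("*", "").replace("-", "")
    nonstandard = set(seq) - set(AA_ORDER)
    if not nonstandard:
        return seq
    if policy == "strict":
        raise ValueError(f"nonstandard residues {sorted(nonstandard)}")
    if policy == "drop":
        return None
    unknown = nonstandard - set(AMBIGUOUS_MAP) - {"X"}
    if unknown:
        raise ValueError(f"unrecognized residue letters {sorted(unknown)}")
    return seq.translate(str.maketrans(AMBIGUOUS_MAP))


def read_fasta(path: str | Path, policy: str = "map") -> list[ProteinRecord]:
    """Read a FASTA file into ProteinRecords, order preserved.

    The first whitespace-delimited header token is the id.  Sequences are
    uppercased and ambiguity codes handled per ``policy`` (see
    :func:`normalize_sequence`); under ``drop`` the offending record is
    skipped with a logged reason.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = normalize_sequence(str(entry.seq), policy=policy)
        if seq is None:
            logger.warning("dropping %s: nonstandard residues under drop policy",
                           entry.id)
            continue
        records.append(ProteinRecord(entry.id, seq))
    if not records:
        logger.warning("no records read from %s", path)
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


@dataclass
class PSSMProfile:
    """PSI-BLAST position-specific scoring matrix (log-odds payload)."""

    protein_id: str
    matrix: np.ndarray  # L x 20 in AA_ORDER
    column_order: str = AA_ORDER

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise ValueError(f"PSSM must be L x 20, got {self.matrix.shape}")


@dataclass
class HMMProfile:
    """HH-suite profile HMM match-state emission probabilities."""

    protein_id: str
    matrix: np.ndarray  # L x 20 in AA_ORDER

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise ValueError(f"HMM profile must be L x 20, got {self.matrix.shape}")


@dataclass
class ConservationTrack:
    """Per-residue relative-entropy conservation scores."""

    protein_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float).ravel()


def parse_pssm_ascii(path: str | Path, protein_id: str | None = None) -> PSSMProfile:
    """Parse the standard PSI-BLAST ASCII PSSM dialect.

    The payload is the first 20 columns (position-specific log-odds); the
    trailing 20 weighted-frequency columns and summary statistics are ignored.
    Columns are re-mapped from the header's amino-acid order to
    :data:`AA_ORDER`.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header_cols: list[str] | None = None
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines, start=1):
        parts = line.split()
        if header_cols is None:
            # the column-header line is 40 single amino-acid letters
            if len(parts) >= 40 and all(len(p) == 1 and p.isalpha() for p in parts[:40]):
                header_cols = parts[:20]
                if sorted(header_cols) != sorted(AA_ORDER):
                    raise ParseError(f"{path}: unexpected PSSM header alphabet")
            continue
        if not parts or not parts[0].isdigit():
            continue  # footer (lambda/K statistics) or blank
        if len(parts) < 22:
            raise ParseError(f"{path}: truncated PSSM row at line {lineno}")
        try:
            rows.append([float(v) for v in parts[2:22]])
        except ValueError as exc:
            raise ParseError(f"{path}: bad value in row at line {lineno}: {exc}")
    if header_cols is None:
        raise ParseError(f"{path}: no PSSM column header found")
    if not rows:
        raise ParseError(f"{path}: no PSSM rows found")
    matrix = np.asarray(rows, dtype=float)
    perm = [header_cols.index(aa) for aa in AA_ORDER]
    return PSSMProfile(protein_id or path.stem, matrix[:, perm])


def parse_hhm(path: str | Path, protein_id: str | None = None) -> HMMProfile:
    """Parse match-state emissions from an HH-suite ``.hhm`` file.

    Stored integers x encode probabilities as 2^(-x/1000); the ``*`` token is
    probability 0.  Only the 20 match-emission columns are read.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        start = next(i for i, l in enumerate(lines) if l.split() and l.split()[0] == "HMM")
    except StopIteration:
        raise ParseError(f"{path}: missing HMM section")
    header = lines[start].split()[1:21]
    if sorted(header) != sorted(AA_ORDER):
        raise ParseError(f"{path}: unexpected .hhm emission alphabet")
    perm = [header.index(aa) for aa in AA_ORDER]

    def decode(tok: str) -> float:
        return 0.0 if tok == "*" else 2.0 ** (-float(tok) / 1000.0)

    rows: list[list[float]] = []
    i = start + 1
    # skip the transition header line and the NULL frequency line
    while i < len(lines):
        parts = lines[i].split()
        i += 1
        if not parts or parts[0] in ("M->M", "NULL"):
            continue
        if parts[0] == "//":
            break
        # match-state line: residue letter, state index, 20 emissions
        if len(parts) >= 22 and len(parts[0]) == 1 and parts[1].isdigit():
            try:
                vals = [decode(t) for t in parts[2:22]]
            except ValueError as exc:
                raise ParseError(f"{path}: bad emission value: {exc}")
            rows.append([vals[j] for j in perm])
    if not rows:
        raise ParseError(f"{path}: no match states found")
    return HMMProfile(protein_id or path.stem, np.asarray(rows))


@dataclass
class ResidueTracks:
    """Per-residue boolean/count annotation tracks, all of length L.

    helix/sheet/coil are mutually exclusive secondary-structure states;
    ``ptm`` holds predicted-site flags for the four
    :data:`PREDICTED_PTM_TYPES`; ``deleterious``/``neutral`` are per-residue
    counts of predicted-substitution labels from a saturation-mutagenesis
    track.
    """

    protein_id: str
    helix: np.ndarray
    sheet: np.ndarray
    coil: np.ndarray
    accessible: np.ndarray
    disordered: np.ndarray
    rna_binding: np.ndarray
    dna_binding: np.ndarray
    ptm: np.ndarray  # L x 4 boolean
    deleterious: np.ndarray  # integer counts
    neutral: np.ndarray

    def __post_init__(self) -> None:
        for name in ("helix", "sheet", "coil", "accessible", "disordered",
                     "rna_binding", "dna_binding"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        self.ptm = np.asarray(self.ptm, dtype=bool)
        self.deleterious = np.asarray(self.deleterious, dtype=int)
        self.neutral = np.asarray(self.neutral, dtype=int)
        L = len(self.helix)
        arrays = [self.sheet, self.coil, self.accessible, self.disordered,
                  self.rna_binding, self.dna_binding, self.deleterious,
                  self.neutral]
        if any(len(a) != L for a in arrays) or self.ptm.shape != (L, 4):
            raise ValueError(f"{self.protein_id}: track lengths inconsistent")
        if np.any(self.helix.astype(int) + self.sheet + self.coil != 1):
            raise ValueError(f"{self.protein_id}: helix/sheet/coil not exclusive")

    @property
    def length(self) -> int:
        return len(self.helix)

    def subset(self, keep: np.ndarray) -> "ResidueTracks":
        """Restrict all tracks to the kept (0-based) positions."""
        return ResidueTracks(
            self.protein_id,
            self.helix[keep], self.sheet[keep], self.coil[keep],
            self.accessible[keep], self.disordered[keep],
            self.rna_binding[keep], self.dna_binding[keep],
            self.ptm[keep], self.deleterious[keep], self.neutral[keep],
        )


_TRACK_COLUMNS = [
    "position", "helix", "sheet", "coil", "accessible", "disordered",
    "rna_binding", "dna_binding",
    "ptm_phosphorylation", "ptm_methylation", "ptm_s_nitrosylation",
    "ptm_palmitoylation", "deleterious", "neutral",
]


def read_tracks_tsv(path: str | Path, protein_id: str | None = None) -> ResidueTracks:
    df = pd.read_csv(path, sep="\t")
    missing = set(_TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing track columns {sorted(missing)}")
    df = df.sort_values("position")
    if not np.array_equal(df["position"].to_numpy(), np.arange(1, len(df) + 1)):
        raise ParseError(f"{path}: positions must be 1..L without gaps")
    ptm = df[[f"ptm_{t}" for t in PREDICTED_PTM_TYPES]].to_numpy(dtype=bool)
    return ResidueTracks(
        protein_id or Path(path).stem,
        *(df[c].to_numpy() for c in _TRACK_COLUMNS[1:8]),
        ptm,
        df["deleterious"].to_numpy(dtype=int),
        df["neutral"].to_numpy(dtype=int),
    )


def write_tracks_tsv(tracks: ResidueTracks, path: str | Path) -> None:
    df = pd.DataFrame({
        "position": np.arange(1, tracks.length + 1),
        "helix": tracks.helix.astype(int),
        "sheet": tracks.sheet.astype(int),
        "coil": tracks.coil.astype(int),
        "accessible": tracks.accessible.astype(int),
        "disordered": tracks.disordered.astype(int),
        "rna_binding": tracks.rna_binding.astype(int),
        "dna_binding": tracks.dna_binding.astype(int),
    })
    for j, t in enumerate(PREDICTED_PTM_TYPES):
        df[f"ptm_{t}"] = tracks.ptm[:, j].astype(int)
    df["deleterious"] = tracks.deleterious
    df["neutral"] = tracks.neutral
    df.to_csv(path, sep="\t", index=False)


@dataclass
class Variant:
    position: int
    ref: str
    alt: str
    clazz: str

    def __post_init__(self) -> None:
        if self.clazz not in VARIANT_CLASSES:
            raise ParseError(
                f"unknown variant class {self.clazz!r}; allowed: {VARIANT_CLASSES}"
            )


@dataclass
class AnnotationTables:
    """Protein-level annotation tables; absent tables stay empty and are
    flagged unavailable so downstream feature blocks can be masked."""

    ptm_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    variants: dict[str, list[Variant]] = field(default_factory=dict)
    abundance: dict[str, float] = field(default_factory=dict)
    age: dict[str, float] = field(default_factory=dict)
    essential: set[str] = field(default_factory=set)
    housekeeping: set[str] = field(default_factory=set)
    available: dict[str, bool] = field(default_factory=dict)

    def is_available(self, table: str) -> bool:
        return self.available.get(table, False)


def load_annotations(paths: dict[str, str | Path]) -> AnnotationTables:
    """Load the protein-level annotation tables from TSV files.

    ``paths`` maps table names (``ptm``, ``variants``, ``abundance``, ``age``,
    ``essential``, ``housekeeping``) to files; missing entries or nonexistent
    files yield empty tables flagged unavailable.
    """
    tables = AnnotationTables()
    tables.available = {k: False for k in
                        ("ptm", "variants", "abundance", "age", "essential",
                         "housekeeping")}

    def present(key: str) -> Path | None:
        p = paths.get(key)
        if p is None or not Path(p).exists():
            logger.info("annotation table %r absent; block slot masked", key)
            return None
        return Path(p)

    if (p := present("ptm")) is not None:
        df = pd.read_csv(p, sep="\t", header=None,
                         names=["protein", "ptm_type", "count"])
        for row in df.itertuples(index=False):
            if row.ptm_type not in PTM_TYPES:
                raise ParseError(
                    f"unknown PTM type {row.ptm_type!r}; allowed: {PTM_TYPES}")
            if row.count < 0:
                raise ParseError(f"negative PTM count for {row.protein}")
            tables.ptm_counts.setdefault(row.protein, {})[row.ptm_type] = int(row.count)
        tables.available["ptm"] = True
    if (p := present("variants")) is not None:
        df = pd.read_csv(p, sep="\t", header=None,
                         names=["protein", "position", "ref", "alt", "clazz"])
        for row in df.itertuples(index=False):
            tables.variants.setdefault(row.protein, []).append(
                Variant(int(row.position), row.ref, row.alt, row.clazz))
        tables.available["variants"] = True
    if (p := present("abundance")) is not None:
        df = pd.read_csv(p, sep="\t", header=None, names=["protein", "ppm"])
        tables.abundance = dict(zip(df["protein"], df["ppm"].astype(float)))
        if any(v < 0 for v in tables.abundance.values()):
            raise ParseError("negative abundance value")
        tables.available["abundance"] = True
    if (p := present("age")) is not None:
        df = pd.read_csv(p, sep="\t", header=None, names=["protein", "age"])
        tables.age = dict(zip(df["protein"], df["age"].astype(float)))
        tables.available["age"] = True
    if (p := present("essential")) is not None:
        tables.essential = set(p.read_text().split())
        tables.available["essential"] = True
    if (p := present("housekeeping")) is not None:
        tables.housekeeping = set(p.read_text().split())
        tables.available["housekeeping"] = True
    return tables


def load_ppi(path: str | Path) -> nx.Graph:
    """Load a two-column TSV edge list as a simple undirected graph.

    Self-loops and duplicate edges are dropped (count logged); an empty file
    yields an empty graph.
    """
    graph: nx.Graph = nx.Graph()
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 2:
                raise ParseError(f"{path}: line {lineno} is not a two-column edge")
            a, b = parts
            if a == b or graph.has_edge(a, b):
                dropped += 1
                continue
            graph.add_edge(a, b)
    if dropped:
        logger.info("load_ppi: dropped %d self-loop/duplicate edges", dropped)
    return graph
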