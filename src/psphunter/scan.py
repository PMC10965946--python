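"""Sliding-window truncation scan, key-residue/region calling and
mutation-impact scoring.

The scan deletes a window of ``unit`` consecutive residues (default 20,
roughly 1/30 of a typical phase-separating protein) for every admissible
window position, rescores each truncated form with a trained model, and
assigns the score change to the residue at the window's center.  With the
default even unit the window for center i (1-based) is [i-10, i+9], so
exactly 10 positions at each terminus never serve as a center and stay
undefined.  A residue's contribution is

    delta_i = mean over all variants of score  -  score of variant i,

i.e. how far deleting that residue's window pulls the prediction below the
average truncated score; large positive delta marks key residues.  The
full-protein score is recorded alongside and can be used as the reference
instead.

Candidate key residues are the top-N positions by delta, where N is a
length-banded percentage of L (5% for L <= 500, 4% for 500 < L <= 1000, 2%
for 1000 < L <= 2000, 1% for L > 2000); maximal runs of consecutive
candidates form key regions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .classifier import TrainedModel, predict_scores
from .extract import FeatureExtractor
from .io import ProteinRecord

logger = logging.getLogger("psphunter")

DEFAULT_UNIT = 20


def window_for_center(center: int, unit: int = DEFAULT_UNIT) -> tuple[int, int]:
    """1-based inclusive deleted window for a center position; an even unit
    sits asymmetrically as [i - unit//2, i + unit - unit//2 - 1]."""
    half = unit // 2
    return center - half, center + (unit - half) - 1


def scan_centers(length: int, unit: int = DEFAULT_UNIT) -> np.ndarray:
    """Admissible 1-based center positions: floor(unit/2)+1 .. L-ceil(unit/2),
    leaving symmetric undefined margins at the termini."""
    half = unit // 2
    lo, hi = half + 1, length - (unit - half)
    if hi < lo:
        raise ValueError(f"sequence length {length} too short for unit {unit}")
    return np.arange(lo, hi + 1)


def truncation_variants(seq: str, unit: int = DEFAULT_UNIT
                        ) -> list[tuple[int, str]]:
    """All (center, variant) pairs; each variant deletes the unit-length
    window around its center and is exactly ``unit`` residues shorter."""
    out = []
    for center in scan_centers(len(seq), unit):
        start, end = window_for_center(int(center), unit)
        out.append((int(center), seq[:start - 1] + seq[end:]))
    return out


def _keep_indices(length: int, start: int, end: int) -> np.ndarray:
    """0-based retained positions after deleting 1-based [start, end]."""
    return np.concatenate([np.arange(0, start - 1), np.arange(end, length)])


@dataclass
class ResidueScoreTrack:
    """Per-residue truncation-scan deltas with undefined termini."""

    protein_id: str
    length: int
    centers: np.ndarray  # 1-based defined positions
    variant_scores: np.ndarray
    full_score: float
    unit: int = DEFAULT_UNIT
    reference: str = "mean"  # or "full"

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=int)
        self.variant_scores = np.asarray(self.variant_scores, dtype=float)
        if len(self.centers) != len(self.variant_scores):
            raise ValueError("centers and scores length mismatch")

    @property
    def mean_variant_score(self) -> float:
        return float(self.variant_scores.mean())

    @property
    def deltas(self) -> np.ndarray:
        """delta_i = reference - variant score; higher = more important."""
        ref = (self.mean_variant_score if self.reference == "mean"
               else self.full_score)
        return ref - self.variant_scores

    def delta_at(self, position: int) -> float:
        idx = np.flatnonzero(self.centers == position)
        if idx.size == 0:
            raise KeyError(f"position {position} is undefined in the scan")
        return float(self.deltas[idx[0]])

    def is_defined(self, position: int) -> bool:
        return bool(np.any(self.centers == position))


def scan_track(model: TrainedModel, extractor: FeatureExtractor,
               record: ProteinRecord, unit: int = DEFAULT_UNIT,
               reference: str = "mean") -> ResidueScoreTrack:
    """Score every unit-deleted form of a protein and build its delta track.

    Sequence-derived feature blocks are recomputed per variant (with
    per-residue side inputs sliced to the retained positions); annotation
    and network blocks are held at their wild-type values.
    """
    L = record.length
    centers = scan_centers(L, unit)
    rows = []
    for center in centers:
        start, end = window_for_center(int(center), unit)
        keep = _keep_indices(L, start, end)
        variant_seq = record.sequence[:start - 1] + record.sequence[end:]
        try:
            rows.append(extractor.variant_vector(record, variant_seq, keep))
        except Exception as exc:
            raise RuntimeError(
                f"{record.id}: scoring failed at center {center}") from exc
    variant_scores = predict_scores(model, np.vstack(rows))
    full_score = float(predict_scores(
        model, extractor.vector(record).concat())[0])
    return ResidueScoreTrack(record.id, L, centers, variant_scores,
                             full_score, unit=unit, reference=reference)


# --------------------------------------------------------------------------
# candidate selection and key regions


def candidate_fraction(length: int) -> float:
    """Length-banded fraction of residues retained as key-residue
    candidates."""
    if length > 2000:
        return 0.01
    if length > 1000:
        return 0.02
    if length > 500:
        return 0.04
    return 0.05


def select_candidates(track: ResidueScoreTrack,
                      n_candidates: int | None = None) -> list[int]:
    """Top-N defined positions by delta (ties -> smaller position).

    N defaults to the length-banded percentage of L rounded to the nearest
    integer; pass ``n_candidates`` for the absolute-count mode (e.g. the
    20-40 residue heuristic).  N rounding to 0 keeps one candidate.
    """
    if n_candidates is None:
        n_candidates = int(np.floor(candidate_fraction(track.length)
                                    * track.length + 0.5))
    if n_candidates == 0:
        logger.warning("%s: candidate count rounded to 0; keeping 1",
                       track.protein_id)
        n_candidates = 1
    n_candidates = min(n_candidates, len(track.centers))
    order = sorted(range(len(track.centers)),
                   key=lambda i: (-track.deltas[i], track.centers[i]))
    return sorted(int(track.centers[i]) for i in order[:n_candidates])


@dataclass
class KeyRegion:
    """A maximal run of consecutive candidate key residues."""

    start: int  # 1-based inclusive
    end: int
    mean_delta: float
    rank: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must be <= end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def merge_regions(candidates: list[int], track: ResidueScoreTrack,
                  gap: int = 0) -> list[KeyRegion]:
    """Attach consecutive candidate positions into key regions.

    Candidates whose gap is <= ``gap`` join the same region.  Regions are
    returned sorted by position, with ``rank`` 1 assigned to the region of
    highest mean delta.
    """
    if not candidates:
        raise ValueError("candidate set is empty")
    positions = sorted(set(candidates))
    runs: list[list[int]] = [[positions[0]]]
    for p in positions[1:]:
        if p - runs[-1][-1] <= gap + 1:
            runs[-1].append(p)
        else:
            runs.append([p])
    regions = [
        KeyRegion(r[0], r[-1],
                  float(np.mean([track.delta_at(p) for p in r
                                 if track.is_defined(p)])))
        for r in runs
    ]
    for rank, region in enumerate(
            sorted(regions, key=lambda g: -g.mean_delta), start=1):
        region.rank = rank
    return regions


# --------------------------------------------------------------------------
# mutation impact


@dataclass
class MutationSpec:
    """A substitution (G100V), interval deletion (A322-E327del) or IDR
    fusion (append a tag sequence to the C terminus)."""

    kind: str  # substitution | deletion | idr_fusion
    start: int = 0  # 1-based
    end: int = 0
    ref: str = ""
    alt: str = ""
    tag: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "deletion", "idr_fusion"):
            raise ValueError(f"unknown mutation kind {self.kind!r}")


_SUB_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_DEL_RE = re.compile(r"^([A-Z])(\d+)-([A-Z])(\d+)del$")


def parse_mutation(text: str) -> MutationSpec:
    """Parse ``G100V``, ``A322-E327del`` or ``fuse:<sequence>`` notation."""
    if text.startswith("fuse:"):
        return MutationSpec("idr_fusion", tag=text[5:].upper())
    if (m := _DEL_RE.match(text)):
        return MutationSpec("deletion", start=int(m.group(2)),
                            end=int(m.group(4)), ref=m.group(1),
                            alt=m.group(3))
    if (m := _SUB_RE.match(text)):
        return MutationSpec("substitution", start=int(m.group(2)),
                            end=int(m.group(2)), ref=m.group(1),
                            alt=m.group(3))
    raise ValueError(f"cannot parse mutation {text!r}")


def _check_ref(seq: str, position: int, ref: str) -> None:
    observed = seq[position - 1]
    if ref and observed != ref:
        raise ValueError(
            f"reference mismatch at position {position}: expected {ref}, "
            f"sequence has {observed}")


def apply_mutation(seq: str, mut: MutationSpec) -> tuple[str, np.ndarray]:
    """Apply a mutation, returning the mutant sequence and the 0-based
    wild-type positions it retains (for slicing per-residue inputs)."""
    L = len(seq)
    if mut.kind == "substitution":
        if not 1 <= mut.start <= L:
            raise ValueError(f"position {mut.start} outside 1..{L}")
        _check_ref(seq, mut.start, mut.ref)
        mutant = seq[:mut.start - 1] + mut.alt + seq[mut.start:]
        return mutant, np.arange(L)
    if mut.kind == "deletion":
        if not 1 <= mut.start <= mut.end <= L:
            raise ValueError(f"deletion [{mut.start},{mut.end}] outside 1..{L}")
        _check_ref(seq, mut.start, mut.ref)
        _check_ref(seq, mut.end, mut.alt)
        mutant = seq[:mut.start - 1] + seq[mut.end:]
        return mutant, _keep_indices(L, mut.start, mut.end)
    # idr_fusion: append the tag; all wild-type positions retained
    return seq + mut.tag, np.arange(L)


def mutation_impact(model: TrainedModel, extractor: FeatureExtractor,
                    record: ProteinRecord, mut: MutationSpec) -> float:
    """score(wild type) - score(mutant); positive impact means the mutation
    is predicted to weaken phase separation."""
    mutant_seq, keep = apply_mutation(record.sequence, mut)
    wt = float(predict_scores(model, extractor.vector(record).concat())[0])
    mt = float(predict_scores(
        model, extractor.variant_vector(record, mutant_seq, keep))[0])
    return wt - mt
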