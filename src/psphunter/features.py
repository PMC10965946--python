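"""Sequence-derived feature blocks of the phase-separation feature vector.

Each protein is summarized by eight fixed-length blocks (122 dimensions in
total): amino-acid composition (20), compressed PSSM (4), conservation-score
distribution (5), compressed HMM profile (4), predicted functional sites
(14), word2vec sequence embedding (60), protein annotations (11) and PPI
network properties (4).  Blocks whose inputs are unavailable are filled with
zeros and flagged in a per-block availability mask; models must be trained
and applied under the same mask policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AA_ORDER, ProteinRecord, ResidueTracks

# Amino-acid categories: polar, charged, hydrophobic, and glycine/proline,
# which get their own class for their outsized role in condensate material
# properties (flexible spacers).
CATEGORY_ORDER = ("polar", "charged", "hydrophobic", "gp")
CATEGORIES = {
    "polar": "NQST",
    "charged": "RKDE",
    "hydrophobic": "LAVIFYMHWC",
    "gp": "GP",
}
AA_CATEGORY_INDEX = {
    aa: ci for ci, cat in enumerate(CATEGORY_ORDER) for aa in CATEGORIES[cat]
}

#: Block layout of the concatenated feature vector, order fixed (v1).
BLOCK_SPEC = {
    "composition": 20,
    "pssm": 4,
    "conservation": 5,
    "hmm": 4,
    "funcsite": 14,
    "word2vec": 60,
    "annotation": 11,
    "network": 4,
}
N_FEATURES = sum(BLOCK_SPEC.values())


def feature_names() -> list[str]:
    """Column names of the concatenated vector, ``block.index`` (0-based)."""
    return [f"{b}.{i}" for b, n in BLOCK_SPEC.items() for i in range(n)]


@dataclass
class FeatureVector:
    """Named feature blocks for one protein plus availability mask."""

    protein_id: str
    blocks: dict[str, np.ndarray] = field(default_factory=dict)
    available: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, n in BLOCK_SPEC.items():
            if name not in self.blocks:
                self.blocks[name] = np.zeros(n)
                self.available.setdefault(name, False)
            else:
                self.blocks[name] = np.asarray(self.blocks[name], dtype=float)
                if self.blocks[name].shape != (n,):
                    raise ValueError(
                        f"block {name!r} must have length {n}, "
                        f"got {self.blocks[name].shape}")
                self.available.setdefault(name, True)

    def concat(self) -> np.ndarray:
        return np.concatenate([self.blocks[b] for b in BLOCK_SPEC])


def composition_block(seq: str) -> np.ndarray:
    """20-dim residue-composition block.

    Entries 0-3 are the fractions of polar/charged/hydrophobic/GP residues;
    entries 4-19 are the fractions of the 16 ordered category doublets over
    consecutive residue pairs.  Residues outside the 20-letter alphabet (X)
    are skipped in both counts but still occupy sequence positions, so a pair
    containing X contributes to neither doublet.
    """
    if len(seq) < 2:
        raise ValueError("composition_block needs length >= 2 (no pairs)")
    cats = [AA_CATEGORY_INDEX.get(aa) for aa in seq]
    singles = np.zeros(4)
    for c in cats:
        if c is not None:
            singles[c] += 1
    if singles.sum() > 0:
        singles /= singles.sum()
    pairs = np.zeros((4, 4))
    for a, b in zip(cats, cats[1:]):
        if a is not None and b is not None:
            pairs[a, b] += 1
    if pairs.sum() > 0:
        pairs /= pairs.sum()
    return np.concatenate([singles, pairs.ravel()])


def zscore_rows(matrix: np.ndarray) -> np.ndarray:
    """Z-score each row across its 20 entries (population SD, ddof=0).

    Zero-variance rows map to all-zero rows rather than NaN.
    """
    matrix = np.asarray(matrix, dtype=float)
    mean = matrix.mean(axis=1, keepdims=True)
    sd = matrix.std(axis=1, keepdims=True)
    out = np.zeros_like(matrix)
    np.divide(matrix - mean, sd, out=out, where=sd > 0)
    return out


_CATEGORY_MEMBERSHIP = np.zeros((20, 4))
for _i, _aa in enumerate(AA_ORDER):
    _CATEGORY_MEMBERSHIP[_i, AA_CATEGORY_INDEX[_aa]] = 1.0


def profile_block(matrix: np.ndarray) -> np.ndarray:
    """Compress an L x 20 evolutionary profile (PSSM or HMM) to 4 values.

    Rows are z-scored, column means taken over all L rows, and the 20 means
    summed within the four residue categories (polar, charged, hydrophobic,
    GP).  Columns must follow :data:`~psphunter.io.AA_ORDER`.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != 20:
        raise ValueError(f"profile must be L x 20, got {matrix.shape}")
    col_means = zscore_rows(matrix).mean(axis=0)
    return col_means @ _CATEGORY_MEMBERSHIP


def conservation_block(scores: np.ndarray) -> np.ndarray:
    """Five-number summary (min, Q1, median, Q3, max) of per-residue
    conservation, with linear-interpolation quantiles."""
    scores = np.asarray(scores, dtype=float).ravel()
    if scores.size == 0:
        raise ValueError("conservation track is empty")
    return np.quantile(scores, [0.0, 0.25, 0.5, 0.75, 1.0])


def funcsite_block(record: ProteinRecord, tracks: ResidueTracks) -> np.ndarray:
    """14-dim predicted-functional-site block.

    Fractions of helix/sheet/coil/accessible/disordered/RNA-binding/
    DNA-binding residues (7), fractions of residues carrying each of the four
    predicted PTM site types (4), fractions of deleterious and neutral labels
    among all saturation-mutagenesis predictions (2), and protein length (1).
    """
    if tracks.length != record.length:
        raise ValueError(
            f"{record.id}: tracks length {tracks.length} != "
            f"sequence length {record.length}")
    L = record.length
    fractions = [
        tracks.helix.mean(), tracks.sheet.mean(), tracks.coil.mean(),
        tracks.accessible.mean(), tracks.disordered.mean(),
        tracks.rna_binding.mean(), tracks.dna_binding.mean(),
    ]
    ptm_fractions = tracks.ptm.mean(axis=0)
    n_labels = tracks.deleterious.sum() + tracks.neutral.sum()
    if n_labels > 0:
        mut = [tracks.deleterious.sum() / n_labels,
               tracks.neutral.sum() / n_labels]
    else:
        mut = [0.0, 0.0]
    return np.concatenate([fractions, ptm_fractions, mut, [float(L)]])
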