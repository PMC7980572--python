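"""Structure-derived features.

Three feature families are computed here:

* A seven-state RNA secondary-structure string derived from a base-pair set
  (stem S, hairpin loop H, multi-loop M, internal loop I, bulge B, external
  loop X, end E) — the per-nucleotide loop-type annotation used by
  macroscopic secondary-structure representations.
* Per-protein means of the per-residue tertiary descriptors (ASA, CN,
  HSEα-up, HSEα-down).
* The interface propensity (IP) of a pair: the mean residue–nucleotide
  binding preference over all (residue, nucleotide) combinations, looked up
  in a 60×8 table conditioned on the protein three-state structure and the
  RNA paired/unpaired state.

Loop-type conventions for states the nomenclature alone does not pin down:
an unpaired region between two helices under one closing pair is an internal
loop (I) if both strands contain unpaired bases and a bulge (B) if exactly
one does; unpaired terminal runs (before the first paired base / after the
last) are ends (E) while unpaired positions between top-level helices are
external (X).  Crossing pairs (pseudoknots) are removed before
classification by keeping a maximal non-crossing subset, greedily by helix
size with a deterministic 5'-most tie-break.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .records import (
    PROTEIN_ALPHABET,
    PROTEIN_SS_ALPHABET,
    RNA_ALPHABET,
    ProteinRecord,
    RnaRecord,
)

PAIRING_STATES = ("paired", "unpaired")
IP_ROW_LABELS = [
    f"{aa}:{ss}" for aa in PROTEIN_ALPHABET for ss in PROTEIN_SS_ALPHABET
]
IP_COL_LABELS = [f"{nt}:{state}" for nt in RNA_ALPHABET for state in PAIRING_STATES]


class StructureError(ValueError):
    """Raised for invalid base-pair sets or malformed structure inputs."""


@dataclass(frozen=True)
class BasePairSet:
    """A set of base pairs on a molecule of ``length`` nucleotides (1-based)."""

    length: int
    pairs: FrozenSet[Tuple[int, int]]

    def __post_init__(self) -> None:
        if self.length < 1:
            raise StructureError("length must be >= 1")
        seen: Dict[int, Tuple[int, int]] = {}
        for i, j in self.pairs:
            if not (1 <= i < j <= self.length):
                raise StructureError(f"pair ({i}, {j}) out of range for length {self.length}")
            for pos in (i, j):
                if pos in seen:
                    raise StructureError(f"position {pos} appears in more than one pair")
                seen[pos] = (i, j)

    @classmethod
    def from_pairs(cls, length: int, pairs) -> "BasePairSet":
        return cls(length=length, pairs=frozenset(tuple(sorted(p)) for p in pairs))


def _crosses(a: Tuple[int, int], b: Tuple[int, int]) -> bool:
    (i, j), (k, l) = a, b
    return (i < k < j < l) or (k < i < l < j)


def _helices(pairs: Sequence[Tuple[int, int]]) -> List[List[Tuple[int, int]]]:
    """Group pairs into helices of consecutively stacked pairs."""
    remaining = set(pairs)
    helices = []
    for i, j in sorted(remaining):
        if (i, j) not in remaining:
            continue
        helix = [(i, j)]
        remaining.discard((i, j))
        k, l = i + 1, j - 1
        while (k, l) in remaining:
            helix.append((k, l))
            remaining.discard((k, l))
            k, l = k + 1, l - 1
        helices.append(helix)
    return helices


def remove_pseudoknots(bp: BasePairSet) -> BasePairSet:
    """Return a non-crossing subset of ``bp``.

    Helices are accepted greedily in order of decreasing size, ties broken by
    the 5'-most opening position, skipping any helix that crosses an accepted
    pair.  Deterministic.
    """
    helices = _helices(sorted(bp.pairs))
    order = sorted(helices, key=lambda h: (-len(h), h[0][0]))
    accepted: List[Tuple[int, int]] = []
    for helix in order:
        if any(_crosses(p, q) for p in helix for q in accepted):
            continue
        accepted.extend(helix)
    return BasePairSet.from_pairs(bp.length, accepted)


def classify_loop_types(bp: BasePairSet, resolve_pseudoknots: bool = True) -> str:
    """Annotate every nucleotide with its seven-state loop type.

    Paired positions are S.  Unpaired positions are labeled by the loop they
    sit in: hairpin (H), internal loop (I), bulge (B), multi-loop (M),
    external (X), or terminal end (E).  See the module docstring for the
    B/I and E/X conventions.
    """
    if resolve_pseudoknots:
        bp = remove_pseudoknots(bp)
    pairs = sorted(bp.pairs)
    for a, b in itertools.combinations(pairs, 2):
        if _crosses(a, b):
            raise StructureError(f"crossing pairs {a} and {b} after pseudoknot removal")

    n = bp.length
    labels = ["?"] * (n + 1)  # 1-based
    paired_pos = sorted(p for pair in pairs for p in pair)
    for i, j in pairs:
        labels[i] = labels[j] = "S"

    # Parent of each pair: the smallest-span pair strictly enclosing it.
    def enclosing(span: Tuple[int, int]) -> Optional[Tuple[int, int]]:
        i, j = span
        best = None
        for k, l in pairs:
            if k < i and j < l:
                if best is None or (l - k) < (best[1] - best[0]):
                    best = (k, l)
        return best

    children: Dict[Optional[Tuple[int, int]], List[Tuple[int, int]]] = {}
    for pair in pairs:
        children.setdefault(enclosing(pair), []).append(pair)

    if paired_pos:
        first_paired, last_paired = paired_pos[0], paired_pos[-1]
    for p in range(1, n + 1):
        if labels[p] == "S":
            continue
        parent = enclosing((p, p))
        if parent is None:
            if not paired_pos or p < first_paired or p > last_paired:
                labels[p] = "E"
            else:
                labels[p] = "X"
            continue
        kids = children.get(parent, [])
        if len(kids) == 0:
            labels[p] = "H"
        elif len(kids) >= 2:
            labels[p] = "M"
        else:
            (k, l) = kids[0]
            (i, j) = parent
            left_unpaired = k - i - 1
            right_unpaired = j - l - 1
            labels[p] = "I" if (left_unpaired > 0 and right_unpaired > 0) else "B"
    return "".join(labels[1:])


def read_ct_pairs(path: Union[str, Path]) -> BasePairSet:
    """Read a CT-like base-pair TSV: columns ``pos``, ``pairs_with`` (0 = unpaired)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("pos", "pairs_with"):
        if col not in df.columns:
            raise StructureError(f"{path}: missing column {col!r}")
    length = int(df["pos"].max())
    pairs = set()
    for row in df.itertuples(index=False):
        j = int(row.pairs_with)
        if j > 0:
            i = int(row.pos)
            pairs.add((min(i, j), max(i, j)))
    return BasePairSet.from_pairs(length, pairs)


@dataclass(frozen=True)
class ProteinTertiarySummary:
    asa_mean: float
    cn_mean: float
    hse_up_mean: float
    hse_down_mean: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.asa_mean, self.cn_mean, self.hse_up_mean, self.hse_down_mean]
        )


def summarize_tertiary(tert: pd.DataFrame) -> ProteinTertiarySummary:
    """Arithmetic mean of each per-residue tertiary column."""
    if tert is None or len(tert) == 0:
        raise StructureError("empty tertiary table")
    means = tert.loc[:, ["asa", "cn", "hse_up", "hse_down"]].mean()
    if not np.isfinite(means.to_numpy()).all():
        raise StructureError("non-finite tertiary mean")
    return ProteinTertiarySummary(
        asa_mean=float(means["asa"]),
        cn_mean=float(means["cn"]),
        hse_up_mean=float(means["hse_up"]),
        hse_down_mean=float(means["hse_down"]),
    )


class IPTable:
    """60×8 residue–nucleotide interface-propensity matrix.

    Rows are (amino acid, protein SS state) with labels ``"A:H"`` ...;
    columns are (nucleotide, RNA pairing state) with labels ``"A:paired"``,
    ``"A:unpaired"`` ...  The published table's numeric content is external
    input; :meth:`uniform` provides a documented neutral default (all 1.0)
    so the pipeline runs without it.
    """

    def __init__(self, matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (60, 8):
            raise StructureError(f"IP table must be 60x8, got {matrix.shape}")
        if not np.isfinite(matrix).all():
            raise StructureError("IP table contains non-finite entries")
        self.matrix = matrix
        self._row_index = {label: i for i, label in enumerate(IP_ROW_LABELS)}
        self._col_index = {label: i for i, label in enumerate(IP_COL_LABELS)}

    @classmethod
    def uniform(cls, value: float = 1.0) -> "IPTable":
        return cls(np.full((60, 8), value))

    def lookup(self, aa: str, ss3: str, nt: str, paired: bool) -> float:
        row = self._row_index[f"{aa}:{ss3}"]
        col = self._col_index[f"{nt}:{'paired' if paired else 'unpaired'}"]
        return float(self.matrix[row, col])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=IP_ROW_LABELS, columns=IP_COL_LABELS)

    def save(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="row")


def load_ip_table(path: Union[str, Path]) -> IPTable:
    """Load and validate a 60×8 IP table from TSV with labeled rows/columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape != (60, 8):
        raise StructureError(f"{path}: IP table must be 60x8, got {df.shape}")
    if set(df.index) != set(IP_ROW_LABELS):
        unknown = sorted(set(df.index) - set(IP_ROW_LABELS))[:3]
        raise StructureError(f"{path}: unexpected row labels, e.g. {unknown}")
    if set(df.columns) != set(IP_COL_LABELS):
        unknown = sorted(set(df.columns) - set(IP_COL_LABELS))[:3]
        raise StructureError(f"{path}: unexpected column labels, e.g. {unknown}")
    df = df.loc[IP_ROW_LABELS, IP_COL_LABELS]
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise StructureError(f"{path}: non-finite IP table entry")
    return IPTable(values)


def pair_interface_propensity(
    rna: RnaRecord, protein: ProteinRecord, table: IPTable
) -> float:
    """Mean binding propensity over all (residue, nucleotide) cross pairs.

    Each residue contributes its (amino acid, three-state SS) row; each
    nucleotide its (base, paired/unpaired) column, where "paired" means the
    seven-state label is S.  The result is the mean of the corresponding
    table cells over the full cross product — equivalently a weighted
    bilinear form of the composition vectors, so it is invariant under
    permuting residues or nucleotides.
    """
    if rna.ss is None or protein.ss is None:
        raise StructureError("both rna.ss and protein.ss are required for IP")
    if len(rna) == 0 or len(protein) == 0:
        raise StructureError("zero-length input")
    row_weights = np.zeros(60)
    for aa, ss in zip(protein.seq, protein.ss):
        row_weights[table._row_index[f"{aa}:{ss}"]] += 1
    col_weights = np.zeros(8)
    for nt, state in zip(rna.seq, rna.ss):
        key = f"{nt}:{'paired' if state == 'S' else 'unpaired'}"
        col_weights[table._col_index[key]] += 1
    total = row_weights @ table.matrix @ col_weights
    return float(total / (len(protein) * len(rna)))
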