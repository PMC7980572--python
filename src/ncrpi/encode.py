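"""Conjoint k-mer feature encoder.

The encoder turns each (ncRNA, protein) pair into two fixed-length numeric
vectors:

* ncRNA, 3141 elements: k-mer frequency blocks of the primary sequence for
  k = 1..4 over the 4-letter alphabet (4 + 16 + 64 + 256 = 340), k-mer
  frequency blocks of the seven-state secondary-structure string for
  k = 1..4 (7 + 49 + 343 + 2401 = 2800), and the pair-level interface
  propensity scalar (1).
* protein, 443 elements: k-mer blocks of the seven-group reduced primary
  sequence for k = 1..3 (7 + 49 + 343 = 399), k-mer blocks of the
  three-state secondary-structure string for k = 1..3 (3 + 9 + 27 = 39),
  and five tertiary scalars: IP, ASA mean, CN mean, HSEα-up mean,
  HSEα-down mean.

Within a block the (L-k+1) sliding windows are counted and divided by
(L-k+1), so each block is a probability distribution over the |alphabet|^k
k-mers (it sums to 1 whenever L >= k).  Block index order is lexicographic
in the declared alphabet order; the orders are frozen module constants and
recorded in exported feature-matrix headers.

The amino-acid reduction groups the 20 residues by dipole moment and
side-chain volume: G1={A,G,V}, G2={I,L,F,P}, G3={Y,M,T,S}, G4={H,N,Q,W},
G5={R,K}, G6={D,E}, G7={C}.
"""

from __future__ import annotations

import itertools
import json
import logging
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np

from .records import PairSample, ProteinRecord, RnaRecord
from .structfeat import IPTable, pair_interface_propensity, summarize_tertiary

logger = logging.getLogger(__name__)

RNA_PRIMARY_ALPHABET = "ACGU"
RNA_SS_ALPHABET = "SHMIBXE"
REDUCED_ALPHABET = "1234567"
PROTEIN_SS_ALPHABET = "HEC"

RNA_K_RANGE = (1, 2, 3, 4)
PROTEIN_K_RANGE = (1, 2, 3)

RNA_VECTOR_LENGTH = sum(4 ** k for k in RNA_K_RANGE) + sum(7 ** k for k in RNA_K_RANGE) + 1
PROTEIN_VECTOR_LENGTH = (
    sum(7 ** k for k in PROTEIN_K_RANGE) + sum(3 ** k for k in PROTEIN_K_RANGE) + 5
)

AA_GROUPS = {
    "1": "AGV",
    "2": "ILFP",
    "3": "YMTS",
    "4": "HNQW",
    "5": "RK",
    "6": "DE",
    "7": "C",
}
_AA_TO_GROUP = {aa: g for g, members in AA_GROUPS.items() for aa in members}


class EncodingError(ValueError):
    """Raised when a record cannot be encoded."""


def reduce_protein_alphabet(seq: str) -> str:
    """Map a protein sequence onto the seven physicochemical groups '1'..'7'."""
    try:
        return "".join(_AA_TO_GROUP[aa] for aa in seq)
    except KeyError as exc:
        raise EncodingError(f"unknown amino acid {exc.args[0]!r}") from None


def kmer_block(seq: str, alphabet: str, k: int) -> np.ndarray:
    """Frequency vector over all |alphabet|^k k-mers, lexicographic order.

    Counts the (L-k+1) sliding windows and normalizes by (L-k+1).  If the
    sequence is shorter than k the block is all zeros (logged).
    """
    if not (1 <= k <= 4):
        raise EncodingError(f"k must be in 1..4, got {k}")
    m = len(alphabet)
    index = {ch: i for i, ch in enumerate(alphabet)}
    out = np.zeros(m ** k)
    L = len(seq)
    if L < k:
        logger.warning("sequence of length %d shorter than k=%d: zero block", L, k)
        return out
    for start in range(L - k + 1):
        code = 0
        for ch in seq[start : start + k]:
            try:
                code = code * m + index[ch]
            except KeyError:
                raise EncodingError(f"character {ch!r} not in alphabet {alphabet!r}") from None
        out[code] += 1.0
    out /= L - k + 1
    return out


def _conjoint(seq: str, alphabet: str, k_range: Sequence[int]) -> np.ndarray:
    return np.concatenate([kmer_block(seq, alphabet, k) for k in k_range])


def encode_rna(rna: RnaRecord, ip: float) -> np.ndarray:
    """Encode one ncRNA into its 3141-element feature vector."""
    if rna.ss is None:
        raise EncodingError(f"RNA {rna.id!r}: secondary-structure string required")
    primary = _conjoint(rna.seq, RNA_PRIMARY_ALPHABET, RNA_K_RANGE)
    secondary = _conjoint(rna.ss, RNA_SS_ALPHABET, RNA_K_RANGE)
    vec = np.concatenate([primary, secondary, [float(ip)]])
    assert vec.shape == (RNA_VECTOR_LENGTH,)
    return vec


def encode_protein(protein: ProteinRecord, ip: float) -> np.ndarray:
    """Encode one protein into its 443-element feature vector."""
    if protein.ss is None:
        raise EncodingError(f"protein {protein.id!r}: secondary-structure string required")
    if protein.tert is None:
        raise EncodingError(f"protein {protein.id!r}: tertiary table required")
    reduced = reduce_protein_alphabet(protein.seq)
    primary = _conjoint(reduced, REDUCED_ALPHABET, PROTEIN_K_RANGE)
    secondary = _conjoint(protein.ss, PROTEIN_SS_ALPHABET, PROTEIN_K_RANGE)
    summary = summarize_tertiary(protein.tert)
    scalars = np.concatenate([[float(ip)], summary.as_array()])
    vec = np.concatenate([primary, secondary, scalars])
    assert vec.shape == (PROTEIN_VECTOR_LENGTH,)
    return vec


def encode_dataset(
    rna_records: Sequence[RnaRecord],
    protein_records: Sequence[ProteinRecord],
    pairs: Sequence[PairSample],
    ip_table: IPTable,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encode every pair; rows follow the input pair order.

    The interface propensity is a pair-level scalar computed once per pair
    and injected into both the RNA and the protein vector of that pair.
    Labels of unlabeled pairs come back as -1.
    """
    rna_by_id = {r.id: r for r in rna_records}
    prot_by_id = {p.id: p for p in protein_records}
    rna_X = np.zeros((len(pairs), RNA_VECTOR_LENGTH))
    prot_X = np.zeros((len(pairs), PROTEIN_VECTOR_LENGTH))
    labels = np.full(len(pairs), -1, dtype=int)
    for i, pair in enumerate(pairs):
        try:
            rna = rna_by_id[pair.rna_id]
            protein = prot_by_id[pair.protein_id]
        except KeyError as exc:
            raise EncodingError(
                f"pair ({pair.rna_id}, {pair.protein_id}): unknown id {exc.args[0]!r}"
            ) from None
        try:
            ip = pair_interface_propensity(rna, protein, ip_table)
            rna_X[i] = encode_rna(rna, ip)
            prot_X[i] = encode_protein(protein, ip)
        except Exception as exc:
            raise EncodingError(
                f"pair ({pair.rna_id}, {pair.protein_id}): {exc}"
            ) from exc
        if pair.label is not None:
            labels[i] = pair.label
    return rna_X, prot_X, labels


def _layout() -> Dict[str, object]:
    return {
        "rna": {
            "primary_alphabet": RNA_PRIMARY_ALPHABET,
            "ss_alphabet": RNA_SS_ALPHABET,
            "k_range": list(RNA_K_RANGE),
            "blocks": ["primary k=1..4", "secondary k=1..4", "ip"],
            "length": RNA_VECTOR_LENGTH,
        },
        "protein": {
            "reduced_alphabet": REDUCED_ALPHABET,
            "ss_alphabet": PROTEIN_SS_ALPHABET,
            "k_range": list(PROTEIN_K_RANGE),
            "blocks": ["reduced primary k=1..3", "secondary k=1..3",
                       "ip,asa,cn,hse_up,hse_down"],
            "length": PROTEIN_VECTOR_LENGTH,
        },
        "aa_groups": AA_GROUPS,
    }


def save_feature_matrix(path: Union[str, Path], matrix: np.ndarray, kind: str) -> None:
    """Export a feature matrix as TSV with a JSON layout header (bit-exact reload)."""
    with open(path, "w") as fh:
        header = {"kind": kind, "layout": _layout()[kind]}
        fh.write("# " + json.dumps(header) + "\n")
        for row in matrix:
            fh.write("\t".join(np.format_float_scientific(v, precision=17) for v in row))
            fh.write("\n")


def load_feature_matrix(path: Union[str, Path]) -> Tuple[np.ndarray, Dict]:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# "):
            raise EncodingError(f"{path}: missing layout header")
        header = json.loads(first[2:])
        rows = [np.array(line.split("\t"), dtype=float) for line in fh if line.strip()]
    matrix = np.vstack(rows) if rows else np.zeros((0, header["layout"]["length"]))
    return matrix, header
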