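"""Core domain records: ncRNA and protein sequences with optional structure annotations.

An :class:`RnaRecord` carries the primary sequence over {A,C,G,U} and, once a
secondary-structure annotation is attached, a seven-state structure string
(S = stem, H = hairpin loop, M = multi-loop, I = internal loop, B = bulge,
X = external loop, E = end) of the same length.

A :class:`ProteinRecord` carries the primary sequence over the 20 standard
amino acids, an optional three-state secondary structure string over {H,E,C}
(helix, sheet, coil), and an optional per-residue tertiary table with columns
``asa`` (solvent accessible surface area, Å²), ``cn`` (contact number),
``hse_up`` / ``hse_down`` (half-sphere exposures).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

RNA_ALPHABET = "ACGU"
RNA_SS_ALPHABET = "SHMIBXE"
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_SS_ALPHABET = "HEC"
TERTIARY_COLUMNS = ("asa", "cn", "hse_up", "hse_down")


class RecordError(ValueError):
    """Raised when a record violates its alphabet or length invariants."""


def _check_alphabet(seq: str, alphabet: str, what: str, rec_id: str) -> None:
    allowed = set(alphabet)
    for pos, ch in enumerate(seq, start=1):
        if ch not in allowed:
            raise RecordError(
                f"record {rec_id!r}: illegal {what} character {ch!r} at position {pos}"
            )


@dataclass
class RnaRecord:
    id: str
    seq: str
    ss: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise RecordError(f"record {self.id!r}: empty sequence")
        _check_alphabet(self.seq, RNA_ALPHABET, "nucleotide", self.id)
        if self.ss is not None:
            self.attach_ss(self.ss)

    def attach_ss(self, ss: str) -> None:
        if len(ss) != len(self.seq):
            raise RecordError(
                f"record {self.id!r}: structure length {len(ss)} != sequence length {len(self.seq)}"
            )
        _check_alphabet(ss, RNA_SS_ALPHABET, "structure", self.id)
        self.ss = ss

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ProteinRecord:
    id: str
    seq: str
    ss: Optional[str] = None
    tert: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.seq:
            raise RecordError(f"record {self.id!r}: empty sequence")
        _check_alphabet(self.seq, PROTEIN_ALPHABET, "residue", self.id)
        if self.ss is not None:
            self.attach_ss(self.ss)
        if self.tert is not None:
            self.attach_tert(self.tert)

    def attach_ss(self, ss: str) -> None:
        if len(ss) != len(self.seq):
            raise RecordError(
                f"record {self.id!r}: structure length {len(ss)} != sequence length {len(self.seq)}"
            )
        _check_alphabet(ss, PROTEIN_SS_ALPHABET, "structure", self.id)
        self.ss = ss

    def attach_tert(self, tert: pd.DataFrame) -> None:
        missing = [c for c in TERTIARY_COLUMNS if c not in tert.columns]
        if missing:
            raise RecordError(f"record {self.id!r}: tertiary table missing columns {missing}")
        tert = tert.loc[:, list(TERTIARY_COLUMNS)].astype(float)
        if len(tert) != len(self.seq):
            raise RecordError(
                f"record {self.id!r}: tertiary table has {len(tert)} rows for "
                f"{len(self.seq)} residues"
            )
        if not np.isfinite(tert.to_numpy()).all():
            raise RecordError(f"record {self.id!r}: non-finite tertiary value")
        self.tert = tert.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PairSample:
    """One (ncRNA, protein) pair with a binary interaction label.

    ``label`` may be None for prediction-only pair lists.
    """

    rna_id: str
    protein_id: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (0, 1):
            raise RecordError(
                f"pair ({self.rna_id}, {self.protein_id}): label must be 0 or 1, "
                f"got {self.label!r}"
            )
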