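"""Negative-pair generation by random re-pairing with a similarity discard rule.

Non-interacting pairs are sampled by randomly re-pairing the ncRNAs and
proteins that occur in the positive set.  A candidate pair (R2, P2) is
discarded if it is itself a known positive, a duplicate of an accepted
negative, or if some positive (R1, P1) exists with P2 sharing >= 40%
sequence identity with P1 AND R2 sharing >= 80% identity with R1 (both
conditions must hold; thresholds configurable).

Sequence identity is computed from a global (Needleman-Wunsch style)
alignment with match=1, mismatch=0 and a simple gap penalty, as
100 * matches / alignment_length.  The alignment procedure is a package
choice and is configurable through :class:`IdentityScorer`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from Bio import Align

from .records import PairSample, ProteinRecord, RnaRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IdentityThresholds:
    """Discard thresholds, in percent identity."""

    protein_min: float = 40.0
    rna_min: float = 80.0

    def __post_init__(self) -> None:
        for v in (self.protein_min, self.rna_min):
            if not (0.0 < v <= 100.0):
                raise ValueError(f"threshold {v} outside (0, 100]")


class IdentityScorer:
    """Global-alignment percent identity with memoization."""

    def __init__(self, match: float = 1.0, mismatch: float = 0.0, gap: float = -1.0):
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = match
        aligner.mismatch_score = mismatch
        aligner.open_gap_score = gap
        aligner.extend_gap_score = gap
        self._aligner = aligner
        self._cache: Dict[Tuple[str, str], float] = {}

    def identity(self, a: str, b: str) -> float:
        """Percent identity: 100 * matched positions / alignment length."""
        if not a or not b:
            raise ValueError("empty sequence")
        key = (a, b) if a <= b else (b, a)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        alignment = self._aligner.align(a, b)[0]
        counts = alignment.counts()
        value = 100.0 * counts.identities / alignment.length
        self._cache[key] = value
        return value


_default_scorer = IdentityScorer()


def sequence_identity(a: str, b: str) -> float:
    """Percent identity between two sequences under global alignment.

    Symmetric in its arguments; 100.0 for identical sequences, 0.0 when no
    position matches.
    """
    return _default_scorer.identity(a, b)


class NegativeGenerationError(RuntimeError):
    """Raised when the attempt budget is exhausted before n negatives accepted."""


def generate_negative_pairs(
    positives: Sequence[PairSample],
    rna_records: Sequence[RnaRecord],
    protein_records: Sequence[ProteinRecord],
    n: int,
    seed: int,
    thresholds: IdentityThresholds = IdentityThresholds(),
    attempt_budget_factor: int = 100,
    scorer: IdentityScorer | None = None,
) -> List[PairSample]:
    """Draw ``n`` non-interacting pairs by random re-pairing.

    Deterministic for a fixed seed.  Raises
    :class:`NegativeGenerationError` with the observed acceptance rate if
    the budget of ``attempt_budget_factor * n`` draws is exhausted first.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not positives:
        raise ValueError("positive set must be non-empty")
    scorer = scorer or IdentityScorer()
    rng = np.random.default_rng(seed)
    rna_by_id = {r.id: r for r in rna_records}
    prot_by_id = {p.id: p for p in protein_records}
    rna_ids = sorted({p.rna_id for p in positives})
    prot_ids = sorted({p.protein_id for p in positives})
    for rid in rna_ids:
        if rid not in rna_by_id:
            raise ValueError(f"positive rna_id {rid!r} has no record")
    for pid in prot_ids:
        if pid not in prot_by_id:
            raise ValueError(f"positive protein_id {pid!r} has no record")
    positive_keys = {(p.rna_id, p.protein_id) for p in positives}
    positive_list = list(positives)

    # For a candidate protein, precompute which positives pass the protein
    # half of the discard predicate; the RNA half is only evaluated there.
    similar_positives: Dict[str, List[PairSample]] = {}

    def protein_similar(pid: str) -> List[PairSample]:
        hits = similar_positives.get(pid)
        if hits is None:
            seq = prot_by_id[pid].seq
            hits = [
                pos
                for pos in positive_list
                if scorer.identity(seq, prot_by_id[pos.protein_id].seq)
                >= thresholds.protein_min
            ]
            similar_positives[pid] = hits
        return hits

    def discard(rid: str, pid: str) -> bool:
        rna_seq = rna_by_id[rid].seq
        return any(
            scorer.identity(rna_seq, rna_by_id[pos.rna_id].seq) >= thresholds.rna_min
            for pos in protein_similar(pid)
        )

    accepted: List[PairSample] = []
    accepted_keys = set()
    budget = attempt_budget_factor * n
    attempts = 0
    while len(accepted) < n and attempts < budget:
        attempts += 1
        rid = rna_ids[rng.integers(len(rna_ids))]
        pid = prot_ids[rng.integers(len(prot_ids))]
        key = (rid, pid)
        if key in positive_keys or key in accepted_keys:
            continue
        if discard(rid, pid):
            continue
        accepted_keys.add(key)
        accepted.append(PairSample(rna_id=rid, protein_id=pid, label=0))
    if len(accepted) < n:
        rate = len(accepted) / attempts if attempts else 0.0
        raise NegativeGenerationError(
            f"accepted only {len(accepted)}/{n} negatives in {attempts} draws "
            f"(acceptance rate {rate:.3f}); the positive set may cover all "
            f"acceptable combinations"
        )
    logger.info("accepted %d negatives in %d draws", n, attempts)
    return accepted
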