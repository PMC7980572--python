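"""Reading and writing sequences, pair lists, structure sidecars and predictions.

File formats
------------
* FASTA for primary sequences (DNA-style ``T`` in RNA files is transliterated
  to ``U``; ambiguity codes are rejected).
* FASTA-like sidecars for structure strings: ``>id`` followed by the structure
  line(s), one entry per annotated record.
* TSV for pair lists (columns ``rna_id``, ``protein_id``, ``label``; the label
  column may be absent for prediction inputs), per-residue tertiary tables
  (``id``, ``pos``, ``asa``, ``cn``, ``hse_up``, ``hse_down``) and predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .records import (
    PairSample,
    ProteinRecord,
    RecordError,
    RnaRecord,
    TERTIARY_COLUMNS,
)

logger = logging.getLogger(__name__)

Record = Union[RnaRecord, ProteinRecord]

# Length filters applied to benchmark-style datasets: RNAs shorter than 15 nt
# or longer than 500 nt are dropped (the 500-nt cap mirrors the input limit of
# secondary-structure predictors trained on <=500-nt RNAs); proteins shorter
# than 25 aa are dropped.
RNA_MIN_LEN = 15
RNA_MAX_LEN = 500
PROTEIN_MIN_LEN = 25


def read_fasta(path: Union[str, Path], kind: str) -> List[Record]:
    """Read a FASTA file into RNA or protein records.

    For ``kind="rna"`` sequences are uppercased and T is transliterated to U.
    Raises :class:`RecordError` on an empty file or an illegal residue.
    """
    if kind not in ("rna", "protein"):
        raise ValueError(f"kind must be 'rna' or 'protein', got {kind!r}")
    path = Path(path)
    records: List[Record] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if kind == "rna":
            seq = seq.replace("T", "U")
            records.append(RnaRecord(id=entry.id, seq=seq))
        else:
            records.append(ProteinRecord(id=entry.id, seq=seq))
    if not records:
        raise RecordError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[Record], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


def read_pairs(
    path: Union[str, Path],
    rna_records: Optional[Sequence[RnaRecord]] = None,
    protein_records: Optional[Sequence[ProteinRecord]] = None,
    require_label: bool = True,
) -> List[PairSample]:
    """Read a TSV pair list.

    Columns: ``rna_id``, ``protein_id`` and, unless the file is a prediction
    input, ``label`` in {0,1}.  Duplicate (rna_id, protein_id) rows are
    rejected, as are ids that do not resolve against supplied records.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["rna_id", "protein_id"] + (["label"] if require_label else [])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RecordError(f"{path}: missing column(s) {missing}")
    dup = df.duplicated(subset=["rna_id", "protein_id"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise RecordError(
            f"{path}: duplicate pair ({first.rna_id}, {first.protein_id})"
        )
    pairs: List[PairSample] = []
    for row in df.itertuples(index=False):
        label: Optional[int] = None
        if "label" in df.columns and getattr(row, "label", None) is not None:
            raw = getattr(row, "label")
            if raw not in ("0", "1"):
                raise RecordError(
                    f"{path}: label for ({row.rna_id}, {row.protein_id}) must be "
                    f"0 or 1, got {raw!r}"
                )
            label = int(raw)
        elif require_label:
            raise RecordError(f"{path}: missing label")
        pairs.append(PairSample(rna_id=row.rna_id, protein_id=row.protein_id, label=label))
    _resolve_ids(pairs, rna_records, protein_records, source=str(path))
    return pairs


def _resolve_ids(pairs, rna_records, protein_records, source: str) -> None:
    if rna_records is not None:
        known = {r.id for r in rna_records}
        for p in pairs:
            if p.rna_id not in known:
                raise RecordError(f"{source}: unknown rna_id {p.rna_id!r}")
    if protein_records is not None:
        known = {r.id for r in protein_records}
        for p in pairs:
            if p.protein_id not in known:
                raise RecordError(f"{source}: unknown protein_id {p.protein_id!r}")


def write_pairs(pairs: Sequence[PairSample], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("rna_id\tprotein_id\tlabel\n")
        for p in pairs:
            label = "" if p.label is None else str(p.label)
            fh.write(f"{p.rna_id}\t{p.protein_id}\t{label}\n")


def read_structure_sidecar(
    path: Union[str, Path], records: Sequence[Record]
) -> Dict[str, str]:
    """Read a FASTA-like structure sidecar and attach structures to records.

    Entries whose id matches no record are skipped with a warning; a structure
    whose length disagrees with its record's sequence raises.  Returns the
    id -> structure map that was attached.
    """
    by_id = {r.id: r for r in records}
    attached: Dict[str, str] = {}
    current_id: Optional[str] = None
    chunks: List[str] = []

    def flush() -> None:
        nonlocal current_id, chunks
        if current_id is None:
            return
        ss = "".join(chunks)
        rec = by_id.get(current_id)
        if rec is None:
            logger.warning("structure sidecar: id %r matches no record; skipped", current_id)
        else:
            rec.attach_ss(ss)
            attached[current_id] = ss
        current_id, chunks = None, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                current_id = line[1:].split()[0]
            else:
                chunks.append(line)
        flush()
    return attached


def read_tertiary_table(
    path: Union[str, Path], records: Sequence[ProteinRecord]
) -> Dict[str, pd.DataFrame]:
    """Read a per-residue tertiary table and attach it to protein records.

    TSV columns: ``id``, ``pos`` (1-based), ``asa``, ``cn``, ``hse_up``,
    ``hse_down``.  Rows are grouped by id; each group must cover every residue
    of its protein exactly once.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["id", "pos", *TERTIARY_COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RecordError(f"{path}: missing column(s) {missing}")
    by_id = {r.id: r for r in records}
    attached: Dict[str, pd.DataFrame] = {}
    for rec_id, grp in df.groupby("id", sort=False):
        rec = by_id.get(str(rec_id))
        if rec is None:
            logger.warning("tertiary table: id %r matches no record; skipped", rec_id)
            continue
        grp = grp.sort_values("pos")
        expected = np.arange(1, len(rec.seq) + 1)
        if len(grp) != len(expected) or not np.array_equal(grp["pos"].to_numpy(), expected):
            raise RecordError(
                f"{path}: tertiary rows for {rec_id!r} do not cover positions "
                f"1..{len(rec.seq)} exactly"
            )
        table = grp.loc[:, list(TERTIARY_COLUMNS)].reset_index(drop=True)
        rec.attach_tert(table)
        attached[str(rec_id)] = rec.tert
    return attached


@dataclass
class FilterReport:
    rna_too_short: int = 0
    rna_too_long: int = 0
    protein_too_short: int = 0
    pairs_dropped: int = 0
    records_unpaired: int = 0


def apply_dataset_filters(
    rna_records: Sequence[RnaRecord],
    protein_records: Sequence[ProteinRecord],
    pairs: Sequence[PairSample],
) -> Tuple[List[RnaRecord], List[ProteinRecord], List[PairSample], FilterReport]:
    """Apply benchmark length filters.

    RNAs are kept iff ``15 <= len <= 500`` (both bounds inclusive), proteins
    iff ``len >= 25``; pairs survive iff both members survive; records left
    with no pair are then dropped.  Idempotent.
    """
    report = FilterReport()
    kept_rna: Dict[str, RnaRecord] = {}
    for r in rna_records:
        if len(r) < RNA_MIN_LEN:
            report.rna_too_short += 1
        elif len(r) > RNA_MAX_LEN:
            report.rna_too_long += 1
        else:
            kept_rna[r.id] = r
    kept_prot: Dict[str, ProteinRecord] = {}
    for p in protein_records:
        if len(p) < PROTEIN_MIN_LEN:
            report.protein_too_short += 1
        else:
            kept_prot[p.id] = p
    kept_pairs = [
        s for s in pairs if s.rna_id in kept_rna and s.protein_id in kept_prot
    ]
    report.pairs_dropped = len(pairs) - len(kept_pairs)
    used_rna = {s.rna_id for s in kept_pairs}
    used_prot = {s.protein_id for s in kept_pairs}
    out_rna = [r for r in rna_records if r.id in kept_rna and r.id in used_rna]
    out_prot = [p for p in protein_records if p.id in kept_prot and p.id in used_prot]
    report.records_unpaired = (len(kept_rna) - len(out_rna)) + (len(kept_prot) - len(out_prot))
    logger.info(
        "dataset filters: removed %d short RNAs, %d long RNAs, %d short proteins, "
        "%d pairs, %d unpaired records",
        report.rna_too_short,
        report.rna_too_long,
        report.protein_too_short,
        report.pairs_dropped,
        report.records_unpaired,
    )
    return out_rna, out_prot, kept_pairs, report


def write_predictions(
    pairs: Sequence[PairSample],
    scores: Sequence[float],
    path: Union[str, Path],
    threshold: float = 0.5,
    graph_path: Optional[Union[str, Path]] = None,
) -> None:
    """Write predicted interaction scores as a TSV, optionally with an edge list.

    Scores must lie in [0,1] and align with ``pairs``.  The optional edge-list
    export (``source``, ``target``, ``weight``) is suitable for network viewers.
    """
    scores = np.asarray(list(scores), dtype=float)
    if len(scores) != len(pairs):
        raise ValueError(f"{len(scores)} scores for {len(pairs)} pairs")
    if len(scores) and (scores.min() < 0.0 or scores.max() > 1.0):
        bad = scores[(scores < 0) | (scores > 1)][0]
        raise ValueError(f"score {bad} outside [0, 1]")
    with open(path, "w") as fh:
        fh.write("rna_id\tprotein_id\tscore\tpredicted_label\n")
        for p, s in zip(pairs, scores):
            fh.write(f"{p.rna_id}\t{p.protein_id}\t{s:.6f}\t{int(s >= threshold)}\n")
    if graph_path is not None:
        with open(graph_path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for p, s in zip(pairs, scores):
                fh.write(f"{p.rna_id}\t{p.protein_id}\t{s:.6f}\n")
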