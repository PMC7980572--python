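import numpy as np
import pytest

from ncrpi import PairSample, RnaRecord, apply_dataset_filters, read_fasta, read_pairs
from ncrpi.records import ProteinRecord, RecordError
from ncrpi.seqio import (
    read_structure_sidecar,
    read_tertiary_table,
    write_fasta,
    write_pairs,
    write_predictions,
)


class TestReadFasta:
    def test_rna_normalization(self, tmp_path):
        path = tmp_path / "r.fa"
        path.write_text(">r1\nacgt\n")
        (rec,) = read_fasta(path, kind="rna")
        assert rec.id == "r1"
        assert rec.seq == "ACGU"

    def test_protein(self, tmp_path):
        path = tmp_path / "p.fa"
        path.write_text(">p1\nMKV\n")
        (rec,) = read_fasta(path, kind="protein")
        assert rec.seq == "MKV"

    def test_illegal_residue_names_position(self, tmp_path):
        path = tmp_path / "r.fa"
        path.write_text(">r1\nACGX\n")
        with pytest.raises(RecordError, match="position 4"):
            read_fasta(path, kind="rna")

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.fa"
        path.write_text("")
        with pytest.raises(RecordError):
            read_fasta(path, kind="rna")

    def test_round_trip(self, tmp_path, small_records):
        rna, _, _ = small_records
        path = tmp_path / "out.fa"
        write_fasta(rna, path)
        back = read_fasta(path, kind="rna")
        assert [(r.id, r.seq) for r in back] == [(r.id, r.seq) for r in rna]


class TestReadPairs:
    def test_basic(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        path.write_text("rna_id\tprotein_id\tlabel\nr1\tp1\t1\n")
        (pair,) = read_pairs(path)
        assert pair == PairSample("r1", "p1", 1)

    def test_duplicate_rejected(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        path.write_text("rna_id\tprotein_id\tlabel\nr1\tp1\t1\nr1\tp1\t0\n")
        with pytest.raises(RecordError, match="duplicate"):
            read_pairs(path)

    def test_bad_label(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        path.write_text("rna_id\tprotein_id\tlabel\nr1\tp1\t2\n")
        with pytest.raises(RecordError, match="label"):
            read_pairs(path)

    def test_unresolvable_id(self, tmp_path, small_records):
        rna, prot, _ = small_records
        path = tmp_path / "pairs.tsv"
        path.write_text("rna_id\tprotein_id\tlabel\nzz\tp1\t1\n")
        with pytest.raises(RecordError, match="zz"):
            read_pairs(path, rna, prot)

    def test_unlabeled_prediction_list(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        path.write_text("rna_id\tprotein_id\nr1\tp1\n")
        (pair,) = read_pairs(path, require_label=False)
        assert pair.label is None

    def test_write_read_round_trip(self, tmp_path):
        pairs = [PairSample("r1", "p1", 1), PairSample("r2", "p1", 0)]
        path = tmp_path / "pairs.tsv"
        write_pairs(pairs, path)
        assert read_pairs(path) == pairs


class TestStructureSidecar:
    def test_attach(self, tmp_path):
        rec = RnaRecord("r1", "ACGUAC")
        path = tmp_path / "ss.fa"
        path.write_text(">r1\nSSHHSS\n")
        attached = read_structure_sidecar(path, [rec])
        assert rec.ss == "SSHHSS"
        assert attached == {"r1": "SSHHSS"}

    def test_length_mismatch(self, tmp_path):
        rec = RnaRecord("r1", "ACGUAC")
        path = tmp_path / "ss.fa"
        path.write_text(">r1\nSSH\n")
        with pytest.raises(RecordError, match="length"):
            read_structure_sidecar(path, [rec])

    def test_orphan_id_skipped_with_warning(self, tmp_path, caplog):
        rec = RnaRecord("r1", "ACGUAC")
        path = tmp_path / "ss.fa"
        path.write_text(">zz\nSSHHSS\n")
        with caplog.at_level("WARNING"):
            attached = read_structure_sidecar(path, [rec])
        assert attached == {}
        assert "zz" in caplog.text


class TestTertiaryTable:
    def test_attach_and_mismatch(self, tmp_path):
        rec = ProteinRecord("p1", "MKV")
        path = tmp_path / "tert.tsv"
        rows = ["id\tpos\tasa\tcn\thse_up\thse_down"]
        rows += [f"p1\t{i}\t10.0\t3.0\t1.0\t2.0" for i in (1, 2, 3)]
        path.write_text("\n".join(rows) + "\n")
        read_tertiary_table(path, [rec])
        assert rec.tert is not None and len(rec.tert) == 3

        bad = tmp_path / "bad.tsv"
        bad.write_text("\n".join(rows[:3]) + "\n")  # only 2 residues covered
        rec2 = ProteinRecord("p1", "MKV")
        with pytest.raises(RecordError):
            read_tertiary_table(bad, [rec2])


def _rna(rec_id, n):
    rng = np.random.default_rng(abs(hash(rec_id)) % 2 ** 31)
    return RnaRecord(rec_id, "".join(np.array(list("ACGU"))[rng.integers(4, size=n)]))


def _prot(rec_id, n):
    rng = np.random.default_rng(abs(hash(rec_id)) % 2 ** 31)
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    return ProteinRecord(rec_id, "".join(letters[rng.integers(20, size=n)]))


class TestDatasetFilters:
    @pytest.mark.parametrize(
        "rna_len,prot_len,kept",
        [
            (14, 30, False),   # RNA below the 15-nt minimum
            (15, 30, True),    # boundary inclusive
            (500, 30, True),   # boundary inclusive
            (501, 30, False),  # RNA above the 500-nt cap
            (30, 24, False),   # protein below the 25-aa minimum
            (30, 25, True),    # boundary inclusive
        ],
    )
    def test_boundaries(self, rna_len, prot_len, kept):
        rna = [_rna("r", rna_len)]
        prot = [_prot("p", prot_len)]
        pairs = [PairSample("r", "p", 1)]
        out_rna, out_prot, out_pairs, _ = apply_dataset_filters(rna, prot, pairs)
        assert (len(out_pairs) == 1) == kept
        assert (len(out_rna) == 1) == kept

    def test_unpaired_records_dropped(self):
        rna = [_rna("r1", 30), _rna("r2", 30)]
        prot = [_prot("p1", 30), _prot("p2", 10)]  # p2 too short
        pairs = [PairSample("r1", "p1", 1), PairSample("r2", "p2", 1)]
        out_rna, out_prot, out_pairs, report = apply_dataset_filters(rna, prot, pairs)
        assert [p.rna_id for p in out_pairs] == ["r1"]
        # r2 survives the length filter but loses its only pair
        assert [r.id for r in out_rna] == ["r1"]
        assert report.protein_too_short == 1
        assert report.records_unpaired == 1

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        rna = [_rna(f"r{i}", int(rng.integers(5, 600))) for i in range(20)]
        prot = [_prot(f"p{i}", int(rng.integers(10, 100))) for i in range(20)]
        pairs = [
            PairSample(f"r{rng.integers(20)}", f"p{rng.integers(20)}", 1)
            for _ in range(15)
        ]
        pairs = list(dict.fromkeys(pairs))
        once = apply_dataset_filters(rna, prot, pairs)
        twice = apply_dataset_filters(once[0], once[1], once[2])
        assert [r.id for r in twice[0]] == [r.id for r in once[0]]
        assert [p.id for p in twice[1]] == [p.id for p in once[1]]
        assert twice[2] == once[2]


class TestWritePredictions:
    def test_rows(self, tmp_path):
        pairs = [PairSample("r1", "p1"), PairSample("r2", "p2")]
        out = tmp_path / "pred.tsv"
        graph = tmp_path / "graph.tsv"
        write_predictions(pairs, [0.9, 0.2], out, graph_path=graph)
        lines = out.read_text().strip().split("\n")
        assert lines[0] == "rna_id\tprotein_id\tscore\tpredicted_label"
        assert lines[1].split("\t") == ["r1", "p1", "0.900000", "1"]
        assert lines[2].split("\t") == ["r2", "p2", "0.200000", "0"]
        assert graph.read_text().startswith("source\ttarget\tweight")

    def test_score_out_of_range(self, tmp_path):
        with pytest.raises(ValueError, match="1.2"):
            write_predictions([PairSample("r1", "p1")], [1.2], tmp_path / "x.tsv")

    def test_empty_is_header_only(self, tmp_path):
        out = tmp_path / "pred.tsv"
        write_predictions([], [], out)
        assert out.read_text() == "rna_id\tprotein_id\tscore\tpredicted_label\n"

    def test_length_mismatch(self, tmp_path):
        with pytest.raises(ValueError):
            write_predictions([PairSample("r1", "p1")], [0.5, 0.6], tmp_path / "x.tsv")
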