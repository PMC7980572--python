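import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncrpi import (
    BasePairSet,
    IPTable,
    ProteinRecord,
    RnaRecord,
    classify_loop_types,
    load_ip_table,
    pair_interface_propensity,
    summarize_tertiary,
)
from ncrpi.structfeat import (
    IP_COL_LABELS,
    IP_ROW_LABELS,
    StructureError,
    read_ct_pairs,
    remove_pseudoknots,
)
from ncrpi.synth import random_nested_pairs

from .oracles import loop_type_oracle


class TestBasePairSet:
    def test_position_in_two_pairs_rejected(self):
        with pytest.raises(StructureError):
            BasePairSet.from_pairs(10, [(1, 5), (5, 9)])

    def test_out_of_range_rejected(self):
        with pytest.raises(StructureError):
            BasePairSet.from_pairs(5, [(1, 6)])


class TestClassifyLoopTypes:
    @pytest.mark.parametrize(
        "length,pairs,expected",
        [
            (10, [(1, 10), (2, 9), (3, 8)], "SSSHHHHSSS"),   # plain stem-loop
            (4, [], "EEEE"),                                  # fully unpaired
            (12, [(2, 11), (3, 10), (5, 8)], "ESSISHHSISSE"),  # internal loop
            # one-sided unpaired run between stacked helices -> bulge
            (11, [(2, 11), (3, 10), (5, 9)], "ESSBSHHHSSS"),
            # two top-level helices: X between, E outside
            (16, [(2, 7), (3, 6), (10, 15), (11, 14)],
             "ESSHHSSXXSSHHSSE"),
            # closing pair with two child helices -> multi-loop
            (14, [(1, 14), (2, 6), (3, 5), (8, 13), (9, 12)],
             "SSSHSSMSSHHSSS"),
        ],
    )
    def test_examples(self, length, pairs, expected):
        assert classify_loop_types(BasePairSet.from_pairs(length, pairs)) == expected

    def test_matches_tracing_oracle_on_random_nested_structures(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            length = int(rng.integers(1, 80))
            bp = random_nested_pairs(rng, length)
            got = classify_loop_types(bp)
            assert got == loop_type_oracle(length, bp.pairs)

    def test_length_and_paired_positions(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            length = int(rng.integers(5, 120))
            bp = random_nested_pairs(rng, length)
            labels = classify_loop_types(bp)
            assert len(labels) == length
            paired = {p for pair in bp.pairs for p in pair}
            assert {i + 1 for i, ch in enumerate(labels) if ch == "S"} == paired

    @given(stem=st.integers(1, 30), loop=st.integers(1, 30))
    @settings(max_examples=50, deadline=None)
    def test_pure_stem_loop_pattern(self, stem, loop):
        """A stem of s pairs around an l-nt loop labels as S^s H^l S^s."""
        length = 2 * stem + loop
        pairs = [(i, length - i + 1) for i in range(1, stem + 1)]
        labels = classify_loop_types(BasePairSet.from_pairs(length, pairs))
        assert labels == "S" * stem + "H" * loop + "S" * stem
        assert labels == loop_type_oracle(length, pairs)


class TestPseudoknotRemoval:
    def test_keeps_larger_helix(self):
        # helix (1..3) x (10..12) of size 3 crosses pair (5, 15): keep the helix
        pairs = [(1, 12), (2, 11), (3, 10), (5, 15)]
        kept = remove_pseudoknots(BasePairSet.from_pairs(16, pairs))
        assert kept.pairs == frozenset({(1, 12), (2, 11), (3, 10)})

    def test_tie_broken_towards_five_prime(self):
        kept = remove_pseudoknots(BasePairSet.from_pairs(10, [(1, 6), (4, 9)]))
        assert kept.pairs == frozenset({(1, 6)})

    def test_classification_after_removal_is_valid(self):
        bp = BasePairSet.from_pairs(16, [(1, 12), (2, 11), (3, 10), (5, 15)])
        labels = classify_loop_types(bp)
        assert len(labels) == 16
        assert set(labels) <= set("SHMIBXE")

    def test_crossing_pairs_without_removal_error(self):
        bp = BasePairSet.from_pairs(10, [(1, 6), (4, 9)])
        with pytest.raises(StructureError, match="crossing"):
            classify_loop_types(bp, resolve_pseudoknots=False)


class TestSummarizeTertiary:
    def test_single_residue(self):
        t = pd.DataFrame({"asa": [10.0], "cn": [3.0], "hse_up": [1.0], "hse_down": [2.0]})
        s = summarize_tertiary(t)
        assert (s.asa_mean, s.cn_mean, s.hse_up_mean, s.hse_down_mean) == (10, 3, 1, 2)

    def test_mean_of_two(self):
        t = pd.DataFrame({"asa": [0.0, 10.0], "cn": [1, 1], "hse_up": [1, 1], "hse_down": [1, 1]})
        assert summarize_tertiary(t).asa_mean == 5.0

    def test_empty_errors(self):
        with pytest.raises(StructureError):
            summarize_tertiary(pd.DataFrame({"asa": [], "cn": [], "hse_up": [], "hse_down": []}))

    def test_linearity(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame(rng.lognormal(size=(8, 4)), columns=["asa", "cn", "hse_up", "hse_down"])
        s1 = summarize_tertiary(t)
        s3 = summarize_tertiary(t * 3.0)
        assert np.allclose(s3.as_array(), 3.0 * s1.as_array())


def _annotated_pair(rna_seq, rna_ss, prot_seq, prot_ss):
    rna = RnaRecord("r", rna_seq, ss=rna_ss)
    prot = ProteinRecord("p", prot_seq, ss=prot_ss)
    return rna, prot


class TestInterfacePropensity:
    def test_constant_table_gives_constant(self, small_records, uniform_ip):
        rna, prot, _ = small_records
        assert pair_interface_propensity(rna[0], prot[0], uniform_ip) == pytest.approx(1.0)

    def test_single_cell(self, ip_table):
        rna, prot = _annotated_pair("A", "S", "M", "H")
        expected = ip_table.lookup("M", "H", "A", paired=True)
        assert pair_interface_propensity(rna, prot, ip_table) == pytest.approx(expected)

    def test_mean_of_four_cells(self, ip_table):
        rna, prot = _annotated_pair("AG", "SH", "MK", "HE")
        cells = [
            ip_table.lookup(aa, ss, nt, paired=(state == "S"))
            for aa, ss in zip("MK", "HE")
            for nt, state in zip("AG", "SH")
        ]
        assert pair_interface_propensity(rna, prot, ip_table) == pytest.approx(
            np.mean(cells)
        )

    def test_permutation_invariance(self, ip_table):
        rna1, prot1 = _annotated_pair("AGCU", "SHXE", "MKRD", "HECC")
        rna2, prot2 = _annotated_pair("UCGA", "EXHS", "DRKM", "CCEH")
        assert pair_interface_propensity(rna1, prot1, ip_table) == pytest.approx(
            pair_interface_propensity(rna2, prot2, ip_table)
        )

    def test_missing_ss_errors(self, ip_table):
        rna = RnaRecord("r", "ACGU")
        prot = ProteinRecord("p", "MKVL", ss="HHHH")
        with pytest.raises(StructureError):
            pair_interface_propensity(rna, prot, ip_table)


class TestIPTableIO:
    def test_round_trip(self, tmp_path, ip_table):
        path = tmp_path / "ip.tsv"
        ip_table.save(path)
        back = load_ip_table(path)
        assert np.allclose(back.matrix, ip_table.matrix)

    def test_wrong_shape(self, tmp_path, ip_table):
        path = tmp_path / "ip.tsv"
        df = ip_table.to_frame().iloc[:59]
        df.to_csv(path, sep="\t", index_label="row")
        with pytest.raises(StructureError, match="60x8"):
            load_ip_table(path)

    def test_nan_rejected(self, tmp_path, ip_table):
        path = tmp_path / "ip.tsv"
        df = ip_table.to_frame().copy()
        df.iloc[0, 0] = float("nan")
        df.to_csv(path, sep="\t", index_label="row")
        with pytest.raises(StructureError, match="non-finite"):
            load_ip_table(path)

    def test_labels(self):
        assert len(IP_ROW_LABELS) == 60
        assert len(IP_COL_LABELS) == 8


class TestReadCT:
    def test_basic(self, tmp_path):
        path = tmp_path / "ct.tsv"
        rows = ["pos\tpairs_with"]
        pairing = {1: 6, 2: 5, 3: 0, 4: 0, 5: 2, 6: 1}
        rows += [f"{p}\t{q}" for p, q in pairing.items()]
        path.write_text("\n".join(rows) + "\n")
        bp = read_ct_pairs(path)
        assert bp.length == 6
        assert bp.pairs == frozenset({(1, 6), (2, 5)})
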