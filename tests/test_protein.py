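"""Protein-space descriptors: worked examples, invariants, brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bowspace.exceptions import DegenerateLengthError, InvalidInputError
from bowspace.protein import (
    AMINO_ACIDS,
    ELEG,
    EXG,
    GROUPINGS,
    HG,
    PROTEIN_COLUMNS,
    RG,
    SCG,
    ProteinSequence,
    PropertyScaleTable,
    basic_physicochemical,
    composition_moment_vector,
    composition_vector,
    group_composition,
    index_physicochemical,
    neighbourhood_physicochemical,
    protein_feature_block,
    protein_feature_frame,
)

AA_IDX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

sequences = st.text(alphabet=AMINO_ACIDS, min_size=3, max_size=120).map(
    lambda s: ProteinSequence(id="h", residues=s)
)


def seq(residues: str) -> ProteinSequence:
    return ProteinSequence(id="t", residues=residues)


class TestSequenceValidation:
    def test_rejects_empty_and_noncanonical(self):
        with pytest.raises(InvalidInputError):
            ProteinSequence(id="x", residues="")
        with pytest.raises(InvalidInputError):
            ProteinSequence(id="x", residues="ACDX")

    def test_permissive_mode_drops_noncanonical(self):
        s = ProteinSequence.from_raw("x", "ACdXUB", permissive=True)
        assert s.residues == "ACD"

    def test_strict_mode_raises_on_noncanonical(self):
        with pytest.raises(InvalidInputError):
            ProteinSequence.from_raw("x", "ACXU")


class TestCompositionVector:
    @pytest.mark.parametrize("residues, expected", [
        ("AAAA", {"A": 1.0}),
        ("ACDE", {"A": 0.25, "C": 0.25, "D": 0.25, "E": 0.25}),
        ("ACA", {"A": 2 / 3, "C": 1 / 3}),
    ])
    def test_worked_examples(self, residues, expected):
        cv = composition_vector(seq(residues))
        want = np.zeros(20)
        for aa, v in expected.items():
            want[AA_IDX[aa]] = v
        np.testing.assert_allclose(cv, want)

    @given(sequences)
    @settings(max_examples=50, deadline=None)
    def test_sums_to_one(self, s):
        assert composition_vector(s).sum() == pytest.approx(1.0)


class TestCompositionMomentVector:
    def test_first_order_example(self):
        cmv = composition_moment_vector(seq("ACD"), 1)
        want = np.zeros(20)
        want[AA_IDX["A"]], want[AA_IDX["C"]], want[AA_IDX["D"]] = 1 / 6, 2 / 6, 3 / 6
        np.testing.assert_allclose(cmv, want)

    def test_second_order_example(self):
        cmv = composition_moment_vector(seq("ACD"), 2)
        want = np.zeros(20)
        want[AA_IDX["A"]], want[AA_IDX["C"]], want[AA_IDX["D"]] = 1 / 6, 4 / 6, 9 / 6
        np.testing.assert_allclose(cmv, want)

    def test_zero_normalizer_is_degenerate(self):
        with pytest.raises(DegenerateLengthError):
            composition_moment_vector(seq("AA"), 2)

    @given(sequences)
    @settings(max_examples=100, deadline=None)
    def test_order_zero_collapses_to_composition(self, s):
        np.testing.assert_allclose(composition_moment_vector(s, 0),
                                   composition_vector(s), atol=1e-12)


class TestBasicPhysicochemical:
    def test_homodimer_is_twice_residue_value(self, table):
        got = basic_physicochemical(seq("AA"), table)
        np.testing.assert_allclose(got, 2 * table.raw[AA_IDX["A"]])

    def test_concatenation_additivity(self, table, random_sequences):
        s1, s2 = random_sequences[0], random_sequences[1]
        combined = seq(s1.residues + s2.residues)
        np.testing.assert_allclose(
            basic_physicochemical(combined, table),
            basic_physicochemical(s1, table) + basic_physicochemical(s2, table),
            rtol=1e-12,
        )


class TestNeighbourhoodPhysicochemical:
    @pytest.mark.parametrize("residues", ["AAA", "GGGGGGG", "WWWW"])
    def test_zero_on_homopolymers(self, table, residues):
        np.testing.assert_array_equal(
            neighbourhood_physicochemical(seq(residues), table), np.zeros(7)
        )

    def test_single_interior_site(self, table):
        a, c = table.raw[AA_IDX["A"]], table.raw[AA_IDX["C"]]
        np.testing.assert_allclose(
            neighbourhood_physicochemical(seq("ACA"), table), np.abs(c**2 - a * a)
        )

    def test_short_sequence_yields_zero_vector(self, table):
        np.testing.assert_array_equal(
            neighbourhood_physicochemical(seq("AC"), table), np.zeros(7)
        )


def ipc_bruteforce(s: ProteinSequence, table: PropertyScaleTable) -> np.ndarray:
    """Independent O(N^2) direct summation of the lagged squared differences."""
    p = table.standardized[[AA_IDX[r] for r in s.residues], :]
    n = len(s.residues)
    out = np.zeros(p.shape[1])
    for prop in range(p.shape[1]):
        total = 0.0
        for k in range(1, n):
            delta = 0.0
            for i in range(n - k):
                delta += (p[i + k, prop] - p[i, prop]) ** 2
            total += delta / (n - k)
        out[prop] = total / (n - 1)
    return out


class TestIndexPhysicochemical:
    def test_zero_on_homopolymer(self, table):
        np.testing.assert_array_equal(
            index_physicochemical(seq("GGGG"), table), np.zeros(7)
        )

    def test_two_residue_example(self, table):
        got = index_physicochemical(seq("AC"), table)
        want = (table.standardized[AA_IDX["C"]] - table.standardized[AA_IDX["A"]]) ** 2
        np.testing.assert_allclose(got, want)

    def test_nonnegative_and_positive_when_mixed(self, table):
        # A and D differ in the raw value of all seven property scales
        assert (index_physicochemical(seq("ADADAD"), table) > 0).all()
        # A and C share a charge value, so that property stays exactly zero
        got = index_physicochemical(seq("ACACAC"), table)
        assert (got >= 0).all() and got[0] > 0 and got[1] == 0

    def test_matches_bruteforce_oracle(self, table, random_sequences):
        for s in random_sequences:
            np.testing.assert_allclose(
                index_physicochemical(s, table), ipc_bruteforce(s, table),
                atol=1e-10,
            )


class TestGroupings:
    def test_group_tables_cover_expected_universes(self):
        for grouping, n_covered in [(RG, 20), (EXG, 20), (HG, 20), (ELEG, 19)]:
            union = set().union(*grouping.groups)
            assert len(union) == n_covered
        assert "C" not in set().union(*ELEG.groups)

    def test_positively_charged_example(self):
        got = group_composition(seq("HKR"), RG)
        np.testing.assert_allclose(got, [0, 0, 1.0, 0, 0])

    def test_cysteine_is_its_own_exchange_group(self):
        got = group_composition(seq("CCC"), EXG)
        np.testing.assert_allclose(got, [1.0, 0, 0, 0, 0, 0])

    def test_overlapping_side_chain_groups(self):
        got = group_composition(seq("DE"), SCG)
        np.testing.assert_allclose(got, [0, 0, 1.0, 1.0, 1.0, 0])

    def test_unknown_grouping_name(self):
        with pytest.raises(InvalidInputError):
            group_composition(seq("ACD"), "XYZ")

    @given(sequences)
    @settings(max_examples=50, deadline=None)
    def test_partition_groupings_sum_to_one(self, s):
        for grouping in (RG, EXG, HG):
            assert group_composition(s, grouping).sum() == pytest.approx(1.0)
        cv_c = composition_vector(s)[AA_IDX["C"]]
        assert group_composition(s, ELEG).sum() == pytest.approx(1.0 - cv_c)


class TestFeatureBlock:
    def test_length_and_column_header(self, table, random_sequences):
        block = protein_feature_block(random_sequences[0], table)
        assert block.to_array().shape == (107,)
        assert len(PROTEIN_COLUMNS) == 107
        assert PROTEIN_COLUMNS[0] == "cv_A" and PROTEIN_COLUMNS[-1] == "scg_6"

    def test_sub_block_lengths(self, table):
        b = protein_feature_block(seq("ACDEFGHIKLMNPQRSTVWY"), table)
        lengths = [len(b.cv), len(b.cmv1), len(b.cmv2), len(b.bpc), len(b.npc),
                   len(b.ipc), len(b.rg), len(b.eleg), len(b.exg), len(b.hg),
                   len(b.scg)]
        assert lengths == [20, 20, 20, 7, 7, 7, 5, 5, 6, 4, 6]

    def test_deterministic(self, table):
        s = seq("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")
        a = protein_feature_block(s, table).to_array()
        b = protein_feature_block(s, table).to_array()
        np.testing.assert_array_equal(a, b)

    def test_homopolymer_zero_subblocks(self, table):
        b = protein_feature_block(seq("AAAAA"), table)
        np.testing.assert_array_equal(b.npc, np.zeros(7))
        np.testing.assert_array_equal(b.ipc, np.zeros(7))

    def test_too_short_raises(self, table):
        with pytest.raises(DegenerateLengthError):
            protein_feature_block(seq("AC"), table)

    def test_frame_shape_and_index(self, table, random_sequences):
        frame = protein_feature_frame(random_sequences[:5], table)
        assert frame.shape == (5, 107)
        assert list(frame.index) == [s.id for s in random_sequences[:5]]


class TestPropertyTable:
    def test_standardized_has_zero_mean_unit_sd(self, table):
        np.testing.assert_allclose(table.standardized.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(table.standardized.std(axis=0), 1, atol=1e-12)

    def test_csv_roundtrip(self, table, tmp_path):
        path = tmp_path / "scales.csv"
        table.to_csv(path)
        again = PropertyScaleTable.from_csv(path)
        np.testing.assert_allclose(again.raw, table.raw)

    def test_bad_shape_rejected(self):
        with pytest.raises(InvalidInputError):
            PropertyScaleTable(raw=np.ones((19, 7)))

    def test_grouping_registry(self):
        assert set(GROUPINGS) == {"RG", "EleG", "ExG", "HG", "SCG"}
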