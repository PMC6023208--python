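import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from contactforge.contacts import ContactDefinition
from contactforge.decoys import (
    DecoySet,
    RankTable,
    best_method_counts,
    column_median,
    elimination_fraction,
    elimination_fraction_from_sets,
    friedman_paired,
    load_rank_table_fixture,
    rank_native,
    score_structure,
)
from contactforge.errors import InsufficientDataError
from contactforge.potential import AA_ALPHABET, read_potential_csv
from contactforge.synthetic_fixtures import make_compact_chain, make_decoys

import pandas as pd


def _table(data, methods=("m1", "m2")):
    frame = pd.DataFrame(data, columns=list(methods))
    frame.index = [f"p{k}" for k in range(len(frame))]
    return RankTable(frame)


class TestScoreStructure:
    def _uniform_potential(self, overrides=None):
        overrides = overrides or {}
        lines = []
        for ia, a in enumerate(AA_ALPHABET):
            for b in AA_ALPHABET[ia:]:
                lines.append(f"{a},{b},{overrides.get((a, b), 0.0)}")
        return read_potential_csv("\n".join(lines))

    def test_no_contacts_scores_zero(self):
        from contactforge.synthetic_fixtures import make_toy_backbone
        structure = make_toy_backbone("collinear", length=4, spacing=30.0)
        pot = self._uniform_potential({("A", "A"): 5.0})
        assert score_structure(structure, pot, ContactDefinition.any_heavy(), min_separation=2) == 0.0

    def test_zero_potential_scores_zero(self):
        structure = make_compact_chain(seed=1, length=30)
        pot = self._uniform_potential()
        assert score_structure(structure, pot, ContactDefinition.cbeta(), min_separation=2) == 0.0

    def test_hand_sum(self):
        from contactforge.structure_model import Atom, Residue, Structure
        coords = {
            0: ("A", [0.0, 0.0, 0.0]),
            1: ("V", [5.0, 0.0, 0.0]),
            2: ("V", [10.0, 0.0, 0.0]),
        }
        residues = [
            Residue("A", k + 1, "", aa, [Atom("CA", "C", xyz), Atom("CB", "C", xyz)])
            for k, (aa, xyz) in coords.items()
        ]
        structure = Structure("toy", {"A": residues})
        pot = self._uniform_potential({("A", "V"): -0.5, ("V", "V"): 0.2, ("A", "A"): 9.0})
        # contacts at separation >= 2: only (0, 2) = A-V at 10 A: not < 8 -> none
        # use separation 1: pairs (0,1) A-V 5A, (1,2) V-V 5A, (0,2) A-V 10A
        got = score_structure(structure, pot, ContactDefinition.cbeta(), min_separation=1)
        assert got == pytest.approx(-0.5 + 0.2)


class TestRankNative:
    def test_best(self):
        assert rank_native(-5.0, [-4.0, -3.0]) == 1

    def test_tie_uses_min_rank(self):
        assert rank_native(-4.0, [-5.0, -4.0, -3.0]) == 2

    def test_sort_oracle(self):
        rng = np.random.default_rng(0)
        decoys = list(rng.normal(size=100))
        native = sorted(decoys)[6] - 1e-9
        assert rank_native(native, decoys) == 7

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=30), st.floats(-10, 10))
    def test_bounds_and_worse_decoy_invariance(self, decoys, native):
        rank = rank_native(native, decoys)
        assert 1 <= rank <= 1 + len(decoys)
        assert rank_native(native, decoys + [native + 1.0]) == rank


class TestRankTableStats:
    def test_table2_fixture_counts(self):
        table = load_rank_table_fixture("itasser")
        assert len(table) == 56
        assert best_method_counts(table) == {
            "cd": 37, "any_heavy": 4, "cbeta": 10, "centroid": 10}

    def test_table3_fixture_counts(self):
        table = load_rank_table_fixture("rosetta")
        assert len(table) == 59
        assert best_method_counts(table) == {
            "cd": 27, "any_heavy": 7, "cbeta": 17, "centroid": 25}

    def test_single_method_counts_all_rows(self):
        table = _table([[3], [1], [7]], methods=("only",))
        assert best_method_counts(table) == {"only": 3}

    def test_table2_medians(self):
        table = load_rank_table_fixture("itasser")
        assert column_median(table, "cd") == 79.5
        assert column_median(table, "any_heavy") == 297.5
        assert column_median(table, "cbeta") == 244.5
        assert column_median(table, "centroid") == 228.5

    def test_table3_medians(self):
        table = load_rank_table_fixture("rosetta")
        assert [column_median(table, m) for m in ("cd", "any_heavy", "cbeta", "centroid")] \
            == [13, 40, 15, 15]

    def test_even_n_median(self):
        table = _table([[1], [2], [3], [4]], methods=("m",))
        assert column_median(table, "m") == 2.5

    def test_tsv_roundtrip(self):
        table = load_rank_table_fixture("rosetta")
        again = RankTable.from_tsv(table.to_tsv())
        pd.testing.assert_frame_equal(table.frame, again.frame)


class TestFriedman:
    def test_identical_columns(self):
        table = _table([[5, 5], [9, 9], [2, 2], [7, 7]])
        stat, p = friedman_paired(table, "m1", "m2")
        assert stat == 0.0
        assert p == 1.0

    def test_untied_unanimous_closed_form(self):
        n = 56
        table = _table([[k + 1, k + 2] for k in range(n)])
        stat, p = friedman_paired(table, "m1", "m2")
        assert stat == pytest.approx(n)
        assert p == pytest.approx(chi2.sf(n, 1))

    def test_table2_cd_vs_any_heavy_order_of_magnitude(self):
        table = load_rank_table_fixture("itasser")
        _, p = friedman_paired(table, "cd", "any_heavy")
        assert 7.9e-11 < p < 7.9e-9

    def test_insufficient_rows(self):
        table = _table([[1, 2], [2, 1]])
        with pytest.raises(InsufficientDataError):
            friedman_paired(table, "m1", "m2")

    def test_p_decreases_with_more_unanimous_rows(self):
        previous = 1.0
        for n in (8, 16, 32):
            table = _table([[1, 2]] * n)
            _, p = friedman_paired(table, "m1", "m2")
            assert p < previous
            previous = p


class TestEliminationFraction:
    def test_hand_built_presence_matrix(self):
        native = {(0, 5), (1, 7)}
        decoy_sets = [{(0, 5)}, set(), {(1, 7)}, {(0, 5), (1, 7)}]
        assert elimination_fraction_from_sets(native, decoy_sets) == pytest.approx(0.5)

    def test_identical_decoys_eliminate_nothing(self):
        native = make_compact_chain(seed=2, length=30)
        decoy_set = make_decoys(native, n=3, perturbation=0.0, seed=0)
        value = elimination_fraction(decoy_set, ContactDefinition.cbeta(min_separation=2))
        assert value == 0.0

    def test_disjoint_decoys_eliminate_everything(self):
        native = {(0, 5), (2, 9)}
        assert elimination_fraction_from_sets(native, [{(3, 8)}, set()]) == 1.0

    def test_bounds_and_order_invariance_random(self):
        native = make_compact_chain(seed=3, length=25)
        decoy_set = make_decoys(native, n=6, perturbation=2.0, seed=1)
        value = elimination_fraction(decoy_set, ContactDefinition.cbeta(min_separation=2))
        assert 0.0 <= value <= 1.0
        reordered = DecoySet(decoy_set.protein_id, decoy_set.native,
                             list(reversed(decoy_set.decoys)))
        assert elimination_fraction(reordered, ContactDefinition.cbeta(min_separation=2)) \
            == pytest.approx(value)


def test_perturbation_controls_elimination():
    native = make_compact_chain(seed=4, length=30)
    values = []
    for sigma in (0.1, 1.0, 3.0):
        decoy_set = make_decoys(native, n=8, perturbation=sigma, seed=2)
        values.append(elimination_fraction(decoy_set, ContactDefinition.cbeta(min_separation=2)))
    assert values[0] < values[2]


def test_scoring_pipeline_end_to_end():
    # derive a potential from synthetic structures, then score a native
    # against coordinate-perturbed decoys and rank it
    from contactforge.potential import count_contacts, derive_potential

    native = make_compact_chain(seed=6, length=40)
    db = [make_compact_chain(seed=100 + k, length=40) for k in range(5)]
    counts = count_contacts(db, ContactDefinition.cbeta(), min_separation=2)
    potential = derive_potential(counts)
    decoy_set = make_decoys(native, n=10, perturbation=6.0, seed=3)
    definition = ContactDefinition.cbeta(min_separation=2)
    native_score = score_structure(native, potential, definition)
    decoy_scores = [score_structure(d, potential, definition) for d in decoy_set.decoys]
    assert 1 <= rank_native(native_score, decoy_scores) <= 11
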