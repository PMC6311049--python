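"""Inverse index construction, candidate lookup, attribution, and the
brute-force oracle equivalence."""

import dataclasses

import numpy as np
import pytest

from egfr_discordance import (
    ComparisonPolicy,
    ParameterGrid,
    attribute_pair,
    attribute_pair_bruteforce,
    build_inverse_index,
    candidates_for_value,
    categorize_explanation,
    match_count,
    mdrd_egfr,
    round_to_precision,
)
from egfr_discordance.attribution import (
    AttributionResult,
    CandidateCombo,
    explanation_super_category,
)
from egfr_discordance.cohort import CohortRow
from egfr_discordance.concordance import build_pair
from egfr_discordance.egfr import Gender, RaceDetail
from tests.conftest import make_snapshot


def pair_for(automated, snapshot):
    row = CohortRow(snapshot=snapshot, automated_egfr=automated)
    return build_pair(row)


def rounded_mdrd(age, scr, female=False, black=False):
    return round_to_precision(mdrd_egfr(age, scr, female, black), 0.1)


class TestIndexConstruction:
    def test_total_combo_count(self, full_index):
        # 103 ages x 2 genders x 2 races x 2991 Scr steps
        assert full_index.n_in_clip + full_index.n_out_of_clip == 1_232_292

    def test_min_key_is_one_point_zero(self, full_index):
        assert full_index.keys.min() == 10  # 1.0 in tenths

    def test_clip_respected(self, full_index):
        assert full_index.keys.max() <= 2510
        assert np.all((full_index.oc_keys < 10) | (full_index.oc_keys > 2510))

    def test_singleton_grid(self):
        g = ParameterGrid(age_min=60, age_max=60, scr_min=1.10, scr_max=1.10)
        idx = build_inverse_index(g)
        assert idx.n_in_clip + idx.n_out_of_clip == 4  # 2 genders x 2 races

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            ParameterGrid(age_min=50, age_max=40)
        with pytest.raises(ValueError):
            ParameterGrid(scr_step=-0.01)

    def test_drop_out_of_clip_flag(self, reduced_grid):
        idx = build_inverse_index(reduced_grid, drop_out_of_clip=True)
        assert idx.n_out_of_clip == 0


class TestCandidateLookup:
    def test_self_membership(self, full_index):
        q = rounded_mdrd(60, 1.10)
        combos = candidates_for_value(full_index, q)
        assert any(c.age == 60 and not c.female and not c.black
                   and abs(c.scr - 1.10) < 1e-9 for c in combos)

    def test_below_minimum_is_empty(self, full_index):
        assert candidates_for_value(full_index, 0.5) == []

    def test_all_candidates_reproduce_query(self, full_index):
        q = rounded_mdrd(45, 0.95, female=True)
        for c in candidates_for_value(full_index, q):
            assert rounded_mdrd(c.age, c.scr, c.female, c.black) == pytest.approx(q)


class TestMatchCount:
    def test_counts(self):
        cur = make_snapshot(age=60, scr=1.10)
        full = CandidateCombo(60, False, False, 1.10, 68.3)
        assert match_count(full, cur) == 4
        assert match_count(dataclasses.replace(full, age=42), cur) == 3
        assert match_count(dataclasses.replace(full, age=42, black=True), cur) == 2

    def test_scr_tolerance(self):
        cur = make_snapshot(scr=1.10)
        near = CandidateCombo(60, False, False, 1.104, 68.3)
        far = CandidateCombo(60, False, False, 1.11, 68.3)
        assert match_count(near, cur) == 4
        assert match_count(far, cur) == 3


class TestAttributePair:
    def test_concordant_pair_is_match(self, full_index):
        snap = make_snapshot(age=60, scr=1.10)
        pair = pair_for(rounded_mdrd(60, 1.10), snap)
        r = attribute_pair(pair, snap, full_index)
        assert r.status == "match" and r.mismatch_sets == frozenset()

    def test_age_change_recovered(self, full_index):
        # the automated value was computed when the record said age 60;
        # the record now says 42
        snap = make_snapshot(age=42, scr=1.10)
        pair = pair_for(rounded_mdrd(60, 1.10), snap)
        r = attribute_pair(pair, snap, full_index)
        assert r.status == "explained"
        assert frozenset({"age"}) in r.mismatch_sets
        assert r.max_match_count == 3

    def test_gender_change_recovered(self, full_index):
        snap = make_snapshot(age=60, scr=1.10, female=False)
        pair = pair_for(rounded_mdrd(60, 1.10, female=True), snap)
        r = attribute_pair(pair, snap, full_index)
        assert r.status == "explained"
        assert frozenset({"gender"}) in r.mismatch_sets

    def test_race_change_recovered(self, full_index):
        snap = make_snapshot(age=60, scr=1.10, black=False)
        pair = pair_for(rounded_mdrd(60, 1.10, black=True), snap)
        r = attribute_pair(pair, snap, full_index)
        assert r.status == "explained"
        assert frozenset({"race"}) in r.mismatch_sets

    def test_off_grid_snapshot_unexplained(self, full_index):
        snap = make_snapshot(age=60, scr=1.105)  # off the 0.01 lattice
        pair = pair_for(rounded_mdrd(60, 1.50), snap)
        r = attribute_pair(pair, snap, full_index)
        assert r.status == "unexplained" and r.reason == "off_grid"

    def test_unattainable_value_unexplained(self, reduced_index):
        # 0.5 lies below every value attainable on the reduced grid
        snap = make_snapshot(age=30, scr=1.00)
        pair = pair_for(0.5, snap)
        r = attribute_pair(pair, snap, reduced_index)
        assert r.status == "unexplained" and r.reason == "no_candidates"

    def test_soundness_of_explanations(self, full_index):
        snap = make_snapshot(age=42, scr=1.10)
        pair = pair_for(rounded_mdrd(60, 1.10), snap)
        attribute_pair(pair, snap, full_index)
        for c in candidates_for_value(full_index, pair.automated_report):
            assert rounded_mdrd(c.age, c.scr, c.female, c.black) == \
                pytest.approx(pair.automated_report)


class TestOracleEquivalence:
    def _random_cases(self, grid, n, seed):
        rng = np.random.default_rng(seed)
        cases = []
        scrs = grid.scr_values
        for _ in range(n):
            # "then" record that produced the automated value
            then_age = int(rng.integers(grid.age_min, grid.age_max + 1))
            then_scr = float(rng.choice(scrs))
            then_f, then_b = bool(rng.random() < 0.5), bool(rng.random() < 0.5)
            auto = rounded_mdrd(then_age, then_scr, then_f, then_b)
            # current record: possibly drifted
            cur_age = int(rng.integers(grid.age_min, grid.age_max + 1))
            cur_scr = float(rng.choice(scrs))
            cur_f, cur_b = bool(rng.random() < 0.5), bool(rng.random() < 0.5)
            snap = make_snapshot(age=cur_age, scr=cur_scr, female=cur_f,
                                 black=cur_b)
            cases.append((pair_for(auto, snap), snap))
        return cases

    def test_indexed_equals_bruteforce(self, reduced_grid, reduced_index):
        for pair, snap in self._random_cases(reduced_grid, 500, seed=1234):
            a = attribute_pair(pair, snap, reduced_index)
            b = attribute_pair_bruteforce(pair, snap, reduced_grid)
            assert a.status == b.status
            assert a.max_match_count == b.max_match_count
            assert a.mismatch_sets == b.mismatch_sets
            assert a.category_label == b.category_label

    def test_no_candidate_beats_max_match(self, reduced_grid, reduced_index):
        # minimality: brute-force scan confirms m* is the true maximum
        for pair, snap in self._random_cases(reduced_grid, 50, seed=77):
            a = attribute_pair(pair, snap, reduced_index)
            if a.status != "explained":
                continue
            best = 0
            for c in candidates_for_value(reduced_index, pair.automated_report):
                best = max(best, match_count(c, snap))
            assert best == a.max_match_count


def result_with_sets(sets, status="explained"):
    return AttributionResult(
        pair_id="P", status=status, max_match_count=3,
        mismatch_sets=frozenset(frozenset(s) for s in sets),
        definitive=len(sets) == 1, category_label=None,
        abs_value_difference=1.0,
    )


class TestCategorize:
    @pytest.mark.parametrize(
        "sets,label",
        [
            ([{"age"}], "Age"),
            ([{"race"}], "Race"),
            ([{"gender"}], "Gender"),
            ([{"scr"}], "1 clinical"),
            ([{"age", "race"}], "2 demographics"),
            ([{"age", "scr"}], "1 demographic 1 clinical"),
            ([{"age"}, {"race"}], "Race or age"),
            ([{"gender"}, {"age"}], "Gender or age"),
            ([{"race"}, {"gender"}], "Race or gender"),
            ([{"race"}, {"gender"}, {"age"}], "Race, gender, or age"),
            ([{"scr"}, {"age"}], "Scr or age"),
            ([{"scr"}, {"race"}, {"age"}], "Scr, race, or age"),
        ],
    )
    def test_labels(self, sets, label):
        assert categorize_explanation(result_with_sets(sets)) == label

    @pytest.mark.parametrize(
        "sets,super_label",
        [
            ([{"age"}], "1 demographic"),
            ([{"age"}, {"race"}], "1 demographic"),
            ([{"scr"}], "1 clinical"),
            ([{"age", "gender"}], "2 demographics"),
            ([{"race", "scr"}], "1 demographic 1 clinical"),
        ],
    )
    def test_super_categories(self, sets, super_label):
        assert explanation_super_category(result_with_sets(sets)) == super_label

    def test_match_rejected(self):
        with pytest.raises(ValueError):
            categorize_explanation(result_with_sets([], status="match"))

    def test_prefer_demographic_strategy(self, full_index):
        # when an Scr set ties with a pure demographic set, the optional
        # strategy keeps only the demographic explanation
        snap = make_snapshot(age=42, scr=1.10)
        pair = pair_for(rounded_mdrd(60, 1.10), snap)
        dis = attribute_pair(pair, snap, full_index, tie_strategy="disjunction")
        pref = attribute_pair(pair, snap, full_index,
                              tie_strategy="prefer-demographic")
        assert all("scr" not in s for s in pref.mismatch_sets)
        assert pref.mismatch_sets <= dis.mismatch_sets
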