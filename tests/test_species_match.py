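import numpy as np
import pytest

from fireflash.species_match import (
    FLYING_MALE_TABLE,
    MatchPolicy,
    MatchResult,
    SpeciesReference,
    activity_timecourse,
    assign_species,
    compare_groups,
    composition,
    default_references,
    load_references,
    match_fraction,
    summarize,
)
from fireflash.synth import flying_profile, matched_truncnorm
from fireflash.video_io import InputError


class TestSummarize:
    def test_order_statistics_with_full_coverage(self):
        s = summarize(range(1, 11), coverage=1.0)
        assert (s.range_lo, s.range_hi) == (1, 10)
        assert s.median == 5.5
        assert s.n == 10

    def test_degenerate_constant_sample(self):
        s = summarize([0.7] * 12)
        for field in ("mean", "median", "q1", "q3", "range_lo", "range_hi"):
            assert getattr(s, field) == pytest.approx(0.7)
        assert s.sd == pytest.approx(0.0, abs=1e-12)

    def test_ninety_percent_span_trims_five_percent_per_tail(self):
        pts = np.arange(1, 101, dtype=float)  # 1..100
        s = summarize(pts, coverage=0.90)
        assert s.range_lo == pytest.approx(np.quantile(pts, 0.05))
        assert s.range_hi == pytest.approx(np.quantile(pts, 0.95))
        inside = (pts >= s.range_lo) & (pts <= s.range_hi)
        assert inside.mean() == pytest.approx(0.90, abs=0.02)

    def test_recovers_packaged_fi_median(self):
        # 129 draws from the flying A. cerata FI profile: sample median
        # within 2 SE (~1.25 sd/sqrt(n)) of the published 0.88 s
        p = flying_profile("A. cerata")
        dist = matched_truncnorm(p.fi_mean, p.fi_sd, p.fi_lo, p.fi_hi)
        pts = dist.rvs(size=129, random_state=np.random.default_rng(42))
        s = summarize(pts)
        se_median = 1.2533 * dist.std() / np.sqrt(129)
        assert abs(s.median - 0.88) <= 2 * se_median + 0.01

    def test_empty_input_is_an_error(self):
        with pytest.raises(InputError):
            summarize([])


class TestMatchFraction:
    @pytest.mark.parametrize(
        "points,rng,expected",
        [
            ([0.7, 0.8, 0.9, 1.0], (0.6, 1.2), 1.0),
            ([0.5, 0.7], (0.6, 1.2), 0.5),
            ([0.6], (0.6, 1.2), 1.0),  # boundary points count (inclusive)
            ([1.2], (0.6, 1.2), 1.0),
            ([0.59999], (0.6, 1.2), 0.0),
        ],
    )
    def test_inclusive_interval_fraction(self, points, rng, expected):
        assert match_fraction(points, rng) == pytest.approx(expected)

    def test_widening_a_range_never_lowers_the_fraction(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 2, size=50)
        fracs = [match_fraction(pts, (0.8 - w, 1.2 + w)) for w in np.linspace(0, 1, 9)]
        assert fracs == sorted(fracs)


def refs_abc():
    return [
        SpeciesReference("A", fi_lo=0.6, fi_hi=1.2, fd_lo=0.1, fd_hi=0.29),
        SpeciesReference("B", fi_lo=0.42, fi_hi=0.53, fd_lo=0.07, fd_hi=0.15),
        SpeciesReference("C", fi_lo=0.07, fi_hi=0.41, fd_lo=0.03, fd_hi=0.2),
    ]


class TestAssignSpecies:
    def test_matching_rule_truth_table(self):
        refs = refs_abc()
        # >50% for A, <=50% for the others -> A
        pts = [0.8] * 8 + [2.0] * 2
        assert assign_species(pts, refs).assignment == "A"
        # two species above 50% (overlapping ranges) -> unmatched
        refs_overlap = [
            SpeciesReference("A", 0.5, 1.0, 0.1, 0.2),
            SpeciesReference("B", 0.5, 1.0, 0.1, 0.2),
        ]
        assert assign_species([0.7] * 10, refs_overlap).assignment == "unmatched"
        # nothing above 50% -> unmatched
        pts = [0.8] * 5 + [2.0] * 5
        assert assign_species(pts, refs).assignment == "unmatched"

    def test_exactly_half_is_not_enough(self):
        refs = refs_abc()
        res = assign_species([0.8, 0.8, 2.0, 2.0], refs)
        assert res.fractions["A"] == 0.5
        assert res.assignment == "unmatched"

    def test_sparse_flasher_is_excluded_not_unmatched(self):
        refs = refs_abc()
        res = assign_species(
            [0.8] * 6, refs, event_times=np.arange(6) * 5.0,  # 6 flashes, 25 s span
        )
        assert res.assignment == "excluded"
        # same points, dense enough within a 10 s window
        res = assign_species(
            [0.8] * 7, refs, event_times=np.arange(7) * 0.9,
        )
        assert res.assignment == "A"

    def test_invariant_to_point_and_reference_order(self):
        refs = refs_abc()
        rng = np.random.default_rng(2)
        pts = list(rng.uniform(0.6, 1.2, size=9)) + [2.0]
        a = assign_species(pts, refs).assignment
        b = assign_species(pts[::-1], list(reversed(refs))).assignment
        assert a == b == "A"

    def test_disjoint_fi_ranges_always_separate_two_species(self):
        # packaged flying FI ranges: 0.6-1.2 vs 0.42-0.53 are disjoint
        refs = default_references()
        rng = np.random.default_rng(3)
        for lo, hi, name in [(0.6, 1.2, "A. cerata"), (0.42, 0.53, "L. kagiana")]:
            for _ in range(20):
                pts = rng.uniform(lo, hi, size=10)
                assert assign_species(pts, refs).assignment == name


class TestComposition:
    @staticmethod
    def results(counts):
        out = []
        for name, k in counts.items():
            out += [MatchResult(f"{name}{i}", {}, name, "FI", 10) for i in range(k)]
        return out

    def test_case_study_percentages(self):
        comp = composition(
            self.results({"A. cerata": 56, "L. kagiana": 10, "unmatched": 12})
        )
        pct = dict(zip(comp["assignment"], comp["percent"]))
        assert pct == {"A. cerata": 72, "L. kagiana": 13, "unmatched": 15}
        assert comp["count"].sum() == 78

    def test_single_species_is_hundred_percent(self):
        comp = composition(self.results({"A. cerata": 7}))
        assert comp["percent"].tolist() == [100]

    def test_raw_fractions_sum_to_one(self):
        comp = composition(
            self.results({"A. cerata": 13, "L. kagiana": 5, "unmatched": 3})
        )
        assert comp["fraction"].sum() == pytest.approx(1.0)

    def test_excluded_individuals_kept_out_of_the_denominator(self):
        results = self.results({"A. cerata": 3, "excluded": 2})
        comp = composition(results)
        row = comp[comp["assignment"] == "A. cerata"].iloc[0]
        assert row["percent"] == 100
        assert comp[comp["assignment"] == "excluded"]["count"].iloc[0] == 2


class TestActivityTimecourse:
    @staticmethod
    def result(name, t, behavior="flying"):
        r = MatchResult(f"{name}-{t}", {}, name, "FI", 10)
        r.t_first = t
        r.behavior = behavior
        return r

    def test_no_individuals_gives_all_zero_bins(self):
        tc = activity_timecourse([], bin_width=60.0)
        assert tc.counts.to_numpy().sum() == 0

    def test_species_switch_splits_active_periods(self):
        # species A active before t=600, species B after: recovered periods split
        results = [self.result("A", t) for t in np.arange(0, 580, 45)] + [
            self.result("B", t) for t in np.arange(620, 1100, 60)
        ]
        tc = activity_timecourse(results, bin_width=60.0)
        a_lo, a_hi = tc.active_period("A")
        b_lo, b_hi = tc.active_period("B")
        assert a_hi <= 600.0
        assert b_lo >= 600.0

    def test_bin_totals_conserve_individuals(self):
        rng = np.random.default_rng(4)
        results = [self.result("A", float(t)) for t in rng.uniform(0, 900, 37)]
        tc = activity_timecourse(results, bin_width=120.0)
        assert tc.counts.to_numpy().sum() == 37


class TestCompareGroups:
    def test_identical_groups_give_zero_statistic(self):
        stat, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert stat == pytest.approx(0.0)

    def test_separated_groups_are_significant(self):
        stat, p = compare_groups([0, 0, 0, 1], [10, 10, 10, 11])
        # closed form: means 0.25/10.25, each var 0.25 -> t = -10/sqrt(0.125)
        assert stat == pytest.approx(-10 / np.sqrt(0.125))
        assert p < 0.001

    def test_swapping_groups_flips_the_sign(self):
        a, b = [0.5, 0.9, 0.7], [2.0, 2.2, 1.9, 2.4]
        s1, p1 = compare_groups(a, b)
        s2, p2 = compare_groups(b, a)
        assert s1 == pytest.approx(-s2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_equal_constants_give_p_one(self):
        stat, p = compare_groups([1.0, 1.0], [1.0, 1.0])
        assert (stat, p) == (0.0, 1.0)

    def test_too_small_groups_are_an_error(self):
        with pytest.raises(InputError):
            compare_groups([1.0], [1.0, 2.0])


def test_reference_file_round_trip(tmp_path):
    import json

    entries = [
        {"species": r.species, "pulse_form": r.pulse_form,
         "fi_lo": r.fi_lo, "fi_hi": r.fi_hi, "fd_lo": r.fd_lo, "fd_hi": r.fd_hi,
         "provenance": "packaged flying-male table"}
        for r in default_references()
    ]
    path = tmp_path / "refs.json"
    path.write_text(json.dumps({"species": entries}))
    back = load_references(path)
    assert [r.species for r in back] == list(FLYING_MALE_TABLE)
    assert back[0].range("FI") == (0.6, 1.2)
    assert back[1].pulse_form == "triple"
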