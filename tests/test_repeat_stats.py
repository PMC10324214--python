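import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from repeatscape.io_formats import RepeatRecord
from repeatscape.repeat_stats import (
    ShapeLabel,
    TESubclass,
    classify_landscape_shape,
    classify_te,
    compute_landscape,
    compute_te_totals,
    diversity_profile,
    shannon_index,
    simpson_index,
)
from repeatscape.synthetic_data import SimulationConfig, TEPlan, simulate_genome


def _rec(pct_div, span, family="LINE/L1", begin=1, query="chr1", rid=1):
    return RepeatRecord(
        sw_score=100, pct_div=pct_div, pct_del=0.0, pct_ins=0.0,
        query_id=query, q_begin=begin, q_end=begin + span - 1, strand="+",
        repeat_name="rep", class_family=family, record_id=rid,
    )


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("LINE/L1", TESubclass.LINE),
        ("SINE/tRNA", TESubclass.SINE),
        ("LTR/Gypsy", TESubclass.LTR),
        ("DNA/hAT-Charlie", TESubclass.DNA),
        ("DNA?/hAT", TESubclass.DNA),
        ("RC/Helitron", TESubclass.ROLLING_CIRCLE),
        ("Satellite", TESubclass.SATELLITE),
        ("Simple_repeat", TESubclass.SIMPLE),
        ("Low_complexity", TESubclass.LOW_COMPLEXITY),
        ("Unknown", TESubclass.UNKNOWN),
        ("Unspecified", TESubclass.UNKNOWN),
        ("ARTEFACT", TESubclass.OTHER),
        ("LTR?", TESubclass.LTR),
    ],
)
def test_classify_te_is_total_and_strips_question_marks(raw, expected):
    assert classify_te(raw) is expected


class TestTotals:
    def test_single_line_record(self):
        totals = compute_te_totals([_rec(1.0, 500)], 10_000)
        row = totals.set_index("subclass").loc["LINE"]
        assert row.bp == 500
        assert row.pct_of_genome == 5.0

    def test_empty_records_all_zero(self):
        totals = compute_te_totals([], 1000)
        assert (totals.bp == 0).all()

    def test_identical_overlapping_records_merge_mode(self):
        recs = [_rec(1.0, 500, rid=1), _rec(1.0, 500, rid=2)]
        plain = compute_te_totals(recs, 10_000)
        merged = compute_te_totals(recs, 10_000, merge_overlaps=True)
        assert plain.set_index("subclass").loc["LINE"].bp == 1000
        assert merged.set_index("subclass").loc["LINE"].bp == 500

    def test_record_beyond_genome_length_rejected(self):
        with pytest.raises(ValueError, match="beyond genome"):
            compute_te_totals([_rec(1.0, 500, begin=9900)], 10_000)


class TestLandscape:
    def test_single_record_lands_in_floor_bin(self):
        ls = compute_landscape([_rec(3.4, 500)], 10_000)
        col = ls.subclasses.index(TESubclass.LINE)
        assert ls.coverage[3, col] == 5.0
        assert ls.coverage.sum() == 5.0

    def test_no_records_zero_matrix(self):
        ls = compute_landscape([], 10_000)
        assert not ls.coverage.any()

    def test_divergence_at_max_div_dropped_and_counted(self):
        ls = compute_landscape([_rec(50.0, 100)], 10_000)
        assert ls.n_dropped == 1
        assert not ls.coverage.any()

    def test_bin_totals_reconcile_with_totals(self):
        rng = np.random.default_rng(5)
        fams = ["LINE/L1", "LTR/Gypsy", "DNA/hAT", "SINE/tRNA", "Unknown"]
        recs = [
            _rec(float(rng.uniform(0, 55)), int(rng.integers(50, 500)),
                 family=fams[int(rng.integers(len(fams)))], rid=i)
            for i in range(200)
        ]
        ls = compute_landscape(recs, 1_000_000)
        totals = compute_te_totals(recs, 1_000_000).set_index("subclass")
        for sub in TESubclass:
            kept = sum(r.span for r in recs
                       if classify_te(r.class_family) is sub and r.pct_div < 50)
            assert ls.subclass_total(sub) == pytest.approx(100 * kept / 1e6)
            dropped_bp = totals.loc[sub.name].bp - kept
            assert dropped_bp >= 0

    def test_invalid_genome_length_rejected(self):
        with pytest.raises(ValueError):
            compute_landscape([], 0)


class TestShapeClassification:
    def _landscape_with_peaks(self, peak_bins, width=3.0):
        recs = []
        rid = 0
        for b in peak_bins:
            for offset in (-1, 0, 0, 1):  # triangular peak
                rid += 1
                recs.append(_rec(b + offset + 0.5, 500, rid=rid))
        return compute_landscape(recs, 100_000)

    def test_single_recent_peak_is_l_shaped(self):
        shape = classify_landscape_shape(self._landscape_with_peaks([2]))
        assert shape.label is ShapeLabel.L_SHAPED

    def test_two_peaks_are_bimodal(self):
        shape = classify_landscape_shape(self._landscape_with_peaks([4, 30]))
        assert shape.label is ShapeLabel.BIMODAL

    def test_three_peaks_are_multi_peaked(self):
        shape = classify_landscape_shape(self._landscape_with_peaks([3, 18, 33]))
        assert shape.label is ShapeLabel.MULTI_PEAKED

    def test_single_old_peak_is_unimodal_old(self):
        shape = classify_landscape_shape(self._landscape_with_peaks([25]))
        assert shape.label is ShapeLabel.UNIMODAL_OLD

    def test_all_zero_landscape_rejected(self):
        with pytest.raises(ValueError, match="no coverage"):
            classify_landscape_shape(compute_landscape([], 1000))

    def test_planted_cohorts_recover_expected_shapes(self):
        bimodal = simulate_genome(SimulationConfig(
            seed=21, genome_length=450_000,
            te_plan=(TEPlan("young", "LINE/L1", 100, 3.0, 1000),
                     TEPlan("old", "LTR/Gypsy", 100, 30.0, 1000)),
        ))
        ls = compute_landscape(bimodal.repeats, bimodal.genome.length)
        assert classify_landscape_shape(ls).label is ShapeLabel.BIMODAL

        recent = simulate_genome(SimulationConfig(
            seed=22, genome_length=200_000,
            te_plan=(TEPlan("young", "LINE/L1", 100, 2.0, 1000),),
        ))
        ls = compute_landscape(recent.repeats, recent.genome.length)
        assert classify_landscape_shape(ls).label is ShapeLabel.L_SHAPED


class TestDiversityIndices:
    def test_simpson_known_values(self):
        assert simpson_index([100]) == 0.0
        assert simpson_index([40, 30, 20, 10]) == pytest.approx(
            1 - 2900 / 9900
        )

    def test_simpson_limit_four_equal_counts(self):
        assert simpson_index([10**9] * 4) == pytest.approx(0.75, abs=1e-6)

    def test_simpson_undefined_below_two(self):
        with pytest.raises(ValueError, match="undefined"):
            simpson_index([1])

    def test_simpson_matches_resampling_oracle(self):
        counts = [40, 30, 20, 10]
        rng = np.random.default_rng(17)
        pool = np.repeat(np.arange(4), counts)
        draws = rng.choice(len(pool), size=(200_000, 2), replace=True)
        ok = draws[:, 0] != draws[:, 1]
        diff = pool[draws[ok, 0]] != pool[draws[ok, 1]]
        assert simpson_index(counts) == pytest.approx(diff.mean(), abs=5e-3)

    def test_shannon_known_values(self):
        assert shannon_index([100]) == 0.0
        assert shannon_index([25, 25, 25, 25]) == pytest.approx(math.log(4))
        assert shannon_index([50, 25, 25]) == pytest.approx(1.5 * math.log(2))

    def test_shannon_bounded_by_log_richness(self):
        counts = [5, 10, 0, 85]
        assert 0 <= shannon_index(counts) <= math.log(3)

    def test_shannon_undefined_for_empty_community(self):
        with pytest.raises(ValueError):
            shannon_index([0, 0])

    @given(st.permutations([40, 30, 20, 10]))
    def test_indices_permutation_invariant(self, counts):
        ref = [40, 30, 20, 10]
        assert simpson_index(counts) == pytest.approx(simpson_index(ref), abs=1e-12)
        assert shannon_index(counts) == pytest.approx(shannon_index(ref), abs=1e-12)

    def test_profile_uses_four_subclasses_only(self):
        recs = [
            _rec(1, 400, "LINE/L1", rid=1),
            _rec(1, 300, "LTR/Gypsy", rid=2),
            _rec(1, 200, "DNA/hAT", rid=3),
            _rec(1, 100, "SINE/tRNA", rid=4),
            _rec(1, 999, "RC/Helitron", rid=5),  # excluded by default
        ]
        prof = diversity_profile(recs)
        assert prof.total_bp == 1000
        assert prof.simpson == pytest.approx(simpson_index([400, 300, 200, 100]))
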