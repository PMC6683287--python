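import math

import numpy as np
import pytest
from scipy.stats import chisquare

from phageome.calibration import (
    CutoffCurve,
    FRAGMENT_SIZES,
    FragmentTooLarge,
    LabelledPair,
    calibrate_database,
    calibrate_per_size,
    concordance_cutoff,
    cutoff_for_size,
    fit_cutoff_curve,
    fragment_genome,
    fragment_pairs,
    whole_genome_pairs,
)
from phageome.simulate import make_reference_db
from phageome.wgrr import InputError

from conftest import make_repertoire
from oracles import bruteforce_concordance_cutoff, grid_search_rss


class TestConcordanceCutoff:
    def test_all_same_label_returns_min_wgrr(self):
        pairs = [LabelledPair(w, True) for w in (5.0, 40.0, 17.0)]
        assert concordance_cutoff(pairs) == 5.0

    def test_all_different_labels_unattainable(self):
        pairs = [LabelledPair(w, False) for w in (10.0, 90.0)]
        assert concordance_cutoff(pairs) is None

    def test_planted_threshold_recovered(self):
        # >= 50: 20 concordant pairs; below 50: 1-in-4 concordance, so any
        # lower candidate dilutes cumulative concordance under 95%
        pairs = [LabelledPair(50.0 + i, True) for i in range(20)]
        for value in range(10, 50, 2):
            pairs.append(LabelledPair(float(value), True))
            pairs.extend(LabelledPair(float(value), False) for _ in range(3))
        assert concordance_cutoff(pairs, 0.95) == 50.0
        assert bruteforce_concordance_cutoff(pairs, 0.95) == 50.0

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            n = int(rng.integers(1, 200))
            pairs = [
                LabelledPair(float(np.round(rng.uniform(0, 100), 1)),
                             bool(rng.uniform() < 0.6))
                for _ in range(n)
            ]
            target = float(rng.choice([0.5, 0.8, 0.95, 1.0]))
            assert concordance_cutoff(pairs, target) == \
                bruteforce_concordance_cutoff(pairs, target)

    def test_monotone_in_target(self):
        rng = np.random.default_rng(8)
        pairs = [
            LabelledPair(float(rng.uniform(0, 100)), bool(rng.uniform() < 0.7))
            for _ in range(300)
        ]
        previous = -math.inf
        for target in (0.5, 0.7, 0.9, 0.99, 1.0):
            cutoff = concordance_cutoff(pairs, target)
            value = math.inf if cutoff is None else cutoff
            assert value >= previous
            previous = value

    def test_empty_pairs_rejected(self):
        with pytest.raises(InputError, match="at least one"):
            concordance_cutoff([])


class TestFragmentGenome:
    def test_full_genome_is_single_window(self):
        rep = make_repertoire("P", 5)
        frag = fragment_genome(rep, 5, 0)
        assert frag.protein_ids == rep.protein_ids
        assert frag.start == 0

    def test_deterministic_given_seed(self):
        rep = make_repertoire("P", 60)
        first = fragment_genome(rep, 10, 123)
        second = fragment_genome(rep, 10, 123)
        assert first == second

    def test_window_is_contiguous(self):
        rep = make_repertoire("P", 40)
        rng = np.random.default_rng(3)
        for _ in range(50):
            frag = fragment_genome(rep, 7, rng)
            assert frag.protein_ids == rep.protein_ids[frag.start:frag.start + 7]

    def test_oversized_fragment_raises_skip_signal(self):
        with pytest.raises(FragmentTooLarge):
            fragment_genome(make_repertoire("P", 4), 5, 0)

    def test_start_positions_uniform(self):
        # 20-gene phage, size 5 -> 16 valid starts
        rep = make_repertoire("P", 20)
        rng = np.random.default_rng(42)
        starts = [fragment_genome(rep, 5, rng).start for _ in range(10_000)]
        observed = np.bincount(starts, minlength=16)
        assert chisquare(observed).pvalue > 0.01


class TestCalibratePerSize:
    def test_planted_two_family_separation(self, ref_db, hit_table):
        rng = np.random.default_rng(101)
        for size in (5, 15, 30):
            pairs = fragment_pairs(ref_db.phages, hit_table, "family",
                                   size, 1, rng)
            cutoff = concordance_cutoff(pairs)
            within = [p.wgrr for p in pairs if p.same_label]
            between = [p.wgrr for p in pairs if not p.same_label]
            assert max(between) < cutoff <= min(within)

    def test_cutoffs_present_for_all_attainable_sizes(self, ref_db, hit_table):
        cutoffs = calibrate_per_size(ref_db.phages, hit_table, "family",
                                     sizes=(5, 10, 20), seed=1)
        assert set(cutoffs) == {5, 10, 20}
        assert all(50 < c <= 100 for c in cutoffs.values())

    def test_full_genome_size_equals_whole_genome_cutoff(self):
        db = make_reference_db(genes_per_phage=(12, 12), seed=21)
        table = db.hit_table()
        per_size = calibrate_per_size(db.phages, table, "family",
                                      sizes=(12,), seed=4)
        whole = concordance_cutoff(whole_genome_pairs(db.phages, table, "family"))
        assert per_size[12] == pytest.approx(whole)

    def test_single_family_cutoff_is_min_observed(self):
        db = make_reference_db(n_families=1, phages_per_family=6, seed=3)
        table = db.hit_table()
        rng = np.random.default_rng(0)
        pairs = fragment_pairs(db.phages, table, "family", 10, 1, rng)
        assert all(p.same_label for p in pairs)
        cutoff = concordance_cutoff(pairs)
        assert cutoff == pytest.approx(min(p.wgrr for p in pairs))

    def test_missing_attribute_rejected(self, ref_db, hit_table):
        with pytest.raises(InputError, match="lacks attribute"):
            calibrate_per_size(ref_db.phages, hit_table, "genome_size",
                               sizes=(5,))

    def test_sizes_larger_than_every_genome_skipped(self, ref_db, hit_table):
        cutoffs = calibrate_per_size(ref_db.phages, hit_table, "family",
                                     sizes=(5, 500), seed=1)
        assert 500 not in cutoffs


class TestFitCutoffCurve:
    def test_noiseless_parameter_recovery(self):
        alpha, beta, gamma = 30.0, 0.1, 3.0
        data = {x: alpha * math.exp(-beta * x) + gamma for x in FRAGMENT_SIZES}
        fit = fit_cutoff_curve(data)
        assert fit.alpha == pytest.approx(alpha, abs=1e-6)
        assert fit.beta == pytest.approx(beta, abs=1e-6)
        assert fit.gamma == pytest.approx(gamma, abs=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_flat_data_degenerates_to_constant(self):
        fit = fit_cutoff_curve({x: 7.0 for x in (5, 10, 20, 40)})
        assert fit.gamma == pytest.approx(7.0, abs=1e-6)
        assert fit.alpha == pytest.approx(0.0, abs=1e-6)

    def test_noisy_fit_beats_grid_search_oracle(self):
        rng = np.random.default_rng(77)
        xs = np.array(FRAGMENT_SIZES, float)
        ys = 30.0 * np.exp(-0.1 * xs) + 3.0 + rng.normal(0, 0.5, len(xs))
        fit = fit_cutoff_curve(dict(zip(FRAGMENT_SIZES, ys)))
        oracle_rss = grid_search_rss(xs, ys)
        assert fit.rss <= oracle_rss * 1.01

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError, match=">= 3"):
            fit_cutoff_curve({5: 30.0, 10: 20.0})

    def test_none_cutoffs_excluded_from_fit(self):
        data = {5: 30.0, 10: 20.0, 20: None, 40: 8.0}
        fit = fit_cutoff_curve(data)
        assert math.isfinite(fit.rss)


class TestCutoffForSize:
    def test_constant_curve(self):
        curve = CutoffCurve("db", "family", alpha=0.0, beta=1.0, gamma=5.2)
        assert cutoff_for_size(curve, 7) == pytest.approx(5.2)
        assert cutoff_for_size(curve, 300) == pytest.approx(5.2)

    def test_hand_evaluated_point(self):
        curve = CutoffCurve("db", "family", alpha=30.0, beta=0.1, gamma=3.0)
        assert cutoff_for_size(curve, 5) == pytest.approx(
            30.0 * math.exp(-0.5) + 3.0
        )

    def test_strictly_decreasing_for_positive_parameters(self):
        curve = CutoffCurve("db", "family", alpha=30.0, beta=0.1, gamma=3.0)
        thresholds = [cutoff_for_size(curve, x) for x in FRAGMENT_SIZES]
        assert all(a > b for a, b in zip(thresholds, thresholds[1:]))

    def test_floored_at_zero(self):
        curve = CutoffCurve("db", "family", alpha=-50.0, beta=0.01, gamma=1.0)
        assert cutoff_for_size(curve, 5) == 0.0

    def test_invalid_size_rejected(self):
        curve = CutoffCurve("db", "family", alpha=1.0, beta=0.1, gamma=0.0)
        with pytest.raises(InputError):
            cutoff_for_size(curve, 0)


class TestCalibrateDatabase:
    def test_curve_serialization_round_trip(self, ref_db, hit_table):
        curve = calibrate_database(ref_db.phages, hit_table, "family",
                                   "phage_ref", sizes=(5, 10, 20, 40), seed=2)
        restored = CutoffCurve.from_dict(curve.to_dict())
        assert restored == curve

    def test_held_out_fragments_meet_target(self, ref_db, hit_table):
        """Calibrated per-size cutoffs classify unseen fragments correctly."""
        sizes = (5, 10, 20)
        per_size = calibrate_per_size(ref_db.phages, hit_table, "family",
                                      sizes=sizes, seed=6)
        rng = np.random.default_rng(1234)
        correct = total = 0
        for _ in range(60):
            phage = ref_db.phages[int(rng.integers(len(ref_db.phages)))]
            size = int(rng.choice(sizes))
            if size > phage.repertoire.n_proteins:
                continue
            frag = fragment_genome(phage.repertoire, size, rng)
            frep = frag.to_repertoire()
            best_value, best_family = -1.0, None
            from phageome.wgrr import wgrr_between
            for other in ref_db.phages:
                if other.phage_id == phage.phage_id:
                    continue
                score = wgrr_between(frep, other.repertoire, hit_table,
                                     source_a=phage.phage_id)
                if score.value > best_value:
                    best_value, best_family = score.value, other.family
            total += 1
            if best_value >= per_size[size] and best_family == phage.family:
                correct += 1
        assert total > 0
        assert correct / total >= 0.95
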