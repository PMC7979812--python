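import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from readscan.interest_mapping import assign_fixations, build_interest_areas
from readscan.preprocess import clean_trial, derive_saccades
from readscan.saccade_taxonomy import (CATEGORIES, TaxonomyConfig,
                                       classify_saccades,
                                       detect_line_initial,
                                       polar_histogram, saccade_angle)
from readscan.synthetic_data import (control_profile, dyslexia_profile,
                                     generate_layout, simulate_trial)

from _oracles import brute_classify
from conftest import make_trial, seeds_for


class TestSaccadeAngle:
    def test_rightward_is_zero(self):
        assert saccade_angle(10, 0) == 0.0

    def test_screen_downward_is_minus_ninety(self):
        assert saccade_angle(0, 10) == -90.0

    def test_screen_upward_is_plus_ninety(self):
        assert saccade_angle(0, -10) == 90.0

    def test_leftward_is_one_eighty(self):
        assert saccade_angle(-10, 0) == 180.0

    @given(st.floats(-500, 500), st.floats(-500, 500))
    @settings(deadline=None, max_examples=200)
    def test_reversal_symmetry(self, dx, dy):
        if dx == 0 and dy == 0:
            return
        a = saccade_angle(dx, dy)
        b = saccade_angle(-dx, -dy)
        diff = (a - b) % 360.0
        assert diff == pytest.approx(180.0, abs=1e-9)
        assert -180.0 < a <= 180.0

    def test_zero_displacement_rejected(self):
        with pytest.raises(ValueError):
            saccade_angle(0, 0)


def classify_simulated(layout, areas, profile, seed):
    trial = simulate_trial(layout, profile, seed=seed)
    cleaned, _ = clean_trial(trial)
    assigned = assign_fixations(cleaned, areas)
    return cleaned, assigned, classify_saccades(cleaned, assigned, layout)


class TestSweepDetection:
    def _sweep_trial(self, layout, launch_word, land_word, corrective=None):
        """Fixations: mid-line, launch, landing (+ optional corrective)."""
        line0_mid = layout.words[launch_word].word_index - 1
        points = [layout.words[line0_mid].center,
                  layout.words[launch_word].center,
                  layout.words[land_word].center]
        if corrective is not None:
            points.append(layout.words[corrective].center)
        fixes = [(1000 + 300 * i, 1200 + 300 * i, x, y)
                 for i, (x, y) in enumerate(points)]
        return derive_saccades(make_trial(fixes, duration=10_000))

    def test_line_final_to_next_line_start_is_return_sweep(self, layout150,
                                                           areas150):
        first1, last0 = layout150.line_word_span(1)[0], \
            layout150.line_word_span(0)[1]
        trial = self._sweep_trial(layout150, last0, first1)
        assigned = assign_fixations(trial, areas150)
        labels = classify_saccades(trial, assigned, layout150)
        assert labels[1].category == "return_sweep"

    def test_launch_four_words_from_end_is_not_return_sweep(self, layout150,
                                                            areas150):
        last0 = layout150.line_word_span(0)[1]
        first1 = layout150.line_word_span(1)[0]
        trial = self._sweep_trial(layout150, last0 - 3, first1)
        assigned = assign_fixations(trial, areas150)
        labels = classify_saccades(trial, assigned, layout150)
        assert labels[1].category != "return_sweep"

    def test_mid_landing_with_corrective_is_undersweep(self, layout150,
                                                       areas150):
        last0 = layout150.line_word_span(0)[1]
        first1 = layout150.line_word_span(1)[0]
        trial = self._sweep_trial(layout150, last0, first1 + 5,
                                  corrective=first1)
        assigned = assign_fixations(trial, assigned_areas := areas150)
        labels = classify_saccades(trial, assigned, layout150)
        assert labels[1].category == "undersweep"

    def test_generator_sweeps_and_undersweeps_recovered(self, layout150,
                                                        areas150):
        """Recall 1.0 against generator bookkeeping (blink-free trials)."""
        profile = dyslexia_profile(blink_rate=0.0, deviation_rate=0.0)
        for seed in seeds_for(25, label=31):
            trial, truth = simulate_trial(layout150, profile, seed=seed,
                                          return_truth=True)
            cleaned, _ = clean_trial(trial)
            assigned = assign_fixations(cleaned, areas150)
            labels = classify_saccades(cleaned, assigned, layout150)
            counts = Counter(lb.category for lb in labels)
            assert counts["return_sweep"] == truth.n_return_sweeps
            assert counts["undersweep"] == truth.n_undersweeps


class TestDirectionalDeviations:
    def test_straight_down_mid_line_is_deviation(self, layout150, areas150):
        w = layout150.words[3]
        fixes = [(1000, 1200, *w.center),
                 (1225, 1500, w.center[0], w.center[1] + 60),
                 (1525, 1800, w.center[0] + 150, w.center[1])]
        trial = derive_saccades(make_trial(fixes, duration=10_000))
        assigned = assign_fixations(trial, areas150)
        labels = classify_saccades(trial, assigned, layout150)
        assert labels[0].angle == pytest.approx(-90.0)
        assert labels[0].category == "directional_deviation"

    def test_blink_during_vertical_saccade_excludes_it(self, layout150,
                                                       areas150):
        w = layout150.words[3]
        fixes = [(1000, 1200, *w.center),
                 (1325, 1600, w.center[0], w.center[1] + 60)]
        trial = derive_saccades(make_trial(fixes, blinks=[(1220, 1300)],
                                           duration=10_000))
        assigned = assign_fixations(trial, areas150)
        labels = classify_saccades(trial, assigned, layout150)
        assert labels[0].category == "blink_adjacent"

    def test_band_bounds_inclusive_at_35_and_145(self, layout150, areas150):
        w = layout150.words[3]
        for angle, expected in [(34.9, "forward"), (35.0, "directional_deviation"),
                                (145.0, "directional_deviation"),
                                (145.1, "other"), (-35.0, "directional_deviation")]:
            dx = 80 * math.cos(math.radians(angle))
            dy = -80 * math.sin(math.radians(angle))
            fixes = [(1000, 1200, *w.center),
                     (1225, 1500, w.center[0] + dx, w.center[1] + dy)]
            trial = derive_saccades(make_trial(fixes, duration=10_000))
            assigned = assign_fixations(trial, areas150)
            labels = classify_saccades(trial, assigned, layout150)
            assert labels[0].category == expected, angle


class TestPartitionAndOracle:
    def test_every_saccade_gets_exactly_one_category(self, layout150,
                                                     areas150):
        for seed in seeds_for(10, label=41):
            cleaned, assigned, labels = classify_simulated(
                layout150, areas150, dyslexia_profile(), seed)
            assert len(labels) == len(cleaned.saccades)
            assert all(lb.category in CATEGORIES for lb in labels)

    def test_matches_brute_force_on_randomized_trials(self, layout150,
                                                      areas150):
        """Full-classifier equivalence on >= 10^4 simulated saccades."""
        total = 0
        cfg = TaxonomyConfig()
        for seed in seeds_for(60, label=43):
            profile = dyslexia_profile() if seed % 2 else control_profile()
            cleaned, assigned, labels = classify_simulated(
                layout150, areas150, profile, seed)
            expected = brute_classify(cleaned, assigned, layout150, cfg)
            assert [lb.category for lb in labels] == expected
            total += len(labels)
        assert total >= 10_000


class TestLineInitial:
    def test_sweep_landing_with_rightward_continuation_qualifies(
            self, layout150, areas150):
        profile = control_profile(undersweep_prob=0.0, blink_rate=0.0,
                                  deviation_rate=0.0, regression_prob=0.0,
                                  refixation_prob=0.0, skip_prob=0.0)
        trial = simulate_trial(layout150, profile, seed=2)
        cleaned, _ = clean_trial(trial)
        assigned = assign_fixations(cleaned, areas150)
        li = detect_line_initial(cleaned, assigned, layout150)
        # a perfect reading trial yields one line-initial per line
        assert len(li) == layout150.line_count
        assert sorted(x.line_index for x in li) == list(
            range(layout150.line_count))

    def test_corrective_to_the_left_disqualifies(self, layout150, areas150):
        first1 = layout150.line_word_span(1)[0]
        w1 = layout150.words[first1 + 1]   # second word of line 1
        w0 = layout150.words[first1]
        nxt = layout150.words[first1 + 3]
        fixes = [(1000, 1200, *layout150.words[2].center),
                 (1225, 1500, *w1.center),     # lands on word 2 of the line
                 (1525, 1800, *w0.center),     # leftward within the line
                 (1825, 2100, *nxt.center)]
        trial = derive_saccades(make_trial(fixes, duration=10_000))
        assigned = assign_fixations(trial, areas150)
        li = detect_line_initial(trial, assigned, layout150)
        assert all(x.line_index != 1 for x in li)

    def test_line_initial_durations_exceed_trial_median(self, layout150,
                                                        areas150):
        """With a positive line-initial inflation the detected line-initial
        fixations are longer than the trial median in expectation."""
        gaps = []
        for seed in seeds_for(40, label=47):
            trial = simulate_trial(layout150, dyslexia_profile(), seed=seed)
            cleaned, _ = clean_trial(trial)
            assigned = assign_fixations(cleaned, areas150)
            li = detect_line_initial(cleaned, assigned, layout150)
            if not li:
                continue
            med = np.median([f.duration for f in cleaned.fixations])
            gaps.append(np.median([x.duration for x in li]) - med)
        assert np.mean(gaps) > 0


class TestPolarHistogram:
    def test_empty_input_all_zero(self):
        edges, counts = polar_histogram([])
        assert counts.sum() == 0
        assert len(edges) == len(counts) + 2  # two concatenated bands

    def test_ten_deviations_at_minus_ninety_in_single_bin(self):
        _, counts = polar_histogram([-90.0] * 10)
        assert counts.max() == 10 and counts.sum() == 10

    def test_counts_sum_to_number_of_deviations(self):
        rng = np.random.default_rng(5)
        angles = np.concatenate([rng.uniform(35, 145, 40),
                                 rng.uniform(-145, -35, 60)])
        _, counts = polar_histogram(angles)
        assert counts.sum() == 100

    def test_downward_mode_fills_downward_half(self, layout150, areas150):
        angles = []
        for seed in seeds_for(60, label=53):
            cleaned, assigned, labels = classify_simulated(
                layout150, areas150, dyslexia_profile(), seed)
            angles.extend(lb.angle for lb in labels
                          if lb.category == "directional_deviation")
        edges, counts = polar_histogram(angles)
        half = len(counts) // 2
        assert counts[:half].sum() > counts[half:].sum()  # negative band
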