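"""Synthetic cohort generator: determinism, chain dynamics, calibration."""

import numpy as np
import pytest

from somnoscore.concordance import cohort_concordance, collapse_hypnogram
from somnoscore.epoch_data import clean_default_runs
from somnoscore.scoring import ScoringConfig, score_sleep_wake
from somnoscore.simulate import (SimulationConfig, generate_activity,
                                 generate_cohort, generate_hypnogram, write_cohort)
from somnoscore.summary import summarize_night


def stationary_distribution(transition):
    """Left eigenvector oracle for the chain's long-run stage occupancy."""
    vals, vecs = np.linalg.eig(transition.T)
    i = np.argmin(np.abs(vals - 1.0))
    pi = np.real(vecs[:, i])
    return pi / pi.sum()


class TestHypnogram:
    def test_determinism_same_seed_and_index(self):
        cfg = SimulationConfig(seed=9)
        h1 = generate_hypnogram(cfg, 3)
        h2 = generate_hypnogram(cfg, 3)
        np.testing.assert_array_equal(h1.stages, h2.stages)
        h3 = generate_hypnogram(cfg, 4)
        assert not np.array_equal(h1.stages, h3.stages)

    def test_absorbing_state_degenerate_chain(self):
        t = np.zeros((5, 5))
        t[:, 2] = 1.0  # everything jumps to N2 and stays
        cfg = SimulationConfig(stage_transition=t,
                               initial_stage_dist=np.array([0, 0, 1.0, 0, 0]))
        h = generate_hypnogram(cfg, 0)
        assert (h.stages == "N2").all()

    def test_invalid_transition_matrix_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(stage_transition=np.ones((5, 5)))

    def test_long_run_wake_fraction_matches_stationary_oracle(self):
        base = SimulationConfig()
        pi = stationary_distribution(base.stage_transition)
        # start the chain at stationarity so per-night wake fraction is unbiased
        cfg = SimulationConfig(initial_stage_dist=pi, seed=21)
        fracs = [np.mean(generate_hypnogram(cfg, p).stages == "W") for p in range(50)]
        se = np.std(fracs, ddof=1) / np.sqrt(50)
        assert abs(np.mean(fracs) - pi[0]) <= 2 * se + 1e-9


class TestActivity:
    def test_separable_parameters_give_separable_counts(self):
        cfg = SimulationConfig(burst_prob=0.0, quiet_wake_prob=0.0,
                               wake_count_mean=1000.0, wake_count_sigma=1e-9, seed=2)
        h = generate_hypnogram(cfg, 0)
        a = generate_activity(h, cfg, 0)
        pad = cfg.default_pad_minutes
        core = a.counts[pad:-pad]
        wake_min = collapse_hypnogram(h).states == 0
        np.testing.assert_allclose(core[wake_min], 1000.0, rtol=1e-6)
        np.testing.assert_array_equal(core[~wake_min], 0.0)

    def test_padding_removed_by_default_cleaning(self):
        cfg = SimulationConfig(default_pad_minutes=5, seed=2)
        h = generate_hypnogram(cfg, 0)
        a = generate_activity(h, cfg, 0)
        assert (a.counts[:5] == 20).all() and (a.counts[-5:] == 20).all()
        cleaned, removed = clean_default_runs(a, min_run=5)
        assert cleaned.missing_mask[:5].all() and cleaned.missing_mask[-5:].all()
        assert removed >= 10

    def test_wake_count_mean_law_of_large_numbers(self):
        # all-wake hypnogram gives ~1e4 moving wake draws over a few nights
        t = np.zeros((5, 5))
        t[:, 0] = 1.0
        cfg = SimulationConfig(stage_transition=t,
                               initial_stage_dist=np.array([1.0, 0, 0, 0, 0]),
                               quiet_wake_prob=0.0, night_minutes=2500, seed=8)
        h = generate_hypnogram(cfg, 0)
        a = generate_activity(h, cfg, 0)
        pad = cfg.default_pad_minutes
        draws = a.counts[pad:-pad]
        assert draws.size >= 2500
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - cfg.wake_count_mean) <= 3 * se


class TestCohort:
    def test_empty_cohort(self):
        assert generate_cohort(SimulationConfig(n_participants=0)) == []

    def test_csv_export_byte_identical_across_runs(self, tmp_path):
        cfg = SimulationConfig(n_participants=2, night_minutes=60, seed=5)
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        write_cohort(generate_cohort(cfg), d1)
        write_cohort(generate_cohort(cfg), d2)
        for f in sorted(d1.iterdir()):
            assert f.read_bytes() == (d2 / f.name).read_bytes().replace(
                str(d2).encode(), str(d1).encode())

    def test_calibration_matches_cohort_sleep_architecture(self):
        """Cohort mean TST within the target band (478 +/- 75 min) and mean
        WASO near 21 min on the default configuration, n = 50 nights."""
        cfg = SimulationConfig(n_participants=50, seed=1)
        tst, waso = [], []
        for _, h in generate_cohort(cfg):
            s = summarize_night(collapse_hypnogram(h))
            tst.append(s.tst_min)
            waso.append(s.waso_min)
        assert 478 - 75 <= np.mean(tst) <= 478 + 75
        assert abs(np.mean(waso) - 21) <= 10

    def test_pipeline_smoke_sensitivity_exceeds_specificity(self):
        """Sleep-dominant nights with quiet wake: scoring at threshold 10
        detects sleep much better than wake, as in real actigraphy."""
        cfg = SimulationConfig(n_participants=5, seed=4)
        pairs = []
        for a, h in generate_cohort(cfg):
            cleaned, _ = clean_default_runs(a)
            pairs.append((collapse_hypnogram(h),
                          score_sleep_wake(cleaned, ScoringConfig(10))))
        c = cohort_concordance(pairs)
        assert c.pooled.sensitivity > c.pooled.specificity
        assert c.pooled.sensitivity > 0.9

    def test_separability_limit_accuracy_approaches_one(self):
        # with fully separated count distributions the only residual errors
        # are the kernel-spillover minutes flanking each (sparse) wake bout
        cfg = SimulationConfig(n_participants=3, burst_prob=0.0, quiet_wake_prob=0.0,
                               wake_count_mean=1e6, wake_count_sigma=0.1, seed=6)
        pairs = []
        for a, h in generate_cohort(cfg):
            cleaned, _ = clean_default_runs(a)
            pairs.append((collapse_hypnogram(h),
                          score_sleep_wake(cleaned, ScoringConfig(10))))
        c = cohort_concordance(pairs)
        assert c.pooled.specificity == 1.0
        assert c.pooled.accuracy > 0.93


def mechanism_config(quiet_wake_prob, seed=0):
    """Wake-rich configuration used to probe the quiet-wake mechanism: more,
    shorter wake bouts concentrate the realized quiet-minute fraction."""
    t = np.array([
        [0.800, 0.180, 0.020, 0.000, 0.000],
        [0.030, 0.690, 0.260, 0.005, 0.015],
        [0.018, 0.020, 0.891, 0.050, 0.021],
        [0.015, 0.003, 0.060, 0.917, 0.005],
        [0.020, 0.030, 0.060, 0.004, 0.886],
    ])
    return SimulationConfig(n_participants=20, stage_transition=t,
                            quiet_wake_prob=quiet_wake_prob, seed=seed)


def test_quiet_wake_fraction_depresses_specificity_by_about_q():
    """Making a fraction q of wake minutes motionless lowers specificity by
    ~q while sleep scoring is untouched: the quiet-wakefulness failure mode."""

    def run(q):
        pairs = []
        for a, h in generate_cohort(mechanism_config(q, seed=13)):
            cleaned, _ = clean_default_runs(a)
            pairs.append((collapse_hypnogram(h),
                          score_sleep_wake(cleaned, ScoringConfig(10))))
        c = cohort_concordance(pairs)
        return c.pooled.sensitivity, c.pooled.specificity

    sens0, spec0 = run(0.0)
    sens4, spec4 = run(0.4)
    assert abs((spec0 - spec4) - 0.4) <= 0.05
    assert abs(sens4 - sens0) <= 0.02
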