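"""Generator contracts: schedules, determinism, heterogeneity semantics."""

import numpy as np
import pytest

import wearaffect as wa
from wearaffect.synth import (
    BASE_MEAN,
    CohortSizingError,
    state_conditional_means,
    subject_signature,
)

TABLE_RANGES = {  # per-participant class-distribution ranges being emulated, %
    0: (51.8, 54.0),
    1: (29.0, 31.8),
    2: (16.3, 17.4),
}


def _block_runs(labels):
    """(state, length) runs of a label vector."""
    change = np.flatnonzero(np.diff(labels)) + 1
    bounds = np.concatenate([[0], change, [len(labels)]])
    return [
        (int(labels[a]), int(b - a)) for a, b in zip(bounds[:-1], bounds[1:])
    ]


class TestStateSchedule:
    def test_exact_fraction_rounding_single_block(self):
        cfg = wa.CohortConfig(
            sampling_rate=1.0,
            duration=1000.0,
            class_fractions=(0.53, 0.30, 0.17),
            n_blocks_per_state=1,
        )
        labels = wa.make_state_schedule(cfg, np.random.default_rng(0))
        counts = np.bincount(labels, minlength=3)
        assert counts.tolist() in ([530, 300, 170], sorted([530, 300, 170]))
        assert sorted(counts.tolist()) == [170, 300, 530]
        runs = _block_runs(labels)
        assert len(runs) == 3  # one contiguous block per state

    def test_equal_thirds(self):
        cfg = wa.CohortConfig(
            sampling_rate=1.0,
            duration=99.0,
            class_fractions=(1 / 3, 1 / 3, 1 / 3),
            n_blocks_per_state=1,
        )
        labels = wa.make_state_schedule(
            cfg, np.random.default_rng(1), min_block_samples=1
        )
        runs = _block_runs(labels)
        assert [n for _, n in runs] == [33, 33, 33]

    def test_default_fractions_inside_emulated_ranges(self):
        cfg = wa.CohortConfig(sampling_rate=32.0, duration=600.0)
        labels = wa.make_state_schedule(cfg, np.random.default_rng(2))
        counts = np.bincount(labels, minlength=3)
        pct = 100.0 * counts / counts.sum()
        for cls, (lo, hi) in TABLE_RANGES.items():
            assert lo <= pct[cls] <= hi

    def test_blocks_contiguous_and_counted(self):
        cfg = wa.CohortConfig(sampling_rate=32.0, duration=600.0, n_blocks_per_state=2)
        labels = wa.make_state_schedule(cfg, np.random.default_rng(3))
        runs = _block_runs(labels)
        # adjacent blocks of the same state may merge in a shuffle; never more
        # runs than blocks requested
        assert len(runs) <= 3 * 2
        per_state = {s: sum(n for st, n in runs if st == s) for s in range(3)}
        assert sum(per_state.values()) == cfg.n_samples

    def test_too_short_names_minimum(self):
        cfg = wa.CohortConfig(sampling_rate=32.0, duration=10.0)
        with pytest.raises(CohortSizingError, match="at least"):
            wa.make_state_schedule(cfg, np.random.default_rng(0))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"heterogeneity": -0.1},
            {"class_fractions": (0.5, 0.5, 0.2)},
            {"class_fractions": (1.0, 0.0, 0.0)},
            {"ar_coefficient": 1.0},
            {"noise_sd": -1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            wa.CohortConfig(**kwargs)


class TestCohortGeneration:
    def test_unique_ids_and_shared_rate(self, small_cohort, small_config):
        assert len(small_cohort.recordings) == small_config.n_participants
        assert len(set(small_cohort.participant_ids)) == small_config.n_participants

    def test_bit_identical_regeneration(self, small_config):
        a = wa.generate_cohort(small_config)
        b = wa.generate_cohort(small_config)
        for ra, rb in zip(a.recordings, b.recordings):
            np.testing.assert_array_equal(ra.signals, rb.signals)
            np.testing.assert_array_equal(ra.labels, rb.labels)

    def test_seeds_change_noise(self, small_config):
        a = wa.generate_cohort(small_config)
        b = wa.generate_cohort(small_config.replace(seed=small_config.seed + 1))
        assert not np.allclose(a.recordings[0].signals, b.recordings[0].signals)

    def test_labels_and_signals_aligned(self, small_cohort):
        for rec in small_cohort.recordings:
            assert rec.signals.shape == (8, rec.labels.shape[0])


class TestHeterogeneity:
    def test_eta_zero_equalizes_state_means(self):
        cfg = wa.CohortConfig(
            n_participants=3,
            sampling_rate=32.0,
            duration=300.0,
            heterogeneity=0.0,
            seed=5,
        )
        cohort = wa.generate_cohort(cfg)
        means = np.stack([state_conditional_means(r) for r in cohort.recordings])
        # state-conditional expected means equal across participants up to
        # noise: n_eff per state >= fraction * n / tau with AR(1) tau ~ 9
        spread = means.std(axis=0)
        assert spread.max() < 0.15

    def test_monte_carlo_recovers_subject_means(self):
        # eta=2, noise 0.5: empirical state means match base + eta*delta
        cfg = wa.CohortConfig(
            n_participants=2,
            sampling_rate=32.0,
            duration=600.0,
            heterogeneity=2.0,
            noise_sd=0.5,
            seed=11,
        )
        cohort = wa.generate_cohort(cfg)
        root = np.random.SeedSequence(cfg.seed)
        streams = root.spawn(cfg.n_participants)
        for i, rec in enumerate(cohort.recordings):
            _, delta_ss, _, _ = streams[i].spawn(4)
            delta = subject_signature(delta_ss, cfg)
            expected = BASE_MEAN + cfg.heterogeneity * delta
            observed = state_conditional_means(rec)
            counts = np.bincount(rec.labels, minlength=3).astype(float)
            # AR(1) inflates the SE of a mean by sqrt((1+a)/(1-a))
            tau = (1 + cfg.ar_coefficient) / (1 - cfg.ar_coefficient)
            se = cfg.noise_sd * np.sqrt(tau / counts)[:, None]
            # sinusoid partial cycles add at most ~amp/(freq*T) per channel;
            # allow 3 SE plus that deterministic remainder
            slack = 3 * se + 0.05
            assert np.all(np.abs(observed - expected) < slack)

    def test_between_participant_variance_nondecreasing_in_eta(self):
        spreads = []
        for eta in (0.0, 1.0, 2.0):
            cfg = wa.CohortConfig(
                n_participants=6,
                sampling_rate=32.0,
                duration=240.0,
                heterogeneity=eta,
                seed=21,  # same seed: same noise realizations across etas
            )
            cohort = wa.generate_cohort(cfg)
            means = np.stack(
                [state_conditional_means(r) for r in cohort.recordings]
            )
            spreads.append(means.var(axis=0).mean())
        assert spreads[0] <= spreads[1] <= spreads[2]

    def test_noise_free_signal_is_step_function_plus_sinusoid(self):
        cfg = wa.CohortConfig(
            n_participants=1,
            sampling_rate=32.0,
            duration=120.0,
            heterogeneity=0.0,
            noise_sd=0.0,
            seed=2,
        )
        rec = wa.generate_cohort(cfg).recordings[0]
        # temperature-like channel has amplitude 0.05 and near-zero frequency:
        # within a state its value stays within the sinusoid band of the mean
        temp = rec.signals[4]
        for s in range(3):
            mask = rec.labels == s
            assert np.all(np.abs(temp[mask] - BASE_MEAN[s, 4]) <= 0.05 * 1.4 + 1e-9)


class TestRecordingContainer:
    def test_roundtrip(self, small_cohort, tmp_path):
        from wearaffect.io import load_cohort, save_cohort

        save_cohort(small_cohort, tmp_path)
        back = load_cohort(tmp_path)
        assert back.participant_ids == small_cohort.participant_ids
        np.testing.assert_array_equal(
            back.recordings[0].signals, small_cohort.recordings[0].signals
        )
        np.testing.assert_array_equal(
            back.recordings[0].labels, small_cohort.recordings[0].labels
        )
        assert back.recordings[0].sampling_rate == 32.0

    def test_yaml_config_roundtrip(self, small_config, tmp_path):
        from wearaffect.io import load_configs, save_configs

        mc = wa.ModelConfig(base_channels=8, fc_hidden=32)
        tc = wa.TrainConfig(max_epochs=60, seed=3)
        path = tmp_path / "config.yaml"
        save_configs(path, small_config, mc, tc)
        cohort_cfg, model_cfg, train_cfg = load_configs(path)
        assert cohort_cfg == small_config
        assert model_cfg == mc
        assert train_cfg == tc
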