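"""The synthetic-data generators: determinism, calibration, recovery hooks."""

import numpy as np
import pytest

from conftest import small_worm_config
from wormscreen.imaging import SegmentationConfig, segment_stack
from wormscreen.rtquic import call_plate, compute_threshold
from wormscreen.simulate import (
    CorpusSimConfig,
    RtQuicSimConfig,
    WormSimConfig,
    simulate_corpus,
    simulate_rtquic_plate,
    simulate_worm_recording,
)


class TestWormSimulator:
    def test_no_coil_states_when_probability_zero(self):
        _, truth = simulate_worm_recording(small_worm_config(coil_prob=0, turn_prob=0, n_frames=10))
        assert truth.true_coil_fraction == 0.0

    def test_always_coiled_when_probability_one(self):
        _, truth = simulate_worm_recording(small_worm_config(coil_prob=1.0, turn_prob=0.0, n_frames=10))
        assert truth.true_coil_fraction == 1.0

    def test_coil_fraction_within_binomial_bound(self):
        """10 worms x 720 frames at coil_prob 0.05: within 3 binomial SE."""
        config = small_worm_config(coil_prob=0.05, turn_prob=0.0, n_frames=720, seed=17)
        _, truth = simulate_worm_recording(config)
        se = np.sqrt(0.05 * 0.95 / 7200)
        assert abs(truth.true_coil_fraction - 0.05) < 3 * se

    def test_same_seed_reproduces_recording(self):
        a_stack, a_truth = simulate_worm_recording(small_worm_config(n_frames=6))
        b_stack, b_truth = simulate_worm_recording(small_worm_config(n_frames=6))
        assert np.array_equal(a_stack.frames, b_stack.frames)
        assert np.array_equal(a_truth.posture, b_truth.posture)
        assert np.array_equal(a_truth.centroids, b_truth.centroids)

    def test_centroids_inside_arena(self, mixed_recording):
        config, _, truth = mixed_recording
        w, h = config.arena
        assert truth.centroids[..., 0].min() >= 0
        assert truth.centroids[..., 0].max() <= w
        assert truth.centroids[..., 1].min() >= 0
        assert truth.centroids[..., 1].max() <= h

    def test_coil_fraction_unbiased_over_seeds(self):
        """Mean ground-truth coil fraction tracks coil_prob within 3 SE."""
        p = 0.2
        n_seeds, n_worms, n_frames = 20, 5, 60
        fractions = []
        for seed in range(n_seeds):
            config = small_worm_config(
                n_worms=n_worms, n_frames=n_frames, coil_prob=p, turn_prob=0.0, seed=seed
            )
            _, truth = simulate_worm_recording(config)
            fractions.append(truth.true_coil_fraction)
        se = np.sqrt(p * (1 - p) / (n_seeds * n_worms * n_frames))
        assert abs(np.mean(fractions) - p) < 3 * se

    def test_rendered_posture_circularity_regimes(self, mixed_recording):
        """Over >= 100 rendered worm-frames, coil silhouettes score > 0.6
        and sinusoidal ones < 0.4."""
        config, stack, truth = mixed_recording
        seg = SegmentationConfig(worm_length=config.worm_length, worm_width=config.worm_width)
        matched = {"sinusoidal": [], "turn": [], "coil": []}
        for j, dets in enumerate(segment_stack(stack, seg)):
            for d in dets:
                dist = np.linalg.norm(truth.centroids[:, j] - np.array(d.centroid), axis=1)
                i = int(dist.argmin())
                if dist[i] < config.worm_length / 4:
                    matched[truth.posture[i, j]].append(d.circularity)
        assert sum(len(v) for v in matched.values()) >= 100
        assert max(matched["sinusoidal"]) < 0.4
        assert min(matched["coil"]) > 0.6

    def test_arena_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            WormSimConfig(arena=(80, 80), worm_length=100.0, worm_width=10.0)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            small_worm_config(coil_prob=0.7, turn_prob=0.5)

    def test_crowded_arena_errors_after_bounded_retries(self):
        config = small_worm_config(n_worms=40)
        with pytest.raises(RuntimeError, match="crowded"):
            simulate_worm_recording(config)


class TestCorpusSimulator:
    def test_same_seed_identical_corpus(self):
        config = CorpusSimConfig(n_known=3, n_candidates=5, vocab_size=50, seed=4)
        a = simulate_corpus(config)
        b = simulate_corpus(config)
        assert a.documents == b.documents
        assert a.roles == b.roles

    def test_zero_separation_makes_roles_exchangeable(self):
        """At separation 0 knowns and candidates share one distribution:
        pooled term histograms match closely in expectation."""
        config = CorpusSimConfig(
            n_known=10, n_candidates=10, docs_per_entity=4, vocab_size=50,
            topic_separation=0.0, seed=5,
        )
        corpus = simulate_corpus(config)

        def histogram(entities):
            counts: dict[str, int] = {}
            total = 0
            for e in entities:
                for d in corpus.entity_map[e]:
                    for t in corpus.documents[d]:
                        counts[t] = counts.get(t, 0) + 1
                        total += 1
            return {t: c / total for t, c in counts.items()}

        hk = histogram(corpus.known)
        hc = histogram(corpus.candidates)
        common = set(hk) | set(hc)
        l1 = sum(abs(hk.get(t, 0) - hc.get(t, 0)) for t in common)
        assert l1 < 0.25  # sampling noise only

    def test_full_separation_planted_positive_matches_known_topic(self):
        """At separation 1, planted positives use exactly the known-topic
        term block, disjoint from other candidates."""
        config = CorpusSimConfig(
            n_known=3, n_candidates=4, n_planted_positives=1, vocab_size=50,
            topic_separation=1.0, seed=6,
        )
        corpus = simulate_corpus(config)
        def terms_of(entity):
            return {
                t for d in corpus.entity_map[entity] for t in corpus.documents[d]
            }
        known_terms = set().union(*(terms_of(e) for e in corpus.known))
        assert terms_of("cand_000") <= known_terms  # planted positive on topic
        assert terms_of("cand_003").isdisjoint(known_terms)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CorpusSimConfig(vocab_size=5)
        with pytest.raises(ValueError):
            CorpusSimConfig(n_candidates=2, n_planted_positives=3)


class TestPlateSimulator:
    def test_noiseless_null_plate_is_flat_background(self):
        config = RtQuicSimConfig(
            background_sd=0.0, seeded_amplitude=0.0, frac_seeded=0.0, seed=7
        )
        plate, truth = simulate_rtquic_plate(config)
        assert np.all(plate.readings == config.background_mean)
        assert not any(truth.values())

    def test_zero_amplitude_wells_indistinguishable_from_background(self):
        """With no seeding signal, no well mean strays 5 SD above the
        background mean (Gaussian tail at this n)."""
        config = RtQuicSimConfig(seeded_amplitude=0.0, frac_seeded=1.0, seed=8)
        plate, _ = simulate_rtquic_plate(config)
        well_means = plate.readings.mean(axis=1)
        assert well_means.max() - config.background_mean < 5 * config.background_sd

    def test_strong_seeding_gives_every_sample_a_positive_replicate(self):
        config = RtQuicSimConfig(frac_seeded=1.0, seed=9)  # amplitude >> 5 SD
        plate, truth = simulate_rtquic_plate(config)
        calls = call_plate(plate)
        assert all(truth.values())
        assert all(calls.sample_positive.values())

    def test_same_seed_identical_plate(self):
        config = RtQuicSimConfig(seed=10)
        a, ta = simulate_rtquic_plate(config)
        b, tb = simulate_rtquic_plate(config)
        assert np.array_equal(a.readings, b.readings)
        assert ta == tb

    def test_schedule_covers_duration_at_interval(self):
        plate, _ = simulate_rtquic_plate(RtQuicSimConfig(seed=0))
        assert plate.times[0] == 0.0
        assert plate.times[-1] == pytest.approx(60.0)
        assert np.allclose(np.diff(plate.times), 0.75)

    def test_threshold_converges_to_mean_plus_5sd(self):
        """Large pooled background: threshold ~ 1200 + 5 x 400 = 3200 rfu,
        a realistic scale for the assay."""
        plate, _ = simulate_rtquic_plate(RtQuicSimConfig(n_background_wells=16, seed=11))
        assert compute_threshold(plate) == pytest.approx(3200.0, rel=0.05)

    def test_group_map_controls_seeded_fractions(self):
        config = RtQuicSimConfig(
            n_samples_per_group=4,
            groups={"vehicle": 1.0, "treated": 0.0},
            seed=12,
        )
        plate, truth = simulate_rtquic_plate(config)
        assert sum(truth[s] for s in truth if s.startswith("vehicle")) == 4
        assert sum(truth[s] for s in truth if s.startswith("treated")) == 0
        groups = {info.group for info in plate.well_map.values() if not info.is_background}
        assert groups == {"vehicle", "treated"}
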