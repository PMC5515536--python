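import numpy as np
import pytest
from scipy import stats

from squiggleid import (
    ReadEvents,
    compute_qc,
    current_summary,
    median_noise,
    model_shift,
    read_event_table,
    skips_per_base,
    stays_per_base,
    write_event_table,
)
from squiggleid.fixtures import simulate_read_events
from squiggleid.simulate import random_genome


def make_read(moves, means=None, stdvs=None, states=None, read_id="r"):
    n = len(moves)
    return ReadEvents(
        read_id=read_id,
        mean=np.asarray(means if means is not None else [80.0] * n),
        stdv=np.asarray(stdvs if stdvs is not None else [1.0] * n),
        length=np.full(n, 0.01),
        model_state=np.asarray(states if states is not None else ["AA"] * n, dtype=object),
        move=np.asarray(moves),
    )


class TestEventTableIO:
    def test_roundtrip_lossless(self, k2_model, tmp_path):
        read = simulate_read_events(
            random_genome(200, seed=1), k2_model, seed=2,
            stay_prob=0.3, skip_prob=0.1, read_id="sim",
        )
        path = tmp_path / "sim.tsv"
        write_event_table(read, path)
        loaded = read_event_table(path, read_id="sim")
        assert np.array_equal(loaded.move, read.move)
        assert loaded.mean == pytest.approx(read.mean)
        assert loaded.stdv == pytest.approx(read.stdv)
        assert list(loaded.model_state) == list(read.model_state)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("mean\tstdv\n80\t1\n")
        with pytest.raises(ValueError, match="missing required column"):
            read_event_table(path)

    def test_negative_move_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("mean\tstdv\tlength\tmodel_state\tmove\n80\t1\t0.1\tAA\t-1\n")
        with pytest.raises(ValueError, match="negative move"):
            read_event_table(path)

    def test_empty_table_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("mean\tstdv\tlength\tmodel_state\tmove\n")
        with pytest.raises(ValueError, match="empty"):
            read_event_table(path)


class TestStaySkipRates:
    def test_no_stays(self):
        assert stays_per_base(make_read([1, 1, 1])) == 0.0
        assert skips_per_base(make_read([1, 1, 1])) == 0.0

    def test_hand_counted_ratios(self):
        read = make_read([1, 0, 0, 1, 2])
        assert stays_per_base(read) == 0.5  # 2 stays / 4 bases
        assert skips_per_base(read) == 0.25  # 1 skip / 4 bases

    def test_all_zero_moves_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            stays_per_base(make_read([0, 0, 0]))

    def test_basecalled_length_denominator(self):
        read = make_read([1, 0, 0, 1, 2])
        read.basecalled_length = 8
        assert stays_per_base(read, use_basecalled_length=True) == 2 / 8

    def test_generator_stay_rate_oracle(self, k2_model):
        # geometric stays with continuation 0.8 give p/(1-p) = 4 stays/base
        read = simulate_read_events(
            random_genome(3000, seed=3), k2_model, seed=4, stay_prob=0.8
        )
        rate = stays_per_base(read)
        n = int(read.move.sum())
        # negative-binomial mean 4/base; generous 99.9% normal interval
        se = np.sqrt(4 * (1 + 4) / n)
        assert abs(rate - 4) < 3.3 * se

    def test_generator_skip_rate_oracle(self, k2_model):
        read = simulate_read_events(
            random_genome(5000, seed=5), k2_model, seed=6, skip_prob=0.1
        )
        rate = skips_per_base(read)
        n = int(read.move.sum())
        lo = stats.binom.ppf(0.0005, n, 0.1) / n
        hi = stats.binom.isf(0.0005, n, 0.1) / n
        assert lo <= rate <= hi


class TestCurrentSummary:
    def test_single_event(self):
        per_read, cohort = current_summary([make_read([1], means=[80.0])])
        assert per_read["r"] == 80.0 and cohort == 80.0

    def test_odd_count_median(self):
        read = make_read([1, 1, 1], means=[70.0, 90.0, 80.0])
        per_read, _ = current_summary([read])
        assert per_read["r"] == 80.0

    def test_cohort_median_tracks_generator(self, k2_model, rng):
        reads = [
            simulate_read_events(
                random_genome(400, seed=10 + i), k2_model, seed=20 + i, noise_sd=0.5,
                read_id=f"r{i}",
            )
            for i in range(20)
        ]
        _, cohort = current_summary(reads)
        true_median = np.median(list(k2_model.levels.values()))
        assert abs(cohort - true_median) < 5.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            current_summary([])


class TestModelShift:
    def test_model_exact_events_zero_shift(self, k2_model):
        states = list(k2_model.levels)
        means = [k2_model.levels[s] for s in states]
        read = make_read([1] * len(states), means=means, states=states)
        table, shift = model_shift([read], k2_model)
        assert shift == pytest.approx(0.0)
        assert table["shift"].abs().max() == pytest.approx(0.0)

    def test_constant_offset_recovered(self, k2_model):
        states = list(k2_model.levels)
        means = [k2_model.levels[s] + 10.0 for s in states]
        read = make_read([1] * len(states), means=means, states=states)
        _, shift = model_shift([read], k2_model)
        assert shift == pytest.approx(10.0)

    def test_table_ordered_by_model_level(self, k2_model):
        states = list(k2_model.levels)
        read = make_read([1] * len(states), means=[80.0] * len(states), states=states)
        table, _ = model_shift([read], k2_model)
        assert table["model_level"].is_monotonic_increasing

    def test_noisy_events_small_shift(self, k2_model, rng):
        states = rng.choice(list(k2_model.levels), size=10_000)
        means = np.array([k2_model.levels[s] for s in states]) + rng.normal(0, 2, 10_000)
        read = make_read([1] * 10_000, means=means, states=states)
        _, shift = model_shift([read], k2_model)
        assert abs(shift) < 0.1

    def test_unknown_kmer_rejected(self, k2_model):
        read = make_read([1], states=["NN"])
        with pytest.raises(ValueError, match="absent from model"):
            model_shift([read], k2_model)


class TestMedianNoiseAndQC:
    def test_median_noise_examples(self):
        assert median_noise(make_read([1] * 3, stdvs=[0.9, 0.9, 0.9])) == 0.9
        assert median_noise(make_read([1] * 3, stdvs=[0.5, 5.0, 0.9])) == 0.9

    def test_compute_qc_consistency(self):
        read = make_read([1, 0, 0, 1, 2], means=[70, 75, 80, 85, 90])
        qc = compute_qc(read)
        assert qc.n_events == 5
        assert qc.bases_called == 4
        assert qc.stays_per_base == 0.5
        assert qc.skips_per_base == 0.25
        assert qc.median_current == 80.0
        n_stays = int((read.move == 0).sum())
        n_moving = int((read.move >= 1).sum())
        assert qc.n_events == n_stays + n_moving
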