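import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from squiggleid import (
    FingerprintParams,
    build_database,
    classify_read,
    classify_reads,
    compute_spectrogram,
    detect_peaks,
    pair_peaks,
    sequence_to_signal,
)
from squiggleid.fingerprint import FingerprintDB, fingerprint_signal, pack_hash, unpack_hash
from squiggleid.simulate import random_genome

SMALL = FingerprintParams(window=32, overlap=16, amplitude_threshold=0.0, pairing_limit=20)


class TestComputeSpectrogram:
    def test_constant_signal_is_dc_only(self):
        spec = compute_spectrogram(np.full(300, 80.0), FingerprintParams())
        assert np.all(spec[0] == pytest.approx(80.0 * 128))
        assert np.all(spec[1:] < 1e-8)

    def test_cosine_lands_in_its_bin(self):
        n = 128 * 4
        signal = np.cos(2 * np.pi * 8 * np.arange(n) / 128)
        spec = compute_spectrogram(signal, FingerprintParams())
        assert np.all(np.argmax(spec[1:], axis=0) + 1 == 8)

    def test_frame_count_formula(self):
        params = FingerprintParams()
        spec = compute_spectrogram(np.zeros(128 + 64), params)
        assert spec.shape == (65, 2)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="shorter than FFT window"):
            compute_spectrogram(np.zeros(100), FingerprintParams())


class TestDetectPeaks:
    def test_all_zero_spectrogram_empty(self):
        assert len(detect_peaks(np.zeros((65, 40)), FingerprintParams())) == 0

    def test_single_cell_forced_peak(self):
        spec = np.zeros((65, 40))
        spec[12, 7] = 6.0
        peaks = detect_peaks(spec, FingerprintParams())
        assert peaks.tolist() == [(7, 12, 6.0)]

    def test_below_threshold_suppressed(self):
        spec = np.zeros((65, 40))
        spec[12, 7] = 4.0
        assert len(detect_peaks(spec, FingerprintParams())) == 0

    def test_matches_bruteforce_neighborhood_check(self, rng):
        spec = rng.uniform(0, 30, size=(33, 50))
        params = FingerprintParams()
        peaks = detect_peaks(spec, params)
        nb = params.neighborhood
        expected = []
        for b in range(spec.shape[0]):
            for f in range(spec.shape[1]):
                val = spec[b, f]
                if val < params.amplitude_threshold:
                    continue
                window = spec[
                    max(0, b - nb) : b + nb + 1, max(0, f - nb) : f + nb + 1
                ]
                if np.sum(window >= val) == 1:
                    expected.append((f, b, val))
        expected.sort()
        assert [tuple(p) for p in peaks] == [pytest.approx(e) for e in expected]


def _peaks(rows):
    arr = np.empty(len(rows), dtype=[("frame", "i4"), ("bin", "i4"), ("amplitude", "f8")])
    for i, (f, b, a) in enumerate(rows):
        arr[i] = (f, b, a)
    return arr


class TestPairPeaks:
    def test_single_peak_no_hashes(self):
        keys, t1 = pair_peaks(_peaks([(5, 3, 10.0)]), FingerprintParams())
        assert len(keys) == 0

    def test_two_peaks_forced_pair(self):
        keys, t1 = pair_peaks(_peaks([(10, 3, 9.0), (15, 7, 9.0)]), FingerprintParams())
        assert len(keys) == 1
        f1, f2, dt = unpack_hash(keys)
        assert (f1[0], f2[0], dt[0]) == (3, 7, 5)
        assert t1[0] == 10

    def test_beyond_pairing_limit_excluded(self):
        params = FingerprintParams()
        keys, _ = pair_peaks(
            _peaks([(0, 3, 9.0), (params.pairing_limit + 1, 7, 9.0)]), params
        )
        assert len(keys) == 0

    def test_same_frame_not_paired(self):
        keys, _ = pair_peaks(_peaks([(4, 3, 9.0), (4, 9, 9.0)]), FingerprintParams())
        assert len(keys) == 0

    def test_fanout_cap(self):
        rows = [(0, 1, 9.0)] + [(i, 2, 9.0) for i in range(1, 40)]
        keys, t1 = pair_peaks(_peaks(rows), FingerprintParams())
        assert np.sum(t1 == 0) == 10

    @settings(max_examples=100, derandomize=True)
    @given(
        f1=st.integers(0, 512),
        f2=st.integers(0, 512),
        dt=st.integers(1, 1023),
    )
    def test_hash_packing_bijective(self, f1, f2, dt):
        key = pack_hash(np.array([f1]), np.array([f2]), np.array([dt]))
        uf1, uf2, udt = unpack_hash(key)
        assert (uf1[0], uf2[0], udt[0]) == (f1, f2, dt)


@pytest.fixture(scope="module")
def small_refs(k5_model):
    return [(f"ref_{i}", random_genome(8000, seed=40 + i)) for i in range(3)]


@pytest.fixture(scope="module")
def small_db(small_refs, k5_model):
    return build_database(small_refs, k5_model, FingerprintParams(), samples_per_event=10)


class TestBuildDatabase:
    def test_empty_reference_set_rejected(self, k5_model):
        with pytest.raises(ValueError, match="empty reference set"):
            build_database([], k5_model)

    def test_duplicate_genome_identical_hash_sets(self, k5_model):
        genome = random_genome(4000, seed=1)
        db = build_database(
            [("a", genome), ("b", genome)], k5_model, FingerprintParams(), 10
        )
        keys_a = set(db.keys[db.ref_index == 0].tolist())
        keys_b = set(db.keys[db.ref_index == 1].tolist())
        assert keys_a == keys_b

    def test_pruning_bounds_per_reference_occurrences(self, k5_model):
        genome = random_genome(30_000, seed=2)
        params = FingerprintParams(max_occurrences=5)
        db = build_database([("a", genome)], k5_model, params, 10)
        _, counts = np.unique(db.keys, return_counts=True)
        assert counts.max() <= 5

    def test_pruning_monotone(self, k5_model):
        genome = random_genome(20_000, seed=3)
        pruned = build_database(
            [("a", genome)], k5_model, FingerprintParams(max_occurrences=5), 10
        )
        keep_all = build_database(
            [("a", genome)], k5_model, FingerprintParams(max_occurrences=10**9), 10
        )
        assert pruned.n_postings <= keep_all.n_postings

    def test_keep_last_unique_postings(self, k5_model):
        genome = random_genome(30_000, seed=4)
        db = build_database(
            [("a", genome)], k5_model, FingerprintParams(db_mode="keep_last"), 10
        )
        combo = db.keys * 2 + db.strand
        assert len(np.unique(combo)) == len(combo)

    def test_too_short_reference_skipped_with_warning(self, k5_model):
        genome = random_genome(4000, seed=5)
        with pytest.warns(UserWarning, match="too short"):
            db = build_database(
                [("ok", genome), ("tiny", "ACGTACGTAC")], k5_model,
                FingerprintParams(), 10,
            )
        assert db.reference_ids == ["ok"]

    def test_save_load_roundtrip(self, small_db, tmp_path):
        path = tmp_path / "db.npz"
        small_db.save(path)
        loaded = FingerprintDB.load(path)
        assert loaded.params == small_db.params
        assert loaded.reference_ids == small_db.reference_ids
        assert np.array_equal(loaded.keys, small_db.keys)
        assert np.array_equal(loaded.t1, small_db.t1)


class TestClassifyRead:
    def test_self_match_full_reference(self, small_refs, small_db, k5_model):
        ref_id, seq = small_refs[0]
        sig = sequence_to_signal(seq, k5_model, 10)
        res = classify_read(sig, None, small_db)
        assert res.call == (ref_id,)
        assert res.best_offset[ref_id] == 0

    def test_duplicated_references_share_weight(self, k5_model):
        genome = random_genome(4000, seed=6)
        db = build_database(
            [("a", genome), ("b", genome)], k5_model, FingerprintParams(), 10
        )
        sig = sequence_to_signal(genome[:2000], k5_model, 10)
        res = classify_read(sig, None, db)
        assert set(res.call) == {"a", "b"}
        assert res.weights == {"a": 0.5, "b": 0.5}

    def test_substring_offset_recovered(self, small_refs, small_db, k5_model):
        _, seq = small_refs[1]
        start = 3000
        sig = sequence_to_signal(seq[start : start + 2000], k5_model, 10)
        res = classify_read(sig, None, small_db)
        assert res.call == ("ref_1",)
        expected_offset = start * 10 / 64
        assert abs(res.best_offset["ref_1"] - expected_offset) <= 1

    def test_shift_covariance(self, small_refs, small_db, k5_model):
        _, seq = small_refs[2]
        sig = sequence_to_signal(seq[2000:4500], k5_model, 10)
        base = classify_read(sig, None, small_db)
        delta = 20  # frames of silence prepended
        hop = small_db.params.hop
        shifted = np.concatenate([np.zeros(delta * hop), sig.values])
        res = classify_read(shifted, None, small_db)
        assert res.call == base.call
        ref = base.call[0]
        assert abs(res.best_offset[ref] - (base.best_offset[ref] - delta)) <= 1

    def test_short_signal_unclassified_with_reason(self, small_db):
        res = classify_read(np.zeros(50), None, small_db)
        assert not res.classified
        assert "shorter" in res.reason

    def test_two_strand_self_match(self, small_refs, small_db, k5_model):
        from squiggleid import make_2d_read

        _, seq = small_refs[0]
        read = make_2d_read(seq[1000:4000])
        mid = len(read) // 2
        sig_t = sequence_to_signal(read[:mid], k5_model, 10)
        sig_c = sequence_to_signal(read[mid:], k5_model, 10)
        res = classify_read(sig_t, sig_c, small_db)
        assert res.call == ("ref_0",)


class TestClassifyReads:
    def test_empty_input(self, small_db):
        counts, results = classify_reads([], small_db)
        assert results == []
        assert all(v == 0 for v in counts.values())

    def test_fractional_counts_conserved(self, small_refs, small_db, k5_model):
        reads = []
        for ref_idx in (0, 1, 2):
            seq = small_refs[ref_idx][1]
            for start in (0, 2500, 5000):
                reads.append(
                    (sequence_to_signal(seq[start : start + 2000], k5_model, 10), None)
                )
        counts, results = classify_reads(reads, small_db)
        n_classified = sum(r.classified for r in results)
        assert sum(counts.values()) == pytest.approx(n_classified)
        assert n_classified == 9
        assert counts["ref_0"] == counts["ref_1"] == counts["ref_2"] == 3
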