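"""Spectrogram-landmark fingerprinting of event-space signals.

The approach adapts audio landmark fingerprinting (the scheme popularized by
song-identification services) to nanopore squiggles: a reference genome is
converted to event space, a short-time Fourier transform turns the signal
into a spectrogram, local spectral peaks are paired into (f1, f2, dt)
*landmark hashes*, and an inverted index maps each hash to the reference and
frame offset where it occurred.  A read is classified by fingerprinting its
signal the same way and voting for the reference that accumulates the most
matching hashes at one consistent frame offset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .pore_model import EventSignal, PoreModel, reverse_complement, sequence_to_signal

__all__ = [
    "FingerprintParams",
    "FingerprintDB",
    "ClassificationResult",
    "compute_spectrogram",
    "detect_peaks",
    "pair_peaks",
    "fingerprint_signal",
    "build_database",
    "classify_read",
    "classify_reads",
]

# hash key packs (f1, f2, dt) bijectively: 10 bits each is ample for
# window/2 <= 512 frequency bins and pairing limits <= 1023 frames.
_F1_SHIFT = 20
_F2_SHIFT = 10
_MAX_FIELD = 1 << 10


@dataclass(frozen=True)
class FingerprintParams:
    """Tunable parameters of the landmark fingerprinting pipeline.

    Defaults are the benchmark profile: FFT window 128 frames with overlap
    64, spectrogram amplitude threshold 5, peaks paired within 100 frames,
    and hashes occurring more than 50 times in any one reference pruned.
    ``real_data_profile`` raises the threshold to 20 and the pairing limit to
    300 and keeps only the last instance of each hash, trading sensitivity
    for specificity on noisy reads.
    """

    window: int = 128
    overlap: int = 64
    amplitude_threshold: float = 5.0
    pairing_limit: int = 100
    max_occurrences: int = 50
    db_mode: str = "keep_all_pruned"
    neighborhood: int = 2
    fanout: int = 10
    query_phases: int = 8
    strand_tolerance: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.overlap < self.window:
            raise ValueError("need 0 < overlap < window")
        if self.pairing_limit <= 0 or self.pairing_limit >= _MAX_FIELD:
            raise ValueError("pairing_limit must be in 1..1023")
        if self.max_occurrences < 1:
            raise ValueError("max_occurrences must be >= 1")
        if self.db_mode not in ("keep_all_pruned", "keep_last"):
            raise ValueError(f"unknown db_mode {self.db_mode!r}")
        if self.window // 2 + 1 > _MAX_FIELD:
            raise ValueError("window too large for hash packing")
        if self.query_phases < 1:
            raise ValueError("query_phases must be >= 1")
        if self.strand_tolerance < 0:
            raise ValueError("strand_tolerance must be >= 0")

    @property
    def hop(self) -> int:
        return self.window - self.overlap

    @classmethod
    def benchmark_profile(cls) -> "FingerprintParams":
        return cls()

    @classmethod
    def real_data_profile(cls) -> "FingerprintParams":
        return cls(amplitude_threshold=20.0, pairing_limit=300, db_mode="keep_last")

    def n_frames(self, n_samples: int) -> int:
        if n_samples < self.window:
            return 0
        return (n_samples - self.window) // self.hop + 1


def pack_hash(f1: np.ndarray, f2: np.ndarray, dt: np.ndarray) -> np.ndarray:
    return (
        (np.asarray(f1, dtype=np.int64) << _F1_SHIFT)
        | (np.asarray(f2, dtype=np.int64) << _F2_SHIFT)
        | np.asarray(dt, dtype=np.int64)
    )


def unpack_hash(key: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    key = np.asarray(key, dtype=np.int64)
    return key >> _F1_SHIFT, (key >> _F2_SHIFT) & (_MAX_FIELD - 1), key & (_MAX_FIELD - 1)


def compute_spectrogram(
    signal: EventSignal | np.ndarray, params: FingerprintParams
) -> np.ndarray:
    """Magnitude spectrogram of a signal, shape (window//2 + 1, n_frames).

    Each column is the magnitude of the real FFT of one rectangular-windowed
    segment; segments advance by ``window - overlap`` samples and a trailing
    partial segment is dropped.
    """
    values = signal.values if isinstance(signal, EventSignal) else np.asarray(signal, float)
    if len(values) < params.window:
        raise ValueError(
            f"signal of length {len(values)} shorter than FFT window {params.window}"
        )
    segments = np.lib.stride_tricks.sliding_window_view(values, params.window)[:: params.hop]
    return np.abs(np.fft.rfft(segments, axis=1)).T


def detect_peaks(spectrogram: np.ndarray, params: FingerprintParams) -> np.ndarray:
    """Spectral peaks: strict local maxima over threshold.

    A cell is a peak when its amplitude is at least ``amplitude_threshold``
    and strictly exceeds every other cell in its
    ``(2*neighborhood+1)**2`` square neighborhood.  Returns a structured
    array with fields ``frame``, ``bin``, ``amplitude`` sorted by frame then
    bin.
    """
    size = 2 * params.neighborhood + 1
    footprint = np.ones((size, size), dtype=bool)
    footprint[params.neighborhood, params.neighborhood] = False
    neighbor_max = ndimage.maximum_filter(
        spectrogram, footprint=footprint, mode="constant", cval=-np.inf
    )
    mask = (spectrogram > neighbor_max) & (spectrogram >= params.amplitude_threshold)
    bins, frames = np.nonzero(mask)
    order = np.lexsort((bins, frames))
    peaks = np.empty(len(order), dtype=[("frame", "i4"), ("bin", "i4"), ("amplitude", "f8")])
    peaks["frame"] = frames[order]
    peaks["bin"] = bins[order]
    peaks["amplitude"] = spectrogram[bins[order], frames[order]]
    return peaks


def pair_peaks(peaks: np.ndarray, params: FingerprintParams) -> tuple[np.ndarray, np.ndarray]:
    """Pair each anchor peak with later peaks within the time limit.

    For an anchor at frame t1 every peak at frame t1 + dt with
    ``0 < dt <= pairing_limit`` is a candidate; up to ``fanout`` candidates
    evenly spread across the candidate range are kept, so the frame gaps dt
    cover the whole pairing window rather than clustering at small values
    (which would collapse the hash key space and flood posting lists).
    Returns ``(keys, t1)``: packed (f1, f2, dt) hash keys and the anchor
    frame of each.
    """
    frames = peaks["frame"].astype(np.int64)
    bins = peaks["bin"].astype(np.int64)
    n = len(frames)
    if n < 2:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    # peaks are frame-sorted: candidate ranges found by binary search
    lo = np.searchsorted(frames, frames + 1, side="left")
    hi = np.searchsorted(frames, frames + params.pairing_limit, side="right")
    take = np.minimum(hi - lo, params.fanout)
    total = int(take.sum())
    keys = np.empty(total, dtype=np.int64)
    t1 = np.empty(total, dtype=np.int64)
    pos = 0
    spread_cache: dict[int, np.ndarray] = {}
    fanout = params.fanout
    for i in range(n):
        t = take[i]
        if t == 0:
            continue
        span = hi[i] - lo[i]
        if t == span:
            j = np.arange(lo[i], hi[i])
        else:
            pattern = spread_cache.get(span)
            if pattern is None:
                pattern = np.unique(
                    np.linspace(0, span - 1, fanout).round().astype(np.int64)
                )
                spread_cache[span] = pattern
            j = lo[i] + pattern
            t = len(j)
        keys[pos : pos + t] = pack_hash(bins[i], bins[j], frames[j] - frames[i])
        t1[pos : pos + t] = frames[i]
        pos += t
    return keys[:pos], t1[:pos]


def fingerprint_signal(
    signal: EventSignal | np.ndarray, params: FingerprintParams
) -> tuple[np.ndarray, np.ndarray]:
    """Full pipeline signal -> spectrogram -> peaks -> (hash keys, anchor frames)."""
    spec = compute_spectrogram(signal, params)
    return pair_peaks(detect_peaks(spec, params), params)


@dataclass
class FingerprintDB:
    """Inverted index from landmark hash keys to (reference, strand, frame) postings.

    Postings are stored as parallel arrays sorted by hash key so queries are
    two binary searches.  ``strand`` is 0 for the forward event signal of a
    reference and 1 for its reverse complement; ``n_frames[ref, strand]``
    records each indexed signal's frame count (needed to map complement-read
    offsets into forward coordinates).
    """

    params: FingerprintParams
    samples_per_event: int
    reference_ids: list[str]
    keys: np.ndarray          # int64, sorted
    ref_index: np.ndarray     # int32
    strand: np.ndarray        # int8
    t1: np.ndarray            # int32
    n_frames: np.ndarray      # int32, shape (n_refs, 2)
    reference_lengths: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    @property
    def n_postings(self) -> int:
        return len(self.keys)

    def lookup(self, query_keys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posting range [lo, hi) for each query key."""
        lo = np.searchsorted(self.keys, query_keys, side="left")
        hi = np.searchsorted(self.keys, query_keys, side="right")
        return lo, hi

    def save(self, path: str | Path) -> None:
        header = {
            "format": "squiggleid-fingerprint-db",
            "version": 1,
            "params": asdict(self.params),
            "samples_per_event": self.samples_per_event,
            "reference_ids": self.reference_ids,
        }
        np.savez_compressed(
            path,
            header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
            keys=self.keys,
            ref_index=self.ref_index,
            strand=self.strand,
            t1=self.t1,
            n_frames=self.n_frames,
            reference_lengths=self.reference_lengths,
        )

    @classmethod
    def load(cls, path: str | Path) -> "FingerprintDB":
        with np.load(path) as z:
            header = json.loads(bytes(z["header"].tobytes()).decode())
            if header.get("format") != "squiggleid-fingerprint-db":
                raise ValueError(f"{path}: not a fingerprint database")
            return cls(
                params=FingerprintParams(**header["params"]),
                samples_per_event=int(header["samples_per_event"]),
                reference_ids=list(header["reference_ids"]),
                keys=z["keys"],
                ref_index=z["ref_index"],
                strand=z["strand"],
                t1=z["t1"],
                n_frames=z["n_frames"],
                reference_lengths=z["reference_lengths"],
            )


def _apply_keep_last(keys: np.ndarray, t1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within one reference keep only the last (largest-t1) posting per hash."""
    order = np.lexsort((t1, keys))
    keys, t1 = keys[order], t1[order]
    last = np.r_[keys[1:] != keys[:-1], True]
    return keys[last], t1[last]


def build_database(
    references: Sequence[tuple[str, str]],
    model: PoreModel,
    params: FingerprintParams | None = None,
    samples_per_event: int = 10,
    both_strands: bool = True,
) -> FingerprintDB:
    """Fingerprint a reference collection into a queryable database.

    Each reference ``(id, sequence)`` is converted to event space on the
    forward and (by default) reverse-complement strand and fingerprinted.
    ``keep_last`` mode retains only the final instance of each hash within a
    reference; ``keep_all_pruned`` retains every instance, then removes any
    hash occurring more than ``max_occurrences`` times in any single
    reference.  References too short to yield one FFT window are skipped.
    """
    params = params or FingerprintParams()
    if not references:
        raise ValueError("empty reference set")
    all_keys, all_ref, all_strand, all_t1 = [], [], [], []
    ref_ids: list[str] = []
    frames_per_strand: list[list[int]] = []
    ref_lengths: list[int] = []
    for ref_id, seq in references:
        strands = [seq, reverse_complement(seq)] if both_strands else [seq]
        n_samples = (len(seq) - model.k + 1) * samples_per_event
        if len(seq) < model.k or n_samples < params.window:
            import warnings

            warnings.warn(f"reference {ref_id!r} too short to fingerprint; skipped")
            continue
        idx = len(ref_ids)
        ref_ids.append(ref_id)
        ref_lengths.append(len(seq))
        frames_per_strand.append([0, 0])
        per_ref_keys, per_ref_strand, per_ref_t1 = [], [], []
        for s, strand_seq in enumerate(strands):
            sig = sequence_to_signal(strand_seq, model, samples_per_event)
            frames_per_strand[idx][s] = params.n_frames(len(sig))
            keys, t1 = fingerprint_signal(sig, params)
            per_ref_keys.append(keys)
            per_ref_strand.append(np.full(len(keys), s, dtype=np.int8))
            per_ref_t1.append(t1)
        keys = np.concatenate(per_ref_keys)
        strand_arr = np.concatenate(per_ref_strand)
        t1 = np.concatenate(per_ref_t1)
        if params.db_mode == "keep_last":
            # "last instance" taken per strand signal so offsets stay coherent
            kept_k, kept_s, kept_t = [], [], []
            for s in range(len(strands)):
                m = strand_arr == s
                kk, tt = _apply_keep_last(keys[m], t1[m])
                kept_k.append(kk)
                kept_s.append(np.full(len(kk), s, dtype=np.int8))
                kept_t.append(tt)
            keys = np.concatenate(kept_k)
            strand_arr = np.concatenate(kept_s)
            t1 = np.concatenate(kept_t)
        all_keys.append(keys)
        all_ref.append(np.full(len(keys), idx, dtype=np.int32))
        all_strand.append(strand_arr)
        all_t1.append(t1)
    if not ref_ids:
        raise ValueError("no reference long enough to fingerprint")
    keys = np.concatenate(all_keys)
    ref_index = np.concatenate(all_ref)
    strand = np.concatenate(all_strand)
    t1 = np.concatenate(all_t1).astype(np.int32)
    if params.db_mode == "keep_all_pruned" and len(keys):
        combo = keys * len(ref_ids) + ref_index
        uniq, counts = np.unique(combo, return_counts=True)
        banned = np.unique(uniq[counts > params.max_occurrences] // len(ref_ids))
        if len(banned):
            pos = np.searchsorted(banned, keys)
            pos = np.clip(pos, 0, len(banned) - 1)
            keep = banned[pos] != keys
            keys, ref_index, strand, t1 = keys[keep], ref_index[keep], strand[keep], t1[keep]
    order = np.argsort(keys, kind="stable")
    return FingerprintDB(
        params=params,
        samples_per_event=samples_per_event,
        reference_ids=ref_ids,
        keys=keys[order],
        ref_index=ref_index[order],
        strand=strand[order],
        t1=t1[order],
        n_frames=np.asarray(frames_per_strand, dtype=np.int32).reshape(len(ref_ids), -1),
        reference_lengths=np.asarray(ref_lengths, dtype=np.int64),
    )


@dataclass
class ClassificationResult:
    """Outcome of classifying one read against a fingerprint database.

    ``scores[ref_id]`` is the maximum number of matching hashes at a single
    consistent frame offset (summed over strands when a complement signal
    was supplied and its offset agreed); ``best_offset[ref_id]`` is that
    offset in frames on the matched reference strand.  ``call`` lists the
    top-scoring reference(s); ties share fractional ``weights`` of
    1/(number tied).  A read with no matching hashes is unclassified with a
    ``reason``.
    """

    scores: dict[str, int]
    best_offset: dict[str, int]
    best_strand: dict[str, int]
    call: tuple[str, ...]
    weights: dict[str, float]
    reason: str | None = None

    @property
    def classified(self) -> bool:
        return len(self.call) > 0

    @property
    def ambiguous(self) -> bool:
        return len(self.call) > 1


def offset_histograms(
    query_keys: np.ndarray, query_t1: np.ndarray, db: FingerprintDB
) -> dict[tuple[int, int], tuple[np.ndarray, np.ndarray]]:
    """Per (reference, strand): histogram of match offsets.

    The offset of a match is ``t1_reference - t1_query``.  Returns, for each
    (reference index, strand) stream with at least one match, sorted unique
    offsets and the number of matching hashes at each.
    """
    if len(query_keys) == 0:
        return {}
    lo, hi = db.lookup(query_keys)
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return {}
    idx = np.repeat(lo, counts) + (
        np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    )
    refs = db.ref_index[idx].astype(np.int64)
    strands = db.strand[idx].astype(np.int64)
    offsets = db.t1[idx].astype(np.int64) - np.repeat(query_t1, counts)
    # combine (ref, strand, offset) into one sortable key; offsets can be negative
    off_min = offsets.min()
    span = int(offsets.max() - off_min) + 1
    combo = (refs * 2 + strands) * span + (offsets - off_min)
    uniq, cnt = np.unique(combo, return_counts=True)
    u_off = (uniq % span) + off_min
    u_rs = uniq // span
    hists: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    boundaries = np.r_[0, np.nonzero(np.diff(u_rs))[0] + 1, len(u_rs)]
    for b0, b1 in zip(boundaries[:-1], boundaries[1:]):
        rs = int(u_rs[b0])
        hists[(rs // 2, rs % 2)] = (u_off[b0:b1], cnt[b0:b1])
    return hists


def _merge_max(
    parts: list[tuple[np.ndarray, np.ndarray]]
) -> tuple[np.ndarray, np.ndarray]:
    """Merge offset histograms, keeping the max count per offset."""
    if len(parts) == 1:
        return parts[0]
    both = np.concatenate([p[0] for p in parts])
    both_cnt = np.concatenate([p[1] for p in parts])
    order = np.argsort(both, kind="stable")
    both, both_cnt = both[order], both_cnt[order]
    first = np.r_[True, both[1:] != both[:-1]]
    group = np.cumsum(first) - 1
    merged = np.zeros(int(group[-1]) + 1, dtype=both_cnt.dtype)
    np.maximum.at(merged, group, both_cnt)
    return both[first], merged


def query_histograms(
    values: np.ndarray, db: FingerprintDB
) -> dict[tuple[int, int], tuple[np.ndarray, np.ndarray]]:
    """Offset histograms of a query signal, scanned over sub-hop phases.

    The database's frame grid starts at sample 0 of each reference signal,
    but a read's signal starts at an arbitrary sample phase relative to that
    grid, which decimates exact spectral matches.  The query is therefore
    fingerprinted at ``query_phases`` evenly spaced sample offsets within
    one hop and the histograms are merged taking the maximum count per
    offset (the near-aligned phase dominates; merging never double-counts
    one offset).
    """
    params = db.params
    step = max(1, params.hop // params.query_phases)
    acc: dict[tuple[int, int], list[tuple[np.ndarray, np.ndarray]]] = {}
    for phi in range(0, min(params.hop, step * params.query_phases), step):
        if len(values) - phi < params.window:
            break
        keys, t1 = fingerprint_signal(values[phi:], params)
        for stream, hist in offset_histograms(keys, t1, db).items():
            acc.setdefault(stream, []).append(hist)
    return {stream: _merge_max(parts) for stream, parts in acc.items()}


def _best_in_hist(off: np.ndarray, cnt: np.ndarray) -> tuple[int, int]:
    j = int(np.argmax(cnt))
    return int(cnt[j]), int(off[j])


def classify_read(
    template_signal: EventSignal | np.ndarray,
    complement_signal: EventSignal | np.ndarray | None,
    db: FingerprintDB,
) -> ClassificationResult:
    """Classify one read by offset-consistent hash voting.

    Template-only: each reference scores the largest number of template
    hashes matching at one frame offset.  With a complement signal, a
    positive hit additionally requires the complement to support the *same*
    placement: complement offsets are mapped into forward coordinates
    (``o' = frames(ref) - o_c - frames(read)``) and the score of a
    candidate offset is the template count plus the best complement count
    within ``strand_tolerance`` frames of it; references with no such joint
    offset are not callable.  The call is the top-scoring reference; ties
    are reported as an ambiguous set with weights 1/(number tied).
    """
    params = db.params

    def _values(sig):
        return sig.values if isinstance(sig, EventSignal) else np.asarray(sig, float)

    tv = _values(template_signal)
    if len(tv) < params.window:
        return ClassificationResult({}, {}, {}, (), {}, reason="signal shorter than FFT window")
    hist_t = query_histograms(tv, db)
    have_complement = complement_signal is not None
    hist_c: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    frames_c = 0
    if have_complement:
        cv = _values(complement_signal)
        if len(cv) >= params.window:
            hist_c = query_histograms(cv, db)
            frames_c = params.n_frames(len(cv))

    scores: dict[str, int] = {}
    best_offset: dict[str, int] = {}
    best_strand: dict[str, int] = {}
    for (ref, strand), (off_t, cnt_t) in hist_t.items():
        ref_id = db.reference_ids[ref]
        if not have_complement:
            cnt, off = _best_in_hist(off_t, cnt_t)
        else:
            # the read's complement strand matches the opposite reference strand
            c_strand = 1 - strand
            hit = hist_c.get((ref, c_strand))
            if hit is None:
                continue
            off_c, cnt_c = hit
            mapped = int(db.n_frames[ref, c_strand]) - off_c - frames_c
            # best complement support near each template offset
            tol = params.strand_tolerance
            lo_edge = min(int(off_t.min()), int(mapped.min()))
            hi_edge = max(int(off_t.max()), int(mapped.max()))
            dense_c = np.zeros(hi_edge - lo_edge + 1, dtype=np.int64)
            np.maximum.at(dense_c, mapped - lo_edge, cnt_c)
            support_win = ndimage.maximum_filter1d(
                dense_c, size=2 * tol + 1, mode="constant", cval=0
            )
            support = support_win[off_t - lo_edge]
            if not (support > 0).any():
                continue
            joint = np.where(support > 0, cnt_t + support, -1)
            j = int(np.argmax(joint))
            cnt, off = int(joint[j]), int(off_t[j])
        if cnt > scores.get(ref_id, -1):
            scores[ref_id] = cnt
            best_offset[ref_id] = off
            best_strand[ref_id] = strand
    if not scores:
        reason = (
            "no reference with offset-consistent template and complement placements"
            if have_complement and hist_t
            else "no matching fingerprints"
        )
        return ClassificationResult({}, {}, {}, (), {}, reason=reason)
    top = max(scores.values())
    call = tuple(sorted(r for r, s in scores.items() if s == top))
    weights = {r: 1.0 / len(call) for r in call}
    return ClassificationResult(scores, best_offset, best_strand, call, weights)


def classify_reads(
    reads: Iterable[tuple[EventSignal | np.ndarray, EventSignal | np.ndarray | None]],
    db: FingerprintDB,
) -> tuple[dict[str, float], list[ClassificationResult]]:
    """Classify many reads; return per-reference fractional counts and per-read results.

    Each classified read contributes total weight 1, split evenly over its
    called references, so the fractional counts sum to the number of
    classified reads.
    """
    counts: dict[str, float] = {ref_id: 0.0 for ref_id in db.reference_ids}
    results = []
    for template, complement in reads:
        res = classify_read(template, complement, db)
        results.append(res)
        for ref_id, w in res.weights.items():
            counts[ref_id] += w
    return counts, results
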