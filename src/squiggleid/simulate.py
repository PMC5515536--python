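"""Benchmark read simulation: fragments, 2D reads, induced errors, artifacts.

The fingerprint classifier is benchmarked by drawing random fragments from a
target genome, joining each to its reverse complement to form a 2D read
(template + complement), corrupting the sequence with mismatches, insertions
and deletions at controlled per-base rates *before* conversion to event
space — mimicking errors in basecalled output — and measuring the fraction
of reads whose top call is the true source genome.  Event-level stay/skip
artifacts can additionally be injected into signals to emulate the time
distortion of real squiggles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import fingerprint as fp
from .pore_model import EventSignal, PoreModel, reverse_complement, sequence_to_signal

__all__ = [
    "SimulationParams",
    "BenchmarkResult",
    "sample_fragments",
    "make_2d_read",
    "induce_errors",
    "inject_stay_skip_artifacts",
    "random_genome",
    "run_benchmark",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
DEFAULT_ERROR_GRID: tuple[tuple[str, float], ...] = tuple(
    ("none", 0.0) if r == 0 else (t, r)
    for t in ("mismatch", "insertion", "deletion")
    for r in (0.0, 0.02, 0.05, 0.10)
    if not (t != "mismatch" and r == 0.0)
)


@dataclass(frozen=True)
class SimulationParams:
    """Benchmark simulation settings.

    Defaults follow the reference benchmark design: 1,000 random 2,500-base
    fragments per condition, joined to reverse complements as 2D reads, with
    one error type varied at a time over the rate grid.
    """

    n_fragments: int = 1000
    fragment_length: int = 2500
    mismatch_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    seed: int = 0
    stay_rate: float = 0.0
    skip_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_fragments < 1:
            raise ValueError("n_fragments must be >= 1")
        for name in ("mismatch_rate", "insertion_rate", "deletion_rate",
                     "stay_rate", "skip_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mismatch_rate + self.deletion_rate > 1.0:
            raise ValueError("mismatch_rate + deletion_rate must be <= 1")


@dataclass
class BenchmarkResult:
    """Accuracy table of a classification benchmark, one row per error condition."""

    target_id: str
    rows: list[dict] = field(default_factory=list)
    params: SimulationParams | None = None

    def add(self, error_type: str, rate: float, fraction_correct: float,
            n_classified: int, n_ambiguous: int, n_fragments: int) -> None:
        self.rows.append(
            {
                "error_type": error_type,
                "rate": rate,
                "fraction_correct": fraction_correct,
                "n_classified": n_classified,
                "n_ambiguous": n_ambiguous,
                "n_unclassified": n_fragments - n_classified,
                "n_fragments": n_fragments,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def fraction_correct(self, error_type: str, rate: float) -> float:
        for row in self.rows:
            if row["error_type"] == error_type and row["rate"] == rate:
                return row["fraction_correct"]
        raise KeyError((error_type, rate))


def random_genome(length: int, seed: int) -> str:
    """Uniform-random DNA sequence, deterministic for a seed."""
    rng = np.random.default_rng(seed)
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def sample_fragments(
    genome: str, n: int, length: int, seed: int
) -> list[tuple[str, int]]:
    """Draw n forward-strand fragments with uniform-random start positions."""
    if length > len(genome):
        raise ValueError(f"fragment length {length} exceeds genome length {len(genome)}")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, len(genome) - length + 1, size=n)
    return [(genome[s : s + length], int(s)) for s in starts]


def make_2d_read(fragment: str) -> str:
    """Template + complement: fragment concatenated with its reverse complement."""
    if not fragment:
        raise ValueError("empty fragment")
    return fragment + reverse_complement(fragment)


def induce_errors(
    seq: str,
    mismatch_rate: float,
    insertion_rate: float,
    deletion_rate: float,
    seed: int,
) -> str:
    """Corrupt a sequence with independent per-base errors.

    Each base draws one outcome from {match, mismatch, delete} with
    probabilities (1 - m - d, m, d); a mismatched base is replaced by a
    uniformly random *different* base.  Independently, a uniform random base
    is inserted after each original position with probability i.
    """
    for name, v in (("mismatch", mismatch_rate), ("insertion", insertion_rate),
                    ("deletion", deletion_rate)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} rate must be in [0, 1], got {v}")
    if mismatch_rate + deletion_rate > 1.0:
        raise ValueError("mismatch_rate + deletion_rate must be <= 1")
    if not seq:
        return ""
    rng = np.random.default_rng(seed)
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n = len(codes)
    u = rng.random(n)
    mismatch = u < mismatch_rate
    delete = (u >= mismatch_rate) & (u < mismatch_rate + deletion_rate)
    if mismatch.any():
        # add 1..3 (mod 4) to the base code: always a different base
        base_idx = np.searchsorted(_BASES, codes[mismatch])
        shifted = (base_idx + rng.integers(1, 4, size=int(mismatch.sum()))) % 4
        codes[mismatch] = _BASES[shifted]
    insert = rng.random(n) < insertion_rate
    inserted = _BASES[rng.integers(0, 4, size=int(insert.sum()))]
    # assemble: each position contributes 0-2 output bases
    out_len = np.ones(n, dtype=np.int64)
    out_len[delete] = 0
    out_len += insert
    total = int(out_len.sum())
    out = np.empty(total, dtype=np.uint8)
    ends = np.cumsum(out_len)
    starts = ends - out_len
    keep = ~delete
    out[starts[keep]] = codes[keep]
    out[ends[insert] - 1] = inserted
    return out.tobytes().decode("ascii")


def inject_stay_skip_artifacts(
    signal: EventSignal, stay_rate: float, skip_rate: float, seed: int
) -> EventSignal:
    """Duplicate (stay) or drop (skip) whole event blocks of a signal.

    Each block of ``samples_per_event`` samples is independently duplicated
    in place with probability ``stay_rate`` and deleted with probability
    ``skip_rate`` (a block drawing both is deleted).
    """
    for name, v in (("stay_rate", stay_rate), ("skip_rate", skip_rate)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    s = signal.samples_per_event
    values = signal.values
    n_events = len(values) // s
    rng = np.random.default_rng(seed)
    repeats = np.ones(n_events, dtype=np.int64)
    repeats += rng.random(n_events) < stay_rate
    repeats[rng.random(n_events) < skip_rate] = 0
    blocks = values[: n_events * s].reshape(n_events, s)
    out = np.repeat(blocks, repeats, axis=0).reshape(-1)
    tail = values[n_events * s :]
    if len(tail):
        out = np.concatenate([out, tail])
    return EventSignal(values=out, samples_per_event=s,
                       source_id=signal.source_id, strand=signal.strand)


def _split_2d(seq: str) -> tuple[str, str]:
    """Split an (error-corrupted) 2D read into template and complement halves."""
    mid = len(seq) // 2
    return seq[:mid], seq[mid:]


def simulate_2d_signals(
    genome: str,
    params: SimulationParams,
    model: PoreModel,
    samples_per_event: int,
) -> list[tuple[EventSignal, EventSignal, int]]:
    """Simulate 2D reads as (template signal, complement signal, start) triples.

    Fragments are drawn from the forward strand, joined to their reverse
    complements, corrupted per the error rates, split at the midpoint, and
    converted to event space; optional stay/skip artifacts are then injected
    into both strand signals.
    """
    rng = np.random.default_rng(params.seed)
    frag_seed, err_seed, art_seed = (int(x) for x in rng.integers(0, 2**31 - 1, 3))
    fragments = sample_fragments(genome, params.n_fragments, params.fragment_length, frag_seed)
    out = []
    for i, (frag, start) in enumerate(fragments):
        read = make_2d_read(frag)
        if params.mismatch_rate or params.insertion_rate or params.deletion_rate:
            read = induce_errors(
                read, params.mismatch_rate, params.insertion_rate,
                params.deletion_rate, err_seed + i,
            )
        template, complement = _split_2d(read)
        if len(template) < model.k or len(complement) < model.k:
            continue
        sig_t = sequence_to_signal(template, model, samples_per_event, strand="template")
        sig_c = sequence_to_signal(complement, model, samples_per_event, strand="complement")
        if params.stay_rate or params.skip_rate:
            sig_t = inject_stay_skip_artifacts(sig_t, params.stay_rate, params.skip_rate,
                                               art_seed + 2 * i)
            sig_c = inject_stay_skip_artifacts(sig_c, params.stay_rate, params.skip_rate,
                                               art_seed + 2 * i + 1)
        out.append((sig_t, sig_c, start))
    return out


def run_benchmark(
    references: list[tuple[str, str]],
    target_id: str,
    params: SimulationParams,
    fingerprint_params: fp.FingerprintParams | None = None,
    model: PoreModel | None = None,
    samples_per_event: int = 10,
    error_grid: tuple[tuple[str, float], ...] = DEFAULT_ERROR_GRID,
    db: fp.FingerprintDB | None = None,
) -> BenchmarkResult:
    """Accuracy-versus-induced-error benchmark of fingerprint classification.

    For each (error type, rate) cell, 2D reads simulated from the target
    reference are classified against the database of all references; a
    read's contribution to ``fraction_correct`` is its fractional weight on
    the target (1 for an unambiguous correct call, 1/t for a t-way tie
    containing the target, 0 otherwise).  Fully deterministic given
    ``params.seed``.
    """
    if model is None:
        raise ValueError("a pore model is required")
    ref_ids = [r[0] for r in references]
    if target_id not in ref_ids:
        raise ValueError(f"target {target_id!r} not among references")
    genome = dict(references)[target_id]
    if db is None:
        db = fp.build_database(references, model,
                               fingerprint_params or fp.FingerprintParams(),
                               samples_per_event)
    result = BenchmarkResult(target_id=target_id, params=params)
    for cell_idx, (error_type, rate) in enumerate(error_grid):
        cell = replace(
            params,
            mismatch_rate=rate if error_type == "mismatch" else 0.0,
            insertion_rate=rate if error_type == "insertion" else 0.0,
            deletion_rate=rate if error_type == "deletion" else 0.0,
            seed=params.seed + 7919 * (cell_idx + 1),
        )
        signals = simulate_2d_signals(genome, cell, model, samples_per_event)
        correct_weight = 0.0
        n_classified = 0
        n_ambiguous = 0
        for sig_t, sig_c, _start in signals:
            res = fp.classify_read(sig_t, sig_c, db)
            if res.classified:
                n_classified += 1
                n_ambiguous += res.ambiguous
                correct_weight += res.weights.get(target_id, 0.0)
        result.add(error_type, rate, correct_weight / params.n_fragments,
                   n_classified, n_ambiguous, params.n_fragments)
    return result
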