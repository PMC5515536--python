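"""Synthetic data generation: genomes, pore models, event tables, file bundles.

Stands in for real reference genomes, the basecaller's proprietary pore
model, and device event tables, with every generation parameter known — so
downstream statistics (stay/skip rates, model shift, classification
accuracy) can be checked against ground truth.

What is emulated: uniform-random genome composition, k-mer-determined mean
currents with additive Gaussian noise, geometric stay runs (each emitted
k-mer is followed by extra move-0 events with probability ``stay_prob``
each, giving an expected ``p/(1-p)`` stays per base), and Bernoulli skips
(a k-mer goes unrecorded with probability ``skip_prob``, incrementing the
next event's move).  Not emulated: genome repeat structure and GC bias,
current drift within a run, dwell-time/current correlation, and basecaller
miscalls in ``model_state``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .event_qc import ReadEvents, write_event_table
from .io import write_fasta
from .pore_model import PoreModel, kmer_levels, synthesize_pore_model, write_pore_model
from .simulate import random_genome, sample_fragments

__all__ = ["FixtureSpec", "simulate_read_events", "generate_fixtures"]


@dataclass(frozen=True)
class FixtureSpec:
    """Sizes and rates of a synthetic data bundle."""

    n_genomes: int = 12
    genome_length: int = 200_000
    k: int = 5
    level_range: tuple[float, float] = (50.0, 110.0)
    n_event_tables: int = 100
    read_length: int = 1000
    stay_prob: float = 0.3
    skip_prob: float = 0.1
    noise_sd: float = 1.5


def simulate_read_events(
    seq: str,
    model: PoreModel,
    seed: int,
    stay_prob: float = 0.0,
    skip_prob: float = 0.0,
    noise_sd: float = 1.0,
    read_id: str = "simulated",
    mean_dwell: float = 0.01,
) -> ReadEvents:
    """Simulate the event table a device would emit for a sequence.

    Walks the sequence's k-mers: each k-mer is skipped with probability
    ``skip_prob`` (its advance accumulates into the next event's move);
    otherwise one move>=1 event is emitted, followed by a geometric run of
    move-0 stay events (continuation probability ``stay_prob``).  Event mean
    currents are the model level plus N(0, noise_sd) noise; event noise
    (stdv) is drawn near ``noise_sd``; durations are exponential with mean
    ``mean_dwell`` seconds.
    """
    if not 0 <= stay_prob < 1 or not 0 <= skip_prob <= 1:
        raise ValueError("stay_prob must be in [0,1) and skip_prob in [0,1]")
    rng = np.random.default_rng(seed)
    levels = kmer_levels(seq, model)
    k = model.k
    kmers = [seq[i : i + k] for i in range(len(seq) - k + 1)]
    means, stdvs, durations, states, moves = [], [], [], [], []
    pending_move = 1
    for i, level in enumerate(levels):
        if skip_prob and rng.random() < skip_prob:
            pending_move += 1
            continue
        n_stays = rng.geometric(1.0 - stay_prob) - 1 if stay_prob else 0
        for j in range(1 + n_stays):
            means.append(level + rng.normal(0.0, noise_sd))
            stdvs.append(abs(rng.normal(noise_sd, 0.3 * noise_sd + 1e-6)))
            durations.append(rng.exponential(mean_dwell))
            states.append(kmers[i])
            moves.append(pending_move if j == 0 else 0)
        pending_move = 1
    if not means:
        raise ValueError("simulation produced no events (skip_prob too high?)")
    mean_arr = np.asarray(means)
    mean_arr[mean_arr <= 0] = 0.01  # currents must stay positive
    return ReadEvents(
        read_id=read_id,
        mean=mean_arr,
        stdv=np.asarray(stdvs),
        length=np.asarray(durations),
        model_state=np.asarray(states, dtype=object),
        move=np.asarray(moves),
    )


def generate_fixtures(
    outdir: str | Path, seed: int, spec: FixtureSpec | None = None
) -> dict:
    """Write a deterministic synthetic bundle and return its manifest.

    Produces ``genomes.fasta`` (``n_genomes`` random genomes), ``model.tsv``
    (a complete synthetic pore model), and ``events/read_NNN.tsv`` event
    tables for reads drawn from genome 0, all derived from one seed.
    """
    spec = spec or FixtureSpec()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "events").mkdir(exist_ok=True)
    ss = np.random.SeedSequence(seed)
    genome_seed, model_seed, read_seed = (
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3)
    )
    genomes = [
        (f"genome_{i:02d}", random_genome(spec.genome_length, genome_seed + i))
        for i in range(spec.n_genomes)
    ]
    write_fasta(genomes, outdir / "genomes.fasta")
    model = synthesize_pore_model(spec.k, model_seed, spec.level_range)
    write_pore_model(model, outdir / "model.tsv")
    fragments = sample_fragments(
        genomes[0][1], spec.n_event_tables, spec.read_length, read_seed
    )
    event_files = []
    for i, (frag, start) in enumerate(fragments):
        read = simulate_read_events(
            frag, model, seed=read_seed + 1 + i,
            stay_prob=spec.stay_prob, skip_prob=spec.skip_prob,
            noise_sd=spec.noise_sd, read_id=f"read_{i:03d}",
        )
        path = outdir / "events" / f"read_{i:03d}.tsv"
        write_event_table(read, path)
        event_files.append({"path": str(path.relative_to(outdir)),
                            "source": "genome_00", "start": start})
    manifest = {
        "seed": seed,
        "spec": {
            "n_genomes": spec.n_genomes,
            "genome_length": spec.genome_length,
            "k": spec.k,
            "level_range": list(spec.level_range),
            "n_event_tables": spec.n_event_tables,
            "read_length": spec.read_length,
            "stay_prob": spec.stay_prob,
            "skip_prob": spec.skip_prob,
            "noise_sd": spec.noise_sd,
        },
        "genomes": [g[0] for g in genomes],
        "model": "model.tsv",
        "event_tables": event_files,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
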