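"""Event-level read quality statistics.

Nanopore acquisition software segments the raw current trace into *events*,
each summarized by a mean current, a current standard deviation (noise), a
duration, the model k-mer believed to occupy the pore, and a *move*: how many
k-mers the pore advanced since the previous event.  A move of 0 is a "stay"
(the event re-reads the same k-mer); a move of 2 or more implies "skips"
(k-mers with no event of their own).  Stays and skips distort the event
signal's time axis, so their per-base rates — together with median current
and median event noise — are the first-line quality report for signal-space
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pore_model import PoreModel

__all__ = [
    "ReadEvents",
    "ReadQC",
    "read_event_table",
    "write_event_table",
    "stays_per_base",
    "skips_per_base",
    "median_noise",
    "compute_qc",
    "current_summary",
    "model_shift",
]

_REQUIRED_COLUMNS = ("mean", "stdv", "length", "model_state", "move")


@dataclass
class ReadEvents:
    """One read's event table."""

    read_id: str
    mean: np.ndarray         # event mean current, pA
    stdv: np.ndarray         # event current s.d. ("noise"), pA
    length: np.ndarray       # event duration (seconds or samples; passed through)
    model_state: np.ndarray  # model k-mer per event
    move: np.ndarray         # k-mer advance since previous event, >= 0
    strand: str = "template"
    basecalled_length: int | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.stdv = np.asarray(self.stdv, dtype=np.float64)
        self.length = np.asarray(self.length, dtype=np.float64)
        self.model_state = np.asarray(self.model_state, dtype=object)
        self.move = np.asarray(self.move, dtype=np.int64)
        n = len(self.mean)
        if n == 0:
            raise ValueError(f"read {self.read_id!r}: empty event table")
        for name in ("stdv", "length", "model_state", "move"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"read {self.read_id!r}: column length mismatch ({name})")
        if (self.move < 0).any():
            row = int(np.argmax(self.move < 0))
            raise ValueError(f"read {self.read_id!r}: negative move at event {row}")
        if not np.all(np.isfinite(self.mean)) or (self.mean <= 0).any():
            raise ValueError(f"read {self.read_id!r}: event currents must be finite and > 0")

    @property
    def n_events(self) -> int:
        return len(self.mean)

    @property
    def k(self) -> int:
        return len(self.model_state[0])


@dataclass
class ReadQC:
    """Per-read quality summary."""

    read_id: str
    n_events: int
    bases_called: int
    stays_per_base: float
    skips_per_base: float
    median_current: float
    median_noise: float


def read_event_table(path: str | Path, read_id: str | None = None) -> ReadEvents:
    """Parse a tab-delimited event table.

    Requires header columns ``mean``, ``stdv``, ``length``, ``model_state``,
    ``move``; extra columns are ignored.  The k-mer length is inferred from
    the ``model_state`` width.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: empty event table")
    return ReadEvents(
        read_id=read_id if read_id is not None else path.stem,
        mean=df["mean"].to_numpy(),
        stdv=df["stdv"].to_numpy(),
        length=df["length"].to_numpy(),
        model_state=df["model_state"].astype(str).to_numpy(),
        move=df["move"].to_numpy(),
    )


def write_event_table(read: ReadEvents, path: str | Path) -> None:
    """Serialize events in the dialect ``read_event_table`` parses."""
    pd.DataFrame(
        {
            "mean": read.mean,
            "stdv": read.stdv,
            "length": read.length,
            "model_state": read.model_state,
            "move": read.move,
        }
    ).to_csv(path, sep="\t", index=False)


def _bases_called(read: ReadEvents, use_basecalled_length: bool = False) -> int:
    # Sum of moves = number of new k-mers traversed; the denominator for the
    # per-base rates unless a basecalled length is supplied and requested.
    if use_basecalled_length:
        if read.basecalled_length is None:
            raise ValueError(f"read {read.read_id!r} has no basecalled length")
        return read.basecalled_length
    return int(read.move.sum())


def stays_per_base(read: ReadEvents, use_basecalled_length: bool = False) -> float:
    """Stays (move = 0 events) per base called.

    Raises when no base was called (all moves zero), since the ratio is then
    undefined.
    """
    bases = _bases_called(read, use_basecalled_length)
    if bases < 1:
        raise ValueError(f"read {read.read_id!r}: no bases called; stay rate undefined")
    return int((read.move == 0).sum()) / bases


def skips_per_base(read: ReadEvents, use_basecalled_length: bool = False) -> float:
    """Skips (sum of move - 1 over events with move >= 2) per base called."""
    bases = _bases_called(read, use_basecalled_length)
    if bases < 1:
        raise ValueError(f"read {read.read_id!r}: no bases called; skip rate undefined")
    return int(np.maximum(read.move - 1, 0).sum()) / bases


def median_noise(read: ReadEvents) -> float:
    """Median of per-event current standard deviations (pA)."""
    if not np.all(np.isfinite(read.stdv)):
        raise ValueError(f"read {read.read_id!r}: event noise unavailable")
    return float(np.median(read.stdv))


def compute_qc(read: ReadEvents, use_basecalled_length: bool = False) -> ReadQC:
    bases = _bases_called(read, use_basecalled_length)
    return ReadQC(
        read_id=read.read_id,
        n_events=read.n_events,
        bases_called=bases,
        stays_per_base=stays_per_base(read, use_basecalled_length),
        skips_per_base=skips_per_base(read, use_basecalled_length),
        median_current=float(np.median(read.mean)),
        median_noise=median_noise(read),
    )


def current_summary(reads: Sequence[ReadEvents]) -> tuple[pd.Series, float]:
    """Per-read median event current and the cohort median of those medians (pA)."""
    if not reads:
        raise ValueError("empty read cohort")
    per_read = pd.Series(
        {r.read_id: float(np.median(r.mean)) for r in reads}, name="median_current_pA"
    )
    return per_read, float(per_read.median())


def model_shift(reads: Sequence[ReadEvents], model: PoreModel) -> tuple[pd.DataFrame, float]:
    """Observed per-k-mer current distributions versus the pore model.

    Returns a table with one row per k-mer seen in the cohort — observed mean
    and s.d. of event currents, the model level, and their difference —
    ordered by model level ascending, plus the global mean shift: the mean
    over k-mers of (observed mean - model level).
    """
    if not reads:
        raise ValueError("empty read cohort")
    states = np.concatenate([r.model_state for r in reads])
    currents = np.concatenate([r.mean for r in reads])
    df = pd.DataFrame({"kmer": states, "current": currents})
    unknown = set(df["kmer"].unique()) - set(model.levels)
    if unknown:
        raise ValueError(f"event k-mer(s) absent from model: {sorted(unknown)[:5]}")
    grouped = df.groupby("kmer")["current"].agg(observed_mean="mean", observed_sd="std", n="size")
    grouped["observed_sd"] = grouped["observed_sd"].fillna(0.0)
    grouped["model_level"] = [model.levels[km] for km in grouped.index]
    grouped["shift"] = grouped["observed_mean"] - grouped["model_level"]
    grouped = grouped.sort_values("model_level").reset_index()
    return grouped, float(grouped["shift"].mean())
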