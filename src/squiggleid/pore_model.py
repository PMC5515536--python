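"""k-mer pore-current models and conversion of DNA into event-space signals.

A nanopore reports an ionic current whose level depends on which k-mer
occupies the pore.  A *pore model* tabulates the expected mean current (pA)
for every k-mer; converting a nucleotide sequence into "event space" replaces
each successive k-mer window with its model current, yielding the idealized
signal a noise-free, stay-free read of that sequence would produce.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PoreModel",
    "EventSignal",
    "PoreModelError",
    "load_pore_model",
    "write_pore_model",
    "synthesize_pore_model",
    "reverse_complement",
    "sequence_to_signal",
]

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
# base -> 0..3 code; N -> 4 (sentinel handled by the N-policy)
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("N")] = 4
_CODE[ord("n")] = 4


class PoreModelError(ValueError):
    """Malformed pore-model table or invalid k-mer lookup."""


@dataclass
class PoreModel:
    """Lookup table from k-mers to expected pore current.

    Parameters
    ----------
    k
        k-mer length.
    levels
        Mapping from k-mer (uppercase, over ``ACGT``) to mean current in pA.
    spreads
        Optional mapping from k-mer to the current standard deviation in pA.
    name
        Free-text label.
    """

    k: int
    levels: Mapping[str, float]
    spreads: Mapping[str, float] | None = None
    name: str = ""
    _level_array: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise PoreModelError(f"k must be positive, got {self.k}")
        for kmer, level in self.levels.items():
            if len(kmer) != self.k or any(b not in _BASES for b in kmer):
                raise PoreModelError(f"invalid k-mer key {kmer!r} for k={self.k}")
            if not np.isfinite(level) or level <= 0:
                raise PoreModelError(f"non-positive or non-finite level for {kmer!r}: {level}")

    @property
    def n_kmers(self) -> int:
        return len(self.levels)

    @property
    def is_complete(self) -> bool:
        return len(self.levels) == 4**self.k

    @property
    def mean_level(self) -> float:
        return float(np.mean(list(self.levels.values())))

    def level(self, kmer: str) -> float:
        try:
            return self.levels[kmer]
        except KeyError:
            raise PoreModelError(f"k-mer {kmer!r} absent from model {self.name!r}") from None

    def level_array(self) -> np.ndarray:
        """Dense array of levels indexed by the base-4 encoding of the k-mer.

        Requires a complete model (all 4^k k-mers); cached after first use.
        """
        if self._level_array is None:
            if not self.is_complete:
                raise PoreModelError(
                    "dense lookup requires a complete model "
                    f"({len(self.levels)}/{4**self.k} k-mers present)"
                )
            arr = np.empty(4**self.k, dtype=np.float64)
            powers = 4 ** np.arange(self.k - 1, -1, -1)
            for kmer, level in self.levels.items():
                idx = int(np.dot(_CODE[[ord(b) for b in kmer]], powers))
                arr[idx] = level
            self._level_array = arr
        return self._level_array


@dataclass
class EventSignal:
    """An event-space current signal.

    ``values[i]`` is the current (pA) of sample ``i``; each underlying event
    (one k-mer dwell) spans ``samples_per_event`` consecutive samples when the
    signal was synthesized from a sequence.
    """

    values: np.ndarray
    samples_per_event: int = 1
    source_id: str = ""
    strand: str = "forward"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("signal values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal contains non-finite values")
        if self.samples_per_event < 1:
            raise ValueError("samples_per_event must be >= 1")

    def __len__(self) -> int:
        return len(self.values)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over ``ACGTN`` (case preserved)."""
    bad = set(seq) - set("ACGTNacgtn")
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def load_pore_model(path: str | Path, name: str | None = None) -> PoreModel:
    """Load a tab-delimited pore-model table.

    The table must have a header naming at least ``kmer`` and ``level_mean``
    columns; ``level_stdv`` is used when present and other columns are
    ignored.  All k-mers must share one length; duplicates and non-positive
    means are rejected with the offending row named.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("kmer", "level_mean"):
        if col not in df.columns:
            raise PoreModelError(f"{path}: missing required column {col!r}")
    kmers = df["kmer"].astype(str).str.upper()
    lengths = kmers.str.len().unique()
    if len(lengths) != 1:
        raise PoreModelError(f"{path}: mixed k-mer lengths {sorted(lengths)}")
    dup = kmers[kmers.duplicated()]
    if len(dup):
        raise PoreModelError(f"{path}: duplicate k-mer {dup.iloc[0]!r}")
    bad = df["level_mean"] <= 0
    if bad.any():
        row = df.index[bad][0]
        raise PoreModelError(
            f"{path}: non-positive level_mean at row {row} (kmer {kmers.iloc[row]!r})"
        )
    levels = dict(zip(kmers, df["level_mean"].astype(float)))
    spreads = None
    if "level_stdv" in df.columns:
        spreads = dict(zip(kmers, df["level_stdv"].astype(float)))
    return PoreModel(k=int(lengths[0]), levels=levels, spreads=spreads,
                     name=name if name is not None else path.stem)


def write_pore_model(model: PoreModel, path: str | Path) -> None:
    """Serialize a model in the same tab-delimited dialect ``load_pore_model`` reads."""
    kmers = sorted(model.levels)
    data = {"kmer": kmers, "level_mean": [model.levels[km] for km in kmers]}
    if model.spreads is not None:
        data["level_stdv"] = [model.spreads[km] for km in kmers]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def synthesize_pore_model(
    k: int,
    seed: int,
    level_range: tuple[float, float] = (50.0, 110.0),
    name: str = "synthetic",
) -> PoreModel:
    """Generate a complete synthetic pore model.

    All ``4**k`` k-mers receive pseudo-random mean levels drawn uniformly from
    ``level_range`` and standard deviations from [0.5, 3.0) pA, deterministic
    for a given ``seed``.  Intended as a stand-in for proprietary pore-model
    tables in tests and simulations.
    """
    if k <= 0:
        raise PoreModelError(f"k must be positive, got {k}")
    low, high = level_range
    if not low < high:
        raise PoreModelError(f"invalid level range {level_range}")
    if low <= 0:
        raise PoreModelError("level range must be positive")
    rng = np.random.default_rng(seed)
    kmers = ["".join(p) for p in itertools.product(_BASES, repeat=k)]
    means = rng.uniform(low, high, size=len(kmers))
    stdvs = rng.uniform(0.5, 3.0, size=len(kmers))
    return PoreModel(
        k=k,
        levels=dict(zip(kmers, means.tolist())),
        spreads=dict(zip(kmers, stdvs.tolist())),
        name=name,
    )


def sequence_codes(seq: str) -> np.ndarray:
    """Encode a DNA string as int codes (A=0 C=1 G=2 T=3, N=4)."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        pos = int(np.argmax(codes < 0))
        raise ValueError(f"invalid base {seq[pos]!r} at position {pos}")
    return codes


def kmer_levels(seq: str, model: PoreModel) -> np.ndarray:
    """Per-k-mer model currents for every window of ``seq``.

    k-mers containing N take the model-wide mean level; a single warning
    reporting the affected window count is emitted.
    """
    k = model.k
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} shorter than k={k}")
    codes = sequence_codes(seq)
    n_mask = codes == 4
    codes_clean = np.where(n_mask, 0, codes)
    powers = 4 ** np.arange(k - 1, -1, -1)
    # rolling base-4 index of each k-mer window
    windows = np.lib.stride_tricks.sliding_window_view(codes_clean, k)
    idx = windows @ powers
    levels = model.level_array()[idx]
    if n_mask.any():
        n_windows = np.lib.stride_tricks.sliding_window_view(n_mask, k).any(axis=1)
        n_hit = int(n_windows.sum())
        if n_hit:
            levels = levels.copy()
            levels[n_windows] = model.mean_level
            warnings.warn(
                f"{n_hit} k-mer window(s) contain N; substituted model mean level",
                stacklevel=2,
            )
    return levels


def sequence_to_signal(
    seq: str,
    model: PoreModel,
    samples_per_event: int = 1,
    source_id: str = "",
    strand: str = "forward",
) -> EventSignal:
    """Convert a DNA sequence into its event-space current signal.

    Each of the ``len(seq) - k + 1`` k-mer windows contributes its model mean
    current repeated ``samples_per_event`` times, so the output length is
    ``(len(seq) - k + 1) * samples_per_event``.
    """
    if samples_per_event < 1:
        raise ValueError("samples_per_event must be >= 1")
    levels = kmer_levels(seq, model)
    values = np.repeat(levels, samples_per_event)
    return EventSignal(values=values, samples_per_event=samples_per_event,
                       source_id=source_id, strand=strand)
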