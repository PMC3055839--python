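"""Base-pair signal construction from two-color tiling-array probe tables.

A tiling array measures fluorescence in two channels (red = Cy5,
immunoprecipitated sample; green = Cy3, genomic control) for 50-mer probes
laid out along the genome with partial overlaps and untiled gaps.  The
wavelet transform wants a regularly sampled signal, so each chromosome is
rendered at 1-base resolution: every base inside a probe's exclusive span
takes that probe's intensity, overlapping stretches are split at their
midpoint between the two neighboring probes, and untiled bases are zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BasePairSignal",
    "PROBE_COLUMNS",
    "assigned_spans",
    "build_base_signal",
    "build_channel_signals",
    "pad_to_dyadic",
    "validate_probe_table",
]

#: required columns of a probe table, in canonical order
PROBE_COLUMNS = ("chrom", "start", "end", "red", "green")


@dataclass
class BasePairSignal:
    """A per-base step signal for one chromosome.

    ``origin`` is the genomic coordinate of ``values[0]`` (0-based).
    ``valid_len`` is the length of the real (unpadded) data; entries at and
    beyond ``valid_len`` are dyadic zero-padding added by
    :func:`pad_to_dyadic`.
    """

    chrom: str
    origin: int
    values: np.ndarray
    valid_len: int = field(default=-1)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("signal values must be one-dimensional")
        if self.valid_len < 0:
            self.valid_len = self.values.shape[0]
        if self.valid_len > self.values.shape[0]:
            raise ValueError("valid_len exceeds the stored array length")

    @property
    def padded_len(self) -> int:
        return self.values.shape[0]

    def __len__(self) -> int:
        return self.values.shape[0]


def validate_probe_table(probes: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a probe table.

    Returns a copy sorted by (chrom, start).  Raises ``ValueError`` for
    missing columns, non-positive or non-finite intensities, empty or
    inverted intervals, and duplicated probe coordinates.
    """
    missing = [c for c in PROBE_COLUMNS if c not in probes.columns]
    if missing:
        raise ValueError(f"probe table is missing columns: {missing}")
    df = probes.loc[:, list(PROBE_COLUMNS)].copy()
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["red"] = df["red"].astype(float)
    df["green"] = df["green"].astype(float)
    if len(df) == 0:
        return df
    if (df["end"] <= df["start"]).any():
        raise ValueError("probe table contains intervals with end <= start")
    bad = ~(
        np.isfinite(df["red"]) & np.isfinite(df["green"])
        & (df["red"] > 0) & (df["green"] > 0)
    )
    if bad.any():
        raise ValueError("probe intensities must be finite and > 0")
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    if df.duplicated(["chrom", "start", "end"]).any():
        raise ValueError("duplicated probe coordinates (chrom, start, end)")
    return df


def assigned_spans(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resolve probe overlaps into disjoint per-probe base assignments.

    Probes must be sorted with strictly increasing starts and ends and may
    overlap only with their immediate genomic neighbors.  Each overlap is
    divided equally at its midpoint; for an odd overlap length the extra
    base goes to the upstream (left) probe.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.shape != ends.shape or starts.ndim != 1 or starts.size == 0:
        raise ValueError("starts and ends must be matching nonempty 1-d arrays")
    if np.any(ends <= starts):
        raise ValueError("every probe must satisfy end > start")
    if starts.size > 1 and (np.any(np.diff(starts) <= 0) or np.any(np.diff(ends) <= 0)):
        raise ValueError("probes must be sorted with strictly increasing starts and ends")
    if starts.size > 2 and np.any(ends[:-2] > starts[2:]):
        raise ValueError("triple-overlapping probes: overlaps must involve neighbors only")

    astart = starts.copy()
    aend = ends.copy()
    if starts.size > 1:
        ov = ends[:-1] - starts[1:]
        mid = starts[1:] + (ov + 1) // 2  # odd overlap: extra base to the left probe
        aend[:-1] = np.where(ov > 0, mid, ends[:-1])
        astart[1:] = np.where(ov > 0, mid, starts[1:])
    return astart, aend


def _fill(starts: np.ndarray, ends: np.ndarray, origin: int, length: int,
          *values: np.ndarray) -> list[np.ndarray]:
    out = [np.zeros(length) for _ in values]
    rel_s = (starts - origin).tolist()
    rel_e = (ends - origin).tolist()
    cols = [v.tolist() for v in values]
    for i, (s, e) in enumerate(zip(rel_s, rel_e)):
        for arr, col in zip(out, cols):
            arr[s:e] = col[i]
    return out


def build_channel_signals(probes: pd.DataFrame) -> tuple[BasePairSignal, BasePairSignal]:
    """Build the red and green base-pair signals for one chromosome at once."""
    if probes["chrom"].nunique() != 1:
        raise ValueError("build_channel_signals expects probes from a single chromosome")
    starts = probes["start"].to_numpy(np.int64)
    ends = probes["end"].to_numpy(np.int64)
    astart, aend = assigned_spans(starts, ends)
    origin = int(astart[0])
    length = int(aend[-1] - origin)
    red, green = _fill(astart, aend, origin, length,
                       probes["red"].to_numpy(float), probes["green"].to_numpy(float))
    chrom = str(probes["chrom"].iat[0])
    return BasePairSignal(chrom, origin, red), BasePairSignal(chrom, origin, green)


def build_base_signal(probes: pd.DataFrame, channel: str) -> BasePairSignal:
    """Build the base-pair signal of one channel (``"red"`` or ``"green"``)."""
    if channel not in ("red", "green"):
        raise ValueError(f"channel must be 'red' or 'green', got {channel!r}")
    red, green = build_channel_signals(probes)
    return red if channel == "red" else green


def next_pow2(n: int) -> int:
    """Smallest power of two >= n (n >= 1)."""
    if n < 1:
        raise ValueError("length must be positive")
    return 1 << (n - 1).bit_length()


def pad_to_dyadic(signal: BasePairSignal, min_len: int = 1) -> BasePairSignal:
    """Right-pad a signal with zeros to the next power of two (idempotent).

    ``min_len`` forces at least that padded length, so that every
    decomposition level up to a chosen depth exists even for short
    chromosomes.
    """
    n = signal.padded_len
    if n == 0:
        raise ValueError("cannot pad an empty signal")
    target = max(next_pow2(n), next_pow2(min_len))
    if target == n:
        return signal
    values = np.zeros(target)
    values[:n] = signal.values
    return BasePairSignal(signal.chrom, signal.origin, values, valid_len=signal.valid_len)
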