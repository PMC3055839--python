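"""Coiflet-1 filter banks and the Mallat pyramid transform.

The discrete wavelet transform used throughout this package is the
orthonormal, periodized Mallat pyramid built on the six-tap Coiflet-1
(Coif1) filters.  Coif1 is chosen because its scaling function is nearly
symmetric and triangle-like, matching the shape of enrichment peaks on
ChIP-chip tiling arrays; its approximation coefficients at level ``m``
summarize the signal at a genomic length-scale of roughly ``2**m`` bases.

Conventions
-----------
* Analysis is a stride-2 *correlation* with the decomposition filters:
  ``A[m+1][n] = sum_k dec_lo[k] * A[m][(2n + k) mod N]`` for tap offsets
  ``k = 0..5`` under periodic extension of the dyadic-length array.
* Synthesis is the adjoint of analysis, which for an orthonormal bank is
  the exact inverse; it coincides with the usual reconstruction-filter
  formula up to this fixed index alignment.
* The three tap offsets with the largest absolute weights (|0.8526|,
  |0.3849|, |0.3379|, i.e. offsets 3, 2, 4) define the *dominant children*
  of a coefficient — the three coefficients one level finer that
  contribute most of its value.  They drive the cross-level consistency
  check and the traceback from a called coefficient to a genomic interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .signals import BasePairSignal, pad_to_dyadic

__all__ = [
    "DOMINANT_OFFSETS",
    "FILTER_LEN",
    "FilterBank",
    "WaveletPyramid",
    "coif1_filter_bank",
    "decompose_level",
    "dominant_children",
    "dominant_descendants",
    "multilevel_decompose",
    "reconstruct_level",
    "wavelet_width",
]

#: number of taps of the Coif1 filters
FILTER_LEN = 6

#: tap offsets (0-based) of the three largest-|weight| low-pass taps;
#: child indices of coefficient n one level finer are 2n + offset
DOMINANT_OFFSETS = (2, 3, 4)


@dataclass(frozen=True)
class FilterBank:
    """The four filters of an orthonormal two-channel filter bank.

    ``dec_lo``/``dec_hi`` are the decomposition (analysis) low/high-pass
    filters; ``rec_lo``/``rec_hi`` the reconstruction (synthesis) pair.
    For an orthonormal bank the reconstruction filters are the reversed
    decomposition filters and the high-pass is the quadrature mirror of
    the low-pass.
    """

    dec_lo: np.ndarray
    dec_hi: np.ndarray
    rec_lo: np.ndarray
    rec_hi: np.ndarray

    def __post_init__(self) -> None:
        for name in ("dec_lo", "dec_hi", "rec_lo", "rec_hi"):
            arr = np.asarray(getattr(self, name), dtype=float)
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)


def coif1_filter_bank() -> FilterBank:
    """The Coiflet-1 filter bank at full double precision.

    The taps come from the exact closed form of the order-1 Coiflet
    scaling filter,

        rec_lo = sqrt(2)/32 * [1-s, 5+s, 14+2s, 14-2s, 1-s, -3+s],
        s = sqrt(7),

    with ``dec_lo`` its reversal and the high-pass filters obtained by the
    quadrature-mirror rule ``dec_hi[k] = (-1)**(k+1) * rec_lo[k]``.  The
    low-pass taps sum to sqrt(2) and the high-pass taps to zero.
    """
    s7 = math.sqrt(7.0)
    rec_lo = (math.sqrt(2.0) / 32.0) * np.array(
        [1 - s7, 5 + s7, 14 + 2 * s7, 14 - 2 * s7, 1 - s7, -3 + s7]
    )
    dec_lo = rec_lo[::-1].copy()
    signs = np.where(np.arange(FILTER_LEN) % 2 == 0, -1.0, 1.0)
    dec_hi = signs * rec_lo  # (-1)**(k+1) * rec_lo[k]
    rec_hi = dec_hi[::-1].copy()
    return FilterBank(dec_lo=dec_lo, dec_hi=dec_hi, rec_lo=rec_lo, rec_hi=rec_hi)


_COIF1: FilterBank | None = None


def _default_bank() -> FilterBank:
    global _COIF1
    if _COIF1 is None:
        _COIF1 = coif1_filter_bank()
    return _COIF1


def _periodic_ext(values: np.ndarray, extra: int) -> np.ndarray:
    """values extended on the right by ``extra`` periodically wrapped entries."""
    n = values.shape[0]
    if extra <= n:
        return np.concatenate([values, values[:extra]])
    reps = -(-extra // n) + 1
    return np.tile(values, reps)[: n + extra]


def decompose_level(
    values: np.ndarray, bank: FilterBank | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """One analysis step: split a signal into approximation and detail.

    ``values`` must have even length.  Both outputs have half the input
    length.  Periodic boundary extension keeps the step orthonormal, so
    ``||values||^2 == ||approx||^2 + ||detail||^2`` to rounding error.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n < 2 or n % 2:
        raise ValueError(f"decompose_level needs an even-length input, got length {n}")
    bank = bank or _default_bank()
    ext = _periodic_ext(values, FILTER_LEN - 1)
    half = n // 2
    approx = np.zeros(half)
    detail = np.zeros(half)
    for k in range(FILTER_LEN):
        seg = ext[k : k + n : 2]
        approx += bank.dec_lo[k] * seg
        detail += bank.dec_hi[k] * seg
    return approx, detail


def reconstruct_level(
    approx: np.ndarray, detail: np.ndarray, bank: FilterBank | None = None
) -> np.ndarray:
    """One synthesis step, the exact inverse of :func:`decompose_level`."""
    approx = np.asarray(approx, dtype=float)
    detail = np.asarray(detail, dtype=float)
    if approx.shape != detail.shape or approx.ndim != 1:
        raise ValueError(
            f"approx and detail must be 1-d arrays of equal length, "
            f"got {approx.shape} and {detail.shape}"
        )
    bank = bank or _default_bank()
    half = approx.shape[0]
    n = 2 * half
    buf = np.zeros(n + FILTER_LEN - 1)
    for k in range(FILTER_LEN):
        buf[k : k + n : 2] += bank.dec_lo[k] * approx + bank.dec_hi[k] * detail
    out = buf[:n].copy()
    tail = buf[n:]
    while tail.size:  # fold the periodic wrap-around back in
        take = min(n, tail.size)
        out[:take] += tail[:take]
        tail = tail[take:]
    return out


def wavelet_width(level: int) -> int:
    """Genomic width (bases) resolved by level ``m``: 2**m."""
    if level < 0:
        raise ValueError("level must be non-negative")
    return 1 << level


@dataclass
class WaveletPyramid:
    """Multilevel decomposition of one chromosome's base-pair signal.

    ``approx[m]`` / ``detail[m]`` hold the coefficients at level ``m``;
    ``approx[0]`` is the padded input itself and ``detail[0]`` is ``None``.
    ``origin`` is the genomic coordinate of index 0 at level 0 and
    ``valid_len`` the unpadded signal length, so coefficients supported
    only on padding are identifiable.
    """

    chrom: str
    origin: int
    valid_len: int
    approx: list[np.ndarray]
    detail: list[np.ndarray | None]

    @property
    def padded_len(self) -> int:
        return self.approx[0].shape[0]

    @property
    def max_level(self) -> int:
        return len(self.approx) - 1

    def level_len(self, level: int) -> int:
        return self.approx[level].shape[0]

    def reconstruct(self, bank: FilterBank | None = None) -> np.ndarray:
        """Invert the full pyramid back to the level-0 signal."""
        bank = bank or _default_bank()
        cur = self.approx[self.max_level]
        for m in range(self.max_level, 0, -1):
            if self.detail[m] is None:
                raise ValueError(f"detail coefficients at level {m} were not kept")
            cur = reconstruct_level(cur, self.detail[m], bank)
        return cur


def multilevel_decompose(
    signal: BasePairSignal,
    max_level: int,
    bank: FilterBank | None = None,
    keep_details: bool = True,
) -> WaveletPyramid:
    """Run the Mallat pyramid down to ``max_level``.

    The signal is zero-padded to dyadic length first (a no-op if already
    dyadic).  ``keep_details=False`` drops the detail arrays to halve the
    memory footprint; peak scoring only reads approximation coefficients.
    """
    if max_level < 1:
        raise ValueError("max_level must be >= 1")
    sig = pad_to_dyadic(signal)
    n = sig.padded_len
    if (1 << max_level) > n:
        raise ValueError(
            f"max_level {max_level} is too deep for a padded signal of length {n}"
        )
    bank = bank or _default_bank()
    approx: list[np.ndarray] = [np.asarray(sig.values, dtype=float)]
    detail: list[np.ndarray | None] = [None]
    cur = approx[0]
    for _ in range(max_level):
        a, d = decompose_level(cur, bank)
        approx.append(a)
        detail.append(d if keep_details else None)
        cur = a
    return WaveletPyramid(
        chrom=sig.chrom,
        origin=sig.origin,
        valid_len=sig.valid_len,
        approx=approx,
        detail=detail,
    )


def dominant_children(index: int, level_len: int | None = None) -> list[int]:
    """Indices one level finer of the three dominant contributors.

    Under the analysis alignment used here, coefficient ``n`` at level
    ``m+1`` is a weighted sum of coefficients ``2n + k`` (``k = 0..5``) at
    level ``m``; the three largest-|weight| taps sit at offsets 2, 3, 4.
    ``level_len`` wraps the indices periodically into the finer level.
    """
    if index < 0:
        raise ValueError("index must be non-negative")
    kids = [2 * index + k for k in DOMINANT_OFFSETS]
    if level_len is not None:
        kids = [k % level_len for k in kids]
    return kids


def dominant_descendants(
    index: int, depth: int, level_len: int | None = None
) -> list[int]:
    """Deduplicated dominant-descendant indices ``depth`` levels finer.

    One step gives 3 children; two steps give 7 distinct grandchildren
    (the three 3-sets overlap).  Indices wrap into ``level_len`` if given.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    cur = {index}
    for _ in range(depth):
        cur = {2 * i + k for i in cur for k in DOMINANT_OFFSETS}
    if level_len is not None:
        cur = {i % level_len for i in cur}
    return sorted(cur)
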