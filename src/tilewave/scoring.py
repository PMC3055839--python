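"""The multiscale peak caller: thresholding, consistency, traceback, merging.

Pipeline (per two-channel array):

1.  Build red/green base-pair signals per chromosome, zero-pad to dyadic
    length and decompose both with the Coif1 Mallat pyramid down to level
    ``M2``, the coarsest scale of interest.
2.  At every level ``M1-2 <= m <= M2`` form the per-coefficient log-ratio
    ``ln(A_red(m)/A_green(m))``, masking coefficients where either channel
    is at or below the validity floor (default 1, which removes
    coefficients supported only on untiled gaps or padding).
3.  Fit a Gaussian to each level's unmasked log-ratios.  Under the null —
    cross-hybridization only — the wavelet coefficients follow a
    log-normal law, so the log-ratio is approximately normal with level
    standard deviation ``sigma_m``.  Coefficients whose (optionally
    mean-centered) log-ratio exceeds ``alpha * sigma_m`` are threshold
    candidates; the shared multiplier ``alpha`` calls peaks of every width
    at the same confidence.
4.  A candidate at a callable level (``M1 <= m <= M2``) is confirmed only
    if enough of its dominant supporters at the two next-finer levels —
    3 dominant children at ``m-1`` plus 7 deduplicated dominant
    grandchildren at ``m-2`` — are themselves above threshold.  The two
    sub-``M1`` levels exist only for this check and never yield hits.
5.  Confirmed coefficients are traced back through their dominant
    children to base-pair intervals; overlapping or book-ended intervals
    merge into final hit regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .filters import (
    DOMINANT_OFFSETS,
    WaveletPyramid,
    multilevel_decompose,
)
from .signals import (
    BasePairSignal,
    assigned_spans,
    next_pow2,
    validate_probe_table,
)

__all__ = [
    "ChromRatios",
    "HitRegion",
    "LevelStats",
    "PreparedTable",
    "ScoringParams",
    "call_peaks",
    "consistency_filter",
    "fit_level_stats",
    "fit_stats",
    "level_log_ratios",
    "merge_hits",
    "score_ratio_maps",
    "threshold_candidates",
    "traceback_region",
    "zscore_tracks",
]

#: deduplicated dominant grandchild offsets: {2*(2n+j)+k} for j,k in {2,3,4}
_GRANDCHILD_OFFSETS = tuple(range(6, 13))


@dataclass(frozen=True)
class ScoringParams:
    """Caller parameters.

    m1, m2
        Decomposition-level bounds: hits are called at levels
        ``m1 <= m <= m2``, targeting peaks of width 2**m1 .. 2**m2 bases.
        Defaults (8, 11) target 256-2048 bp, suitable for Pol II-like
        factors; use ``m2=12`` for broad histone-modification domains.
    alpha
        Threshold multiplier on the per-level log-ratio spread sigma_m.
    floor
        Coefficient validity floor in raw intensity units; coefficient
        pairs where either channel is <= floor are excluded (they sit on
        untiled gaps or padding, where log transforms are meaningless).
    min_consistent
        How many of the 10 dominant supporting coefficients (3 children +
        7 grandchildren) must pass threshold for a candidate to become a
        hit.  0 disables the consistency check.
    center
        Subtract the fitted level mean before thresholding (robust to a
        global dye imbalance).  ``False`` thresholds the raw log-ratio.
    robust
        Fit mu/sigma by median and 1.4826*MAD instead of mean/SD.
    """

    m1: int = 8
    m2: int = 11
    alpha: float = 3.0
    floor: float = 1.0
    min_consistent: int = 3
    center: bool = True
    robust: bool = False

    def __post_init__(self) -> None:
        if self.m1 < 3:
            raise ValueError("m1 must be >= 3 (levels m1-1 and m1-2 must exist)")
        if self.m2 < self.m1:
            raise ValueError("m2 must be >= m1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.min_consistent < 0:
            raise ValueError("min_consistent must be >= 0")

    @property
    def levels(self) -> range:
        """Callable levels m1..m2."""
        return range(self.m1, self.m2 + 1)

    @property
    def support_levels(self) -> range:
        """All levels that are thresholded: m1-2..m2."""
        return range(self.m1 - 2, self.m2 + 1)

    def peak_width_range(self) -> tuple[int, int]:
        """Targeted peak widths in bases: (2**m1, 2**m2)."""
        return (1 << self.m1, 1 << self.m2)


@dataclass(frozen=True)
class LevelStats:
    """Gaussian fit of one level's log-ratio distribution."""

    level: int
    mu: float
    sigma: float
    n_used: int


@dataclass(frozen=True)
class HitRegion:
    """A called genomic interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    levels: tuple[int, ...]
    score: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("hit region must satisfy end > start")
        object.__setattr__(self, "levels", tuple(sorted(set(self.levels))))

    @property
    def name(self) -> str:
        return "+".join(f"m{m}" for m in self.levels)

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class ChromRatios:
    """Per-level masked log-ratio arrays for one chromosome."""

    chrom: str
    origin: int
    valid_len: int
    ratios: dict[int, np.ma.MaskedArray]


def level_log_ratios(
    pyr_red: WaveletPyramid,
    pyr_green: WaveletPyramid,
    floor: float = 1.0,
    levels: Iterable[int] | None = None,
) -> dict[int, np.ma.MaskedArray]:
    """Masked ``ln(A_red/A_green)`` per level.

    Positions where either channel's approximation coefficient is <= floor
    are masked and never enter fitting or thresholding.
    """
    if (
        pyr_red.chrom != pyr_green.chrom
        or pyr_red.origin != pyr_green.origin
        or pyr_red.padded_len != pyr_green.padded_len
        or pyr_red.max_level != pyr_green.max_level
    ):
        raise ValueError("red and green pyramids do not share geometry")
    if levels is None:
        levels = range(1, pyr_red.max_level + 1)
    out: dict[int, np.ma.MaskedArray] = {}
    for m in levels:
        ar = pyr_red.approx[m]
        ag = pyr_green.approx[m]
        valid = (ar > floor) & (ag > floor)
        ratio = np.ones_like(ar)
        np.divide(ar, ag, out=ratio, where=valid)
        lr = np.log(ratio)
        out[m] = np.ma.masked_array(lr, mask=~valid)
    return out


def fit_level_stats(
    log_ratios: np.ndarray | np.ma.MaskedArray,
    level: int,
    robust: bool = False,
) -> LevelStats:
    """Gaussian fit (mu, sigma) of one level's unmasked log-ratios.

    The default is the sample mean and SD (n-1 denominator) over *all*
    unmasked values — enrichment outliers are not trimmed.  ``robust=True``
    uses the median and 1.4826*MAD instead.
    """
    vals = np.ma.compressed(np.ma.masked_invalid(log_ratios))
    n = vals.shape[0]
    if n < 2:
        raise ValueError(f"level {level}: need >= 2 unmasked log-ratios, got {n}")
    if robust:
        mu = float(np.median(vals))
        sigma = float(1.4826 * np.median(np.abs(vals - mu)))
    else:
        mu = float(vals.mean())
        sigma = float(vals.std(ddof=1))
    return LevelStats(level=level, mu=mu, sigma=sigma, n_used=n)


def fit_stats(
    maps: Sequence[ChromRatios], params: ScoringParams
) -> dict[int, LevelStats]:
    """Fit per-level stats pooling unmasked log-ratios across chromosomes."""
    stats: dict[int, LevelStats] = {}
    for m in params.support_levels:
        pooled = np.concatenate(
            [np.ma.compressed(cr.ratios[m]) for cr in maps if m in cr.ratios]
        )
        stats[m] = fit_level_stats(pooled, m, robust=params.robust)
    return stats


def _thresholds(
    stats: Mapping[int, LevelStats], params: ScoringParams
) -> dict[int, float]:
    thr = {}
    for m in params.support_levels:
        st = stats[m]
        if st.sigma <= 0:
            raise ValueError(f"level {m}: sigma is 0; thresholding is undefined")
        thr[m] = params.alpha * st.sigma + (st.mu if params.center else 0.0)
    return thr


def _passed_arrays(
    ratios: Mapping[int, np.ma.MaskedArray],
    stats: Mapping[int, LevelStats],
    params: ScoringParams,
) -> dict[int, np.ndarray]:
    """Boolean per-level arrays of threshold-passing, unmasked positions."""
    thr = _thresholds(stats, params)
    out = {}
    for m in params.support_levels:
        arr = ratios[m]
        out[m] = np.asarray(arr.data > thr[m]) & ~np.ma.getmaskarray(arr)
    return out


def threshold_candidates(
    ratios: Mapping[int, np.ma.MaskedArray],
    stats: Mapping[int, LevelStats],
    params: ScoringParams,
) -> set[tuple[int, int]]:
    """Positions exceeding ``alpha*sigma_m`` at every level m1-2..m2.

    The two levels below m1 are thresholded only to support the
    consistency check; they can never become hits themselves.
    """
    passed = _passed_arrays(ratios, stats, params)
    return {
        (m, int(n)) for m in params.support_levels for n in np.nonzero(passed[m])[0]
    }


def consistency_filter(
    candidates: set[tuple[int, int]],
    ratios: Mapping[int, np.ma.MaskedArray],
    stats: Mapping[int, LevelStats],
    params: ScoringParams,
) -> set[tuple[int, int]]:
    """Keep candidates whose dominant support also passes threshold.

    A candidate ``(m, n)`` with ``m1 <= m <= m2`` is confirmed iff at
    least ``min_consistent`` of its 10 dominant supporters — children
    ``2n+2..2n+4`` at level m-1 and grandchildren ``4n+6..4n+12`` at level
    m-2, wrapped periodically — are themselves candidates at their level.
    """
    passed: dict[int, np.ndarray] = {}
    for m in params.support_levels:
        arr = np.zeros(ratios[m].shape[0], dtype=bool)
        passed[m] = arr
    for m, n in candidates:
        if m in passed:
            passed[m][n] = True

    confirmed: set[tuple[int, int]] = set()
    for m in params.levels:
        ns = np.array(sorted(n for (lm, n) in candidates if lm == m), dtype=np.int64)
        if ns.size == 0:
            continue
        l1 = passed[m - 1].shape[0]
        l2 = passed[m - 2].shape[0]
        count = np.zeros(ns.size, dtype=np.int64)
        for off in DOMINANT_OFFSETS:
            count += passed[m - 1][(2 * ns + off) % l1]
        for off in _GRANDCHILD_OFFSETS:
            count += passed[m - 2][(4 * ns + off) % l2]
        for n, c in zip(ns.tolist(), count.tolist()):
            if c >= params.min_consistent:
                confirmed.add((m, n))
    return confirmed


def traceback_region(
    level: int, index: int, origin: int = 0, valid_len: int | None = None
) -> tuple[int, int] | None:
    """Genomic interval reached by dominant-child descent to level 0.

    Expanding ``n -> {2n+2, 2n+3, 2n+4}`` level by level keeps the index
    set contiguous, so the descent reduces to tracking its end points:
    after ``m`` steps the level-0 span is
    ``[2**m * n + 2*(2**m - 1), 2**m * n + 4*(2**m - 1) + 1)``.
    The result is clipped to the unpadded signal extent and shifted by
    ``origin``; ``None`` means the span lies entirely in padding.
    """
    if level < 0 or index < 0:
        raise ValueError("level and index must be non-negative")
    lo = hi = index
    for _ in range(level):
        lo = 2 * lo + DOMINANT_OFFSETS[0]
        hi = 2 * hi + DOMINANT_OFFSETS[-1]
    hi += 1
    if valid_len is not None:
        hi = min(hi, valid_len)
        if lo >= valid_len:
            return None
    if hi <= lo:
        return None
    return (origin + lo, origin + hi)


def merge_hits(
    intervals: Iterable[tuple[str, int, int, Iterable[int], float] | HitRegion],
) -> list[HitRegion]:
    """Union overlapping or book-ended scored intervals into hit regions.

    Levels aggregate by union, scores by max.  Output is sorted by
    (chrom, start).  Idempotent.
    """
    norm: list[tuple[str, int, int, tuple[int, ...], float]] = []
    for item in intervals:
        if isinstance(item, HitRegion):
            norm.append((item.chrom, item.start, item.end, item.levels, item.score))
        else:
            chrom, start, end, levels, score = item
            norm.append((chrom, int(start), int(end), tuple(levels), float(score)))
    norm.sort(key=lambda t: (t[0], t[1], t[2]))
    out: list[HitRegion] = []
    cur: list | None = None
    for chrom, start, end, levels, score in norm:
        if cur is not None and chrom == cur[0] and start <= cur[2]:
            cur[2] = max(cur[2], end)
            cur[3] |= set(levels)
            cur[4] = max(cur[4], score)
        else:
            if cur is not None:
                out.append(HitRegion(cur[0], cur[1], cur[2], tuple(cur[3]), cur[4]))
            cur = [chrom, start, end, set(levels), score]
    if cur is not None:
        out.append(HitRegion(cur[0], cur[1], cur[2], tuple(cur[3]), cur[4]))
    return out


class PreparedTable:
    """Per-chromosome geometry and green-channel pyramids, cached.

    Shuffle-based FPR estimation and alpha sweeps re-run the caller many
    times on the same probe coordinates; only the red channel changes.
    This cache builds the green pyramids once and re-derives red pyramids
    from any red-intensity vector in table order.
    """

    def __init__(self, probes: pd.DataFrame, max_level: int):
        self.max_level = max_level
        self.red_values = probes["red"].to_numpy(float)
        self._chroms: list[dict] = []
        min_len = 1 << max_level
        for chrom, grp in probes.groupby("chrom", sort=True):
            starts = grp["start"].to_numpy(np.int64)
            ends = grp["end"].to_numpy(np.int64)
            astart, aend = assigned_spans(starts, ends)
            origin = int(astart[0])
            valid_len = int(aend[-1] - origin)
            padded_len = max(next_pow2(valid_len), min_len)
            green = np.zeros(padded_len)
            rel_s = (astart - origin).tolist()
            rel_e = (aend - origin).tolist()
            gv = grp["green"].to_numpy(float).tolist()
            for s, e, g in zip(rel_s, rel_e, gv):
                green[s:e] = g
            gsig = BasePairSignal(str(chrom), origin, green, valid_len=valid_len)
            gpyr = multilevel_decompose(gsig, max_level, keep_details=False)
            self._chroms.append(
                dict(
                    chrom=str(chrom),
                    origin=origin,
                    valid_len=valid_len,
                    padded_len=padded_len,
                    rel_s=rel_s,
                    rel_e=rel_e,
                    rows=slice(
                        int(grp.index[0]), int(grp.index[-1]) + 1
                    ),
                    green_pyr=gpyr,
                )
            )

    @classmethod
    def from_probes(cls, probes: pd.DataFrame, max_level: int) -> "PreparedTable":
        return cls(validate_probe_table(probes), max_level)

    def ratio_maps(
        self, red_values: np.ndarray, params: ScoringParams
    ) -> list[ChromRatios]:
        """Build red pyramids from a red-intensity vector and form ratios."""
        red_values = np.asarray(red_values, float)
        if red_values.shape != self.red_values.shape:
            raise ValueError("red_values has the wrong length for this table")
        maps = []
        for ch in self._chroms:
            red = np.zeros(ch["padded_len"])
            rv = red_values[ch["rows"]].tolist()
            for s, e, r in zip(ch["rel_s"], ch["rel_e"], rv):
                red[s:e] = r
            rsig = BasePairSignal(ch["chrom"], ch["origin"], red, valid_len=ch["valid_len"])
            rpyr = multilevel_decompose(rsig, self.max_level, keep_details=False)
            ratios = level_log_ratios(
                rpyr, ch["green_pyr"], floor=params.floor, levels=params.support_levels
            )
            maps.append(
                ChromRatios(ch["chrom"], ch["origin"], ch["valid_len"], ratios)
            )
        return maps


def score_ratio_maps(
    maps: Sequence[ChromRatios],
    stats: Mapping[int, LevelStats],
    params: ScoringParams,
    collect_counts: bool = False,
):
    """Threshold, confirm, traceback and merge; the caller's back half."""
    hits: list[HitRegion] = []
    cand_counts = {m: 0 for m in params.support_levels}
    conf_counts = {m: 0 for m in params.levels}
    for cr in maps:
        cands = threshold_candidates(cr.ratios, stats, params)
        confirmed = consistency_filter(cands, cr.ratios, stats, params)
        if collect_counts:
            for m, _ in cands:
                cand_counts[m] += 1
            for m, _ in confirmed:
                conf_counts[m] += 1
        scored = []
        for m, n in confirmed:
            st = stats[m]
            z = (float(cr.ratios[m].data[n]) - st.mu) / st.sigma
            span = traceback_region(m, n, cr.origin, cr.valid_len)
            if span is not None:
                scored.append((cr.chrom, span[0], span[1], (m,), z))
        hits.extend(merge_hits(scored))
    hits.sort(key=lambda h: (h.chrom, h.start))
    if collect_counts:
        return hits, cand_counts, conf_counts
    return hits


def call_peaks(
    probes: pd.DataFrame,
    params: ScoringParams | None = None,
    stats_override: Mapping[int, LevelStats] | None = None,
) -> list[HitRegion]:
    """End-to-end peak calling on a probe table.

    Composition: build signals -> pad -> decompose to m2 -> log-ratios ->
    fit per-level Gaussians (pooled across chromosomes) -> threshold ->
    consistency -> traceback -> merge.  Deterministic given inputs.
    """
    params = params or ScoringParams()
    probes = validate_probe_table(probes)
    if len(probes) == 0:
        return []
    prep = PreparedTable(probes, params.m2)
    maps = prep.ratio_maps(prep.red_values, params)
    stats = dict(stats_override) if stats_override else fit_stats(maps, params)
    return score_ratio_maps(maps, stats, params)


def zscore_tracks(
    maps: Sequence[ChromRatios],
    stats: Mapping[int, LevelStats],
    params: ScoringParams,
) -> dict[int, list[tuple[str, int, int, float]]]:
    """Per-level browser tracks of standardized log-ratios.

    Each unmasked coefficient is rendered as a non-overlapping 2**m-base
    cell centered on its dominant-support midpoint.
    """
    tracks: dict[int, list[tuple[str, int, int, float]]] = {}
    for m in params.levels:
        rows: list[tuple[str, int, int, float]] = []
        width = 1 << m
        shift = 3 * (width - 1) - width // 2
        st = stats[m]
        for cr in maps:
            arr = cr.ratios[m]
            idx = np.nonzero(~np.ma.getmaskarray(arr))[0]
            z = (arr.data[idx] - st.mu) / st.sigma
            for n, zi in zip(idx.tolist(), z.tolist()):
                s = n * width + shift
                e = min(s + width, cr.valid_len)
                s = max(s, 0)
                if e > s:
                    rows.append((cr.chrom, cr.origin + s, cr.origin + e, float(zi)))
        tracks[m] = rows
    return tracks
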