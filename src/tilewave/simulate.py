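"""Synthetic two-channel tiling arrays with known truth, and ROC scoring.

The generator emulates a Nimblegen-style tiling design — 50-mer probes
every 38 bases (12-base overlaps) with untiled repeat gaps — and the
statistical structure the caller assumes: green-channel background drawn
from a log-normal (multiplicative cross-hybridization noise), red equal
to green times a triangular enrichment profile times per-probe log-normal
ratio noise.  Truth intervals are returned alongside the probe table, so
calls can be scored ROC-style: sensitivity = TP/n_truth against
fp_ratio = FP/n_truth as the threshold alpha is swept.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .scoring import (
    HitRegion,
    PreparedTable,
    ScoringParams,
    fit_stats,
    score_ratio_maps,
)
from .signals import validate_probe_table

__all__ = ["RocPoint", "SimParams", "evaluate_calls", "roc_curve", "simulate_array"]


@dataclass(frozen=True)
class SimParams:
    """Synthetic tiling-array study conditions.

    Defaults emulate the ENCODE Nimblegen design: ~30 Mb of sequence,
    50-mer probes spaced every 38 bases (12-base overlap), with roughly
    half of the territory untiled (interspersed repeats), giving ~380k
    probes.  Background intensities are log-normal in arbitrary
    fluorescence units (median ~1100, well above the validity floor of 1);
    per-probe ratio noise has log-SD 0.3.  Spike-in peaks are triangular,
    100 per array, 200-2000 bases wide at 3-6 fold apex enrichment —
    narrow-peak conditions scored with m1=8, m2=9.
    """

    genome_length: int = 30_000_000
    probe_len: int = 50
    spacing: int = 38
    gap_fraction: float = 0.5
    mean_gap_length: float = 2000.0
    gap_intervals: tuple[tuple[int, int], ...] | None = None
    background_meanlog: float = 7.0
    background_sdlog: float = 0.5
    noise_sd: float = 0.3
    n_peaks: int = 100
    peak_width: tuple[float, float] = (200.0, 2000.0)
    enrichment: tuple[float, float] = (3.0, 6.0)
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.probe_len <= 0 or self.spacing <= 0:
            raise ValueError("probe_len and spacing must be positive")
        if not (0 <= self.gap_fraction < 1):
            raise ValueError("gap_fraction must be in [0, 1)")
        if self.n_peaks < 0:
            raise ValueError("n_peaks must be >= 0")
        if self.n_peaks:
            if self.peak_width[0] < self.spacing:
                raise ValueError("peak widths must be >= probe spacing")
            if self.enrichment[0] <= 1:
                raise ValueError("enrichment must be > 1")


def _draw_gaps(params: SimParams, rng: np.random.Generator) -> list[tuple[int, int]]:
    if params.gap_intervals is not None:
        gaps = sorted((int(s), int(e)) for s, e in params.gap_intervals)
        for s, e in gaps:
            if e <= s:
                raise ValueError("gap intervals must satisfy end > start")
        return gaps
    f = params.gap_fraction
    if f <= 0:
        return []
    mean_tiled = params.mean_gap_length * (1.0 - f) / f
    gaps = []
    pos = 0
    while pos < params.genome_length:
        pos += max(int(rng.exponential(mean_tiled)), 2 * params.probe_len)
        glen = max(int(rng.exponential(params.mean_gap_length)), 1)
        if pos >= params.genome_length:
            break
        gaps.append((pos, min(pos + glen, params.genome_length)))
        pos += glen
    return gaps


def _in_gap(start: np.ndarray, end: np.ndarray, gaps: list[tuple[int, int]]) -> np.ndarray:
    """True where [start, end) overlaps any gap interval."""
    if not gaps:
        return np.zeros(start.shape, dtype=bool)
    gs = np.array([g[0] for g in gaps])
    ge = np.array([g[1] for g in gaps])
    idx = np.searchsorted(gs, end, side="left") - 1
    hit = np.zeros(start.shape, dtype=bool)
    ok = idx >= 0
    hit[ok] = ge[idx[ok]] > start[ok]
    return hit


def _place_peaks(
    params: SimParams, gaps: list[tuple[int, int]], rng: np.random.Generator
) -> pd.DataFrame:
    """Rejection-sample disjoint triangular peaks inside tiled territory."""
    placed_s: list[int] = []
    placed_e: list[int] = []
    rows = []
    cap = max(1000, 400 * params.n_peaks)
    attempts = 0
    while len(rows) < params.n_peaks:
        if attempts >= cap:
            raise RuntimeError(
                f"could not place {params.n_peaks} disjoint peaks in tiled "
                f"territory after {cap} attempts"
            )
        attempts += 1
        w = rng.uniform(*params.peak_width)
        fold = rng.uniform(*params.enrichment)
        c = rng.uniform(w / 2, params.genome_length - w / 2)
        s, e = int(c - w / 2), int(c + w / 2)
        if e <= s:
            continue
        if _in_gap(np.array([s]), np.array([e]), gaps)[0]:
            continue
        i = bisect.bisect_left(placed_s, s)
        if (i < len(placed_s) and placed_s[i] < e) or (i > 0 and placed_e[i - 1] > s):
            continue
        placed_s.insert(i, s)
        placed_e.insert(i, e)
        rows.append((s, e, fold))
    rows.sort()
    return pd.DataFrame(rows, columns=["start", "end", "fold"])


def simulate_array(
    params: SimParams | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (probe_table, truth) for one synthetic array.

    Deterministic per seed.  The probe table has columns
    chrom/start/end/red/green; truth has chrom/start/end/fold (BED-style,
    0-based half-open).  Peaks never overlap gaps or each other.
    """
    params = params or SimParams()
    rng = np.random.default_rng(seed)
    gaps = _draw_gaps(params, rng)

    starts = np.arange(0, params.genome_length - params.probe_len + 1,
                       params.spacing, dtype=np.int64)
    keep = ~_in_gap(starts, starts + params.probe_len, gaps)
    starts = starts[keep]
    if starts.size == 0:
        raise ValueError("no probes survive the gap model; lower gap_fraction")
    ends = starts + params.probe_len

    green = rng.lognormal(params.background_meanlog, params.background_sdlog,
                          starts.size)

    truth = _place_peaks(params, gaps, rng) if params.n_peaks else pd.DataFrame(
        columns=["start", "end", "fold"]
    )
    enrich = np.ones(starts.size)
    mids = starts + params.probe_len / 2.0
    for s, e, fold in truth.itertuples(index=False):
        c = (s + e) / 2.0
        half = (e - s) / 2.0
        i0, i1 = np.searchsorted(mids, [s, e])
        tri = np.clip(1.0 - np.abs(mids[i0:i1] - c) / half, 0.0, 1.0)
        enrich[i0:i1] = 1.0 + (fold - 1.0) * tri

    red = green * enrich * np.exp(rng.normal(0.0, params.noise_sd, starts.size))

    probes = pd.DataFrame(
        {"chrom": params.chrom, "start": starts, "end": ends,
         "red": red, "green": green}
    )
    truth = truth.assign(chrom=params.chrom)[["chrom", "start", "end", "fold"]]
    return probes, truth


@dataclass(frozen=True)
class RocPoint:
    """One operating point of the caller against a truth set."""

    alpha: float | None
    tp: int
    fp: int
    n_truth: int
    n_hits: int

    @property
    def sensitivity(self) -> float:
        return self.tp / self.n_truth

    @property
    def fp_ratio(self) -> float:
        return self.fp / self.n_truth


def _as_interval_frame(obj) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        return obj[["chrom", "start", "end"]].copy()
    rows = []
    for item in obj:
        if isinstance(item, HitRegion):
            rows.append((item.chrom, item.start, item.end))
        else:
            chrom, start, end = item[0], item[1], item[2]
            rows.append((chrom, int(start), int(end)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def evaluate_calls(
    hits, truth, alpha: float | None = None, min_overlap_frac: float = 0.0
) -> RocPoint:
    """Score called regions against truth intervals.

    TP counts truth intervals overlapped by at least one hit (truth-side
    counting: one hit spanning two truth intervals contributes two TPs);
    FP counts hits overlapping no truth interval.  The overlap criterion
    is >= 1 base, or >= ``min_overlap_frac`` of the truth interval length
    if set.
    """
    hits_df = _as_interval_frame(hits)
    truth_df = _as_interval_frame(truth)
    if len(truth_df) == 0:
        raise ValueError("truth interval set is empty")
    n_truth = len(truth_df)
    tp = 0
    fp = 0
    for chrom in set(truth_df["chrom"]) | set(hits_df["chrom"]):
        t = truth_df[truth_df["chrom"] == chrom]
        h = hits_df[hits_df["chrom"] == chrom]
        ts = t["start"].to_numpy(np.int64)[:, None]
        te = t["end"].to_numpy(np.int64)[:, None]
        hs = h["start"].to_numpy(np.int64)[None, :]
        he = h["end"].to_numpy(np.int64)[None, :]
        if ts.size and hs.size:
            ov = np.clip(np.minimum(te, he) - np.maximum(ts, hs), 0, None)
            need = np.maximum(1, np.ceil(min_overlap_frac * (te - ts)))
            tp += int(np.any(ov >= need, axis=1).sum())
            fp += int(np.all(ov < 1, axis=0).sum())
        else:
            fp += int(hs.size)
    return RocPoint(alpha=alpha, tp=tp, fp=fp, n_truth=n_truth, n_hits=len(hits_df))


def roc_curve(
    probes: pd.DataFrame,
    truth,
    params: ScoringParams | None = None,
    alphas: Sequence[float] = (6.0, 5.0, 4.0, 3.5, 3.0, 2.5, 2.0),
) -> list[RocPoint]:
    """ROC-type sweep: one full caller run per alpha, strictest first.

    ``alphas`` must be sorted in descending order, so candidate sets are
    nested and sensitivity is non-decreasing along the curve.  The
    wavelet pyramids and sigma_m fits are shared across the sweep (they
    do not depend on alpha), so the sweep costs one decomposition.
    """
    alphas = list(alphas)
    if alphas != sorted(alphas, reverse=True):
        raise ValueError("alphas must be sorted in descending order")
    params = params or ScoringParams()
    probes = validate_probe_table(probes)
    prep = PreparedTable(probes, params.m2)
    maps = prep.ratio_maps(prep.red_values, params)
    stats = fit_stats(maps, params)
    points = []
    for a in alphas:
        p = replace(params, alpha=a)
        hits = score_ratio_maps(maps, stats, p)
        points.append(evaluate_calls(hits, truth, alpha=a))
    return points
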