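"""Model/results facade for the multiscale wavelet peak caller.

:class:`WaveletPeakCaller` is built from a probe table (a pandas
DataFrame or TSV file) plus :class:`~tilewave.scoring.ScoringParams`;
``fit()`` runs the full pipeline and returns a :class:`PeakCallResult`
carrying the hit regions, the per-level Gaussian null fits, diagnostic
counts and a ``summary()`` table.  ``fit_fpr()`` first picks the
threshold alpha whose shuffle-estimated false positive rate matches a
requested operating point (the usual way the threshold is chosen in
practice), then fits at that alpha.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import io as twio
from .fpr import FprEstimate, alpha_for_fpr, estimate_fpr
from .scoring import (
    HitRegion,
    LevelStats,
    PreparedTable,
    ScoringParams,
    fit_stats,
    score_ratio_maps,
    zscore_tracks,
)
from .signals import validate_probe_table
from .simulate import RocPoint, evaluate_calls

__all__ = ["PeakCallResult", "WaveletPeakCaller"]


class WaveletPeakCaller:
    """Multiscale wavelet peak caller for a two-channel tiling array.

    Parameters
    ----------
    probes
        Probe table with columns ``chrom start end red green`` (validated
        and sorted on construction).
    params
        Scoring parameters; keyword overrides are applied on top (e.g.
        ``WaveletPeakCaller(df, m1=8, m2=12)``).

    Examples
    --------
    >>> model = WaveletPeakCaller.from_tsv("probes.tsv", m1=8, m2=11)
    >>> res = model.fit(alpha=3.0)
    >>> print(res.summary())
    """

    def __init__(self, probes: pd.DataFrame, params: ScoringParams | None = None,
                 **overrides):
        if params is None:
            params = ScoringParams(**overrides)
        elif overrides:
            params = replace(params, **overrides)
        self.probes = validate_probe_table(probes)
        if len(self.probes) == 0:
            raise ValueError("probe table is empty")
        self.params = params
        self._prep: PreparedTable | None = None

    @classmethod
    def from_tsv(cls, path, params: ScoringParams | None = None, **overrides):
        return cls(twio.read_probe_table(path), params, **overrides)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, params: ScoringParams | None = None,
                       **overrides):
        return cls(df, params, **overrides)

    @property
    def prepared(self) -> PreparedTable:
        if self._prep is None or self._prep.max_level < self.params.m2:
            self._prep = PreparedTable(self.probes, self.params.m2)
        return self._prep

    def fit(self, alpha: float | None = None) -> "PeakCallResult":
        """Run the caller; ``alpha`` overrides the stored threshold."""
        params = self.params if alpha is None else replace(self.params, alpha=alpha)
        prep = self.prepared
        maps = prep.ratio_maps(prep.red_values, params)
        stats = fit_stats(maps, params)
        hits, cand, conf = score_ratio_maps(maps, stats, params, collect_counts=True)
        return PeakCallResult(self, params, hits, stats, cand, conf, maps)

    def fit_fpr(self, target_fpr: float = 0.05, n_replicates: int = 10,
                seed: int = 0, tol: float = 0.01) -> "PeakCallResult":
        """Choose alpha by shuffle-FPR bisection, then fit at that alpha."""
        alpha, est = alpha_for_fpr(
            self.probes, self.params, target_fpr,
            n_replicates=n_replicates, seed=seed, tol=tol,
        )
        res = self.fit(alpha=alpha)
        res.fpr_estimate = est
        return res


class PeakCallResult:
    """Fitted caller output: hits, level fits, diagnostics."""

    def __init__(self, model: WaveletPeakCaller, params: ScoringParams,
                 hits: list[HitRegion], level_stats: dict[int, LevelStats],
                 candidate_counts: dict[int, int], confirmed_counts: dict[int, int],
                 maps):
        self.model = model
        self.params = params
        self.hits = hits
        self.level_stats = level_stats
        self.candidate_counts = candidate_counts
        self.confirmed_counts = confirmed_counts
        self.fpr_estimate: FprEstimate | None = None
        self._maps = maps

    @property
    def n_hits(self) -> int:
        return len(self.hits)

    def hits_frame(self) -> pd.DataFrame:
        rows = [(h.chrom, h.start, h.end, h.name, h.score) for h in self.hits]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])

    def to_bed(self, path) -> None:
        twio.write_bed(self.hits, path)

    def to_bedgraph(self, path) -> None:
        twio.write_bedgraph(
            zscore_tracks(self._maps, self.level_stats, self.params), path
        )

    def estimate_fpr(self, n_replicates: int = 10, seed: int = 0,
                     refit_stats: bool = True) -> FprEstimate:
        """Shuffle-based FPR at this result's alpha (stored on the result)."""
        est = estimate_fpr(self.model.probes, self.params,
                           n_replicates=n_replicates, seed=seed,
                           refit_stats=refit_stats)
        self.fpr_estimate = est
        return est

    def evaluate(self, truth, min_overlap_frac: float = 0.0) -> RocPoint:
        """Sensitivity / FP ratio against a truth interval set."""
        return evaluate_calls(self.hits, truth, alpha=self.params.alpha,
                              min_overlap_frac=min_overlap_frac)

    def level_ratios(self, level: int) -> np.ndarray:
        """Pooled unmasked log-ratios at one level (for diagnostics)."""
        return np.concatenate(
            [np.ma.compressed(cr.ratios[level]) for cr in self._maps]
        )

    def plot_level_qq(self, level: int | None = None, ax=None):
        """Normal quantile-quantile plot of one level's log-ratios.

        A straight line indicates the log-normal null describes the
        coefficients well; upward departures in the right tail are the
        enriched regions.
        """
        from scipy import stats as sps

        if level is None:
            level = self.params.m1
        if ax is None:
            import matplotlib.pyplot as plt

            _, ax = plt.subplots()
        sps.probplot(self.level_ratios(level), dist="norm", plot=ax)
        ax.set_title(f"log-ratio normality, level m={level}")
        return ax

    def summary(self) -> str:
        p = self.params
        w1, w2 = p.peak_width_range()
        n_probes = len(self.model.probes)
        n_chrom = self.model.probes["chrom"].nunique()
        lines = [
            "          Wavelet Peak Caller Results",
            "=" * 64,
            f"Probes: {n_probes}    Chromosomes: {n_chrom}",
            f"Levels: m = {p.m1}..{p.m2}  (peak widths {w1}-{w2} bp)",
            f"alpha: {p.alpha:g}    floor: {p.floor:g}    "
            f"min_consistent: {p.min_consistent}    center: {p.center}",
        ]
        if self.fpr_estimate is not None:
            e = self.fpr_estimate
            lines.append(
                f"shuffle FPR at alpha={e.alpha:.3f}: {e.fpr:.3f} "
                f"({e.n_replicates} replicates)"
            )
        lines += [
            "-" * 64,
            f"{'level':>5} {'width_bp':>9} {'n_used':>9} {'mu':>9} "
            f"{'sigma':>8} {'cand':>7} {'hits':>6}",
        ]
        for m in p.support_levels:
            st = self.level_stats[m]
            support = "*" if m < p.m1 else " "
            conf = self.confirmed_counts.get(m, 0)
            lines.append(
                f"{m:>4}{support} {1 << m:>9} {st.n_used:>9} {st.mu:>9.4f} "
                f"{st.sigma:>8.4f} {self.candidate_counts[m]:>7} "
                f"{conf if m >= p.m1 else '-':>6}"
            )
        lines += [
            "-" * 64,
            "* support-only level (consistency check; never called)",
            f"Hit regions: N = {self.n_hits}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<PeakCallResult: {self.n_hits} hits, "
            f"m={self.params.m1}..{self.params.m2}, alpha={self.params.alpha:g}>"
        )
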