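"""Shuffle-based false-positive-rate estimation.

The caller's global error control: permute the red-channel intensities
uniformly at random across all probes (destroying the spatial coherence
that real peaks require while preserving the intensity distribution),
re-run the identical scoring procedure — including refitting sigma_m on
the shuffled data — and report ``FPR = mean(N_shuff) / N`` where ``N`` is
the hit count on the original data.  Inverting this relation by bisection
over alpha yields the threshold for a requested FPR operating point
(e.g. 5%).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .scoring import (
    PreparedTable,
    ScoringParams,
    fit_stats,
    score_ratio_maps,
)
from .signals import validate_probe_table

__all__ = ["FprEstimate", "alpha_for_fpr", "estimate_fpr", "shuffle_red"]


@dataclass(frozen=True)
class FprEstimate:
    """Result of a shuffle-based FPR estimation at one alpha."""

    alpha: float
    n_real: int
    n_shuff: tuple[int, ...]
    n_replicates: int
    seed: int

    @property
    def fpr(self) -> float:
        return float(np.mean(self.n_shuff)) / self.n_real


def shuffle_red(probes: pd.DataFrame, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Permute red intensities uniformly at random across all probes.

    Green intensities and probe coordinates are untouched; the multiset of
    red values is preserved.  The shuffle is genome-wide, not stratified
    by chromosome.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = probes.copy()
    out["red"] = rng.permutation(out["red"].to_numpy())
    return out


def _replicate_maps(prep: PreparedTable, params: ScoringParams,
                    n_replicates: int, seed: int):
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        yield prep.ratio_maps(rng.permutation(prep.red_values), params)


def estimate_fpr(
    probes: pd.DataFrame,
    params: ScoringParams | None = None,
    n_replicates: int = 10,
    seed: int = 0,
    refit_stats: bool = True,
) -> FprEstimate:
    """Estimate the FPR at ``params.alpha`` from red-channel shuffles.

    Each replicate re-runs the full pipeline on shuffled data; by default
    sigma_m is refit on the shuffled coefficients (``refit_stats=False``
    freezes the original fits for sensitivity analysis).  Raises if the
    original data yields no hits, in which case the FPR is undefined and a
    lower alpha is needed.
    """
    params = params or ScoringParams()
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    probes = validate_probe_table(probes)
    prep = PreparedTable(probes, params.m2)
    maps0 = prep.ratio_maps(prep.red_values, params)
    stats0 = fit_stats(maps0, params)
    n_real = len(score_ratio_maps(maps0, stats0, params))
    if n_real == 0:
        raise ValueError(
            f"no hits at alpha={params.alpha:g}; the FPR is undefined — lower alpha"
        )
    counts = []
    for maps in _replicate_maps(prep, params, n_replicates, seed):
        stats = fit_stats(maps, params) if refit_stats else stats0
        counts.append(len(score_ratio_maps(maps, stats, params)))
    return FprEstimate(
        alpha=params.alpha,
        n_real=n_real,
        n_shuff=tuple(counts),
        n_replicates=n_replicates,
        seed=seed,
    )


def alpha_for_fpr(
    probes: pd.DataFrame,
    params: ScoringParams | None = None,
    target_fpr: float = 0.05,
    *,
    n_replicates: int = 10,
    seed: int = 0,
    tol: float = 0.01,
    bracket: tuple[float, float] = (1.0, 8.0),
    max_iter: int = 30,
) -> tuple[float, FprEstimate]:
    """Find alpha whose shuffle FPR is within ``tol`` of ``target_fpr``.

    Bisection over alpha: the same shuffle replicates (fixed by ``seed``)
    are reused at every alpha, so the estimated FPR is a deterministic,
    essentially monotone decreasing function of alpha and bisection is
    well posed.  Returns the chosen alpha and its FPR estimate.
    """
    params = params or ScoringParams()
    if not (0 < target_fpr < 1):
        raise ValueError("target_fpr must be in (0, 1)")
    probes = validate_probe_table(probes)
    prep = PreparedTable(probes, params.m2)
    maps0 = prep.ratio_maps(prep.red_values, params)
    stats0 = fit_stats(maps0, params)
    reps = [
        (maps, fit_stats(maps, params))
        for maps in _replicate_maps(prep, params, n_replicates, seed)
    ]

    def evaluate(alpha: float) -> FprEstimate | None:
        p = replace(params, alpha=alpha)
        n_real = len(score_ratio_maps(maps0, stats0, p))
        if n_real == 0:
            return None
        counts = tuple(len(score_ratio_maps(m, s, p)) for m, s in reps)
        return FprEstimate(alpha=alpha, n_real=n_real, n_shuff=counts,
                           n_replicates=n_replicates, seed=seed)

    lo, hi = bracket
    best: FprEstimate | None = None
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        est = evaluate(mid)
        fpr = est.fpr if est is not None else 0.0
        if est is not None and (
            best is None or abs(fpr - target_fpr) < abs(best.fpr - target_fpr)
        ):
            best = est
        if est is not None and abs(fpr - target_fpr) <= tol:
            return mid, est
        if fpr > target_fpr:
            lo = mid
        else:
            hi = mid
    if best is None:
        raise ValueError(
            f"no alpha in {bracket} yields any hits; cannot reach FPR {target_fpr}"
        )
    return best.alpha, best
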