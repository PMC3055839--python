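"""Readers and writers: probe-table TSV, BED hits, bedGraph tracks, reports.

All genomic intervals are 0-based half-open, matching BED conventions.
"""

from __future__ import annotations

import json
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .scoring import HitRegion
from .signals import PROBE_COLUMNS, validate_probe_table

__all__ = [
    "read_bed",
    "read_probe_table",
    "write_bed",
    "write_bedgraph",
    "write_probe_table",
    "write_roc_table",
]


def read_probe_table(path) -> pd.DataFrame:
    """Read and validate a tab-separated probe table.

    Requires a header with columns ``chrom start end red green``.
    Validation failures name the offending file row (header = row 1).
    Returns a table sorted by (chrom, start).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        warnings.warn(f"{path}: probe table is empty (header only)")
        return df.loc[:, list(PROBE_COLUMNS)]

    def _first_bad(mask: pd.Series) -> int:
        # data row i (0-based) sits on file row i + 2 (header is row 1)
        return int(np.nonzero(mask.to_numpy())[0][0]) + 2

    bad = df["end"] <= df["start"]
    if bad.any():
        raise ValueError(f"{path}: end <= start on row {_first_bad(bad)}")
    for col in ("red", "green"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(vals) | (vals <= 0)
        if bad.any():
            raise ValueError(
                f"{path}: non-positive or non-numeric {col} intensity "
                f"on row {_first_bad(bad)}"
            )
    return validate_probe_table(df)


def write_probe_table(probes: pd.DataFrame, path) -> None:
    probes.loc[:, list(PROBE_COLUMNS)].to_csv(path, sep="\t", index=False)


def write_bed(hits: Iterable[HitRegion], path) -> None:
    """Write hit regions as 6-column BED: chrom start end name score strand.

    ``name`` lists the contributing levels (e.g. ``m8+m9``); ``score`` is
    the max standardized log-ratio over contributing coefficients; strand
    is ``"."``.  No header lines; sorted input order is preserved.
    """
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.chrom}\t{h.start}\t{h.end}\t{h.name}\t{h.score:.4f}\t.\n")


def read_bed(path) -> list[HitRegion]:
    """Read a BED file back into hit regions.

    Only the first three columns are required; level names of the form
    ``m8+m9`` and numeric scores are recovered when present.
    """
    hits: list[HitRegion] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            levels: tuple[int, ...] = ()
            score = 0.0
            if len(parts) > 3:
                try:
                    levels = tuple(
                        int(tok[1:]) for tok in parts[3].split("+") if tok.startswith("m")
                    )
                except ValueError:
                    levels = ()
            if len(parts) > 4:
                try:
                    score = float(parts[4])
                except ValueError:
                    score = 0.0
            hits.append(HitRegion(chrom, start, end, levels, score))
    return hits


def write_bedgraph(
    tracks: Mapping[int, Sequence[tuple[str, int, int, float]]], path
) -> None:
    """Write per-level standardized log-ratio tracks to one bedGraph file.

    One ``track`` block per decomposition level, named after the level.
    """
    with open(path, "w") as fh:
        for level in sorted(tracks):
            fh.write(
                f'track type=bedGraph name="tilewave_z_m{level}" '
                f'description="standardized log-ratio, level {level}"\n'
            )
            for chrom, start, end, value in tracks[level]:
                fh.write(f"{chrom}\t{start}\t{end}\t{value:.4f}\n")


def write_roc_table(points, path) -> None:
    """ROC sweep as TSV: alpha, tp, fp, sensitivity, fp_ratio."""
    with open(path, "w") as fh:
        fh.write("alpha\ttp\tfp\tn_hits\tsensitivity\tfp_ratio\n")
        for p in points:
            a = "" if p.alpha is None else f"{p.alpha:g}"
            fh.write(
                f"{a}\t{p.tp}\t{p.fp}\t{p.n_hits}"
                f"\t{p.sensitivity:.4f}\t{p.fp_ratio:.4f}\n"
            )


def write_fpr_report(estimate, path) -> None:
    """FPR estimate as a small JSON report."""
    payload = {
        "alpha": estimate.alpha,
        "n_real": estimate.n_real,
        "n_shuff": list(estimate.n_shuff),
        "n_replicates": estimate.n_replicates,
        "seed": estimate.seed,
        "fpr": estimate.fpr,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
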