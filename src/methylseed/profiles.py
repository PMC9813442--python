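"""Density, metaplot, chromosomal, and chromatin-state summaries.

These are the genome-scale descriptive analytics layered on top of the window
tables and DMR sets: kernel-density curves of per-window methylation
differences, feature-anchored metaplots, per-chromosome DMR distributions,
and the chromatin-state composition of DMR base pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .dmr import Dmr
from .intervals import IntervalIndex
from .io import FeatureRecord, StateInterval

__all__ = [
    "DensityCurve",
    "MetaProfile",
    "window_differences",
    "kde_curve",
    "partition_by_regions",
    "methylation_metaplot",
    "dmr_feature_frequency",
    "chromosome_distribution",
    "state_composition",
]


@dataclass(frozen=True)
class DensityCurve:
    """Gaussian KDE of methylation differences on a fixed [-1, 1] x 512 grid.

    The density is renormalized so its trapezoidal integral over the grid is
    exactly 1, keeping curves comparable even when a little kernel mass would
    otherwise fall outside [-1, 1].
    """

    grid: np.ndarray
    density: np.ndarray
    n_windows_used: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"grid": self.grid, "density": self.density})


@dataclass(frozen=True)
class MetaProfile:
    """Feature-anchored profile over +/- flank, binned at fixed width.

    ``values`` holds either mean fractional methylation per bin or the
    proportion of features with a DMR in the bin. ``bin_starts`` are offsets
    of each bin's left edge relative to the anchor (5' side always points
    toward decreasing offsets after strand reflection).
    """

    anchor: str
    bin_starts: np.ndarray
    values: np.ndarray
    n_features: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_start": self.bin_starts, "value": self.values})


def window_differences(
    windows_a: pd.DataFrame,
    windows_b: pd.DataFrame,
    min_informative: int = 10,
    min_frac: float = 0.5,
) -> np.ndarray:
    """Per-window fractional differences (A minus B) under the density filter.

    A window enters the vector iff both samples cover it, each side has at
    least ``min_informative`` sequenced cytosine calls, and the larger of the
    two fractions is at least ``min_frac``.
    """
    paired = windows_a.merge(
        windows_b, on=["chrom", "start", "end"], suffixes=("_a", "_b"), how="inner"
    )
    if len(paired) == 0:
        return np.array([], dtype=float)
    ok = (paired["total_sum_a"] >= min_informative) & (paired["total_sum_b"] >= min_informative)
    paired = paired[ok]
    frac_a = (paired["meth_sum_a"] / paired["total_sum_a"]).to_numpy()
    frac_b = (paired["meth_sum_b"] / paired["total_sum_b"]).to_numpy()
    keep = np.maximum(frac_a, frac_b) >= min_frac
    return (frac_a - frac_b)[keep]


def kde_curve(values: Sequence[float], grid_size: int = 512) -> DensityCurve:
    """Gaussian KDE (Silverman bandwidth) on the fixed [-1, 1] grid."""
    vals = np.asarray(values, dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least 2 values for a density estimate")
    if np.var(vals) == 0:
        raise ValueError("degenerate input: zero variance")
    kde = gaussian_kde(vals, bw_method="silverman")
    grid = np.linspace(-1.0, 1.0, grid_size)
    density = kde(grid)
    area = np.trapezoid(density, grid)
    if area <= 0:
        raise ValueError("degenerate density (zero mass on [-1, 1])")
    return DensityCurve(grid=grid, density=density / area, n_windows_used=len(vals))


def partition_by_regions(
    windows: pd.DataFrame, regions: Iterable[tuple[str, int, int]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split windows into (inside, outside) by >= 1 bp overlap with regions."""
    idx = IntervalIndex(regions)
    if len(windows) == 0:
        return windows.copy(), windows.copy()
    hit = idx.overlaps(
        windows["chrom"].to_numpy(), windows["start"].to_numpy(), windows["end"].to_numpy()
    )
    return windows[hit].copy(), windows[~hit].copy()


def _anchor_position(feature: FeatureRecord, anchor: str) -> tuple[int, int]:
    """Return (anchor coordinate, orientation sign) for a feature.

    Offsets grow in the transcriptional direction: sign +1 for plus-strand
    features, -1 for minus-strand (coordinate reflection), so "5prime" always
    means the transcriptional start side.
    """
    if anchor not in ("5prime", "3prime"):
        raise ValueError(f"anchor must be 5prime or 3prime, got {anchor!r}")
    plus = feature.strand != "-"
    if anchor == "5prime":
        return (feature.start, 1) if plus else (feature.end, -1)
    return (feature.end, 1) if plus else (feature.start, -1)


def methylation_metaplot(
    windows: pd.DataFrame,
    features: Sequence[FeatureRecord],
    anchor: str = "5prime",
    flank: int = 3000,
    bin_size: int = 100,
) -> MetaProfile:
    """Count-weighted mean fractional methylation in fixed bins around features.

    Each window is assigned to the bin containing its midpoint offset from
    the feature anchor (after strand reflection); the bin value is the pooled
    meth_sum / total_sum over all assigned windows across features.
    """
    if not features:
        raise ValueError("no features")
    n_bins = 2 * flank // bin_size
    meth = np.zeros(n_bins, dtype=np.int64)
    total = np.zeros(n_bins, dtype=np.int64)
    by_chrom = {c: g for c, g in windows.groupby("chrom", sort=False)}
    for f in features:
        g = by_chrom.get(f.chrom)
        if g is None:
            continue
        a, sign = _anchor_position(f, anchor)
        mid = (g["start"].to_numpy() + g["end"].to_numpy()) // 2
        rel = sign * (mid - a)
        bidx = (rel + flank) // bin_size
        ok = (bidx >= 0) & (bidx < n_bins)
        np.add.at(meth, bidx[ok].astype(np.int64), g["meth_sum"].to_numpy()[ok])
        np.add.at(total, bidx[ok].astype(np.int64), g["total_sum"].to_numpy()[ok])
    with np.errstate(invalid="ignore"):
        values = np.where(total > 0, meth / np.maximum(total, 1), np.nan)
    bin_starts = np.arange(n_bins) * bin_size - flank
    return MetaProfile(anchor=anchor, bin_starts=bin_starts, values=values,
                       n_features=len(features))


def dmr_feature_frequency(
    dmrs: Sequence[Dmr],
    features: Sequence[FeatureRecord],
    anchor: str = "5prime",
    flank: int = 3000,
    bin_size: int = 100,
) -> MetaProfile:
    """Proportion of features with >= 1 bp DMR overlap in each bin."""
    if not features:
        raise ValueError("no features")
    n_bins = 2 * flank // bin_size
    hits = np.zeros(n_bins, dtype=np.int64)
    idx = IntervalIndex((d.chrom, d.start, d.end) for d in dmrs)
    offsets = np.arange(n_bins) * bin_size - flank
    for f in features:
        a, sign = _anchor_position(f, anchor)
        if sign > 0:
            starts = a + offsets
            ends = starts + bin_size
        else:
            # reflected: offset o covers genomic (a - o - bin, a - o]
            ends = a - offsets
            starts = ends - bin_size
        hit = idx.overlaps(f.chrom, starts, ends)
        hits += hit.astype(np.int64)
    return MetaProfile(anchor=anchor, bin_starts=offsets,
                       values=hits / len(features), n_features=len(features))


def chromosome_distribution(
    dmrs: Sequence[Dmr],
    chrom_lengths: Mapping[str, int],
    bin_size: int = 100_000,
    centromeres: Iterable[tuple[str, int, int]] | None = None,
) -> pd.DataFrame:
    """DMR midpoint counts per fixed chromosomal bin (floor rule on boundaries)."""
    rows = []
    cen = IntervalIndex(centromeres) if centromeres is not None else None
    for chrom in sorted(chrom_lengths):
        n_bins = int(np.ceil(chrom_lengths[chrom] / bin_size))
        counts = np.zeros(n_bins, dtype=np.int64)
        for d in dmrs:
            if d.chrom != chrom:
                continue
            mid = (d.start + d.end) // 2
            b = mid // bin_size
            if 0 <= b < n_bins:
                counts[b] += 1
        for b in range(n_bins):
            start = b * bin_size
            end = min(start + bin_size, chrom_lengths[chrom])
            row = {"chrom": chrom, "start": start, "end": end, "count": int(counts[b])}
            if cen is not None:
                row["centromeric"] = bool(cen.overlaps(chrom, start, end)[0])
            rows.append(row)
    return pd.DataFrame(rows)


def state_composition(
    dmrs: Sequence[Dmr],
    states: Sequence[StateInterval],
    categories: Mapping[str, Sequence[int]] | None = None,
) -> dict:
    """Percent of DMR base pairs per chromatin-state category.

    ``categories`` maps a label to the states it groups (default: one
    category per state, "state_1" ... "state_9"). Base pairs outside every
    state interval are reported as "unannotated". Percentages sum to 100.
    """
    if not dmrs:
        raise ValueError("empty DMR set")
    dmr_ix = IntervalIndex((d.chrom, d.start, d.end) for d in dmrs)
    total_bp = dmr_ix.total_length()
    if categories is None:
        categories = {f"state_{s}": [s] for s in range(1, 10)}
    pct: dict[str, float] = {}
    bp: dict[str, int] = {}
    annotated = 0
    for label, members in categories.items():
        member_set = set(members)
        ix = IntervalIndex(
            (s.chrom, s.start, s.end) for s in states if s.state in member_set
        )
        n = dmr_ix.intersect_length(ix)
        bp[label] = n
        pct[label] = 100.0 * n / total_bp
        annotated += n
    if annotated < total_bp:
        bp["unannotated"] = total_bp - annotated
        pct["unannotated"] = 100.0 * (total_bp - annotated) / total_bp
    return {"percent": pct, "bp": bp, "total_bp": total_bp}
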