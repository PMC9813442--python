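"""CG differentially methylated region (DMR) calling and DMR-set comparison.

The procedure compares two samples' pooled methylation in fixed 50-bp
windows:

1. every co-covered window where both samples have at least ``min_calls``
   sequenced cytosine calls is tested (fractional difference + two-sided
   Fisher's exact test on the pooled counts);
2. candidate windows (|difference| >= 0.3, p < 1e-3) within 300 bp of each
   other and changing in the same direction are merged;
3. each merged region is re-tested on its pooled raw counts and retained iff
   the pooled |difference| > 0.3 (strict), the pooled p < 1e-6, and the region
   spans at least 100 bp.

Note the deliberate asymmetry of the thresholds: the per-window candidate
filter is "at least 0.3" (inclusive) while the merged-region filter is
strictly "> 0.3".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import IntervalIndex
from .stats import fisher_exact_2x2, welch_t

__all__ = [
    "DmrParams",
    "Dmr",
    "window_diff_test",
    "select_candidates",
    "merge_candidates",
    "filter_merged",
    "call_dmrs",
    "overlap_sets",
    "size_summary",
    "dmrs_to_frame",
    "write_dmr_bed",
    "read_dmr_bed",
]

_CAND_COLUMNS = [
    "chrom", "start", "end",
    "meth_a", "total_a", "meth_b", "total_b",
    "frac_a", "frac_b", "diff", "p",
]


@dataclass(frozen=True)
class DmrParams:
    """Tuning knobs of the DMR caller (defaults follow the analysis recipe)."""

    window_size: int = 50
    min_calls: int = 10          # informativeness floor per sample per window
    min_diff: float = 0.3        # candidate filter, inclusive
    candidate_p: float = 1e-3
    merge_gap: int = 300         # end(prev) to start(next), inclusive
    merged_min_diff: float = 0.3  # merged filter, strict
    merged_p: float = 1e-6
    min_length: int = 100


@dataclass(frozen=True)
class Dmr:
    """A merged differentially methylated region.

    ``diff`` is the pooled fractional difference (sample A minus sample B)
    over the region's raw counts; ``direction`` is ``A-hyper`` when A is the
    more methylated sample.
    """

    chrom: str
    start: int
    end: int
    n_windows: int
    diff: float
    p: float
    direction: str
    meth_a: int = 0
    total_a: int = 0
    meth_b: int = 0
    total_b: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


def _pair_windows(windows_a: pd.DataFrame, windows_b: pd.DataFrame) -> pd.DataFrame:
    merged = windows_a.merge(
        windows_b, on=["chrom", "start", "end"], suffixes=("_a", "_b"), how="inner"
    )
    return merged


def window_diff_test(wa, wb) -> pd.Series:
    """Test one pair of co-located windows; returns a Series with diff and p.

    ``wa``/``wb`` are window rows (mappings with chrom/start/end/meth_sum/
    total_sum). Coordinates must match.
    """
    if (wa["chrom"], wa["start"], wa["end"]) != (wb["chrom"], wb["start"], wb["end"]):
        raise ValueError(
            f"window coordinates differ: {wa['chrom']}:{wa['start']}-{wa['end']} vs "
            f"{wb['chrom']}:{wb['start']}-{wb['end']}"
        )
    ma, ta = int(wa["meth_sum"]), int(wa["total_sum"])
    mb, tb = int(wb["meth_sum"]), int(wb["total_sum"])
    diff = ma / ta - mb / tb
    p = fisher_exact_2x2((ma, ta - ma, mb, tb - mb))
    return pd.Series(
        {
            "chrom": wa["chrom"], "start": wa["start"], "end": wa["end"],
            "meth_a": ma, "total_a": ta, "meth_b": mb, "total_b": tb,
            "frac_a": ma / ta, "frac_b": mb / tb, "diff": diff, "p": p,
        }
    )


def select_candidates(
    windows_a: pd.DataFrame,
    windows_b: pd.DataFrame,
    params: DmrParams = DmrParams(),
) -> pd.DataFrame:
    """Candidate windows: co-covered, informative, |diff| >= min_diff, p < candidate_p.

    Fisher tests are computed only for windows already passing the difference
    filter (the p-filter cannot rescue a window the diff-filter rejects).
    """
    paired = _pair_windows(windows_a, windows_b)
    if len(paired) == 0:
        return pd.DataFrame(columns=_CAND_COLUMNS)
    ok = (paired["total_sum_a"] >= params.min_calls) & (paired["total_sum_b"] >= params.min_calls)
    paired = paired[ok]
    frac_a = paired["meth_sum_a"] / paired["total_sum_a"]
    frac_b = paired["meth_sum_b"] / paired["total_sum_b"]
    diff = frac_a - frac_b
    cand = paired[np.abs(diff.to_numpy()) >= params.min_diff].copy()
    if len(cand) == 0:
        return pd.DataFrame(columns=_CAND_COLUMNS)
    pvals = [
        fisher_exact_2x2((int(m_a), int(t_a - m_a), int(m_b), int(t_b - m_b)))
        for m_a, t_a, m_b, t_b in zip(
            cand["meth_sum_a"], cand["total_sum_a"], cand["meth_sum_b"], cand["total_sum_b"]
        )
    ]
    cand["p"] = pvals
    cand = cand[cand["p"] < params.candidate_p]
    out = pd.DataFrame(
        {
            "chrom": cand["chrom"],
            "start": cand["start"].astype(np.int64),
            "end": cand["end"].astype(np.int64),
            "meth_a": cand["meth_sum_a"].astype(np.int64),
            "total_a": cand["total_sum_a"].astype(np.int64),
            "meth_b": cand["meth_sum_b"].astype(np.int64),
            "total_b": cand["total_sum_b"].astype(np.int64),
        }
    )
    out["frac_a"] = out["meth_a"] / out["total_a"]
    out["frac_b"] = out["meth_b"] / out["total_b"]
    out["diff"] = out["frac_a"] - out["frac_b"]
    out["p"] = cand["p"].to_numpy()
    return out.sort_values(["chrom", "start"], ignore_index=True)


def merge_candidates(candidates: pd.DataFrame, max_gap: int = 300) -> pd.DataFrame:
    """Group same-chromosome, same-direction candidates within ``max_gap`` bp.

    The gap is measured end(previous) to start(next), merged when <= max_gap.
    Returns the candidate table with an added ``group`` column.
    """
    if len(candidates) == 0:
        out = candidates.copy()
        out["group"] = pd.Series(dtype=np.int64)
        return out
    cand = candidates.sort_values(["chrom", "start"], ignore_index=True)
    chrom = cand["chrom"].to_numpy()
    start = cand["start"].to_numpy()
    end = cand["end"].to_numpy()
    sign = np.sign(cand["diff"].to_numpy())
    new_group = np.ones(len(cand), dtype=bool)
    if len(cand) > 1:
        same_chrom = chrom[1:] == chrom[:-1]
        same_dir = sign[1:] == sign[:-1]
        close = (start[1:] - end[:-1]) <= max_gap
        new_group[1:] = ~(same_chrom & same_dir & close)
    cand["group"] = np.cumsum(new_group) - 1
    return cand


def filter_merged(grouped: pd.DataFrame, params: DmrParams = DmrParams()) -> list[Dmr]:
    """Re-test merged groups on pooled counts; retain per the merged-DMR rules."""
    out: list[Dmr] = []
    if len(grouped) == 0:
        return out
    for _, g in grouped.groupby("group", sort=True):
        chrom = g["chrom"].iloc[0]
        start = int(g["start"].min())
        end = int(g["end"].max())
        if end - start < params.min_length:
            continue
        ma, ta = int(g["meth_a"].sum()), int(g["total_a"].sum())
        mb, tb = int(g["meth_b"].sum()), int(g["total_b"].sum())
        diff = ma / ta - mb / tb
        if abs(diff) <= params.merged_min_diff:
            continue
        p = fisher_exact_2x2((ma, ta - ma, mb, tb - mb))
        if p >= params.merged_p:
            continue
        out.append(
            Dmr(
                chrom=chrom, start=start, end=end, n_windows=len(g),
                diff=diff, p=p,
                direction="A-hyper" if diff > 0 else "B-hyper",
                meth_a=ma, total_a=ta, meth_b=mb, total_b=tb,
            )
        )
    out.sort(key=lambda d: (d.chrom, d.start))
    return out


def call_dmrs(
    windows_a: pd.DataFrame,
    windows_b: pd.DataFrame,
    params: DmrParams = DmrParams(),
) -> list[Dmr]:
    """Full select -> merge -> filter composition on two window tables."""
    cand = select_candidates(windows_a, windows_b, params)
    grouped = merge_candidates(cand, params.merge_gap)
    return filter_merged(grouped, params)


def overlap_sets(set_a: Sequence[Dmr], set_b: Sequence[Dmr]) -> dict:
    """Venn-style comparison of two DMR sets.

    A DMR is "shared" iff it overlaps >= 1 bp with any DMR of the other set.
    Base-pair totals are computed on interval unions.
    """
    ix_a = IntervalIndex((d.chrom, d.start, d.end) for d in set_a)
    ix_b = IntervalIndex((d.chrom, d.start, d.end) for d in set_b)

    def _shared_count(dmrs: Sequence[Dmr], other: IntervalIndex) -> int:
        return sum(
            bool(other.overlaps(d.chrom, d.start, d.end)[0]) for d in dmrs
        )

    shared_a = _shared_count(set_a, ix_b)
    shared_b = _shared_count(set_b, ix_a)
    bp_a = ix_a.total_length()
    bp_b = ix_b.total_length()
    bp_shared = ix_a.intersect_length(ix_b)
    return {
        "n_a": len(set_a),
        "n_b": len(set_b),
        "only_a": len(set_a) - shared_a,
        "shared_a": shared_a,
        "shared_b": shared_b,
        "only_b": len(set_b) - shared_b,
        "bp_a": bp_a,
        "bp_b": bp_b,
        "bp_shared": bp_shared,
        "bp_only_a": bp_a - bp_shared,
        "bp_only_b": bp_b - bp_shared,
    }


_DEFAULT_SIZE_BINS = (100, 200, 500, 1000, 2000, 5000)


def size_summary(dmrs: Sequence[Dmr], bin_edges: Sequence[int] = _DEFAULT_SIZE_BINS) -> dict:
    """Size-class histogram, cumulative covered length, and raw lengths.

    ``bin_edges`` are lower bounds of half-open size classes; the last class
    is unbounded above. The raw length vector feeds Welch's t-test when two
    sets are compared.
    """
    lengths = np.array([d.length for d in dmrs], dtype=np.int64)
    edges = list(bin_edges) + [np.iinfo(np.int64).max]
    labels = [
        f"[{lo},{hi})" if hi != np.iinfo(np.int64).max else f">={lo}"
        for lo, hi in zip(edges[:-1], edges[1:])
    ]
    counts = {
        label: int(((lengths >= lo) & (lengths < hi)).sum())
        for label, lo, hi in zip(labels, edges[:-1], edges[1:])
    }
    return {
        "n": len(lengths),
        "counts": counts,
        "cumulative_bp": int(lengths.sum()),
        "lengths": lengths,
    }


def compare_lengths(set_a: Sequence[Dmr], set_b: Sequence[Dmr]):
    """Welch's t-test on the two sets' DMR length distributions."""
    la = [d.length for d in set_a]
    lb = [d.length for d in set_b]
    return welch_t(la, lb)


def dmrs_to_frame(dmrs: Sequence[Dmr]) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "n_windows", "diff", "p", "direction",
            "meth_a", "total_a", "meth_b", "total_b"]
    return pd.DataFrame([{c: getattr(d, c) for c in cols} for d in dmrs], columns=cols)


def write_dmr_bed(dmrs: Sequence[Dmr], path) -> None:
    """BED6+ writer: score = -log10(p) capped at 300; extra columns diff,
    n_windows, direction."""
    rows = sorted(dmrs, key=lambda d: (d.chrom, d.start))
    with open(path, "w") as fh:
        for i, d in enumerate(rows):
            score = min(300.0, -np.log10(max(d.p, 5e-324)))
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\tDMR{i + 1:05d}\t{score:.1f}\t.\t"
                f"{d.diff:.4f}\t{d.n_windows}\t{d.direction}\n"
            )


def read_dmr_bed(path) -> list[Dmr]:
    out: list[Dmr] = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}: expected 9 BED6+ columns, got {len(f)}")
            score = float(f[4])
            out.append(
                Dmr(
                    chrom=f[0], start=int(f[1]), end=int(f[2]),
                    n_windows=int(f[7]), diff=float(f[6]),
                    p=10 ** (-score), direction=f[8],
                )
            )
    return out
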