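"""Per-cytosine methylation I/O, genome annotations, and window tiling.

File dialects
-------------
* CX report (Bismark dialect): tab-separated ``chrom, pos (1-based), strand,
  methylated count, unmethylated count, context, trinucleotide`` — the 7th
  column is optional on input and written as the context on output (synthetic
  sites carry no underlying sequence).
* BED: 0-based half-open.
* GFF3: 1-based closed, converted to 0-based half-open on ingest.

All internal coordinates are 0-based half-open; conversion happens only at
these I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Union

import numpy as np
import pandas as pd

__all__ = [
    "CytosineRecord",
    "FeatureRecord",
    "StateInterval",
    "CONTEXTS",
    "iter_cx_records",
    "read_cx_report",
    "write_cx_report",
    "aggregate_windows",
    "estimate_nonconversion",
    "read_features",
    "write_features_gff3",
    "read_states",
    "write_states_bed",
]

CONTEXTS = ("CG", "CHG", "CHH")

CX_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth", "context"]


@dataclass(frozen=True)
class CytosineRecord:
    """One cytosine's strand, sequence context, and call counts."""

    chrom: str
    pos: int  # 1-based
    strand: str
    context: str
    meth: int
    unmeth: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.meth < 0 or self.unmeth < 0:
            raise ValueError("negative call count")


@dataclass(frozen=True)
class FeatureRecord:
    """Gene or TE interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str
    kind: str  # "gene" or "TE"
    id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty feature interval [{self.start},{self.end})")
        if self.kind not in ("gene", "TE"):
            raise ValueError(f"feature kind must be gene or TE, got {self.kind!r}")


@dataclass(frozen=True)
class StateInterval:
    """Chromatin-state interval (states 1-7 euchromatin, 8-9 heterochromatin)."""

    chrom: str
    start: int
    end: int
    state: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty state interval [{self.start},{self.end})")
        if not 1 <= self.state <= 9:
            raise ValueError(f"chromatin state must be 1-9, got {self.state}")


PathLike = Union[str, Path]


def iter_cx_records(path: PathLike) -> Iterator[CytosineRecord]:
    """Stream CytosineRecords from a CX report, reporting bad lines by number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) not in (6, 7):
                raise ValueError(f"{path}: line {lineno}: expected 6 or 7 columns, got {len(fields)}")
            try:
                rec = CytosineRecord(
                    chrom=fields[0],
                    pos=int(fields[1]),
                    strand=fields[2],
                    context=fields[5],
                    meth=int(fields[3]),
                    unmeth=int(fields[4]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            yield rec


def read_cx_report(path: PathLike) -> pd.DataFrame:
    """Read a CX report into a DataFrame with columns chrom, pos, strand,
    meth, unmeth, context (in file order)."""
    rows = [(r.chrom, r.pos, r.strand, r.meth, r.unmeth, r.context) for r in iter_cx_records(path)]
    if not rows:
        return pd.DataFrame(columns=CX_COLUMNS).astype(
            {"pos": np.int64, "meth": np.int64, "unmeth": np.int64}
        )
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "meth", "unmeth", "context"])
    return df


def _check_sorted(df: pd.DataFrame) -> None:
    # chromosome blocks must be contiguous and positions non-decreasing within
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    seen = {}
    prev_chrom = None
    prev_pos = -1
    for c, p in zip(chrom, pos):
        if c != prev_chrom:
            if c in seen:
                raise ValueError(f"records not sorted: chromosome {c} appears in two blocks")
            seen[c] = True
            prev_chrom = c
            prev_pos = -1
        if p < prev_pos:
            raise ValueError(f"records not sorted: {c}:{p} after {c}:{prev_pos}")
        prev_pos = p


def write_cx_report(records, path: PathLike) -> None:
    """Write records (DataFrame or iterable of CytosineRecord) as a CX report.

    Input must be sorted by (chrom, pos); read(write(x)) == x.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(
            [(r.chrom, r.pos, r.strand, r.meth, r.unmeth, r.context) for r in records],
            columns=CX_COLUMNS,
        )
    if len(df):
        _check_sorted(df)
    with open(path, "w") as fh:
        if len(df):
            out = df[CX_COLUMNS].copy()
            out["tri"] = out["context"]
            out.to_csv(fh, sep="\t", header=False, index=False)


def aggregate_windows(
    records: pd.DataFrame,
    window_size: int = 50,
    context: str | None = "CG",
) -> pd.DataFrame:
    """Pool per-cytosine counts into fixed, zero-anchored genomic windows.

    A 1-based position ``p`` falls in window index ``(p - 1) // window_size``,
    i.e. window ``[i*w, (i+1)*w)`` in 0-based half-open coordinates. Windows
    with zero total coverage are omitted.

    Returns a DataFrame with columns chrom, start, end, meth_sum, total_sum,
    n_informative, frac, sorted by (chrom, start).
    """
    df = records
    if context is not None:
        df = df[df["context"] == context]
    if len(df) == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "meth_sum", "total_sum", "n_informative", "frac"]
        )
    widx = (df["pos"].to_numpy(dtype=np.int64) - 1) // window_size
    total = df["meth"].to_numpy(np.int64) + df["unmeth"].to_numpy(np.int64)
    g = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "widx": widx,
            "meth": df["meth"].to_numpy(np.int64),
            "total": total,
            "informative": (total > 0).astype(np.int64),
        }
    ).groupby(["chrom", "widx"], sort=True, observed=True)
    out = g.agg(
        meth_sum=("meth", "sum"),
        total_sum=("total", "sum"),
        n_informative=("informative", "sum"),
    ).reset_index()
    out = out[out["total_sum"] > 0].copy()
    out["start"] = out["widx"] * window_size
    out["end"] = out["start"] + window_size
    out["frac"] = out["meth_sum"] / out["total_sum"]
    out = out[["chrom", "start", "end", "meth_sum", "total_sum", "n_informative", "frac"]]
    return out.sort_values(["chrom", "start"], ignore_index=True)


def estimate_nonconversion(records: pd.DataFrame, spike_chrom: str = "lambda") -> float:
    """Bisulfite non-conversion rate from the unmethylated spike-in chromosome.

    Pools all contexts: rate = methylated calls / total calls on the spike-in.
    """
    sub = records[records["chrom"] == spike_chrom]
    total = int(sub["meth"].sum() + sub["unmeth"].sum())
    if total == 0:
        raise ValueError(f"no calls on spike-in chromosome {spike_chrom!r}")
    return float(sub["meth"].sum()) / total


# --- annotations -----------------------------------------------------------


def read_features(path: PathLike, format: str = "GFF3") -> list[FeatureRecord]:
    """Read gene/TE annotations from GFF3 (1-based closed) or BED.

    GFF3 feature types ``gene`` and ``transposable_element``/``TE`` map to
    kinds ``gene`` and ``TE``; other types are skipped. BED input needs a 4th
    column ``id`` and 5th/6th columns score and strand; the id prefix ``TE``
    marks transposons, otherwise the feature is a gene.
    """
    fmt = format.upper()
    out: list[FeatureRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                if fmt == "GFF3":
                    if len(f) < 9:
                        raise ValueError(f"expected 9 GFF3 columns, got {len(f)}")
                    ftype = f[2]
                    kind = {"gene": "gene", "transposable_element": "TE", "TE": "TE"}.get(ftype)
                    if kind is None:
                        continue
                    start = int(f[3]) - 1  # 1-based closed -> 0-based half-open
                    end = int(f[4])
                    attrs = dict(
                        kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                    )
                    fid = attrs.get("ID", f"{f[0]}:{start}-{end}")
                    out.append(FeatureRecord(f[0], start, end, f[6], kind, fid))
                elif fmt == "BED":
                    if len(f) < 4:
                        raise ValueError(f"expected >= 4 BED columns, got {len(f)}")
                    start, end = int(f[1]), int(f[2])
                    strand = f[5] if len(f) >= 6 else "+"
                    kind = "TE" if f[3].startswith("TE") else "gene"
                    out.append(FeatureRecord(f[0], start, end, strand, kind, f[3]))
                else:
                    raise ValueError(f"unknown feature format {format!r}")
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_features_gff3(features: Iterable[FeatureRecord], path: PathLike) -> None:
    rows = sorted(features, key=lambda r: (r.chrom, r.start))
    type_of = {"gene": "gene", "TE": "transposable_element"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in rows:
            fh.write(
                f"{r.chrom}\tmethylseed\t{type_of[r.kind]}\t{r.start + 1}\t{r.end}\t.\t"
                f"{r.strand}\t.\tID={r.id}\n"
            )


def read_states(path: PathLike) -> list[StateInterval]:
    """Read a chromatin-state BED (4th column = state 1-9).

    Overlapping intervals on the same chromosome are rejected: states are a
    partition of the annotated sequence.
    """
    out: list[StateInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            try:
                if len(f) < 4:
                    raise ValueError(f"expected >= 4 BED columns, got {len(f)}")
                out.append(StateInterval(f[0], int(f[1]), int(f[2]), int(f[3])))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    out.sort(key=lambda s: (s.chrom, s.start))
    for prev, cur in zip(out, out[1:]):
        if prev.chrom == cur.chrom and cur.start < prev.end:
            raise ValueError(
                f"overlapping state intervals {prev.chrom}:{prev.start}-{prev.end} "
                f"and {cur.chrom}:{cur.start}-{cur.end}"
            )
    return out


def write_states_bed(states: Iterable[StateInterval], path: PathLike) -> None:
    rows = sorted(states, key=lambda s: (s.chrom, s.start))
    with open(path, "w") as fh:
        for s in rows:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.state}\n")
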