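"""SNP-based allele partitioning, maternal transcript proportion, and
imprinting comparison.

Reads are assigned to the maternal or paternal genome by majority vote over
the ecotype-diagnostic SNPs they cover; ties and reads covering no SNP are
ambiguous and excluded from the counts. Per gene, the maternal transcript
proportion is m / (m + p). In triploid endosperm (2 maternal : 1 paternal
genomes) the biallelic expectation is 2/3; in diploid embryo it is 1/2, so
the pooled genome-wide maternal:paternal count ratio doubles as a tissue
purity check (2:1 endosperm, 1:1 embryo).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import pearson_r
from scipy import stats as _sps

__all__ = [
    "ImprintSet",
    "read_snp_table",
    "write_snp_table",
    "read_allele_counts",
    "write_allele_counts",
    "read_imprint_set",
    "write_imprint_set",
    "assign_alleles",
    "assign_alleles_bulk",
    "maternal_proportion",
    "add_proportions",
    "library_ratio_check",
    "min_read_filter",
    "imprinting_compare",
]

_BASES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class ImprintSet:
    """Known imprinted genes: maternally and paternally expressed sets."""

    megs: frozenset
    pegs: frozenset

    def __post_init__(self) -> None:
        if self.megs & self.pegs:
            raise ValueError("MEG and PEG sets must be disjoint")
        if not self.megs and not self.pegs:
            raise ValueError("empty imprint set")


def _validate_snps(snps: pd.DataFrame) -> pd.DataFrame:
    required = ["chrom", "pos", "maternal", "paternal"]
    missing = [c for c in required if c not in snps.columns]
    if missing:
        raise ValueError(f"SNP table missing columns: {missing}")
    bad = ~(snps["maternal"].isin(_BASES) & snps["paternal"].isin(_BASES))
    if bad.any():
        raise ValueError("SNP alleles must be A/C/G/T")
    if (snps["maternal"] == snps["paternal"]).any():
        raise ValueError("SNP maternal and paternal alleles must differ")
    return snps


def read_snp_table(path) -> pd.DataFrame:
    snps = pd.read_csv(path, sep="\t", names=["chrom", "pos", "maternal", "paternal"],
                       dtype={"chrom": str})
    return _validate_snps(snps)


def write_snp_table(snps: pd.DataFrame, path) -> None:
    _validate_snps(snps)[["chrom", "pos", "maternal", "paternal"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_allele_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", names=["gene", "maternal", "paternal"])
    if (df[["maternal", "paternal"]] < 0).any().any():
        raise ValueError("negative allele counts")
    return df


def write_allele_counts(counts: pd.DataFrame, path) -> None:
    counts[["gene", "maternal", "paternal"]].to_csv(path, sep="\t", header=False, index=False)


def read_imprint_set(path) -> ImprintSet:
    df = pd.read_csv(path, sep="\t", names=["gene", "klass"])
    megs = frozenset(df.loc[df["klass"] == "MEG", "gene"])
    pegs = frozenset(df.loc[df["klass"] == "PEG", "gene"])
    unknown = set(df["klass"]) - {"MEG", "PEG"}
    if unknown:
        raise ValueError(f"unknown imprint classes: {sorted(unknown)}")
    return ImprintSet(megs=megs, pegs=pegs)


def write_imprint_set(imprint: ImprintSet, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(imprint.megs):
            fh.write(f"{g}\tMEG\n")
        for g in sorted(imprint.pegs):
            fh.write(f"{g}\tPEG\n")


def assign_alleles(
    observations: Sequence[tuple[str, int, str]], snps: pd.DataFrame
) -> str:
    """Assign one read from its (chrom, pos, base) observations.

    Majority vote over covered SNPs; observations at non-SNP positions are
    ignored; ties or zero covered SNPs give "ambiguous".
    """
    lookup = {
        (c, p): (m, f)
        for c, p, m, f in zip(snps["chrom"], snps["pos"], snps["maternal"], snps["paternal"])
    }
    m_votes = p_votes = 0
    for chrom, pos, base in observations:
        alleles = lookup.get((chrom, pos))
        if alleles is None:
            continue
        if base == alleles[0]:
            m_votes += 1
        elif base == alleles[1]:
            p_votes += 1
    if m_votes > p_votes:
        return "maternal"
    if p_votes > m_votes:
        return "paternal"
    return "ambiguous"


def assign_alleles_bulk(obs: pd.DataFrame, snps: pd.DataFrame, n_reads: int) -> np.ndarray:
    """Vectorized per-read assignment.

    ``obs`` has columns read (0..n_reads-1), chrom, pos, base — one row per
    SNP-position observation. Returns an array of labels of length n_reads
    ("maternal"/"paternal"/"ambiguous").
    """
    merged = obs.merge(_validate_snps(snps), on=["chrom", "pos"], how="inner")
    m_votes = np.zeros(n_reads, dtype=np.int64)
    p_votes = np.zeros(n_reads, dtype=np.int64)
    if len(merged):
        rid = merged["read"].to_numpy(np.int64)
        np.add.at(m_votes, rid, (merged["base"] == merged["maternal"]).to_numpy().astype(np.int64))
        np.add.at(p_votes, rid, (merged["base"] == merged["paternal"]).to_numpy().astype(np.int64))
    labels = np.full(n_reads, "ambiguous", dtype=object)
    labels[m_votes > p_votes] = "maternal"
    labels[p_votes > m_votes] = "paternal"
    return labels


def maternal_proportion(m: int, p: int) -> float:
    """m / (m + p); undefined (error) when no reads."""
    if m < 0 or p < 0:
        raise ValueError("negative counts")
    if m + p == 0:
        raise ValueError("zero total reads: proportion undefined")
    return m / (m + p)


def add_proportions(counts: pd.DataFrame) -> pd.DataFrame:
    """Attach maternal_proportion per gene, dropping genes with zero totals."""
    total = counts["maternal"] + counts["paternal"]
    out = counts[total > 0].copy()
    out["maternal_proportion"] = out["maternal"] / (out["maternal"] + out["paternal"])
    return out


_EXPECTED_RATIO = {"endosperm": 2.0, "embryo": 1.0}


def library_ratio_check(counts: pd.DataFrame, tissue: str, tolerance: float = 0.10) -> dict:
    """Genome-wide maternal:paternal count ratio vs the dosage expectation.

    Passes when the pooled ratio is within ``tolerance`` (relative) of 2.0
    for endosperm or 1.0 for embryo.
    """
    if tissue not in _EXPECTED_RATIO:
        raise ValueError(f"tissue must be endosperm or embryo, got {tissue!r}")
    total_m = float(counts["maternal"].sum())
    total_p = float(counts["paternal"].sum())
    if total_p == 0:
        raise ValueError("no paternal reads: ratio undefined")
    ratio = total_m / total_p
    expected = _EXPECTED_RATIO[tissue]
    ok = abs(ratio / expected - 1.0) <= tolerance
    return {"ratio": ratio, "expected": expected, "flag": "pass" if ok else "fail",
            "total_maternal": int(total_m), "total_paternal": int(total_p)}


def min_read_filter(
    counts_by_sample: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame],
    min_total: int = 10,
) -> set:
    """Genes with m + p >= min_total in every compared sample."""
    if isinstance(counts_by_sample, Mapping):
        tables: Iterable[pd.DataFrame] = counts_by_sample.values()
    else:
        tables = counts_by_sample
    kept: set | None = None
    for df in tables:
        total = df["maternal"] + df["paternal"]
        genes = set(df.loc[total >= min_total, "gene"])
        kept = genes if kept is None else kept & genes
    return kept if kept is not None else set()


def imprinting_compare(
    counts_g1: pd.DataFrame,
    counts_g2: pd.DataFrame,
    imprint_set: ImprintSet,
    min_total: int = 10,
    test: str = "paired",
) -> dict:
    """Compare maternal proportions of MEGs/PEGs between two genotypes.

    Per class, genes passing the read filter in both genotypes give paired
    per-gene proportions; a class-level paired t-test (Welch's unpaired as
    option) tests for a shift, and a single Pearson correlation is computed
    over the union of analyzed MEGs and PEGs. Classes with fewer than 3
    shared genes are skipped with a warning.
    """
    keep = min_read_filter([counts_g1, counts_g2], min_total)
    p1 = add_proportions(counts_g1[counts_g1["gene"].isin(keep)]).set_index("gene")
    p2 = add_proportions(counts_g2[counts_g2["gene"].isin(keep)]).set_index("gene")
    shared = p1.index.intersection(p2.index)

    result: dict = {"classes": {}, "n_shared": 0, "pearson_r": None}
    all_genes: list = []
    for klass, members in (("MEG", imprint_set.megs), ("PEG", imprint_set.pegs)):
        genes = [g for g in shared if g in members]
        if len(genes) < 3:
            warnings.warn(f"{klass}: only {len(genes)} shared genes, class skipped")
            continue
        x1 = p1.loc[genes, "maternal_proportion"].to_numpy()
        x2 = p2.loc[genes, "maternal_proportion"].to_numpy()
        if test == "paired":
            if np.allclose(x1, x2):
                t_stat, p_val = 0.0, 1.0
            else:
                res = _sps.ttest_rel(x2, x1)
                t_stat, p_val = float(res.statistic), float(res.pvalue)
        elif test == "welch":
            res = _sps.ttest_ind(x2, x1, equal_var=False)
            t_stat, p_val = float(res.statistic), float(res.pvalue)
        else:
            raise ValueError(f"test must be paired or welch, got {test!r}")
        result["classes"][klass] = {
            "n": len(genes),
            "mean_g1": float(x1.mean()),
            "mean_g2": float(x2.mean()),
            "t": t_stat,
            "p": p_val,
            "genes": genes,
        }
        all_genes.extend(genes)
    if not result["classes"]:
        raise ValueError("no imprinted class has >= 3 comparable genes")
    result["n_shared"] = len(all_genes)
    if len(all_genes) >= 3:
        x1 = p1.loc[all_genes, "maternal_proportion"].to_numpy()
        x2 = p2.loc[all_genes, "maternal_proportion"].to_numpy()
        if np.var(x1) > 0 and np.var(x2) > 0:
            result["pearson_r"] = pearson_r(x1, x2)
    return result
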