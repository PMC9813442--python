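"""Synthetic embryo/endosperm methylomes with planted ground truth.

The generator emulates the statistical structure the analysis assumes, at
desk scale:

* a multi-chromosome genome whose arms are euchromatic (chromatin states 1-7)
  and whose central block is pericentromeric heterochromatin (states 8-9),
  plus a fully unmethylated lambda spike-in chromosome;
* CG/CHG/CHH cytosine site maps with TE-like, gene-body, heterochromatin and
  background methylation baselines (embryo CG higher than endosperm);
* planted maternally demethylated loci ("DME targets"): CG-dense, TE-like
  intervals concentrated in gene-flanking euchromatin (60%) and in
  heterochromatin (40%), demethylated by depth ``dme_delta`` on the maternal
  endosperm genome only;
* an h1-genotype perturbation confined to the endosperm: heterochromatin
  targets, only partially demethylated in the wild type (linker histone H1
  obstructs the glycosylase), are demethylated to full depth, and gene bodies
  gain mild CG hypermethylation. Embryo truth is identical across genotypes;
* triploid endosperm allele dosage (2 maternal : 1 paternal sequencing depth)
  versus diploid 1:1 embryo;
* MEG/PEG imprinted expression with a biallelic 2/3 maternal baseline.

Every output is a deterministic function of (spec, model, seed); per-site
truth tables and planted-interval lists are returned for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FeatureRecord, StateInterval

__all__ = [
    "GenomeSpec",
    "MethModel",
    "ImprintSpec",
    "Genome",
    "TruthTable",
    "build_genome",
    "methylome_truth",
    "planted_dmr_truth",
    "sample_counts",
    "expression_truth_and_counts",
    "simulate_allele_reads",
    "simulate_scenario",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Layout of the synthetic genome.

    Site densities are cytosines per kb (both strands pooled); ``snp_spacing``
    is the mean distance between ecotype-diagnostic SNPs (~1/500 bp emulates
    the density of the Col-0 x Ler cross genome-wide).
    """

    n_chroms: int = 3
    chrom_length: int = 1_000_000
    pericentromere_frac: float = 0.2
    state_tile: int = 10_000
    cg_per_kb_eu: float = 100.0
    cg_per_kb_het: float = 120.0
    chg_per_kb: float = 60.0
    chh_per_kb: float = 150.0
    n_genes_per_chrom: int = 150
    gene_length: tuple[int, int] = (1_000, 4_000)
    n_tes_per_chrom: int = 50
    te_length: tuple[int, int] = (300, 3_000)
    n_dme_targets_per_chrom: int = 60
    dme_target_length: tuple[int, int] = (200, 600)
    dme_het_fraction: float = 0.4
    dme_target_cg_spacing: int = 10
    snp_spacing: int = 500
    spike_length: int = 48_502
    spike_chrom: str = "lambda"

    def __post_init__(self) -> None:
        if not 0 < self.pericentromere_frac < 1:
            raise ValueError("pericentromere_frac must be in (0, 1)")
        for name in ("n_chroms", "chrom_length", "state_tile", "snp_spacing", "spike_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gene_length[1] >= self.chrom_length or self.te_length[1] >= self.chrom_length:
            raise ValueError("features longer than chromosome")


@dataclass(frozen=True)
class MethModel:
    """True methylation probabilities and perturbation depths.

    Baselines are per (location class, context); the endosperm maternal CG
    genome is globally reduced by ``endosperm_cg_demethylation`` (relative)
    outside DME targets, making embryo CG higher than endosperm. At DME
    targets the maternal endosperm probability drops by the effective
    demethylation depth: ``dme_delta`` in euchromatin;
    ``dme_delta * wt_het_efficiency`` at heterochromatin targets in the wild
    type, raised by ``h1_extra_het_demethylation`` (capped at ``dme_delta``)
    in the h1 genotype. ``h1_genic_hypermethylation`` is added to endosperm
    gene-body CG in the h1 genotype only. Embryo parameters are genotype
    independent.
    """

    cg_te: float = 0.90
    cg_gene_body: float = 0.25
    cg_het: float = 0.95
    cg_background: float = 0.05
    chg_te: float = 0.65
    chg_het: float = 0.70
    chg_background: float = 0.02
    chh_te: float = 0.15
    chh_het: float = 0.10
    chh_background: float = 0.02
    endosperm_cg_demethylation: float = 0.15
    dme_delta: float = 0.7
    wt_het_efficiency: float = 0.4
    h1_extra_het_demethylation: float = 0.42
    h1_genic_hypermethylation: float = 0.10

    def __post_init__(self) -> None:
        for name in ("cg_te", "cg_gene_body", "cg_het", "cg_background", "chg_te",
                     "chg_het", "chg_background", "chh_te", "chh_het", "chh_background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("dme_delta", "h1_extra_het_demethylation", "h1_genic_hypermethylation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def het_delta(self, genotype: str) -> float:
        """Effective demethylation depth at heterochromatin targets."""
        base = self.dme_delta * self.wt_het_efficiency
        if genotype == "h1":
            return min(self.dme_delta, base + self.h1_extra_het_demethylation)
        return base


@dataclass(frozen=True)
class ImprintSpec:
    """Imprinted-expression structure for the allele-specific counts."""

    n_meg: int = 80
    n_peg: int = 42
    meg_pi: float = 0.95
    peg_pi: float = 0.10
    biallelic_pi: float = 2.0 / 3.0
    mean_reads: int = 100
    h1_meg_shift: float = 0.02  # small maternal-proportion increase of MEGs in h1


@dataclass
class Genome:
    spec: GenomeSpec
    chrom_lengths: dict[str, int]
    autosomes: list[str]
    states: list[StateInterval]
    features: list[FeatureRecord]
    sites: pd.DataFrame        # chrom, pos (1-based), strand, context
    snps: pd.DataFrame         # chrom, pos, maternal, paternal
    dme_targets: pd.DataFrame  # chrom, start, end, compartment (eu|het)
    pericentromeres: list[tuple[str, int, int]]


@dataclass
class TruthTable:
    """Per-site true methylation probabilities for one (tissue, genotype)."""

    tissue: str
    genotype: str
    sites: pd.DataFrame  # chrom, pos, strand, context, p_maternal, p_paternal


TISSUES = ("embryo", "endosperm")
GENOTYPES = ("wt", "h1")
_MATERNAL_DEPTH_SHARE = {"endosperm": 2.0 / 3.0, "embryo": 0.5}


def _place_nonoverlapping(rng, n, length_range, allowed, max_tries=2000):
    """Greedy placement of n non-overlapping intervals inside allowed regions.

    ``allowed`` is a list of (lo, hi) spans. Returns sorted (start, end)
    pairs; raises if placement is infeasible after max_tries attempts.
    """
    placed: list[tuple[int, int]] = []
    spans = [s for s in allowed if s[1] - s[0] > length_range[0]]
    if not spans and n > 0:
        raise ValueError("no room to place features (infeasible spec)")
    weights = np.array([hi - lo for lo, hi in spans], dtype=float)
    weights /= weights.sum()
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries + 10 * n:
            raise ValueError("could not place features without overlap (infeasible spec)")
        span = spans[rng.choice(len(spans), p=weights)]
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        if span[1] - span[0] <= length:
            continue
        start = int(rng.integers(span[0], span[1] - length))
        end = start + length
        if any(start < e and end > s for s, e in placed):
            continue
        placed.append((start, end))
    return sorted(placed)


def build_genome(spec: GenomeSpec = GenomeSpec(), seed: int = 0) -> Genome:
    """Deterministically build chromosomes, states, features, sites, and SNPs."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(0,))
    rng = np.random.default_rng(ss)
    autosomes = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    chrom_lengths = {c: spec.chrom_length for c in autosomes}
    chrom_lengths[spec.spike_chrom] = spec.spike_length

    states: list[StateInterval] = []
    features: list[FeatureRecord] = []
    pericentromeres: list[tuple[str, int, int]] = []
    target_rows: list[dict] = []
    site_frames: list[pd.DataFrame] = []
    snp_frames: list[pd.DataFrame] = []

    for chrom in autosomes:
        L = spec.chrom_length
        pc_len = int(round(spec.pericentromere_frac * L))
        pc_start, pc_end = (L - pc_len) // 2, (L - pc_len) // 2 + pc_len
        # state tiling: tiles whose midpoint falls in the pericentromere are
        # heterochromatic (8/9), the rest draw from euchromatic states 1-7
        het_spans: list[tuple[int, int]] = []
        for tile_start in range(0, L, spec.state_tile):
            tile_end = min(tile_start + spec.state_tile, L)
            mid = (tile_start + tile_end) // 2
            if pc_start <= mid < pc_end:
                state = int(rng.integers(8, 10))
                het_spans.append((tile_start, tile_end))
            else:
                state = int(rng.integers(1, 8))
            states.append(StateInterval(chrom, tile_start, tile_end, state))
        het_lo = min(s for s, _ in het_spans)
        het_hi = max(e for _, e in het_spans)
        pericentromeres.append((chrom, het_lo, het_hi))
        arms = [(0, het_lo), (het_hi, L)]

        gene_ivs = _place_nonoverlapping(rng, spec.n_genes_per_chrom, spec.gene_length, arms)
        for i, (s, e) in enumerate(gene_ivs):
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(FeatureRecord(chrom, s, e, strand, "gene", f"{chrom}g{i + 1:04d}"))

        # TEs: mostly pericentromeric, some euchromatic, avoiding genes
        n_te_het = int(round(spec.n_tes_per_chrom * 0.6))
        te_het = _place_nonoverlapping(rng, n_te_het, spec.te_length, [(het_lo, het_hi)])
        occupied = sorted(gene_ivs + te_het)
        eu_free: list[tuple[int, int]] = []
        for lo, hi in arms:
            cur = lo
            for s, e in occupied:
                if s >= hi or e <= lo:
                    continue
                if s > cur:
                    eu_free.append((cur, s))
                cur = max(cur, e)
            if cur < hi:
                eu_free.append((cur, hi))
        te_eu = _place_nonoverlapping(
            rng, spec.n_tes_per_chrom - n_te_het, spec.te_length, eu_free
        )
        for i, (s, e) in enumerate(sorted(te_het + te_eu)):
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(FeatureRecord(chrom, s, e, strand, "TE", f"{chrom}te{i + 1:04d}"))

        # DME targets: gene-flanking euchromatic (emulating small flanking
        # TEs) and heterochromatic, non-overlapping
        n_het_t = int(round(spec.n_dme_targets_per_chrom * spec.dme_het_fraction))
        n_eu_t = spec.n_dme_targets_per_chrom - n_het_t
        placed: list[tuple[int, int]] = []
        tries = 0
        while len(placed) < n_eu_t:
            tries += 1
            if tries > 200 * max(n_eu_t, 1):
                raise ValueError("could not place gene-flanking DME targets")
            g = gene_ivs[int(rng.integers(0, len(gene_ivs)))]
            length = int(rng.integers(*spec.dme_target_length))
            if rng.random() < 0.5:
                s, e = g[0] - length, g[0]
            else:
                s, e = g[1], g[1] + length
            if s < 0 or e > L or (het_lo < e and s < het_hi):
                continue
            if any(s < pe and e > ps for ps, pe in placed):
                continue
            if any(s < ge and e > gs for gs, ge in gene_ivs):
                continue
            placed.append((s, e))
        for s, e in sorted(placed):
            target_rows.append({"chrom": chrom, "start": s, "end": e, "compartment": "eu"})
        het_targets = _place_nonoverlapping(
            rng, n_het_t, spec.dme_target_length, [(het_lo, het_hi)]
        )
        for s, e in het_targets:
            target_rows.append({"chrom": chrom, "start": s, "end": e, "compartment": "het"})

        # cytosine site maps; DME targets additionally carry a regular CG
        # grid so planted loci are CG-dense like the small TEs they emulate
        n_cg_eu = rng.poisson(spec.cg_per_kb_eu / 1000.0 * (L - pc_len))
        n_cg_het = rng.poisson(spec.cg_per_kb_het / 1000.0 * pc_len)
        eu_pos = []
        arm_lengths = np.array([hi - lo for lo, hi in arms], dtype=float)
        arm_p = arm_lengths / arm_lengths.sum()
        arm_pick = rng.choice(len(arms), size=n_cg_eu, p=arm_p)
        for ai, (lo, hi) in enumerate(arms):
            k = int((arm_pick == ai).sum())
            eu_pos.append(rng.integers(lo, hi, size=k))
        cg_pos = np.concatenate(
            eu_pos + [rng.integers(het_lo, het_hi, size=n_cg_het)]
        )
        target_grids = [
            np.arange(row["start"], row["end"], spec.dme_target_cg_spacing)
            for row in target_rows
            if row["chrom"] == chrom
        ]
        if target_grids:
            cg_pos = np.concatenate([cg_pos] + target_grids)
        cg_pos = np.unique(cg_pos)
        n_chg = rng.poisson(spec.chg_per_kb / 1000.0 * L)
        n_chh = rng.poisson(spec.chh_per_kb / 1000.0 * L)
        chg_pos = np.unique(rng.integers(0, L, size=n_chg))
        chh_pos = np.unique(rng.integers(0, L, size=n_chh))
        for ctx, pos in (("CG", cg_pos), ("CHG", chg_pos), ("CHH", chh_pos)):
            strand = np.where(rng.random(len(pos)) < 0.5, "+", "-")
            site_frames.append(
                pd.DataFrame(
                    {"chrom": chrom, "pos": pos.astype(np.int64) + 1,
                     "strand": strand, "context": ctx}
                )
            )

        # ecotype SNPs on a jittered grid, ~1 per snp_spacing bp
        grid = np.arange(0, L - spec.snp_spacing, spec.snp_spacing)
        snp_pos = grid + rng.integers(0, spec.snp_spacing, size=len(grid))
        bases = np.array(list("ACGT"))
        mat_idx = rng.integers(0, 4, size=len(snp_pos))
        pat_idx = (mat_idx + rng.integers(1, 4, size=len(snp_pos))) % 4
        snp_frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": snp_pos.astype(np.int64) + 1,
                 "maternal": bases[mat_idx], "paternal": bases[pat_idx]}
            )
        )

    # spike-in: unmethylated lambda chromosome, euchromatic densities
    spike_sites = []
    for ctx, dens in (("CG", spec.cg_per_kb_eu), ("CHG", spec.chg_per_kb),
                      ("CHH", spec.chh_per_kb)):
        n = rng.poisson(dens / 1000.0 * spec.spike_length)
        pos = np.unique(rng.integers(0, spec.spike_length, size=n))
        strand = np.where(rng.random(len(pos)) < 0.5, "+", "-")
        spike_sites.append(
            pd.DataFrame({"chrom": spec.spike_chrom, "pos": pos.astype(np.int64) + 1,
                          "strand": strand, "context": ctx})
        )
    site_frames.extend(spike_sites)

    sites = pd.concat(site_frames, ignore_index=True)
    sites = sites.sort_values(["chrom", "pos"], ignore_index=True)
    snps = pd.concat(snp_frames, ignore_index=True).sort_values(
        ["chrom", "pos"], ignore_index=True
    )
    targets = pd.DataFrame(target_rows).sort_values(["chrom", "start"], ignore_index=True)
    features.sort(key=lambda f: (f.chrom, f.start))
    return Genome(
        spec=spec,
        chrom_lengths=chrom_lengths,
        autosomes=autosomes,
        states=states,
        features=features,
        sites=sites,
        snps=snps,
        dme_targets=targets,
        pericentromeres=pericentromeres,
    )


def _membership(sites: pd.DataFrame, triples) -> np.ndarray:
    from .intervals import IntervalIndex

    idx = IntervalIndex(triples)
    pos0 = sites["pos"].to_numpy(np.int64) - 1
    return idx.overlaps(sites["chrom"].to_numpy(), pos0, pos0 + 1)


def _baseline(genome: Genome, model: MethModel) -> np.ndarray:
    """Per-site baseline probability from location class and context.

    Precedence: DME target (TE-like) > TE > heterochromatin > gene body >
    background. The spike-in chromosome is 0 everywhere.
    """
    sites = genome.sites
    ctx = sites["context"].to_numpy()
    in_te = _membership(
        sites, ((f.chrom, f.start, f.end) for f in genome.features if f.kind == "TE")
    )
    in_gene = _membership(
        sites, ((f.chrom, f.start, f.end) for f in genome.features if f.kind == "gene")
    )
    in_het = _membership(
        sites, ((s.chrom, s.start, s.end) for s in genome.states if s.state >= 8)
    )
    in_target = _membership(
        sites,
        ((r.chrom, r.start, r.end) for r in genome.dme_targets.itertuples()),
    )
    levels = {
        "CG": (model.cg_te, model.cg_het, model.cg_gene_body, model.cg_background),
        "CHG": (model.chg_te, model.chg_het, model.chg_background, model.chg_background),
        "CHH": (model.chh_te, model.chh_het, model.chh_background, model.chh_background),
    }
    p = np.zeros(len(sites))
    for c, (te, het, gene, bg) in levels.items():
        m = ctx == c
        p[m] = bg
        p[m & in_gene] = gene
        p[m & in_het] = het
        p[m & (in_te | in_target)] = te
    p[sites["chrom"].to_numpy() == genome.spec.spike_chrom] = 0.0
    return p


def methylome_truth(
    genome: Genome, model: MethModel, tissue: str, genotype: str
) -> TruthTable:
    """Per-site true methylation probability per parental genome."""
    if tissue not in TISSUES:
        raise ValueError(f"tissue must be one of {TISSUES}, got {tissue!r}")
    if genotype not in GENOTYPES:
        raise ValueError(f"genotype must be one of {GENOTYPES}, got {genotype!r}")
    sites = genome.sites
    base = _baseline(genome, model)
    p_pat = base.copy()
    p_mat = base.copy()
    if tissue == "endosperm":
        is_cg = (sites["context"] == "CG").to_numpy()
        spike = (sites["chrom"] == genome.spec.spike_chrom).to_numpy()
        # global maternal CG hypomethylation (embryo CG > endosperm CG)
        p_mat[is_cg] = p_mat[is_cg] * (1.0 - model.endosperm_cg_demethylation)
        # planted maternal demethylation at DME targets (CG), depth by
        # compartment and genotype
        for compartment, delta in (
            ("eu", model.dme_delta),
            ("het", model.het_delta(genotype)),
        ):
            rows = genome.dme_targets[genome.dme_targets["compartment"] == compartment]
            member = _membership(
                sites, ((r.chrom, r.start, r.end) for r in rows.itertuples())
            )
            m = member & is_cg
            p_mat[m] = np.clip(base[m] - delta, 0.0, 1.0)
        if genotype == "h1":
            # mild genic CG hypermethylation, both parental genomes
            in_gene = _membership(
                sites,
                ((f.chrom, f.start, f.end) for f in genome.features if f.kind == "gene"),
            )
            m = in_gene & is_cg & ~spike
            p_mat[m] = np.clip(p_mat[m] + model.h1_genic_hypermethylation, 0.0, 1.0)
            p_pat[m] = np.clip(p_pat[m] + model.h1_genic_hypermethylation, 0.0, 1.0)
        p_mat[spike] = 0.0
        p_pat[spike] = 0.0
    out = sites.copy()
    out["p_maternal"] = p_mat
    out["p_paternal"] = p_pat
    return TruthTable(tissue=tissue, genotype=genotype, sites=out)


def planted_dmr_truth(genome: Genome, model: MethModel, genotype: str) -> pd.DataFrame:
    """Planted intervals with their expected embryo-minus-endosperm pooled
    CG difference and whether the model expects a callable DMR (> 0.35
    pooled difference, a margin above the 0.3 caller threshold)."""
    em = methylome_truth(genome, model, "embryo", genotype).sites
    en = methylome_truth(genome, model, "endosperm", genotype).sites
    share = _MATERNAL_DEPTH_SHARE["endosperm"]
    rows = []
    cg_em = em[em["context"] == "CG"]
    cg_en = en[en["context"] == "CG"]
    for r in genome.dme_targets.itertuples():
        m_em = (cg_em["chrom"] == r.chrom) & (cg_em["pos"] > r.start) & (cg_em["pos"] <= r.end)
        m_en = (cg_en["chrom"] == r.chrom) & (cg_en["pos"] > r.start) & (cg_en["pos"] <= r.end)
        if m_em.sum() == 0:
            continue
        p_embryo = float(
            (0.5 * cg_em.loc[m_em, "p_maternal"] + 0.5 * cg_em.loc[m_em, "p_paternal"]).mean()
        )
        p_endo = float(
            (share * cg_en.loc[m_en, "p_maternal"]
             + (1 - share) * cg_en.loc[m_en, "p_paternal"]).mean()
        )
        diff = p_embryo - p_endo
        rows.append(
            {
                "chrom": r.chrom, "start": r.start, "end": r.end,
                "compartment": r.compartment, "expected_diff": diff,
                "expected_dmr": diff > 0.35, "direction": "A-hyper",
            }
        )
    return pd.DataFrame(rows)


def sample_counts(
    truth: TruthTable,
    mean_depth: float = 20.0,
    nonconversion: float = 0.01,
    seed: int = 0,
    dispersion: float | None = None,
) -> dict[str, pd.DataFrame]:
    """Draw sequencing calls from a truth table.

    Depth per site and parent is Poisson (negative binomial with shape
    ``dispersion`` when given) around the parent's share of ``mean_depth``
    (2:1 maternal:paternal for endosperm, 1:1 for embryo). The observed
    methylated-call probability is ``p + (1 - p) * nonconversion`` (failed
    conversion reads out as methylated). Returns CX-style DataFrames under
    keys "pooled", "maternal", "paternal".
    """
    if not 0.0 <= nonconversion <= 1.0:
        raise ValueError("nonconversion must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    sites = truth.sites
    share = _MATERNAL_DEPTH_SHARE[truth.tissue]
    out: dict[str, pd.DataFrame] = {}
    counts = {}
    for parent, parent_share in (("maternal", share), ("paternal", 1 - share)):
        mu = mean_depth * parent_share
        if dispersion is None:
            depth = rng.poisson(mu, size=len(sites))
        else:
            p_nb = dispersion / (dispersion + mu)
            depth = rng.negative_binomial(dispersion, p_nb, size=len(sites))
        p_true = sites[f"p_{parent}"].to_numpy()
        p_obs = p_true + (1.0 - p_true) * nonconversion
        meth = rng.binomial(depth, p_obs)
        counts[parent] = (depth, meth)
        df = sites[["chrom", "pos", "strand", "context"]].copy()
        df["meth"] = meth
        df["unmeth"] = depth - meth
        out[parent] = df[["chrom", "pos", "strand", "meth", "unmeth", "context"]]
    pooled = sites[["chrom", "pos", "strand", "context"]].copy()
    pooled["meth"] = counts["maternal"][1] + counts["paternal"][1]
    pooled["unmeth"] = (
        counts["maternal"][0] - counts["maternal"][1]
        + counts["paternal"][0] - counts["paternal"][1]
    )
    out["pooled"] = pooled[["chrom", "pos", "strand", "meth", "unmeth", "context"]]
    return out


def expression_truth_and_counts(
    genome: Genome,
    imprint: ImprintSpec = ImprintSpec(),
    seed: int = 0,
) -> dict:
    """Allele-specific expression counts per genotype with imprinting truth.

    Genes are drawn from the genome's gene annotation: ``n_meg`` MEGs
    (maternal proportion ``meg_pi``), ``n_peg`` PEGs (``peg_pi``), the rest
    biallelic at the triploid 2/3 baseline. In the h1 genotype MEG
    proportions shift up by ``h1_meg_shift`` (capped at 1). Per gene and
    genotype, total reads are Poisson(``mean_reads``) and maternal reads
    binomial in the gene's true proportion.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))
    gene_ids = [f.id for f in genome.features if f.kind == "gene"]
    if imprint.n_meg + imprint.n_peg > len(gene_ids):
        raise ValueError("not enough genes for the requested MEG/PEG counts")
    order = rng.permutation(len(gene_ids))
    megs = [gene_ids[i] for i in order[: imprint.n_meg]]
    pegs = [gene_ids[i] for i in order[imprint.n_meg: imprint.n_meg + imprint.n_peg]]
    klass = {g: "biallelic" for g in gene_ids}
    klass.update({g: "MEG" for g in megs})
    klass.update({g: "PEG" for g in pegs})
    pi_of = {"MEG": imprint.meg_pi, "PEG": imprint.peg_pi, "biallelic": imprint.biallelic_pi}
    counts = {}
    for genotype in GENOTYPES:
        rows = []
        for g in gene_ids:
            pi = pi_of[klass[g]]
            if genotype == "h1" and klass[g] == "MEG":
                pi = min(1.0, pi + imprint.h1_meg_shift)
            total = int(rng.poisson(imprint.mean_reads))
            m = int(rng.binomial(total, pi)) if total > 0 else 0
            rows.append({"gene": g, "maternal": m, "paternal": total - m})
        counts[genotype] = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {
            "gene": gene_ids,
            "klass": [klass[g] for g in gene_ids],
            "pi_wt": [pi_of[klass[g]] for g in gene_ids],
            "pi_h1": [
                min(1.0, pi_of[klass[g]] + imprint.h1_meg_shift)
                if klass[g] == "MEG" else pi_of[klass[g]]
                for g in gene_ids
            ],
        }
    )
    return {"counts": counts, "truth": truth, "megs": sorted(megs), "pegs": sorted(pegs)}


def simulate_allele_reads(
    genome: Genome,
    tissue: str,
    n_reads: int,
    read_length: int = 100,
    seed: int = 0,
    error_rate: float = 0.0,
) -> dict:
    """Simulate parent-of-origin tagged reads and their SNP observations.

    Reads are placed uniformly on the autosomes; each read's true parent is
    maternal with probability 2/3 (endosperm) or 1/2 (embryo); at every SNP a
    read covers it reports its parent's allele (swapped to the other allele
    with probability ``error_rate``). Returns the observation table
    (read, chrom, pos, base), the true parent labels, and n_reads — ready for
    :func:`methylseed.imprinting.assign_alleles_bulk`.
    """
    if tissue not in TISSUES:
        raise ValueError(f"tissue must be one of {TISSUES}, got {tissue!r}")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(3,)))
    share = _MATERNAL_DEPTH_SHARE[tissue]
    lengths = np.array([genome.chrom_lengths[c] for c in genome.autosomes], dtype=float)
    chrom_idx = rng.choice(len(genome.autosomes), size=n_reads, p=lengths / lengths.sum())
    starts = rng.integers(0, (lengths[chrom_idx] - read_length).astype(np.int64))
    is_maternal = rng.random(n_reads) < share

    obs_frames = []
    snps = genome.snps
    for ci, chrom in enumerate(genome.autosomes):
        mask = chrom_idx == ci
        if not mask.any():
            continue
        read_ids = np.nonzero(mask)[0]
        s = starts[mask]
        snp_c = snps[snps["chrom"] == chrom]
        pos = snp_c["pos"].to_numpy(np.int64)  # 1-based
        lo = np.searchsorted(pos, s + 1, side="left")
        hi = np.searchsorted(pos, s + read_length, side="right")
        cnt = hi - lo
        total = int(cnt.sum())
        if total == 0:
            continue
        rep = np.repeat(np.arange(len(s)), cnt)
        offsets = np.arange(total) - np.repeat(np.cumsum(cnt) - cnt, cnt)
        snp_i = np.repeat(lo, cnt) + offsets
        mat = snp_c["maternal"].to_numpy()[snp_i]
        pat = snp_c["paternal"].to_numpy()[snp_i]
        read_maternal = is_maternal[read_ids[rep]]
        base = np.where(read_maternal, mat, pat)
        if error_rate > 0:
            flip = rng.random(total) < error_rate
            base = np.where(flip, np.where(read_maternal, pat, mat), base)
        obs_frames.append(
            pd.DataFrame(
                {"read": read_ids[rep], "chrom": chrom, "pos": pos[snp_i], "base": base}
            )
        )
    obs = (
        pd.concat(obs_frames, ignore_index=True)
        if obs_frames
        else pd.DataFrame(columns=["read", "chrom", "pos", "base"])
    )
    truth = np.where(is_maternal, "maternal", "paternal")
    return {"observations": obs, "true_parent": truth, "n_reads": n_reads}


def simulate_scenario(
    spec: GenomeSpec = GenomeSpec(),
    model: MethModel = MethModel(),
    mean_depth: float = 20.0,
    nonconversion: float = 0.01,
    seed: int = 0,
) -> dict:
    """Full scenario: genome + truth + counts for every (tissue, genotype).

    The per-(tissue, genotype) sampling seeds are derived deterministically
    from ``seed``.
    """
    genome = build_genome(spec, seed=seed)
    truths: dict[tuple[str, str], TruthTable] = {}
    counts: dict[tuple[str, str], dict[str, pd.DataFrame]] = {}
    child = np.random.SeedSequence(entropy=seed, spawn_key=(4,)).generate_state(
        len(TISSUES) * len(GENOTYPES)
    ) % (2**31)
    i = 0
    for tissue in TISSUES:
        for genotype in GENOTYPES:
            t = methylome_truth(genome, model, tissue, genotype)
            truths[(tissue, genotype)] = t
            counts[(tissue, genotype)] = sample_counts(
                t, mean_depth=mean_depth, nonconversion=nonconversion, seed=int(child[i])
            )
            i += 1
    planted = {g: planted_dmr_truth(genome, model, g) for g in GENOTYPES}
    return {"genome": genome, "truths": truths, "counts": counts, "planted": planted}
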