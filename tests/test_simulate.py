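"""Generator contracts: determinism, genome structure, truth arithmetic."""

import numpy as np
import pandas as pd
import pytest

from methylseed.intervals import IntervalIndex
from methylseed.simulate import (
    GenomeSpec,
    ImprintSpec,
    MethModel,
    TruthTable,
    build_genome,
    expression_truth_and_counts,
    methylome_truth,
    planted_dmr_truth,
    sample_counts,
)

SPEC = GenomeSpec(
    n_chroms=1,
    chrom_length=120_000,
    n_genes_per_chrom=20,
    n_tes_per_chrom=8,
    n_dme_targets_per_chrom=10,
    spike_length=10_000,
)


@pytest.fixture(scope="module")
def genome():
    return build_genome(SPEC, seed=3)


class TestBuildGenome:
    def test_same_seed_identical_output(self, genome):
        other = build_genome(SPEC, seed=3)
        pd.testing.assert_frame_equal(genome.sites, other.sites)
        pd.testing.assert_frame_equal(genome.snps, other.snps)
        pd.testing.assert_frame_equal(genome.dme_targets, other.dme_targets)
        assert genome.states == other.states
        assert genome.features == other.features

    def test_different_seed_differs(self, genome):
        other = build_genome(SPEC, seed=4)
        assert not genome.sites.equals(other.sites)

    def test_pericentromere_size_within_one_tile(self, genome):
        het_bp = sum(s.end - s.start for s in genome.states if s.state >= 8)
        target = SPEC.pericentromere_frac * SPEC.chrom_length
        assert abs(het_bp - target) <= SPEC.state_tile

    def test_states_tile_each_chromosome(self, genome):
        for chrom in genome.autosomes:
            ivs = sorted(
                (s.start, s.end) for s in genome.states if s.chrom == chrom
            )
            assert ivs[0][0] == 0 and ivs[-1][1] == SPEC.chrom_length
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 == s2

    def test_zero_te_count(self):
        spec = GenomeSpec(
            n_chroms=1, chrom_length=120_000, n_genes_per_chrom=10,
            n_tes_per_chrom=0, n_dme_targets_per_chrom=5, spike_length=10_000,
        )
        g = build_genome(spec, seed=0)
        assert not any(f.kind == "TE" for f in g.features)

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            GenomeSpec(n_chroms=1, chrom_length=2_000, gene_length=(3_000, 4_000))

    def test_dme_targets_are_cg_dense(self, genome):
        """Planted loci carry >= 10 CG sites per 100 bp, like the small TEs
        they emulate."""
        cg = genome.sites[genome.sites["context"] == "CG"]
        for r in genome.dme_targets.itertuples():
            n = (
                (cg["chrom"] == r.chrom)
                & (cg["pos"] > r.start)
                & (cg["pos"] <= r.end)
            ).sum()
            assert n / (r.end - r.start) >= 10 / 100

    def test_eu_targets_flank_genes_het_targets_pericentromeric(self, genome):
        genes = IntervalIndex(
            (f.chrom, f.start - 1, f.end + 1) for f in genome.features if f.kind == "gene"
        )
        het = IntervalIndex(genome.pericentromeres)
        for r in genome.dme_targets.itertuples():
            if r.compartment == "eu":
                assert genes.overlaps(r.chrom, r.start, r.end)[0]
            else:
                assert het.overlaps(r.chrom, r.start, r.end)[0]


class TestMethylomeTruth:
    def test_embryo_identical_across_genotypes(self, genome):
        wt = methylome_truth(genome, MethModel(), "embryo", "wt")
        h1 = methylome_truth(genome, MethModel(), "embryo", "h1")
        pd.testing.assert_frame_equal(wt.sites, h1.sites)

    def test_probabilities_in_unit_interval(self, genome):
        t = methylome_truth(genome, MethModel(), "endosperm", "h1")
        for col in ("p_maternal", "p_paternal"):
            assert ((t.sites[col] >= 0) & (t.sites[col] <= 1)).all()

    def test_demethylation_depth_arithmetic(self, genome):
        """Euchromatic target, baseline 0.9, depth 0.7: maternal endosperm 0.2."""
        model = MethModel()
        t = methylome_truth(genome, model, "endosperm", "wt").sites
        eu = genome.dme_targets[genome.dme_targets["compartment"] == "eu"]
        r = eu.iloc[0]
        m = (
            (t["chrom"] == r["chrom"]) & (t["pos"] > r["start"]) & (t["pos"] <= r["end"])
            & (t["context"] == "CG")
        )
        vals = t.loc[m, "p_maternal"].unique()
        assert np.allclose(vals, model.cg_te - model.dme_delta)

    def test_h1_deepens_heterochromatin_targets_only_in_endosperm(self, genome):
        model = MethModel()
        wt = methylome_truth(genome, model, "endosperm", "wt").sites
        h1 = methylome_truth(genome, model, "endosperm", "h1").sites
        het = genome.dme_targets[genome.dme_targets["compartment"] == "het"]
        r = het.iloc[0]
        m = (
            (wt["chrom"] == r["chrom"]) & (wt["pos"] > r["start"]) & (wt["pos"] <= r["end"])
            & (wt["context"] == "CG")
        )
        assert (h1.loc[m, "p_maternal"] < wt.loc[m, "p_maternal"]).all()
        assert h1.loc[m, "p_maternal"].iloc[0] == pytest.approx(
            model.cg_te - model.het_delta("h1")
        )

    def test_spike_in_unmethylated_everywhere(self, genome):
        for tissue in ("embryo", "endosperm"):
            t = methylome_truth(genome, MethModel(), tissue, "h1").sites
            spike = t[t["chrom"] == SPEC.spike_chrom]
            assert (spike[["p_maternal", "p_paternal"]] == 0).all().all()

    def test_embryo_cg_above_endosperm(self, genome):
        em = methylome_truth(genome, MethModel(), "embryo", "wt").sites
        en = methylome_truth(genome, MethModel(), "endosperm", "wt").sites
        cg = (em["context"] == "CG") & (em["chrom"] != SPEC.spike_chrom)
        pooled_em = (0.5 * em["p_maternal"] + 0.5 * em["p_paternal"])[cg].mean()
        pooled_en = (2 / 3 * en["p_maternal"] + 1 / 3 * en["p_paternal"])[cg].mean()
        assert pooled_em > pooled_en

    def test_planted_truth_wt_excludes_heterochromatin(self, genome):
        planted = planted_dmr_truth(genome, MethModel(), "wt")
        eu = planted[planted["compartment"] == "eu"]
        het = planted[planted["compartment"] == "het"]
        assert eu["expected_dmr"].all()
        assert not het["expected_dmr"].any()
        assert planted_dmr_truth(genome, MethModel(), "h1")["expected_dmr"].all()


class TestSampleCounts:
    def _tiny_truth(self, p, tissue="embryo"):
        sites = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(1, 401),
                "strand": "+",
                "context": "CG",
                "p_maternal": p,
                "p_paternal": p,
            }
        )
        return TruthTable(tissue=tissue, genotype="wt", sites=sites)

    def test_fully_methylated_no_nonconversion(self):
        counts = sample_counts(self._tiny_truth(1.0), nonconversion=0.0, seed=0)
        pooled = counts["pooled"]
        assert (pooled["unmeth"] == 0).all()
        assert pooled["meth"].sum() > 0

    def test_determinism(self):
        a = sample_counts(self._tiny_truth(0.5), seed=9)
        b = sample_counts(self._tiny_truth(0.5), seed=9)
        for key in ("pooled", "maternal", "paternal"):
            pd.testing.assert_frame_equal(a[key], b[key])

    def test_endosperm_depth_mixes_two_to_one(self):
        counts = sample_counts(
            self._tiny_truth(0.5, tissue="endosperm"), mean_depth=60, seed=1
        )
        dm = (counts["maternal"]["meth"] + counts["maternal"]["unmeth"]).sum()
        dp = (counts["paternal"]["meth"] + counts["paternal"]["unmeth"]).sum()
        assert dm / dp == pytest.approx(2.0, rel=0.1)

    def test_nonconversion_inflates_unmethylated_sites(self):
        counts = sample_counts(
            self._tiny_truth(0.0), mean_depth=50, nonconversion=0.05, seed=2
        )
        pooled = counts["pooled"]
        rate = pooled["meth"].sum() / (pooled["meth"] + pooled["unmeth"]).sum()
        assert rate == pytest.approx(0.05, abs=0.01)

    def test_invalid_nonconversion_rejected(self):
        with pytest.raises(ValueError):
            sample_counts(self._tiny_truth(0.5), nonconversion=1.5)


class TestExpression:
    def test_determinism_and_classes(self, genome):
        ispec = ImprintSpec(n_meg=6, n_peg=4, mean_reads=500)
        a = expression_truth_and_counts(genome, ispec, seed=5)
        b = expression_truth_and_counts(genome, ispec, seed=5)
        for g in ("wt", "h1"):
            pd.testing.assert_frame_equal(a["counts"][g], b["counts"][g])
        assert len(a["megs"]) == 6 and len(a["pegs"]) == 4

    def test_pure_meg_has_no_paternal_reads(self, genome):
        ispec = ImprintSpec(n_meg=5, n_peg=3, meg_pi=1.0, mean_reads=300)
        res = expression_truth_and_counts(genome, ispec, seed=6)
        counts = res["counts"]["wt"].set_index("gene")
        assert (counts.loc[res["megs"], "paternal"] == 0).all()

    def test_biallelic_converges_to_two_thirds(self, genome):
        ispec = ImprintSpec(n_meg=0, n_peg=0, mean_reads=4_000)
        res = expression_truth_and_counts(genome, ispec, seed=7)
        counts = res["counts"]["wt"]
        prop = counts["maternal"].sum() / (counts["maternal"] + counts["paternal"]).sum()
        assert prop == pytest.approx(2 / 3, abs=0.01)

    def test_too_many_imprinted_genes_rejected(self, genome):
        with pytest.raises(ValueError):
            expression_truth_and_counts(genome, ImprintSpec(n_meg=1000, n_peg=0), seed=0)
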