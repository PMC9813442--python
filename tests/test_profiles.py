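"""Density curves, metaplots, chromosome distribution, state composition."""

import numpy as np
import pandas as pd
import pytest

from methylseed.dmr import Dmr
from methylseed.io import FeatureRecord, StateInterval
from methylseed.profiles import (
    chromosome_distribution,
    dmr_feature_frequency,
    kde_curve,
    methylation_metaplot,
    partition_by_regions,
    state_composition,
    window_differences,
)


def _windows(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "meth_sum", "total_sum"])
    df["end"] = df["start"] + 50
    df["n_informative"] = 5
    df["frac"] = df["meth_sum"] / df["total_sum"]
    return df[["chrom", "start", "end", "meth_sum", "total_sum", "n_informative", "frac"]]


class TestWindowDifferences:
    def test_low_methylation_excluded(self):
        # both fractions 0.2: max below the 0.5 floor
        wa = _windows([("chr1", 0, 4, 20)])
        wb = _windows([("chr1", 0, 4, 20)])
        assert len(window_differences(wa, wb)) == 0

    def test_high_methylation_included(self):
        wa = _windows([("chr1", 0, 11, 12)])
        wb = _windows([("chr1", 0, 11, 12)])
        d = window_differences(wa, wb)
        assert len(d) == 1 and d[0] == pytest.approx(0.0)

    def test_under_informative_excluded(self):
        wa = _windows([("chr1", 0, 5, 5)])     # 5 calls only
        wb = _windows([("chr1", 0, 18, 20)])
        assert len(window_differences(wa, wb)) == 0

    def test_sign_convention_first_minus_second(self):
        wa = _windows([("chr1", 0, 18, 20)])
        wb = _windows([("chr1", 0, 2, 20)])
        assert window_differences(wa, wb)[0] == pytest.approx(0.8)


class TestKdeCurve:
    def test_integral_is_one(self):
        rng = np.random.default_rng(0)
        curve = kde_curve(rng.normal(0, 0.2, size=500))
        assert np.trapezoid(curve.density, curve.grid) == pytest.approx(1.0, abs=1e-3)

    def test_symmetric_input_symmetric_curve(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.3, 0.1, size=250)
        vals = np.concatenate([x, -x])
        curve = kde_curve(vals)
        assert np.max(np.abs(curve.density - curve.density[::-1])) < 1e-8

    def test_jittered_point_mass_mode_near_zero(self):
        rng = np.random.default_rng(2)
        curve = kde_curve(rng.normal(0, 0.01, size=400))
        mode = curve.grid[np.argmax(curve.density)]
        assert abs(mode) <= 0.01

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            kde_curve([0.5])


class TestPartition:
    def test_empty_regions_all_outside(self, pooled_windows):
        w = pooled_windows[("embryo", "wt")]
        inside, outside = partition_by_regions(w, [])
        assert len(inside) == 0 and len(outside) == len(w)

    def test_whole_genome_region_all_inside(self, pooled_windows):
        w = pooled_windows[("embryo", "wt")]
        regions = [(c, 0, 10**9) for c in w["chrom"].unique()]
        inside, outside = partition_by_regions(w, regions)
        assert len(inside) == len(w) and len(outside) == 0

    def test_one_bp_overlap_is_inside(self):
        w = _windows([("chr1", 50, 10, 20)])
        inside, outside = partition_by_regions(w, [("chr1", 99, 200)])
        assert len(inside) == 1 and len(outside) == 0

    def test_conservation(self, pooled_windows, scen):
        w = pooled_windows[("endosperm", "wt")]
        regions = [
            (r.chrom, r.start, r.end) for r in scen["genome"].dme_targets.itertuples()
        ]
        inside, outside = partition_by_regions(w, regions)
        assert len(inside) + len(outside) == len(w)
        key = lambda df: set(zip(df["chrom"], df["start"]))
        assert key(inside) | key(outside) == key(w)
        assert not (key(inside) & key(outside))


class TestMetaplot:
    def _uniform_windows(self, frac=0.8, length=20_000):
        rows = [("chr1", s, int(frac * 100), 100) for s in range(0, length, 50)]
        return _windows(rows)

    def test_uniform_methylome_flat_profile(self):
        genes = [FeatureRecord("chr1", 8_000, 12_000, "+", "gene", "g1")]
        prof = methylation_metaplot(self._uniform_windows(), genes, flank=3000)
        assert np.nanmax(np.abs(prof.values - 0.8)) < 1e-12

    def test_minus_strand_equals_reflected_plus(self):
        rng = np.random.default_rng(3)
        rows = [("chr1", s, int(rng.integers(0, 101)), 100) for s in range(0, 20_000, 50)]
        w = _windows(rows)
        minus = [FeatureRecord("chr1", 8_000, 12_000, "-", "gene", "g1")]
        plus = [FeatureRecord("chr1", 8_000, 12_000, "+", "gene", "g1")]
        p5_minus = methylation_metaplot(w, minus, anchor="5prime")
        p3_plus = methylation_metaplot(w, plus, anchor="3prime")
        # the minus-strand 5' profile reads the plus-strand 3' window sequence
        # in reverse
        np.testing.assert_allclose(
            p5_minus.values, p3_plus.values[::-1], equal_nan=True
        )

    def test_no_features_rejected(self):
        with pytest.raises(ValueError):
            methylation_metaplot(self._uniform_windows(), [], flank=3000)

    def test_translation_invariance(self):
        rng = np.random.default_rng(4)
        rows = [("chr1", s, int(rng.integers(0, 101)), 100) for s in range(0, 20_000, 50)]
        w = _windows(rows)
        genes = [FeatureRecord("chr1", 8_000, 12_000, "+", "gene", "g1")]
        shift = 5_000
        w2 = w.copy()
        w2["start"] += shift
        w2["end"] += shift
        genes2 = [FeatureRecord("chr1", 8_000 + shift, 12_000 + shift, "+", "gene", "g1")]
        np.testing.assert_allclose(
            methylation_metaplot(w, genes).values,
            methylation_metaplot(w2, genes2).values,
            equal_nan=True,
        )


class TestDmrFeatureFrequency:
    def _genes(self, n=10):
        return [
            FeatureRecord("chr1", 10_000 + 5_000 * i, 12_000 + 5_000 * i, "+", "gene", f"g{i}")
            for i in range(n)
        ]

    def test_no_dmrs_all_zero(self):
        prof = dmr_feature_frequency([], self._genes(), flank=3000)
        assert np.all(prof.values == 0)

    def test_tss_bin_of_every_feature(self):
        genes = self._genes()
        dmrs = [Dmr("chr1", g.start, g.start + 100, 2, 0.5, 1e-9, "A-hyper") for g in genes]
        prof = dmr_feature_frequency(dmrs, genes, anchor="5prime", flank=3000)
        tss_bin = np.where(prof.bin_starts == 0)[0][0]
        assert prof.values[tss_bin] == pytest.approx(1.0)

    def test_single_feature_fraction(self):
        genes = self._genes(10)
        dmrs = [Dmr("chr1", genes[0].start, genes[0].start + 100, 2, 0.5, 1e-9, "A-hyper")]
        prof = dmr_feature_frequency(dmrs, genes, anchor="5prime", flank=3000)
        tss_bin = np.where(prof.bin_starts == 0)[0][0]
        assert prof.values[tss_bin] == pytest.approx(0.1)


class TestChromosomeDistribution:
    def test_empty_set_zero_counts(self):
        dist = chromosome_distribution([], {"chr1": 300_000})
        assert dist["count"].sum() == 0 and len(dist) == 3

    def test_all_in_one_bin(self):
        dmrs = [Dmr("chr1", 150_000, 150_200, 2, 0.5, 1e-9, "A-hyper") for _ in range(5)]
        dist = chromosome_distribution(dmrs, {"chr1": 300_000})
        assert dist.loc[dist["start"] == 100_000, "count"].item() == 5

    def test_midpoint_on_boundary_floor_rule(self):
        # midpoint exactly 100000 goes to the bin starting at 100000
        dmrs = [Dmr("chr1", 99_950, 100_050, 2, 0.5, 1e-9, "A-hyper")]
        dist = chromosome_distribution(dmrs, {"chr1": 300_000})
        assert dist.loc[dist["start"] == 100_000, "count"].item() == 1

    def test_centromere_annotation(self):
        dist = chromosome_distribution(
            [], {"chr1": 300_000}, centromeres=[("chr1", 120_000, 180_000)]
        )
        assert list(dist["centromeric"]) == [False, True, False]


class TestStateComposition:
    def _states(self):
        # full 200-kb coverage: half state 1, half state 8
        return [StateInterval("chr1", 0, 100_000, 1), StateInterval("chr1", 100_000, 200_000, 8)]

    def test_pure_heterochromatin(self):
        dmrs = [Dmr("chr1", 150_000, 150_500, 3, 0.5, 1e-9, "A-hyper")]
        res = state_composition(dmrs, self._states())
        assert res["percent"]["state_8"] == pytest.approx(100.0)

    def test_percentages_sum_to_100_under_full_coverage(self, dmr_sets, scen):
        res = state_composition(dmr_sets["h1"], scen["genome"].states)
        assert sum(res["percent"].values()) == pytest.approx(100.0, abs=1e-9)
        assert "unannotated" not in res["percent"]

    def test_even_split(self):
        rng = np.random.default_rng(5)
        starts = rng.integers(0, 199_500, size=400)
        dmrs = [Dmr("chr1", int(s), int(s) + 200, 2, 0.5, 1e-9, "A-hyper") for s in starts]
        res = state_composition(dmrs, self._states())
        assert res["percent"]["state_1"] == pytest.approx(50.0, abs=6.0)

    def test_empty_dmr_set_rejected(self):
        with pytest.raises(ValueError):
            state_composition([], self._states())

    def test_directional_heterochromatin_enrichment(self, dmr_sets, scen):
        """The h1 DMR set is more heterochromatic than the wild-type set."""
        cats = {"euchromatin": list(range(1, 8)), "heterochromatin": [8, 9]}
        het = {
            g: state_composition(dmr_sets[g], scen["genome"].states, cats)["percent"][
                "heterochromatin"
            ]
            for g in ("wt", "h1")
        }
        assert het["h1"] > het["wt"]
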