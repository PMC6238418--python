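"""Travelling ratio, antisense quantification, expression classes, row filter."""

import numpy as np
import pandas as pd
import pytest

from promarch.annotation import GeneModel
from promarch.coverage import TagTrack, normalize_rpgc
from promarch.metrics import (
    antisense_density,
    antisense_table,
    class_contrast,
    classify_genes,
    expression_summary,
    kmeans_spike_filter,
    log2_fold_change,
    region_density_matrix,
    spike_filter,
    travelling_ratio,
    upstream_occupancy,
)


def const_tracks(length=30000, plus=1.0, minus=1.0):
    return (
        TagTrack({"c": np.full(length, plus)}, strand="+"),
        TagTrack({"c": np.full(length, minus)}, strand="-"),
    )


GENE = GeneModel("g", "c", "+", 10000, 20000)


class TestTravellingRatio:
    def test_uniform_density_gives_one(self):
        plus, minus = const_tracks(plus=2.0)
        res = travelling_ratio(plus, minus, GENE)
        assert res.usable and np.isclose(res.tr, 1.0, atol=1e-12)

    def test_window_arithmetic_example(self):
        # 560 tags over the 280-bp proximal window, 250 over a 500-bp body
        g = GeneModel("g", "c", "+", 10000, 11000)
        arr = np.zeros(30000)
        arr[9970:10250] = 2.0  # 560 / 280 = 2.0 tags/bp
        arr[10300:10800] = 0.5  # 250 / 500 = 0.5 tags/bp
        res = travelling_ratio(TagTrack({"c": arr}), TagTrack({"c": np.zeros(30000)}), g)
        assert np.isclose(res.proximal_density, 2.0)
        assert np.isclose(res.body_density, 0.5)
        assert np.isclose(res.tr, 4.0)

    def test_minus_strand_reads_minus_track(self):
        g = GeneModel("g", "c", "-", 20000, 10000)
        plus, minus = const_tracks(plus=9.0, minus=3.0)
        res = travelling_ratio(plus, minus, g)
        assert np.isclose(res.proximal_density, 3.0)

    def test_zero_body_unusable(self):
        g = GeneModel("g", "c", "+", 10000, 11000)
        arr = np.zeros(30000)
        arr[9970:10250] = 1.0
        res = travelling_ratio(TagTrack({"c": arr}), TagTrack({"c": np.zeros(30000)}), g)
        assert not res.usable and np.isnan(res.tr)

    def test_short_gene_unusable(self):
        g = GeneModel("g", "c", "+", 10000, 10400)
        res = travelling_ratio(*const_tracks(), g)
        assert not res.usable

    def test_invariant_to_rpgc_scaling(self):
        rng = np.random.default_rng(21)
        arr = rng.poisson(3, size=30000).astype(float)
        raw_p = TagTrack({"c": arr})
        raw_m = TagTrack({"c": np.zeros(30000)})
        norm_p = normalize_rpgc(TagTrack({"c": arr.copy()}), 30000)
        r_raw = travelling_ratio(raw_p, raw_m, GENE)
        r_norm = travelling_ratio(norm_p, raw_m, GENE)
        assert np.isclose(r_raw.tr, r_norm.tr, rtol=1e-12)


class TestAntisense:
    def test_density_example(self):
        # + strand gene with 10 - strand tags in [tss-1000, tss)
        plus = TagTrack({"c": np.zeros(30000)}, strand="+")
        minus = TagTrack({"c": np.zeros(30000)}, strand="-")
        minus.data["c"][9100:9110] = 1.0
        anti, sense = antisense_density(plus, minus, GENE)
        assert np.isclose(anti, 0.01)
        assert sense == 0.0

    def test_equal_conditions_zero_log2fc(self):
        assert log2_fold_change(0.5, 0.5, 1e-4) == 0.0

    def test_antisymmetric_under_condition_swap(self):
        assert np.isclose(
            log2_fold_change(0.8, 0.2, 1e-4), -log2_fold_change(0.2, 0.8, 1e-4)
        )

    def test_table_orientation_minus_gene(self):
        g = GeneModel("g", "c", "-", 10000, 5000)
        plus = TagTrack({"c": np.zeros(30000)}, strand="+")
        minus = TagTrack({"c": np.zeros(30000)}, strand="-")
        plus.data["c"][10000:11000] = 2.0  # antisense side for a - gene
        tab = antisense_table({"control": (plus, minus), "kd": (plus, minus)}, [g])
        assert np.isclose(tab.loc["g", "antisense_density_control"], 2.0)
        assert tab.loc["g", "log2fc_antisense"] == 0.0


class TestUpstreamOccupancy:
    def test_oriented_window(self):
        g = GeneModel("g", "c", "-", 10000, 5000)
        track = TagTrack({"c": np.zeros(30000)})
        track.data["c"][10030:10450] = 1.0  # upstream of the - strand TSS
        assert np.isclose(upstream_occupancy(track, g), 1.0)
        gp = GeneModel("p", "c", "+", 10000, 20000)
        assert upstream_occupancy(track, gp) == 0.0


class TestExpressionSummary:
    def test_cpm_rpkm_example(self):
        counts = pd.Series({"a": 100, "rest": 999_900})
        lengths = pd.Series({"a": 1000, "rest": 1000})
        out = expression_summary(counts, lengths)
        assert np.isclose(out.loc["a", "cpm"], 100.0)
        assert np.isclose(out.loc["a", "rpkm"], 100.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(22)
        counts = pd.Series(rng.poisson(50, 40), index=[f"g{i}" for i in range(40)])
        lengths = pd.Series(rng.integers(500, 5000, 40), index=counts.index)
        a = expression_summary(counts, lengths)
        b = expression_summary(counts * 2, lengths)
        pd.testing.assert_frame_equal(a, b)

    def test_equal_rpkm_ties_stable_quartiles(self):
        counts = pd.Series(10, index=[f"g{i}" for i in range(8)])
        lengths = pd.Series(1000, index=counts.index)
        out = expression_summary(counts, lengths)
        assert out["quantile_class"].value_counts().eq(2).all()

    def test_quartiles_equal_sized(self):
        rng = np.random.default_rng(23)
        counts = pd.Series(rng.poisson(100, 101), index=[f"g{i}" for i in range(101)])
        lengths = pd.Series(rng.integers(500, 5000, 101), index=counts.index)
        sizes = expression_summary(counts, lengths)["quantile_class"].value_counts()
        assert sizes.max() - sizes.min() <= 1


class TestRegionDensityMatrix:
    def regions(self, n=100):
        from promarch.annotation import Region

        return [
            Region("c", 100 + 200 * i, 200 + 200 * i, ".", "gene_body")
            for i in range(n)
        ]

    def test_self_correlation_one(self):
        rng = np.random.default_rng(24)
        arr = rng.random(30000)
        tracks = {"a": TagTrack({"c": arr}), "b": TagTrack({"c": arr.copy()})}
        _, corr = region_density_matrix(tracks, self.regions())
        assert np.isclose(corr.loc["a", "b"], 1.0)

    def test_negation_minus_one(self):
        rng = np.random.default_rng(25)
        arr = rng.random(30000)
        tracks = {"a": TagTrack({"c": arr}), "b": TagTrack({"c": -arr})}
        _, corr = region_density_matrix(tracks, self.regions())
        assert np.isclose(corr.loc["a", "b"], -1.0)

    def test_independent_tracks_near_zero(self):
        rng = np.random.default_rng(26)
        tracks = {
            "a": TagTrack({"c": rng.random(300000)}),
            "b": TagTrack({"c": rng.random(300000)}),
        }
        from promarch.annotation import Region

        regions = [
            Region("c", 200 * i, 200 * i + 150, ".", "gene_body") for i in range(1000)
        ]
        _, corr = region_density_matrix(tracks, regions)
        assert abs(corr.loc["a", "b"]) < 0.1

    def test_zero_variance_column_missing(self):
        tracks = {
            "a": TagTrack({"c": np.ones(30000)}),
            "b": TagTrack({"c": np.random.default_rng(0).random(30000)}),
        }
        _, corr = region_density_matrix(tracks, self.regions())
        assert np.isnan(corr.loc["a", "b"])

    def test_needs_three_regions(self):
        with pytest.raises(ValueError):
            region_density_matrix({"a": TagTrack({"c": np.ones(100)})}, self.regions(2))


class TestClassify:
    def de(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "logfc", "padj"]
        ).set_index("gene_id", drop=False)

    def test_threshold_rules(self):
        de = self.de(
            [
                ("a", 2.0, 0.001),   # up
                ("b", 2.0, 0.02),    # other: fails both rules
                ("c", 0.1, 0.5),     # unchanged
                ("d", -1.5, 0.005),  # down
                ("e", 0.5, 0.001),   # other: significant but small effect
            ]
        )
        out = classify_genes(de, ["a", "c"])
        assert out.loc["a", "de_class"] == "up"
        assert out.loc["b", "de_class"] == "other"
        assert out.loc["c", "de_class"] == "unchanged"
        assert out.loc["d", "de_class"] == "down"
        assert out.loc["e", "de_class"] == "other"
        assert out.loc["a", "label"] == "up:bound"
        assert out.loc["d", "label"] == "down:unbound"

    def test_classes_disjoint_and_cover(self):
        rng = np.random.default_rng(27)
        de = self.de(
            [
                (f"g{i}", rng.normal(0, 2), rng.random())
                for i in range(200)
            ]
        )
        out = classify_genes(de, [])
        assert out["de_class"].isin(["up", "down", "unchanged", "other"]).all()
        assert len(out) == len(de)

    def test_missing_bound_ids_warn_and_drop(self, caplog):
        de = self.de([("a", 2.0, 0.001)])
        with caplog.at_level("WARNING"):
            out = classify_genes(de, ["a", "ghost"])
        assert "absent" in caplog.text
        assert list(out.index) == ["a"]


class TestSpikeFilter:
    def test_concentrated_row_removed(self):
        row = np.zeros(2000)
        row[500:550] = 5.0
        assert not spike_filter(row[None, :])[0]

    def test_uniform_row_kept(self):
        row = np.ones(2000)
        assert spike_filter(row[None, :])[0]

    def test_zero_row_kept(self):
        assert spike_filter(np.zeros((1, 2000)))[0]

    def test_planted_spikes_removed_exactly(self):
        """Simulator snoRNA-like spikes are exactly the removed rows."""
        from promarch.coverage import anchor_matrix, build_stranded_tracks
        from promarch.simdata import TruthConfig, simulate_genome, simulate_netseq

        # narrow expression spread and tall spikes so the subwindow rule is
        # decisive for every row (spikes dominate; no gene is pause-dominated)
        cfg = TruthConfig(
            genes_per_class=10, seed=9, spike_genes=5, spike_tags=20000.0,
            expr_sigma=0.25, body_noise_sigma=0.1,
        )
        genome, genes, truth = simulate_genome(cfg)
        sizes = {c: len(s) for c, s in genome.items()}
        tags = simulate_netseq(genes, truth, "control", cfg)
        plus, minus = build_stranded_tracks(tags, sizes)
        mat, used = anchor_matrix(
            plus, [g.tss_anchor() for g in genes], 2000, minus_track=minus
        )
        keep = spike_filter(mat)
        removed = {genes[used[i]].gene_id for i in np.flatnonzero(~keep)}
        assert removed == set(truth.loc[truth["spike"], "gene_id"])

    def test_kmeans_variant_removes_planted_spikes(self):
        rng = np.random.default_rng(28)
        mat = rng.poisson(2.0, size=(60, 2000)).astype(float)
        spiked = [3, 17, 42]
        for i in spiked:
            mat[i] = 0.0
            mat[i, 800:850] = 200.0
        keep = kmeans_spike_filter(mat, k=4, seed=0)
        assert set(np.flatnonzero(~keep)) == set(spiked)


class TestClassContrast:
    def test_detects_shift_in_bound_up_only(self):
        rng = np.random.default_rng(29)
        ids = [f"g{i}" for i in range(240)]
        classes = pd.DataFrame(
            {
                "gene_id": ids,
                "de_class": ["up"] * 80 + ["down"] * 80 + ["unchanged"] * 80,
                "bound": ([True] * 40 + [False] * 40) * 3,
            }
        ).set_index("gene_id", drop=False)
        values = pd.Series(rng.normal(0, 1, 240), index=ids)
        values.iloc[:40] += 2.0  # bound-up genes shifted
        tab = class_contrast(values, classes).set_index("de_class")
        assert tab.loc["up", "p"] < 1e-6
        assert tab.loc["down", "p"] > 0.01
        assert tab.loc["unchanged", "p"] > 0.01
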