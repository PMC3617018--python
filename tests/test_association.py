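"""Downstream statistics: correlations, chromosome distribution, GC, density,
expression divergence, Fisher enrichment and the alignment-overlap control."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromdiverge import association as assoc
from chromdiverge import simulate as sim
from chromdiverge.association import (
    CLOSED_A,
    NONDIVERGENT,
    OPEN_A,
    ClassLabel,
    assign_genes_to_regions,
    chrom_distribution_test,
    class_enrichment_fisher,
    correlation_matrix,
    density_compare,
    expression_divergence,
    gc_by_class,
    overlap_qc,
)
from chromdiverge.layout import InvalidParameterError

from conftest import make_matrix


def labels_from(polarity, mean_A=None, mean_B=None):
    n = len(polarity)
    ids = [f"R{i:04d}" for i in range(n)]
    cls = pd.Series(polarity).map(
        {0: NONDIVERGENT, 1: OPEN_A, -1: CLOSED_A}
    )
    if mean_A is None:
        absolute = [p != 0 for p in polarity]
    else:
        absolute = [
            (p == 1 and a > 0 and b < 0) or (p == -1 and a < 0 and b > 0)
            for p, a, b in zip(polarity, mean_A, mean_B)
        ]
    return ClassLabel(
        table=pd.DataFrame({"region_id": ids, "cls": cls, "absolute_flag": absolute})
    )


class TestCorrelationMatrix:
    def test_diagonal_unity_and_symmetry(self):
        rng = np.random.default_rng(0)
        cols = {f"c{i}": rng.normal(size=100) for i in range(4)}
        m = make_matrix(cols, {k: "A" for k in cols})
        rho, order = correlation_matrix(m)
        assert np.allclose(np.diag(rho), 1.0)
        assert np.allclose(rho, rho.T)
        assert sorted(order) == sorted(cols)

    def test_reversed_ranks_minus_one(self):
        m = make_matrix({"a": [1, 2, 3, 4], "b": [9, 7, 5, 3]}, {"a": "A", "b": "B"})
        rho, _ = correlation_matrix(m)
        assert rho.loc["a", "b"] == pytest.approx(-1.0)

    def test_synthetic_six_datasets_positive_band(self):
        layout = sim.gen_layout(1, 5000 * 100_000, seed=0)
        track = sim.gen_compartments(layout, 8, 0.5, seed=0)
        vals, _ = sim.gen_structure(
            track, [f"d{i}" for i in range(6)], 1.0, -1.0, 0.2, 0.4, seed=1
        )
        m = make_matrix(
            {f"d{i}": vals[f"d{i}"].to_numpy() for i in range(6)},
            {f"d{i}": "A" for i in range(6)},
        )
        rho, _ = correlation_matrix(m)
        off = rho.to_numpy()[~np.eye(6, dtype=bool)]
        assert (off > 0.3).all() and (off <= 1.0).all()

    def test_constant_column_flagged(self):
        m = make_matrix({"a": [1, 1, 1], "b": [1, 2, 3]}, {"a": "A", "b": "B"})
        with pytest.raises(InvalidParameterError, match="a"):
            correlation_matrix(m)


class TestChromDistribution:
    def test_proportional_counts_null(self):
        out = chrom_distribution_test(
            pd.Series({"chr1": 20, "chr2": 10}), pd.Series({"chr1": 200, "chr2": 100})
        )
        assert out.attrs["statistic"] == pytest.approx(0.0)
        assert not out["flagged"].any()

    def test_hand_worked_example(self):
        # bins (100,100), calls (30,10): expected (20,20), chi2 = 5+5 = 10,
        # residuals +/- 2.236
        out = chrom_distribution_test(
            pd.Series({"chr1": 30, "chr2": 10}), pd.Series({"chr1": 100, "chr2": 100})
        )
        assert out.attrs["statistic"] == pytest.approx(10.0)
        assert np.allclose(np.abs(out["residual"]), np.sqrt(5), atol=1e-9)
        assert out["flagged"].all()

    def test_residual_sum_of_squares_identity(self):
        rng = np.random.default_rng(1)
        bins = pd.Series(rng.integers(50, 200, 8), index=[f"chr{i}" for i in range(8)])
        calls = pd.Series(rng.integers(0, 30, 8), index=bins.index)
        out = chrom_distribution_test(calls, bins)
        assert out.attrs["statistic"] == pytest.approx((out["residual"] ** 2).sum())

    def test_dense_chromosome_flagged(self):
        flagged = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            bins = pd.Series(200, index=[f"chr{i}" for i in range(8)])
            rates = np.full(8, 10.0)
            rates[0] = 20.0
            calls = pd.Series(rng.poisson(rates), index=bins.index)
            out = chrom_distribution_test(calls, bins)
            flagged += bool(out.loc[out["chrom"] == "chr0", "flagged"].iloc[0]
                            and out.loc[out["chrom"] == "chr0", "residual"].iloc[0] > 0)
        assert flagged >= 8


class TestGcByClass:
    def test_collinear_regression_exact(self):
        n = 30
        structure = pd.Series(np.linspace(-1, 1, n),
                              index=[f"R{i:04d}" for i in range(n)])
        gc = 0.35 + 0.05 * structure
        labels = labels_from([0] * n)
        out = gc_by_class(gc, labels, structure)
        reg = out["regression"][NONDIVERGENT]
        assert reg["slope"] == pytest.approx(0.05)
        assert reg["intercept"] == pytest.approx(0.35)

    def test_human_style_inversion_geometry(self):
        # open-divergent bins GC-poor: the divergent-open regression line
        # sits below the nondivergent line across the shared range
        rng = np.random.default_rng(2)
        n = 3000
        state = rng.integers(0, 2, n)
        structure = pd.Series(
            np.where(state == 1, 1.0, -1.0) + rng.normal(0, 0.2, n),
            index=[f"R{i:04d}" for i in range(n)],
        )
        polarity = np.zeros(n, dtype=int)
        open_idx = np.flatnonzero(state == 1)
        polarity[rng.choice(open_idx, 150, replace=False)] = 1
        gc = 0.35 + 0.03 * structure + rng.normal(0, 0.01, n)
        gc[polarity == 1] -= 0.05  # the inversion: divergent-open is GC-poor
        labels = labels_from(polarity)
        out = gc_by_class(pd.Series(gc, index=structure.index), labels, structure)
        nd = out["regression"][NONDIVERGENT]
        op = out["regression"][OPEN_A]
        x = 1.0  # common open-side structure value
        assert op["intercept"] + op["slope"] * x < nd["intercept"] + nd["slope"] * x
        assert out["mw_p"][OPEN_A] < 0.01

    def test_null_gc_no_shift(self):
        rng = np.random.default_rng(3)
        n = 500
        structure = pd.Series(rng.normal(size=n), index=[f"R{i:04d}" for i in range(n)])
        gc = pd.Series(rng.normal(0.37, 0.02, n), index=structure.index)
        polarity = np.zeros(n, dtype=int)
        polarity[:30] = 1
        out = gc_by_class(gc, labels_from(polarity), structure)
        assert out["mw_p"][OPEN_A] > 0.001  # no systematic shift


def region_coords(n):
    return pd.DataFrame(
        {
            "region_id": [f"R{i:04d}" for i in range(n)],
            "chrom_A": "chr1",
            "start_A": np.arange(n) * 100_000,
            "end_A": (np.arange(n) + 1) * 100_000,
            "chrom_B": "chr1",
            "start_B": np.arange(n) * 100_000,
            "end_B": (np.arange(n) + 1) * 100_000,
            "overlap_A": 0.8,
            "overlap_B": 0.75,
        }
    )


class TestDensityCompare:
    def test_no_genes_degenerate(self):
        coords = region_coords(10)
        ann = pd.DataFrame(columns=["chrom", "start", "end", "gene_class"])
        out = density_compare(ann, labels_from([0] * 9 + [1]), coords)
        assert (out["density_per_mb"] == 0).all()
        assert out["mw_p_vs_nondivergent"].isna().all()

    def test_equal_density_rarely_significant(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 400
            coords = region_coords(n)
            counts = rng.poisson(2.0, n)
            ann = pd.DataFrame(
                {
                    "chrom": "chr1",
                    "start": np.repeat(np.arange(n) * 100_000 + 10, counts),
                    "end": np.repeat(np.arange(n) * 100_000 + 500, counts),
                    "gene_class": "protein_coding",
                }
            )
            polarity = np.zeros(n, dtype=int)
            polarity[rng.choice(n, 40, replace=False)] = 1
            out = density_compare(ann, labels_from(polarity), coords)
            p = out.loc[out["region_class"] == OPEN_A, "mw_p_vs_nondivergent"].iloc[0]
            hits += p < 0.05
        assert hits <= 2

    def test_implanted_lincrna_contrast_recovered(self):
        rng = np.random.default_rng(5)
        n = 2000
        coords = region_coords(n)
        polarity = np.zeros(n, dtype=int)
        polarity[rng.choice(n, 200, replace=False)] = -1
        rates = np.where(polarity != 0, 0.4, 0.1)
        counts = rng.poisson(rates)
        ann = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.repeat(np.arange(n) * 100_000 + 10, counts),
                "end": np.repeat(np.arange(n) * 100_000 + 900, counts),
                "gene_class": "lincRNA",
            }
        )
        out = density_compare(ann, labels_from(polarity), coords)
        row = out[(out["gene_class"] == "lincRNA") & (out["region_class"] == CLOSED_A)]
        nd = out[(out["gene_class"] == "lincRNA") & (out["region_class"] == NONDIVERGENT)]
        assert row["density_per_mb"].iloc[0] > nd["density_per_mb"].iloc[0]
        assert row["mw_p_vs_nondivergent"].iloc[0] < 0.001
        # both unit conventions emitted and consistent
        assert row["density_per_mb"].iloc[0] == pytest.approx(
            10 * row["density_per_100kb"].iloc[0]
        )


def expr_frame(region_ids, log2fc, rng):
    rpkm_b = rng.lognormal(1, 0.5, len(region_ids))
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(len(region_ids))],
            "region_id": region_ids,
            "rpkm_A": rpkm_b * np.power(2.0, log2fc),
            "rpkm_B": rpkm_b,
        }
    )


class TestExpressionDivergence:
    def test_sign_convention(self):
        labels = labels_from([1, -1, 0, 0])
        expr = pd.DataFrame(
            {
                "gene_id": ["g1", "g2"],
                "region_id": ["R0000", "R0001"],
                "rpkm_A": [8.0, 2.0],
                "rpkm_B": [2.0, 8.0],
            }
        )
        out = expression_divergence(expr, labels)
        med = out.set_index("region_class")["median_log2fc"]
        assert med[OPEN_A] == pytest.approx(2.0, abs=0.01)
        assert med[CLOSED_A] == pytest.approx(-2.0, abs=0.01)

    def test_implanted_uniform_effect_recovered(self):
        rng = np.random.default_rng(7)
        n = 3000
        polarity = np.zeros(n, dtype=int)
        polarity[:200] = 1
        labels = labels_from(polarity)
        log2fc = np.where(polarity == 1, 1.0, 0.0) + rng.normal(0, 1.0, n)
        expr = expr_frame([f"R{i:04d}" for i in range(n)], log2fc, rng)
        rel = expression_divergence(expr, labels, mode="relative")
        med = rel.set_index("region_class")["median_log2fc"]
        assert med[OPEN_A] - med[NONDIVERGENT] == pytest.approx(1.0, abs=0.3)
        assert rel.set_index("region_class")["p_vs_nondivergent"][OPEN_A] < 1e-6

    def test_absolute_mode_sharpens_contrast(self):
        rng = np.random.default_rng(8)
        n = 3000
        polarity = np.zeros(n, dtype=int)
        polarity[:200] = 1
        mean_A = np.where(polarity == 1, 0.3, 0.0) + rng.normal(0, 0.5, n)
        mean_B = np.where(polarity == 1, -0.3, 0.0) + rng.normal(0, 0.5, n)
        labels = labels_from(polarity, mean_A, mean_B)
        # genes whose conformations truly straddle the open/closed boundary
        # (the absolute subclass) carry the stronger expression shift
        absolute = labels.table["absolute_flag"].to_numpy()
        shift = np.where(polarity == 1, np.where(absolute, 2.5, 0.8), 0.0)
        log2fc = shift + rng.normal(0, 1.0, n)
        expr = expr_frame([f"R{i:04d}" for i in range(n)], log2fc, rng)
        rel = expression_divergence(expr, labels, mode="relative")
        ab = expression_divergence(expr, labels, mode="absolute")
        med_rel = rel.set_index("region_class")["median_log2fc"]
        med_ab = ab.set_index("region_class")["median_log2fc"]
        assert med_ab[OPEN_A] > med_rel[OPEN_A] > med_rel[NONDIVERGENT]
        n_ab = ab.set_index("region_class")["n_genes"][OPEN_A]
        n_rel = rel.set_index("region_class")["n_genes"][OPEN_A]
        assert 0 < n_ab < n_rel  # the subclass is a strict subset

    def test_null_effect_non_significant(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 500
            polarity = np.zeros(n, dtype=int)
            polarity[:50] = 1
            labels = labels_from(polarity)
            expr = expr_frame(
                [f"R{i:04d}" for i in range(n)], rng.normal(0, 1.5, n), rng
            )
            out = expression_divergence(expr, labels)
            p = out.set_index("region_class")["p_vs_nondivergent"][OPEN_A]
            hits += p < 0.05
        assert hits <= 2

    def test_empty_subclass_not_testable(self):
        labels = labels_from([1, 0, 0], mean_A=[-1, 0, 0], mean_B=[-1, 0, 0])
        rng = np.random.default_rng(0)
        expr = expr_frame(["R0000", "R0001", "R0002"], np.zeros(3), rng)
        out = expression_divergence(expr, labels, mode="absolute")
        row = out[out["region_class"] == OPEN_A].iloc[0]
        assert not row["testable"]

    def test_pseudocount_recorded(self):
        labels = labels_from([0])
        rng = np.random.default_rng(0)
        expr = expr_frame(["R0000"], [0.0], rng)
        out = expression_divergence(expr, labels, pseudocount=0.01)
        assert out.attrs["pseudocount"] == 0.01


class TestFisher:
    def test_cross_product_formula(self):
        flags = pd.Series([True] * 30 + [False] * 70)
        in_div = pd.Series([True] * 10 + [False] * 20 + [True] * 30 + [False] * 40)
        out = class_enrichment_fisher(flags, in_div)
        assert out["odds_ratio"] == pytest.approx((10 * 40) / (20 * 30))

    def test_independent_flags_near_unity(self):
        ors = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            flags = pd.Series(rng.random(4000) < 0.3)
            in_div = pd.Series(rng.random(4000) < 0.1)
            ors.append(class_enrichment_fisher(flags, in_div)["odds_ratio"])
        assert abs(np.mean(ors) - 1.0) < 0.15

    def test_generator_odds_ratio_recovered(self):
        rng = np.random.default_rng(3)
        in_div = pd.Series(rng.random(30_000) < 0.1)
        flags = pd.Series(
            sim.gen_regulatory_flags(in_div.to_numpy(), 2.0, 0.2, seed=4)
        )
        out = class_enrichment_fisher(flags, in_div)
        assert 1.7 < out["odds_ratio"] < 2.3
        assert out["p_value"] < 1e-6

    def test_zero_margin_haldane(self):
        flags = pd.Series([True, True, False, False])
        in_div = pd.Series([True, True, True, True])
        out = class_enrichment_fisher(flags, in_div)
        assert np.isnan(out["odds_ratio"]) or np.isinf(out["odds_ratio"])
        assert np.isfinite(out["odds_ratio_haldane"])


class TestOverlapQC:
    def test_identical_distributions_uniform_p(self):
        n = 400
        coords = region_coords(n)
        rng = np.random.default_rng(1)
        coords["overlap_A"] = rng.uniform(0.6, 1.0, n)
        coords["overlap_B"] = rng.uniform(0.6, 1.0, n)
        polarity = np.zeros(n, dtype=int)
        polarity[rng.choice(n, 40, replace=False)] = 1
        out = overlap_qc(coords, labels_from(polarity))
        assert set(out["side"]) == {"overlap_A", "overlap_B"}
        assert (out["mw_p"] > 0.001).all()

    def test_implanted_overlap_bias_detected(self):
        detected = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 600
            coords = region_coords(n)
            polarity = np.zeros(n, dtype=int)
            div = rng.choice(n, 60, replace=False)
            polarity[div] = 1
            ov = rng.uniform(0.7, 1.0, n)
            ov[div] -= 0.15  # divergent regions align worse by construction
            coords["overlap_A"] = ov
            out = overlap_qc(coords, labels_from(polarity))
            p = out.loc[out["side"] == "overlap_A", "mw_p"].iloc[0]
            detected += p < 0.01
        assert detected >= 4


def test_assign_genes_by_start_coordinate():
    coords = region_coords(5)
    genes = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [150_000, 499_999, 100],
            "end": [160_000, 600_000, 200],
        }
    )
    got = assign_genes_to_regions(genes, coords)
    assert got.tolist()[:2] == ["R0001", "R0004"]
    assert pd.isna(got.iloc[2])
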