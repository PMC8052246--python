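import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from placsplice.io import GenotypeMatrix
from placsplice.sqtl import (
    additive_trend,
    bh_fdr,
    classify_cis_trans,
    filter_genotype_classes,
    fit_genotypic_model,
    map_sqtl,
)

from conftest import make_annotation, make_sheet


def geno(rows: dict[str, list[float]], chrom="1", pos0=1000) -> GenotypeMatrix:
    samples = [f"S{i}" for i in range(len(next(iter(rows.values()))))]
    calls = pd.DataFrame(rows, index=samples).T.rename_axis("snp_id").astype(float)
    sites = pd.DataFrame(
        {"snp_id": list(rows), "chrom": chrom, "pos": [pos0 + 10 * i for i in range(len(rows))]}
    )
    return GenotypeMatrix(calls=calls, sites=sites)


class TestGenotypeClassFilter:
    def test_rare_heterozygote_discarded(self):
        gm = geno({"rs1": [0, 0, 0, 0, 0, 1, 2, 2, 2, 2]})
        assert filter_genotype_classes(gm).snps == []

    def test_balanced_snp_retained(self):
        gm = geno({"rs1": [0, 0, 1, 1, 2, 2]})
        assert filter_genotype_classes(gm).snps == ["rs1"]

    def test_monomorphic_discarded(self):
        gm = geno({"rs1": [0, 0, 0, 0, 0, 0]})
        assert filter_genotype_classes(gm).snps == []

    def test_missing_calls_count_for_no_class(self):
        gm = geno({"rs1": [0, 0, 1, 1, 2, np.nan]})
        assert filter_genotype_classes(gm).snps == []

    def test_monotone_in_min_per_class(self, rng):
        calls = {f"rs{i}": list(rng.integers(0, 3, size=12).astype(float)) for i in range(50)}
        gm = geno(calls)
        kept = [set(filter_genotype_classes(gm, m).snps) for m in (1, 2, 3, 4)]
        for lo, hi in zip(kept[1:], kept):
            assert lo <= hi


def normal_equations_f(y, g, cov):
    """Independent oracle: nested-model F via explicit normal equations."""
    n = len(y)
    x_red = np.column_stack([np.ones(n), cov]) if cov is not None else np.ones((n, 1))
    x_full = np.column_stack([x_red, (g == 1).astype(float), (g == 2).astype(float)])

    def rss(x):
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        r = y - x @ beta
        return r @ r

    rf, rr = rss(x_full), rss(x_red)
    df2 = n - x_full.shape[1]
    return ((rr - rf) / 2) / (rf / df2)


class TestGenotypicModel:
    def test_matches_one_way_anova_without_covariates(self):
        from scipy.stats import f_oneway

        y = np.array([1.0, 1.2, 0.9, 1.1, 1.8, 2.0, 1.9, 2.1, 2.9, 3.1, 3.0, 2.8])
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2], dtype=float)
        f, p, n = fit_genotypic_model(y, g)
        ref = f_oneway(y[g == 0], y[g == 1], y[g == 2])
        assert n == 12
        assert f == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_matches_normal_equations_oracle_with_covariates(self, rng):
        for _ in range(50):
            n = int(rng.integers(12, 40))
            g = rng.integers(0, 3, size=n).astype(float)
            if min((g == c).sum() for c in (0, 1, 2)) < 1:
                continue
            cov = np.column_stack([rng.normal(34, 3, n), rng.integers(0, 2, n)])
            y = rng.normal(1.0, 0.2, n) + 0.1 * g
            f, _, _ = fit_genotypic_model(y, g, cov)
            assert f == pytest.approx(normal_equations_f(y, g, cov), abs=1e-8)

    def test_permutation_invariance(self, rng):
        n = 20
        g = np.array([0] * 7 + [1] * 7 + [2] * 6, dtype=float)
        cov = rng.normal(size=(n, 2))
        y = rng.normal(size=n)
        f1, p1, _ = fit_genotypic_model(y, g, cov)
        perm = rng.permutation(n)
        f2, p2, _ = fit_genotypic_model(y[perm], g[perm], cov[perm])
        assert f1 == pytest.approx(f2, rel=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_degenerate_response_rejected(self):
        y = np.ones(12)
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2], dtype=float)
        with pytest.raises(ValueError, match="degenerate"):
            fit_genotypic_model(y, g)

    def test_missing_class_rejected(self):
        y = np.arange(8, dtype=float)
        g = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        with pytest.raises(ValueError, match="class"):
            fit_genotypic_model(y, g)


class TestCisTrans:
    def test_inside_gene(self):
        assert classify_cis_trans(("1", 1_005_000), ("1", 1_000_000, 1_010_000)) == ("cis", 0.0)

    def test_boundary_inclusive_at_one_megabase(self):
        assert classify_cis_trans(("1", 2_010_000), ("1", 1_000_000, 1_010_000)) == ("cis", 1_000_000.0)

    def test_one_bp_past_boundary_is_trans(self):
        stratum, d = classify_cis_trans(("1", 2_010_001), ("1", 1_000_000, 1_010_000))
        assert (stratum, d) == ("trans", 1_000_001.0)

    def test_other_chromosome_is_infinitely_far(self):
        stratum, d = classify_cis_trans(("2", 1_005_000), ("1", 1_000_000, 1_010_000))
        assert stratum == "trans" and math.isinf(d)

    def test_orientation_symmetric(self):
        fwd = classify_cis_trans(("1", 500), ("1", 1_000, 2_000))
        rev = classify_cis_trans(("1", 500), ("1", 2_000, 1_000))
        assert fwd == rev


class TestBhFdr:
    @staticmethod
    def step_up_oracle(p):
        """Reference BH step-up: monotone cumulative minimum of m*p/rank from the top."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        adj = np.empty(m)
        running = 1.0
        for rank_from_top, idx in enumerate(order[::-1]):
            rank = m - rank_from_top
            running = min(running, p[idx] * m / rank)
            adj[idx] = running
        return adj

    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=60))
    @settings(max_examples=300, derandomize=True)
    def test_matches_reference_step_up(self, pvals):
        np.testing.assert_allclose(bh_fdr(pvals), self.step_up_oracle(pvals), atol=1e-12)

    def test_single_p_is_its_own_fdr(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)


class TestMapSqtl:
    def _setup(self, rng, genotype_rows):
        ann = make_annotation({"G1": 2})
        gm = geno(genotype_rows, chrom="9", pos0=5_000_000)
        samples = gm.samples
        sheet = make_sheet(
            samples,
            ["CTRL"] * len(samples),
            ga=list(rng.normal(38, 1, len(samples))),
            sex=["M" if i % 2 else "F" for i in range(len(samples))],
        )
        isi = pd.DataFrame(
            {
                "gene_id": "G1",
                "sample_id": samples,
                "isi": rng.normal(1.0, 0.1, len(samples)),
                "selected_probe_id": "G1_p1",
            }
        )
        return isi, gm, sheet, ann

    def test_single_pair_fdr_equals_p(self, rng):
        isi, gm, sheet, ann = self._setup(rng, {"rs1": [0, 0, 1, 1, 2, 2, 0, 1, 2, 0, 1, 2]})
        out = map_sqtl(isi, gm, sheet, ann)
        assert len(out) == 1
        assert out["fdr"].iloc[0] == pytest.approx(out["p_value"].iloc[0])
        assert out["stratum"].iloc[0] == "trans"  # chrom 9 SNP vs chrom 1 gene

    def test_pair_skipped_when_missingness_kills_a_class(self, rng):
        rows = {"rs1": [0, 0, 1, 1, 2, 2, 0, 1, 2, 0, 1, np.nan]}
        isi, gm, sheet, ann = self._setup(rng, rows)
        # remove the remaining BB carriers from the ISI table instead
        isi.loc[isi["sample_id"].isin(["S4", "S5", "S8"]), "isi"] = np.nan
        out = map_sqtl(isi, gm, sheet, ann)
        assert out.empty
        assert out.attrs["skipped"] == {"genotype_class_lost": 1}

    def test_empty_sample_intersection_raises(self, rng):
        isi, gm, sheet, ann = self._setup(rng, {"rs1": [0, 0, 1, 1, 2, 2]})
        isi["sample_id"] = isi["sample_id"] + "_other"
        with pytest.raises(ValueError, match="no samples"):
            map_sqtl(isi, gm, sheet, ann)


class TestAdditiveTrend:
    def test_exact_linear_relation(self):
        g = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        res = additive_trend(1 + 0.5 * g, g)
        assert res.slope == pytest.approx(0.5, abs=1e-12)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_six_point_closed_form(self):
        g = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        y = np.array([1.0, 1.4, 1.7, 0.9, 1.3, 1.9])
        res = additive_trend(y, g)
        # closed-form least squares computed from sums
        sxx = ((g - g.mean()) ** 2).sum()
        sxy = ((g - g.mean()) * (y - y.mean())).sum()
        syy = ((y - y.mean()) ** 2).sum()
        assert res.slope == pytest.approx(sxy / sxx, abs=1e-12)
        assert res.r == pytest.approx(sxy / np.sqrt(sxx * syy), abs=1e-12)

    def test_constant_genotype_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            additive_trend(np.array([1.0, 2.0, 3.0]), np.zeros(3))

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="3 samples"):
            additive_trend(np.array([1.0, 2.0]), np.array([0.0, 1.0]))
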