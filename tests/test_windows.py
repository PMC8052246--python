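import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from placsplice.windows import NullMaxDistribution, build_windows, monte_carlo_null, select_bandmaster


def couples_df(entries):
    """entries: (snp_id, chrom, pos, gene_id)"""
    return pd.DataFrame(entries, columns=["snp_id", "chrom", "pos", "gene_id"]).assign(p_value=1e-6)


def brute_force_windows(entries, gap):
    """O(n^2) oracle: SNPs are in one window iff connected by a chain of < gap steps."""
    loci = sorted({(c, p, s) for s, c, p, _ in entries})
    clusters: list[list[tuple]] = []
    for locus in loci:
        placed = None
        for cl in clusters:
            if any(l[0] == locus[0] and abs(l[1] - locus[1]) < gap for l in cl):
                placed = cl
                break
        if placed is None:
            clusters.append([locus])
        else:
            placed.append(locus)
    # chain merging: repeat until stable (handles A-B-C chains)
    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(list(clusters), 2):
            if any(x[0] == y[0] and abs(x[1] - y[1]) < gap for x in a for y in b):
                a.extend(b)
                clusters.remove(b)
                changed = True
                break
    out = []
    for cl in clusters:
        snps = {l[2] for l in cl}
        members = [e for e in entries if e[0] in snps]
        out.append(
            {
                "snps": frozenset(snps),
                "n_couples": len(members),
                "n_genes": len({m[3] for m in members}),
            }
        )
    return sorted(out, key=lambda w: sorted(w["snps"]))


class TestBuildWindows:
    def test_hand_example_two_windows(self):
        c = couples_df(
            [("a", "1", 100, "G1"), ("a", "1", 100, "G2"), ("b", "1", 1500, "G3"), ("c", "1", 5000, "G4")]
        )
        ws = build_windows(c, gap=2000)
        w = ws.windows.sort_values("start_pos").reset_index(drop=True)
        assert len(w) == 2
        assert (w.loc[0, "n_couples"], w.loc[0, "n_distinct_genes"]) == (3, 3)
        assert (w.loc[0, "start_pos"], w.loc[0, "end_pos"]) == (100, 1500)
        assert w.loc[1, "n_couples"] == 1

    def test_single_couple(self):
        ws = build_windows(couples_df([("a", "3", 42, "G1")]))
        assert len(ws.windows) == 1
        assert ws.windows.loc[0, "n_couples"] == 1

    def test_all_far_apart_one_window_each(self):
        c = couples_df([(f"s{i}", "1", 10_000 * i, "G") for i in range(1, 6)])
        assert len(build_windows(c, gap=2000).windows) == 5

    def test_windows_never_span_chromosomes(self):
        c = couples_df([("a", "1", 100, "G1"), ("b", "2", 200, "G2")])
        assert len(build_windows(c, gap=2000).windows) == 2

    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=49),  # snp index
                st.sampled_from(["1", "2"]),
                st.integers(min_value=1, max_value=20_000),
                st.sampled_from(["G1", "G2", "G3"]),
            ),
            min_size=1,
            max_size=50,
        )
    )
    @settings(max_examples=200, derandomize=True)
    def test_matches_brute_force_oracle(self, raw):
        # one position per SNP id: keep first occurrence
        seen = {}
        entries = []
        for i, chrom, pos, gene in raw:
            snp = f"s{i}"
            if snp not in seen:
                seen[snp] = (chrom, pos)
            chrom, pos = seen[snp]
            entries.append((snp, chrom, pos, gene))
        ws = build_windows(couples_df(entries), gap=2000)
        expected = brute_force_windows(entries, gap=2000)
        got = sorted(
            (
                {
                    "snps": frozenset(r["snp_ids"].split(";")),
                    "n_couples": r["n_couples"],
                    "n_genes": r["n_distinct_genes"],
                }
                for _, r in ws.windows.iterrows()
            ),
            key=lambda w: sorted(w["snps"]),
        )
        assert got == expected

    def test_couples_conserved_and_gap_monotone(self, rng):
        entries = [
            (f"s{i}", str(rng.integers(1, 4)), int(rng.integers(1, 50_000)), f"G{rng.integers(1, 6)}")
            for i in range(30)
        ]
        c = couples_df(entries)
        n_prev = None
        for gap in (500, 2000, 8000, 50_001):
            ws = build_windows(c, gap=gap)
            assert ws.windows["n_couples"].sum() == len(c)
            if n_prev is not None:
                assert len(ws.windows) <= n_prev
            n_prev = len(ws.windows)


class TestMonteCarloNull:
    panel = pd.DataFrame(
        {"chrom": ["1", "1", "2", "2"], "pos": [100, 600, 5_000, 5_400], "snp_id": ["a", "b", "c", "d"]}
    )

    def test_zero_permutations_give_undefined_p(self):
        c = couples_df([("a", "1", 100, "G1")])
        null = monte_carlo_null(c, self.panel, n_perm=0, seed=1)
        assert null.max_lengths == []
        assert null.empirical_p is None

    def test_forced_outcome_when_all_panel_snps_isolated(self):
        panel = pd.DataFrame({"chrom": "1", "pos": [10_000 * i for i in range(1, 6)], "snp_id": list("abcde")})
        c = couples_df([("a", "1", 10_000, "G1"), ("b", "1", 20_000, "G2")])
        null = monte_carlo_null(c, panel, n_perm=50, seed=3)
        assert null.max_lengths == [1] * 50

    def test_matches_exhaustive_enumeration_on_tiny_panel(self):
        # two clusters of two SNPs; drawing 2 of 4 loci lands both in one
        # cluster with probability 2/C(4,2) = 1/3
        c = couples_df([("a", "1", 100, "G1"), ("c", "2", 5_000, "G2")])
        null = monte_carlo_null(c, self.panel, gap=2000, n_perm=10_000, seed=5)
        freq = np.mean(np.array(null.max_lengths) == 2)
        p_exact = 1 / 3
        se = np.sqrt(p_exact * (1 - p_exact) / 10_000)
        assert abs(freq - p_exact) < 3 * se

    def test_reproducible_for_fixed_seed(self):
        c = couples_df([("a", "1", 100, "G1"), ("c", "2", 5_000, "G2")])
        n1 = monte_carlo_null(c, self.panel, n_perm=200, seed=11)
        n2 = monte_carlo_null(c, self.panel, n_perm=200, seed=11)
        assert n1.max_lengths == n2.max_lengths
        assert n1.empirical_p == n2.empirical_p

    def test_empirical_p_bounds(self):
        c = couples_df([("a", "1", 100, "G1"), ("b", "1", 600, "G2")])  # observed max = 2
        null = monte_carlo_null(c, self.panel, n_perm=100, seed=2)
        assert 1 / 101 <= null.empirical_p <= 1.0

    def test_panel_too_small_rejected(self):
        c = couples_df([(s, "1", 100 * i, "G") for i, s in enumerate("abcde")])
        with pytest.raises(ValueError, match="panel"):
            monte_carlo_null(c, self.panel.iloc[:3], n_perm=10, seed=1)


class TestBandmasterSelection:
    def _windows(self, spec_rows):
        rows = [
            {
                "window_id": i,
                "chrom": "1",
                "start_pos": 100 * i,
                "end_pos": 100 * i + 50,
                "n_snps": 2,
                "n_couples": nc,
                "n_distinct_genes": ng,
                "snp_ids": f"s{i}",
                "gene_ids": "G",
            }
            for i, (nc, ng) in enumerate(spec_rows)
        ]
        from placsplice.windows import WindowSet

        return WindowSet(windows=pd.DataFrame(rows), couples=pd.DataFrame(), gap=2000)

    def null(self, maxima):
        return NullMaxDistribution(
            max_lengths=maxima, n_perm=len(maxima), seed=0, observed_max=max(maxima), empirical_p=0.5
        )

    def test_only_windows_beyond_null_max_selected(self):
        ws = self._windows([(7, 3), (6, 2), (3, 2)])
        out = select_bandmaster(ws, self.null([6, 4, 2]))
        assert list(out["n_couples"]) == [7]

    def test_single_gene_window_excluded(self):
        ws = self._windows([(10, 1)])
        assert select_bandmaster(ws, self.null([6])).empty

    def test_empty_window_set(self):
        ws = self._windows([])
        assert select_bandmaster(ws, self.null([3])).empty

    def test_empty_null_rejected(self):
        ws = self._windows([(7, 3)])
        with pytest.raises(ValueError, match="null"):
            select_bandmaster(ws, NullMaxDistribution(max_lengths=[], n_perm=0, seed=0, observed_max=7))
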