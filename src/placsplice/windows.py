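"""Clustering of significant trans SNP-gene couples into genomic windows.

Significant SNPs are sorted along each chromosome and grouped into windows:
a new window starts whenever the gap to the previous significant SNP is at
least ``gap`` bp (default 2000 bp, on the order of minimal LD block sizes).
A window's length is the number of SNP-gene couples it contains — a SNP
significant for k genes contributes k couples.

The Monte-Carlo null asks how long the longest window would be if the same
number of significant loci, carrying the same per-locus couple counts, were
scattered uniformly over the full tested SNP panel.  Windows whose couple
count exceeds the null maximum and that involve at least two distinct
target genes are the "bandmaster" candidates: compact loci coordinating
the splicing of multiple distant genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from placsplice.io import GenotypeMatrix, natural_chrom_key


def couples_from_sqtl(
    sqtl: pd.DataFrame,
    G: GenotypeMatrix,
    alpha: float,
    stratum: str = "trans",
) -> pd.DataFrame:
    """Extract significant SNP-gene couples (with SNP coordinates) from an sQTL table."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    sel = sqtl[(sqtl["p_value"] < alpha) & (sqtl["stratum"] == stratum)]
    sites = G.sites.set_index("snp_id")
    return pd.DataFrame(
        {
            "snp_id": sel["snp_id"].to_numpy(),
            "chrom": sites.loc[sel["snp_id"], "chrom"].to_numpy(),
            "pos": sites.loc[sel["snp_id"], "pos"].to_numpy(),
            "gene_id": sel["gene_id"].to_numpy(),
            "p_value": sel["p_value"].to_numpy(),
        }
    ).reset_index(drop=True)


@dataclass
class WindowSet:
    """Windows of clustered significant SNPs plus the couple-to-window assignment."""

    windows: pd.DataFrame  # window_id, chrom, start_pos, end_pos, n_snps, n_couples, n_distinct_genes, snp_ids, gene_ids
    couples: pd.DataFrame  # input couples + window_id
    gap: int


def build_windows(couples: pd.DataFrame, gap: int = 2000) -> WindowSet:
    """Group significant SNPs into windows of consecutive SNPs < ``gap`` bp apart.

    Windows never span chromosomes; every couple belongs to exactly one
    window.  Couples of the same SNP (one per affected gene) all join that
    SNP's window.
    """
    if gap <= 0:
        raise ValueError("gap must be positive")
    couples = couples.reset_index(drop=True)
    if couples.empty:
        empty = pd.DataFrame(
            columns=["window_id", "chrom", "start_pos", "end_pos", "n_snps", "n_couples", "n_distinct_genes", "snp_ids", "gene_ids"]
        )
        return WindowSet(windows=empty, couples=couples.assign(window_id=pd.Series(dtype=int)), gap=gap)

    loci = couples[["snp_id", "chrom", "pos"]].drop_duplicates("snp_id")
    loci = loci.sort_values(["chrom", "pos"], key=lambda s: s.map(natural_chrom_key) if s.name == "chrom" else s, kind="mergesort")
    window_of: dict[str, int] = {}
    wid = -1
    prev_chrom, prev_pos = None, None
    for snp_id, chrom, pos in loci.itertuples(index=False):
        if chrom != prev_chrom or pos - prev_pos >= gap:
            wid += 1
        window_of[snp_id] = wid
        prev_chrom, prev_pos = chrom, pos

    assigned = couples.assign(window_id=couples["snp_id"].map(window_of))
    rows = []
    for w, grp in assigned.groupby("window_id", sort=True):
        snps = grp[["snp_id", "pos"]].drop_duplicates("snp_id").sort_values("pos")
        rows.append(
            {
                "window_id": int(w),
                "chrom": grp["chrom"].iloc[0],
                "start_pos": int(grp["pos"].min()),
                "end_pos": int(grp["pos"].max()),
                "n_snps": len(snps),
                "n_couples": len(grp),
                "n_distinct_genes": grp["gene_id"].nunique(),
                "snp_ids": ";".join(snps["snp_id"]),
                "gene_ids": ";".join(sorted(set(grp["gene_id"]))),
            }
        )
    return WindowSet(windows=pd.DataFrame(rows), couples=assigned, gap=gap)


@dataclass
class NullMaxDistribution:
    """Per-permutation maxima of the window couple count under random SNP placement."""

    max_lengths: list[int]
    n_perm: int
    seed: int | None
    observed_max: int
    empirical_p: float | None = field(default=None)

    def __post_init__(self) -> None:
        if len(self.max_lengths) != self.n_perm:
            raise ValueError("max_lengths length must equal n_perm")


def _max_window_count(chrom_codes: np.ndarray, pos: np.ndarray, counts: np.ndarray, gap: int) -> int:
    """Maximal summed couple count over windows of co-clustered loci (vectorized)."""
    order = np.lexsort((pos, chrom_codes))
    c, p, k = chrom_codes[order], pos[order], counts[order]
    if len(p) == 0:
        return 0
    new_window = np.ones(len(p), dtype=bool)
    new_window[1:] = (c[1:] != c[:-1]) | ((p[1:] - p[:-1]) >= gap)
    starts = np.flatnonzero(new_window)
    sums = np.add.reduceat(k, starts)
    return int(sums.max())


def monte_carlo_null(
    couples: pd.DataFrame,
    panel: pd.DataFrame,
    gap: int = 2000,
    n_perm: int = 1000,
    seed: int | None = None,
) -> NullMaxDistribution:
    """Null distribution of the maximal window couple count.

    Each permutation draws, without replacement from the full tested panel
    (columns chrom, pos), as many loci as there are distinct significant
    SNPs, reassigns each real locus's couple count to a drawn locus, and
    rebuilds windows.  ``empirical_p`` for the observed maximum is
    (1 + #{null >= observed}) / (n_perm + 1); undefined (None) at n_perm=0.
    """
    loci = couples.groupby("snp_id", sort=True).size()
    counts = loci.to_numpy(dtype=np.int64)
    n_loci = len(counts)
    if len(panel) < n_loci:
        raise ValueError(f"panel of {len(panel)} SNPs smaller than {n_loci} significant loci")
    observed = build_windows(couples, gap=gap)
    observed_max = int(observed.windows["n_couples"].max()) if len(observed.windows) else 0

    chrom_order = {c: i for i, c in enumerate(sorted(panel["chrom"].unique(), key=natural_chrom_key))}
    panel_chrom = panel["chrom"].map(chrom_order).to_numpy(dtype=np.int64)
    panel_pos = panel["pos"].to_numpy(dtype=np.int64)

    rng = np.random.default_rng(seed)
    maxima: list[int] = []
    for _ in range(n_perm):
        idx = rng.choice(len(panel_pos), size=n_loci, replace=False)
        maxima.append(_max_window_count(panel_chrom[idx], panel_pos[idx], counts, gap))
    empirical_p = None
    if n_perm > 0:
        empirical_p = (1 + sum(m >= observed_max for m in maxima)) / (n_perm + 1)
    return NullMaxDistribution(
        max_lengths=maxima, n_perm=n_perm, seed=seed, observed_max=observed_max, empirical_p=empirical_p
    )


def select_bandmaster(ws: WindowSet, null: NullMaxDistribution, min_genes: int = 2) -> pd.DataFrame:
    """Windows longer than the simulated maximum and hitting >= ``min_genes`` genes.

    Returned sorted by n_couples descending (ties: chromosome order).
    """
    if null.n_perm == 0 or not null.max_lengths:
        raise ValueError("empty Monte-Carlo null: run monte_carlo_null with n_perm > 0")
    threshold = max(null.max_lengths)
    w = ws.windows
    if w.empty:
        return w.copy()
    sel = w[(w["n_couples"] > threshold) & (w["n_distinct_genes"] >= min_genes)]
    return sel.sort_values("n_couples", ascending=False, kind="mergesort").reset_index(drop=True)
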