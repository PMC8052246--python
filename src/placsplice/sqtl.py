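"""Genotype-to-splicing QTL mapping.

The splicing phenotype is the per-sample ISI of a gene; the genetic
predictor is a SNP coded 0 (AA), 1 (AB), 2 (BB).  Association uses a full
genotypic model — two genotype indicators on top of the covariates, so the
three genotype classes have independent means — compared against the
covariate-only model with a 2-df nested F-test:

    full:    ISI ~ 1 + gestational_age + sex + 1[g=1] + 1[g=2]
    reduced: ISI ~ 1 + gestational_age + sex

SNPs are pre-filtered so that each genotype class is carried by at least
``min_per_class`` samples.  Pairs are classified cis (SNP within
``cis_window`` bp of the gene interval, boundary inclusive) or trans, and
Benjamini-Hochberg FDR is computed within each stratum by default (a joint
adjustment is available).  An additive-trend OLS of ISI on allele dosage
summarizes direction and linearity of significant cis effects.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from placsplice.io import GenotypeMatrix, ProbeAnnotation, SampleSheet


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def filter_genotype_classes(G: GenotypeMatrix, min_per_class: int = 2) -> GenotypeMatrix:
    """Retain SNPs whose AA, AB and BB classes each occur in >= ``min_per_class`` samples.

    Missing calls count toward no class.  Raising ``min_per_class`` can only
    shrink the retained set.
    """
    if min_per_class < 1:
        raise ValueError("min_per_class must be >= 1")
    arr = G.calls.to_numpy(dtype=float)
    keep = np.ones(arr.shape[0], dtype=bool)
    for code in (0.0, 1.0, 2.0):
        keep &= (arr == code).sum(axis=1) >= min_per_class
    kept_ids = G.calls.index[keep]
    sites = G.sites[G.sites["snp_id"].isin(set(kept_ids))].reset_index(drop=True)
    return GenotypeMatrix(calls=G.calls.loc[kept_ids], sites=sites)


def fit_genotypic_model(
    isi: np.ndarray,
    genotype: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float, int]:
    """2-df genotype F-test of ISI after covariate adjustment.

    Parameters
    ----------
    isi, genotype
        Aligned per-sample response and genotype codes {0,1,2}; no missing
        values (the caller handles pairwise deletion).
    covariates
        Optional (n_samples, k) array, e.g. gestational age and a sex
        indicator.

    Returns
    -------
    (f_stat, p_value, n_used); p from F(2, n - rank_full).
    """
    y = np.asarray(isi, dtype=float)
    g = np.asarray(genotype, dtype=float)
    n = y.size
    if np.ptp(y) == 0:
        raise ValueError("degenerate response: ISI has zero variance")
    classes = set(np.unique(g))
    if not {0.0, 1.0, 2.0} <= classes:
        raise ValueError(f"genotype classes missing: have {sorted(classes)}")
    cov = np.empty((n, 0)) if covariates is None else np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    x_red = np.column_stack([np.ones(n), cov])
    x_full = np.column_stack([x_red, (g == 1).astype(float), (g == 2).astype(float)])
    rank_full = np.linalg.matrix_rank(x_full)
    df_resid = n - rank_full
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    rss_red = _rss(x_red, y)
    rss_full = _rss(x_full, y)
    if rss_full <= 0:
        return math.inf, float(np.nextafter(0.0, 1.0)), n
    f = ((rss_red - rss_full) / 2.0) / (rss_full / df_resid)
    f = max(f, 0.0)  # guard tiny negative rounding
    p = float(stats.f.sf(f, 2, df_resid))
    return float(f), max(p, float(np.nextafter(0.0, 1.0))), n


def _rss(x: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid)


def classify_cis_trans(
    snp: tuple[str, int],
    gene: tuple[str, int, int],
    cis_window: int = 1_000_000,
) -> tuple[str, float]:
    """Classify a SNP-gene pair as cis or trans and give the distance in bp.

    Distance is 0 when the SNP falls inside the gene interval, otherwise the
    distance to the nearer interval end; pairs on different chromosomes are
    trans with infinite distance.  The cis boundary is inclusive.
    """
    snp_chrom, pos = snp
    gene_chrom, start, end = gene
    start, end = min(start, end), max(start, end)
    if str(snp_chrom) != str(gene_chrom):
        return "trans", math.inf
    if start <= pos <= end:
        distance = 0.0
    else:
        distance = float(min(abs(pos - start), abs(pos - end)))
    return ("cis" if distance <= cis_window else "trans"), distance


def _covariate_design(sheet: SampleSheet, samples: list[str]) -> np.ndarray:
    f = sheet.frame.set_index("sample_id").loc[samples]
    sex = (f["sex"] == "M").astype(float).to_numpy()
    ga = f["gestational_age"].astype(float).to_numpy()
    return np.column_stack([ga, sex])


def map_sqtl(
    isi: pd.DataFrame,
    G: GenotypeMatrix,
    sheet: SampleSheet,
    annotation: ProbeAnnotation,
    cis_window: int = 1_000_000,
    joint_fdr: bool = False,
) -> pd.DataFrame:
    """Test every retained (SNP, gene) pair for a genotypic effect on ISI.

    ``G`` should already be filtered with :func:`filter_genotype_classes`.
    Samples are intersected across the ISI table, the genotype matrix and
    the sample sheet.  Missing genotypes are dropped pairwise; a pair whose
    deletion removes a genotype class is skipped (reason-counted in
    ``result.attrs['skipped']``).

    Returns a DataFrame with snp_id, gene_id, f_stat, p_value, fdr,
    stratum, distance, n_used; FDR is BH within each stratum unless
    ``joint_fdr`` is set.
    """
    isi_wide = isi.pivot(index="gene_id", columns="sample_id", values="isi")
    samples = sorted(set(isi_wide.columns) & set(G.samples) & set(sheet.samples))
    if not samples:
        raise ValueError("no samples shared between ISI, genotypes and sample sheet")
    cov = _covariate_design(sheet, samples)
    iv = isi_wide[samples].to_numpy(dtype=float)
    gv = G.calls[samples].to_numpy(dtype=float)
    sites = G.sites.set_index("snp_id")
    intervals = annotation.gene_intervals().set_index("gene_id")

    skipped: Counter[str] = Counter()
    records = []
    genes = list(isi_wide.index)
    for si, snp_id in enumerate(G.calls.index):
        snp_chrom = sites.at[snp_id, "chrom"]
        snp_pos = int(sites.at[snp_id, "pos"])
        g_row = gv[si]
        g_ok = ~np.isnan(g_row)
        for gi, gene_id in enumerate(genes):
            y_row = iv[gi]
            mask = g_ok & ~np.isnan(y_row)
            g_use = g_row[mask]
            if not all(((g_use == c).sum() >= 1) for c in (0.0, 1.0, 2.0)):
                skipped["genotype_class_lost"] += 1
                continue
            try:
                f, p, n_used = fit_genotypic_model(y_row[mask], g_use, cov[mask])
            except ValueError:
                skipped["degenerate_response"] += 1
                continue
            if gene_id not in intervals.index:
                skipped["gene_unannotated"] += 1
                continue
            row = intervals.loc[gene_id]
            stratum, distance = classify_cis_trans(
                (snp_chrom, snp_pos), (row["chrom"], int(row["start"]), int(row["end"])), cis_window
            )
            records.append((snp_id, gene_id, f, p, stratum, distance, n_used))

    out = pd.DataFrame(
        records, columns=["snp_id", "gene_id", "f_stat", "p_value", "stratum", "distance", "n_used"]
    )
    out["fdr"] = np.nan
    if len(out):
        if joint_fdr:
            out["fdr"] = bh_fdr(out["p_value"].to_numpy())
        else:
            for stratum in ("cis", "trans"):
                m = out["stratum"] == stratum
                if m.any():
                    out.loc[m, "fdr"] = bh_fdr(out.loc[m, "p_value"].to_numpy())
    out = out[["snp_id", "gene_id", "f_stat", "p_value", "fdr", "stratum", "distance", "n_used"]]
    out.attrs["skipped"] = dict(skipped)
    return out


@dataclass
class TrendResult:
    """OLS summary of ISI on allele dosage: slope per B allele, Pearson r, p."""

    snp_id: str
    gene_id: str
    slope: float
    r: float
    p_value: float


def additive_trend(
    isi: np.ndarray,
    genotype: np.ndarray,
    snp_id: str = "",
    gene_id: str = "",
) -> TrendResult:
    """Least-squares trend of ISI on dosage {0,1,2} with Pearson correlation."""
    y = np.asarray(isi, dtype=float)
    g = np.asarray(genotype, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 samples")
    if np.unique(g).size < 2:
        raise ValueError("genotype is constant")
    fit = stats.linregress(g, y)
    return TrendResult(snp_id, gene_id, float(fit.slope), float(fit.rvalue), float(fit.pvalue))
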