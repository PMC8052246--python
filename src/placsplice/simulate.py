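"""Synthetic placental cohorts with known splicing and sQTL ground truth.

The generator emulates the statistical structure the analysis assumes:
per-gene multi-probe log2 signals (gene baseline + probe offset), Gaussian
array noise, group-specific splicing shifts on one probe of selected genes,
Hardy-Weinberg genotypes at configurable MAF, SNP positions with a
configurable share placed in tight (<2000 bp) clusters, additive and
heterozygote-specific genotype effects on single-probe signals, a
multi-gene "master" trans cluster, and gestational-age / sex covariate
effects.  Everything is determined by the seed.

Defaults mirror the cohort scale of the study design this package serves:
17 controls, 7 preeclampsia, 13 growth-restriction samples across two
collection batches, SNPs with minor allele frequency above 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from placsplice.io import GenotypeMatrix, ProbeAnnotation, ProbeMatrix, SampleSheet
from placsplice.isi import compute_isi
from placsplice.splice_index import compute_splice_index, max_si_per_gene, select_spliced
from placsplice.sqtl import filter_genotype_classes, map_sqtl
from placsplice.windows import build_windows, couples_from_sqtl, monte_carlo_null, select_bandmaster

N_CHROMS = 22
CHROM_SPAN = 100_000_000


@dataclass
class TransMasterConfig:
    """A compact SNP cluster whose members each drive splicing of a distant gene."""

    cluster_size: int = 7
    n_targets: int = 7
    effect: float = 1.5  # log2 shift on the target probe per B allele
    spacing: int = 300   # bp between consecutive cluster SNPs (< window gap)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Effects are in log2 fluorescence units; ``noise_sd`` is the per-value
    Gaussian noise SD, so an effect of 1.0 with the default noise is a
    2-residual-SD shift.
    """

    n_genes: int = 48
    probes_per_gene: tuple[int, int] = (4, 8)
    n_samples_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"CTRL": 17, "PE": 7, "IUGR": 13}
    )
    n_snps: int = 300
    maf_range: tuple[float, float] = (0.2, 0.5)
    cluster_fraction: float = 0.25
    cluster_size: int = 3
    splice_effect: float = 5.0
    n_spliced_per_disease: int = 12
    cis_beta: float = 1.0
    n_cis_pairs: int = 3
    het_effect: float = 0.0
    n_het_pairs: int = 0
    trans_master: TransMasterConfig | None = field(default_factory=TransMasterConfig)
    noise_sd: float = 0.5
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"gestational_age": 0.05, "sex": 0.2}
    )
    covariate_probe_fraction: float = 0.1
    signal_floor: float = 2.0  # log2 scanner background; no probe reads below this
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_snps < 1:
            raise ValueError("n_genes and n_snps must be >= 1")
        lo, hi = self.probes_per_gene
        if not 1 <= lo <= hi:
            raise ValueError("probes_per_gene must be an increasing range of positive ints")
        if any(n < 1 for n in self.n_samples_per_group.values()):
            raise ValueError("all group counts must be >= 1")
        if "CTRL" not in self.n_samples_per_group:
            raise ValueError("a CTRL group is required")
        mlo, mhi = self.maf_range
        if not (0 < mlo <= mhi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_spliced_per_disease > self.n_genes:
            raise ValueError("n_spliced_per_disease exceeds n_genes")
        master = self.trans_master
        n_master = master.cluster_size if master else 0
        special = self.n_cis_pairs + self.n_het_pairs + n_master
        n_decoy = int(round(self.cluster_fraction * self.n_snps))
        if special + n_decoy > self.n_snps:
            raise ValueError(
                f"infeasible config: {special} effect SNPs + {n_decoy} clustered decoys "
                f"exceed n_snps={self.n_snps}"
            )
        n_targets = self.n_cis_pairs + self.n_het_pairs + (master.n_targets if master else 0)
        if n_targets > self.n_spliced_per_disease:
            raise ValueError(
                "not enough disease-spliced genes to host all genotype-effect targets; "
                "raise n_spliced_per_disease"
            )


@dataclass
class SimTruth:
    """Ground truth of a generated cohort."""

    spliced: dict[str, list[tuple[str, str, float]]]  # disease -> [(gene, probe, signed effect)]
    cis_pairs: list[dict]                              # snp_id, gene_id, probe_id, mode, beta
    master: dict | None                                # snp_ids, couples [(snp, gene)], effect
    maf: pd.Series                                     # per-SNP minor allele frequency


@dataclass
class SimDataset:
    matrix: ProbeMatrix
    annotation: ProbeAnnotation
    sheet: SampleSheet
    genotypes: GenotypeMatrix
    truth: SimTruth
    config: SimConfig


def cis_recovery_config(seed: int) -> SimConfig:
    """Focused injected-cis-sQTL scenario: one additive cis pair of two residual
    SD per allele (beta = 2 x noise_sd) at MAF 0.3, 15 + 15 samples, moderate
    disease splicing so the ISI residual is noise-dominated."""
    return SimConfig(
        n_genes=12,
        probes_per_gene=(4, 6),
        n_samples_per_group={"CTRL": 15, "PE": 15},
        n_snps=60,
        maf_range=(0.3, 0.3),
        cluster_fraction=0.2,
        splice_effect=2.0,
        n_spliced_per_disease=4,
        n_cis_pairs=1,
        trans_master=None,
        seed=seed,
    )


def master_recovery_config(seed: int) -> SimConfig:
    """Focused bandmaster scenario: a 7-SNP cluster (<2000 bp) driving splicing
    of 7 distinct genes, three-residual-SD per-allele effects."""
    return SimConfig(
        n_genes=12,
        probes_per_gene=(4, 6),
        n_samples_per_group={"CTRL": 15, "PE": 15},
        n_snps=60,
        maf_range=(0.3, 0.3),
        cluster_fraction=0.2,
        splice_effect=2.0,
        n_spliced_per_disease=7,
        n_cis_pairs=0,
        trans_master=TransMasterConfig(cluster_size=7, n_targets=7, effect=1.5),
        seed=seed,
    )


def null_config(seed: int, n_genes: int = 12, n_snps: int = 60) -> SimConfig:
    """No splicing, no genotype effects, no covariate effects: calibration null."""
    return SimConfig(
        n_genes=n_genes,
        probes_per_gene=(4, 6),
        n_samples_per_group={"CTRL": 15, "PE": 15},
        n_snps=n_snps,
        maf_range=(0.3, 0.3),
        cluster_fraction=0.2,
        splice_effect=0.0,
        n_spliced_per_disease=1,
        n_cis_pairs=0,
        n_het_pairs=0,
        trans_master=None,
        covariate_effects={},
        seed=seed,
    )


_GA_BY_GROUP = {"CTRL": (39.0, 1.0), "PE": (33.5, 2.0), "PE_IUGR": (31.5, 2.0), "IUGR": (32.5, 2.0)}


def _make_samples(config: SimConfig, rng: np.random.Generator) -> SampleSheet:
    rows = []
    i = 0
    for group, n in config.n_samples_per_group.items():
        for _ in range(n):
            i += 1
            mu, sd = _GA_BY_GROUP[group]
            ga = float(np.clip(rng.normal(mu, sd), 26.0, 41.5))
            sex = "M" if rng.random() < 0.5 else "F"
            bw = 3400.0 - 170.0 * (39.0 - ga) + rng.normal(0.0, 300.0)
            if group != "CTRL":
                bw -= 700.0
            rows.append((f"P{i:03d}", group, round(ga, 1), sex, round(max(bw, 400.0), 0), ""))
    df = pd.DataFrame(rows, columns=["sample_id", "group", "gestational_age", "sex", "birth_weight", "batch"])
    # two collection batches: PE cohort with ~half the controls, IUGR cohort with the rest
    ctrl = df.index[df["group"] == "CTRL"]
    half = (len(ctrl) + 1) // 2
    df.loc[df["group"].isin(["PE"]), "batch"] = "cohortA"
    df.loc[df["group"].isin(["IUGR", "PE_IUGR"]), "batch"] = "cohortB"
    df.loc[ctrl[:half], "batch"] = "cohortA"
    df.loc[ctrl[half:], "batch"] = "cohortB"
    return SampleSheet(df)


def _make_annotation(config: SimConfig, rng: np.random.Generator) -> ProbeAnnotation:
    lo, hi = config.probes_per_gene
    rows = []
    for j in range(config.n_genes):
        gene = f"G{j + 1:04d}"
        chrom = str((j % N_CHROMS) + 1)
        start = 10_000_000 + (j // N_CHROMS) * 10_000_000
        n_probes = int(rng.integers(lo, hi + 1))
        for k in range(n_probes):
            p_start = start + k * 2000
            rows.append((f"{gene}_p{k + 1}", gene, chrom, p_start, p_start + 199, k + 1))
    return ProbeAnnotation(pd.DataFrame(rows, columns=["probe_id", "gene_id", "chrom", "start", "end", "probe_index"]))


def _place_snps(
    config: SimConfig,
    annotation: ProbeAnnotation,
    rng: np.random.Generator,
    cis_targets: list[str],
    het_targets: list[str],
) -> tuple[pd.DataFrame, list[str], list[str], list[str]]:
    """SNP positions: cis/het SNPs near their target genes, the master cluster,
    decoy clusters, then isolated SNPs.  Returns (sites, cis_ids, het_ids, master_ids)."""
    intervals = annotation.gene_intervals().set_index("gene_id")
    rows: list[tuple[str, str, int]] = []

    def near_gene(gene: str) -> tuple[str, int]:
        row = intervals.loc[gene]
        offset = int(rng.integers(-500_000, 500_001))
        return str(row["chrom"]), max(1, int(row["start"]) + offset)

    cis_ids, het_ids, master_ids = [], [], []
    for i, gene in enumerate(cis_targets):
        chrom, pos = near_gene(gene)
        snp = f"rs_cis{i + 1}"
        cis_ids.append(snp)
        rows.append((snp, chrom, pos))
    for i, gene in enumerate(het_targets):
        chrom, pos = near_gene(gene)
        snp = f"rs_het{i + 1}"
        het_ids.append(snp)
        rows.append((snp, chrom, pos))

    master = config.trans_master
    if master is not None:
        base = 90_000_000  # far from every simulated gene interval
        chrom = str(int(rng.integers(1, N_CHROMS + 1)))
        for i in range(master.cluster_size):
            snp = f"rs_master{i + 1}"
            master_ids.append(snp)
            rows.append((snp, chrom, base + i * master.spacing))

    n_decoy = int(round(config.cluster_fraction * config.n_snps))
    i_decoy = 0
    while i_decoy < n_decoy:
        chrom = str(int(rng.integers(1, N_CHROMS + 1)))
        base = int(rng.integers(1_000_000, CHROM_SPAN - 100_000))
        size = min(config.cluster_size, n_decoy - i_decoy)
        for k in range(size):
            i_decoy += 1
            rows.append((f"rs_c{i_decoy}", chrom, base + k * 300))
    n_iso = config.n_snps - len(rows)
    for i in range(n_iso):
        chrom = str(int(rng.integers(1, N_CHROMS + 1)))
        rows.append((f"rs_i{i + 1}", chrom, int(rng.integers(1_000_000, CHROM_SPAN))))
    sites = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"])
    return sites, cis_ids, het_ids, master_ids


def _draw_filter_passing(rng: np.random.Generator, maf: float, n: int, min_per_class: int = 2) -> np.ndarray:
    """Hardy-Weinberg draw conditioned on every genotype class having >= min_per_class carriers.

    Injected QTL loci emulate discovered sQTLs, which by study design exist
    only within the genotype-class-filtered panel.
    """
    if n < 3 * min_per_class:
        raise ValueError("too few samples to carry all three genotype classes")
    for _ in range(100_000):
        g = rng.binomial(2, maf, size=n).astype(float)
        if all((g == c).sum() >= min_per_class for c in (0.0, 1.0, 2.0)):
            return g
    raise ValueError(f"could not draw filter-passing genotypes at MAF {maf} with n={n}")


def generate(config: SimConfig) -> SimDataset:
    """Draw a complete synthetic cohort (expression, annotation, samples, genotypes, truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    sheet = _make_samples(config, rng)
    annotation = _make_annotation(config, rng)
    ann = annotation.frame
    samples = sheet.samples
    n_samples = len(samples)

    # disease-spliced genes; genotype-effect targets are disjoint subsets of the
    # PE-spliced list so their effects land on each gene's selected probe
    genes = sorted(ann["gene_id"].unique())
    pe_spliced = list(rng.choice(genes, size=config.n_spliced_per_disease, replace=False))
    iugr_spliced = list(rng.choice(genes, size=config.n_spliced_per_disease, replace=False))
    n_master_targets = config.trans_master.n_targets if config.trans_master else 0
    pool = list(pe_spliced)
    cis_targets = [pool.pop(0) for _ in range(config.n_cis_pairs)]
    het_targets = [pool.pop(0) for _ in range(config.n_het_pairs)]
    master_targets = [pool.pop(0) for _ in range(n_master_targets)]

    sites, cis_ids, het_ids, master_ids = _place_snps(config, annotation, rng, cis_targets, het_targets)
    maf = pd.Series(rng.uniform(*config.maf_range, size=len(sites)), index=sites["snp_id"].to_numpy())
    calls = rng.binomial(2, maf.to_numpy()[:, None], size=(len(sites), n_samples)).astype(float)
    snp_row = {snp: i for i, snp in enumerate(sites["snp_id"])}
    for snp in cis_ids + het_ids + master_ids:
        calls[snp_row[snp]] = _draw_filter_passing(rng, float(maf[snp]), n_samples)
    genotypes = GenotypeMatrix(
        calls=pd.DataFrame(calls, index=pd.Index(sites["snp_id"], name="snp_id"), columns=samples),
        sites=sites,
    )

    # expression: baseline + probe offset + effects + noise
    probe_ids = list(ann["probe_id"])
    gene_of = ann.set_index("probe_id")["gene_id"]
    baseline = pd.Series(rng.normal(11.0, 1.2, size=len(genes)), index=genes)
    offsets = rng.normal(0.0, 0.8, size=len(probe_ids))
    per_probe = baseline[gene_of.loc[probe_ids]].to_numpy() + offsets
    expr = np.repeat(per_probe[:, None], n_samples, axis=1)

    probe_pos = {p: i for i, p in enumerate(probe_ids)}
    sample_pos = {s: i for i, s in enumerate(samples)}
    group_of = sheet.frame.set_index("sample_id")["group"]

    def splice_probe_of(gene: str) -> str:
        probes = ann.loc[ann["gene_id"] == gene, "probe_id"].tolist()
        return probes[int(rng.integers(0, len(probes)))]

    spliced: dict[str, list[tuple[str, str, float]]] = {"PE": [], "IUGR": []}
    splice_probe: dict[str, str] = {}
    for disease, gene_list in (("PE", pe_spliced), ("IUGR", iugr_spliced)):
        for gene in gene_list:
            probe = splice_probe.setdefault(gene, splice_probe_of(gene))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            effect = sign * config.splice_effect
            affected = [s for s in samples if group_of[s] in (disease, "PE_IUGR")]
            for s in affected:
                expr[probe_pos[probe], sample_pos[s]] += effect
            spliced[disease].append((gene, probe, effect))

    dosage = genotypes.calls  # snp x sample, aligned with `samples`
    cis_pairs: list[dict] = []
    for snp, gene in zip(cis_ids, cis_targets):
        probe = splice_probe[gene]
        expr[probe_pos[probe], :] += config.cis_beta * dosage.loc[snp].to_numpy()
        cis_pairs.append({"snp_id": snp, "gene_id": gene, "probe_id": probe, "mode": "additive", "beta": config.cis_beta})
    for snp, gene in zip(het_ids, het_targets):
        probe = splice_probe[gene]
        expr[probe_pos[probe], :] += config.het_effect * (dosage.loc[snp].to_numpy() == 1.0)
        cis_pairs.append({"snp_id": snp, "gene_id": gene, "probe_id": probe, "mode": "het", "beta": config.het_effect})

    master_truth = None
    if config.trans_master is not None and master_ids:
        couples = []
        for i, snp in enumerate(master_ids):
            gene = master_targets[i % len(master_targets)]
            probe = splice_probe[gene]
            expr[probe_pos[probe], :] += config.trans_master.effect * dosage.loc[snp].to_numpy()
            couples.append((snp, gene))
        master_truth = {"snp_ids": list(master_ids), "couples": couples, "effect": config.trans_master.effect}

    cov_probes = rng.choice(len(probe_ids), size=int(round(config.covariate_probe_fraction * len(probe_ids))), replace=False)
    ga = sheet.frame.set_index("sample_id").loc[samples, "gestational_age"].to_numpy(dtype=float)
    sexm = (sheet.frame.set_index("sample_id").loc[samples, "sex"] == "M").to_numpy(dtype=float)
    for var, coef in config.covariate_effects.items():
        x = {"gestational_age": ga - ga.mean(), "sex": sexm - sexm.mean()}.get(var)
        if x is None:
            raise ValueError(f"unknown covariate effect {var!r}")
        expr[cov_probes, :] += coef * x[None, :]

    expr += rng.normal(0.0, config.noise_sd, size=expr.shape)
    expr = np.maximum(expr, config.signal_floor)
    matrix = ProbeMatrix(pd.DataFrame(expr, index=pd.Index(probe_ids, name="probe_id"), columns=samples))
    truth = SimTruth(spliced=spliced, cis_pairs=cis_pairs, master=master_truth, maf=maf)
    return SimDataset(matrix=matrix, annotation=annotation, sheet=sheet, genotypes=genotypes, truth=truth, config=config)


def run_end_to_end(
    config: SimConfig,
    alpha: float = 1e-4,
    n_perm: int = 200,
    fdr_threshold: float = 0.05,
    si_threshold: float = 3.0,
    gap: int = 2000,
    min_per_class: int = 2,
) -> dict:
    """Generate a cohort, run SI -> ISI -> sQTL -> windows, and score recovery.

    The report contains the stage outputs plus sensitivity of the disease
    splicing screen, per-injected-pair cis detection (FDR and within-gene
    p rank), and whether the master cluster was selected as a bandmaster.
    """
    ds = generate(config)
    sheet = ds.sheet
    ctrl = sheet.samples_in_group("CTRL")
    pe = sheet.samples_in_group("PE")
    si = compute_splice_index(ds.matrix, ds.annotation, pe, ctrl)
    summaries = max_si_per_gene(si)
    detected_genes = select_spliced(summaries, "si", si_threshold)
    truth_pe = [g for g, _, _ in ds.truth.spliced["PE"]]
    sens = (sum(g in detected_genes for g in truth_pe) / len(truth_pe)) if truth_pe else float("nan")

    isi = compute_isi(ds.matrix, ds.annotation, selection="by_si", reference_si=si)
    Gf = filter_genotype_classes(ds.genotypes, min_per_class=min_per_class)
    sqtl = map_sqtl(isi, Gf, sheet, ds.annotation)

    cis_report = []
    for pair in ds.truth.cis_pairs:
        row = sqtl[(sqtl["snp_id"] == pair["snp_id"]) & (sqtl["gene_id"] == pair["gene_id"])]
        if row.empty:
            cis_report.append({**pair, "tested": False, "detected": False, "p_value": None, "fdr": None, "rank": None})
            continue
        p = float(row["p_value"].iloc[0])
        fdr = float(row["fdr"].iloc[0])
        same_gene = sqtl[sqtl["gene_id"] == pair["gene_id"]]
        rank = int((same_gene["p_value"] < p).sum()) + 1
        cis_report.append(
            {**pair, "tested": True, "detected": fdr < fdr_threshold, "p_value": p, "fdr": fdr, "rank": rank}
        )

    couples = couples_from_sqtl(sqtl, Gf, alpha=alpha, stratum="trans")
    ws = build_windows(couples, gap=gap)
    null = monte_carlo_null(couples, Gf.sites, gap=gap, n_perm=n_perm, seed=config.seed)
    bandmasters = select_bandmaster(ws, null) if n_perm > 0 else ws.windows.iloc[0:0]

    master_recovered = False
    false_bandmasters = 0
    master_snps = set(ds.truth.master["snp_ids"]) if ds.truth.master else set()
    for _, w in bandmasters.iterrows():
        snps = set(w["snp_ids"].split(";"))
        if master_snps and len(snps & master_snps) >= max(1, len(master_snps) // 2):
            master_recovered = True
        elif not snps & master_snps:
            false_bandmasters += 1

    additive_pairs = [r for r in cis_report if r["mode"] == "additive" and r["tested"]]
    return {
        "dataset": ds,
        "si": si,
        "summaries": summaries,
        "detected_genes": detected_genes,
        "splice_sensitivity": sens,
        "isi": isi,
        "sqtl": sqtl,
        "cis_report": cis_report,
        "cis_detected_frac": (
            sum(r["detected"] for r in additive_pairs) / len(additive_pairs) if additive_pairs else float("nan")
        ),
        "couples": couples,
        "windows": ws,
        "null": null,
        "bandmasters": bandmasters,
        "master_recovered": master_recovered,
        "false_bandmasters": false_bandmasters,
    }
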