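"""Readers and writers for the tabular formats used throughout the package.

All files are TSV, UTF-8, header mandatory, ``.`` for missing values.
Genomic coordinates are 1-based inclusive everywhere (array-annotation
convention); BED-style 0-based half-open annotation is converted on read
with ``bed0=True``.  Strand is ignored: probe signals are strandless
summaries.  This module validates schemas and invariants only — no
statistics live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("CTRL", "PE", "PE_IUGR", "IUGR")
SEXES = ("M", "F")
MISSING = "."


class FormatError(ValueError):
    """An input file violates the expected schema or a type invariant."""


def natural_chrom_key(chrom: str) -> tuple:
    """Sort key placing chromosomes 1..22, X, Y, MT first, then others lexicographically."""
    name = str(chrom)
    if name.lower().startswith("chr"):
        name = name[3:]
    if name.isdigit():
        return (0, int(name), "")
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    if name.upper() in special:
        return (0, special[name.upper()], "")
    return (1, 0, name)


def sort_by_position(df: pd.DataFrame, chrom_col: str = "chrom", pos_col: str = "pos") -> pd.DataFrame:
    """Stable sort of a table by (chromosome natural order, position)."""
    key = df[chrom_col].map(natural_chrom_key)
    order = sorted(range(len(df)), key=lambda i: (key.iloc[i], df[pos_col].iloc[i]))
    return df.iloc[order].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class ProbeMatrix:
    """Rectangular matrix of log2 fluorescence, probes x samples.

    ``values``: DataFrame indexed by probe_id with one column per sample_id.
    Every probe is present for every sample and all values are finite.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise FormatError(f"duplicated probe row: {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise FormatError(f"duplicated sample column: {dup!r}")
        arr = v.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            probe_i, sample_i = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                f"non-finite value for probe {v.index[probe_i]!r}, sample {v.columns[sample_i]!r}"
            )

    @property
    def probes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ProbeAnnotation:
    """Probe-to-gene map with 1-based inclusive genomic intervals.

    ``frame`` columns: probe_id, gene_id, chrom, start, end, probe_index
    (ordinal 5'->3' position of the probe within its gene).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        required = ["probe_id", "gene_id", "chrom", "start", "end", "probe_index"]
        missing = [c for c in required if c not in f.columns]
        if missing:
            raise FormatError(f"annotation missing columns: {missing}")
        if f["probe_id"].duplicated().any():
            dup = f.loc[f["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise FormatError(f"probe {dup!r} maps to more than one record")
        bad = f["start"] > f["end"]
        if bad.any():
            raise FormatError(f"start > end for probe {f.loc[bad, 'probe_id'].iloc[0]!r}")
        if (f["start"] < 1).any():
            raise FormatError("coordinates must be 1-based positive")
        dup_idx = f.duplicated(subset=["gene_id", "probe_index"])
        if dup_idx.any():
            g = f.loc[dup_idx, "gene_id"].iloc[0]
            raise FormatError(f"duplicate probe_index within gene {g!r}")

    def gene_of(self) -> pd.Series:
        """probe_id -> gene_id mapping."""
        return self.frame.set_index("probe_id")["gene_id"]

    def gene_intervals(self) -> pd.DataFrame:
        """Per-gene interval spanning all of the gene's probes (chrom, start, end)."""
        f = self.frame
        g = f.groupby("gene_id").agg(chrom=("chrom", "first"), start=("start", "min"), end=("end", "max"))
        multi = f.groupby("gene_id")["chrom"].nunique()
        if (multi > 1).any():
            raise FormatError(f"gene {multi[multi > 1].index[0]!r} spans multiple chromosomes")
        return g.reset_index()


@dataclass
class SampleSheet:
    """Sample metadata: group label, covariates and batch (cohort) assignment.

    ``frame`` columns: sample_id, group, gestational_age (weeks), sex,
    birth_weight (grams, optional), batch.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        required = ["sample_id", "group", "gestational_age", "sex", "batch"]
        missing = [c for c in required if c not in f.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        if f["sample_id"].duplicated().any():
            dup = f.loc[f["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicated sample_id: {dup!r}")
        bad_group = ~f["group"].isin(GROUPS)
        if bad_group.any():
            raise FormatError(f"unknown group label: {f.loc[bad_group, 'group'].iloc[0]!r}")
        bad_sex = ~f["sex"].isin(SEXES)
        if bad_sex.any():
            raise FormatError(f"unknown sex code: {f.loc[bad_sex, 'sex'].iloc[0]!r}")
        for col in ("gestational_age",):
            if f[col].isna().any():
                s = f.loc[f[col].isna(), "sample_id"].iloc[0]
                raise FormatError(f"missing {col} for sample {s!r}")

    @property
    def samples(self) -> list[str]:
        return list(self.frame["sample_id"])

    def samples_in_group(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise FormatError(f"unknown group label: {group!r}")
        f = self.frame
        return list(f.loc[f["group"] == group, "sample_id"])


@dataclass
class GenotypeMatrix:
    """SNP x sample genotype codes with SNP positions.

    ``calls``: DataFrame indexed by snp_id, one float column per sample,
    values in {0 (AA), 1 (AB), 2 (BB)} or NaN for missing.
    ``sites``: DataFrame with snp_id, chrom, pos (1-based).
    """

    calls: pd.DataFrame
    sites: pd.DataFrame
    n_multiallelic_skipped: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if self.calls.index.has_duplicates:
            dup = self.calls.index[self.calls.index.duplicated()][0]
            raise FormatError(f"duplicated SNP row: {dup!r}")
        arr = self.calls.to_numpy(dtype=float)
        ok = np.isnan(arr) | np.isin(arr, (0.0, 1.0, 2.0))
        if arr.size and not ok.all():
            snp_i, sample_i = np.argwhere(~ok)[0]
            raise FormatError(
                f"invalid genotype code for SNP {self.calls.index[snp_i]!r}, "
                f"sample {self.calls.columns[sample_i]!r}"
            )
        s = self.sites
        required = ["snp_id", "chrom", "pos"]
        missing = [c for c in required if c not in s.columns]
        if missing:
            raise FormatError(f"genotype sites missing columns: {missing}")
        if (s["pos"] <= 0).any():
            raise FormatError("SNP positions must be positive 1-based")
        if set(s["snp_id"]) != set(self.calls.index):
            raise FormatError("sites and calls disagree on SNP ids")

    @property
    def snps(self) -> list[str]:
        return list(self.calls.index)

    @property
    def samples(self) -> list[str]:
        return list(self.calls.columns)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", na_values=[MISSING], keep_default_na=False, **kw)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed TSV ({exc})") from exc


def read_probe_matrix(path: str | Path) -> ProbeMatrix:
    """Read a probes x samples log2 intensity TSV (first column probe_id)."""
    df = _read_tsv(path, dtype=str)
    if df.columns[0] != "probe_id":
        raise FormatError(f"{path}: first header column must be 'probe_id', got {df.columns[0]!r}")
    df = df.set_index("probe_id")
    values = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            values[col] = df[col].astype(float)
        except (TypeError, ValueError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise FormatError(
                f"{path}: non-numeric value for probe {bad!r}, sample {col!r}"
            ) from None
    return ProbeMatrix(values)


def read_probe_annotation(path: str | Path, bed0: bool = False) -> ProbeAnnotation:
    """Read probe annotation; ``bed0=True`` converts 0-based half-open to 1-based inclusive."""
    df = _read_tsv(path, dtype={"probe_id": str, "gene_id": str, "chrom": str})
    if bed0 and "start" in df.columns:
        df = df.assign(start=df["start"] + 1)
    for col in ("start", "end", "probe_index"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    return ProbeAnnotation(df)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = _read_tsv(path, dtype={"sample_id": str, "group": str, "sex": str, "batch": str})
    if "gestational_age" in df.columns:
        df["gestational_age"] = pd.to_numeric(df["gestational_age"], errors="coerce")
    if "birth_weight" in df.columns:
        df["birth_weight"] = pd.to_numeric(df["birth_weight"], errors="coerce")
    return SampleSheet(df)


def read_genotype_matrix(path: str | Path) -> GenotypeMatrix:
    """Read a SNP x sample genotype TSV: snp_id, chrom, pos, then one column per sample."""
    df = _read_tsv(path, dtype={"snp_id": str, "chrom": str})
    required = ["snp_id", "chrom", "pos"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: genotype TSV missing columns: {missing}")
    sites = df[["snp_id", "chrom", "pos"]].copy()
    sites["pos"] = sites["pos"].astype(int)
    calls = df.drop(columns=["chrom", "pos"]).set_index("snp_id").astype(float)
    return GenotypeMatrix(calls=calls, sites=sites)


def read_vcf_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read diploid biallelic genotypes from a VCF (GT field).

    Coding: 0/0 -> 0, 0/1 -> 1, 1/1 -> 2, ./. -> missing.  Multiallelic
    records are skipped; their count is warned about and stored on the
    returned matrix as ``n_multiallelic_skipped``.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        if "GT" not in vf.header.formats:
            raise FormatError(f"{path}: VCF has no GT FORMAT field")
        samples = list(vf.header.samples)
        rows, site_rows = [], []
        n_skipped = 0
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1:
                n_skipped += 1
                continue
            genos = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    genos.append(np.nan)
                else:
                    genos.append(float(sum(1 for a in gt if a != 0)))
            snp_id = rec.id or f"{rec.chrom}:{rec.pos}"
            rows.append(genos)
            site_rows.append((snp_id, rec.chrom, rec.pos))
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} multiallelic record(s)", stacklevel=2)
    sites = pd.DataFrame(site_rows, columns=["snp_id", "chrom", "pos"])
    calls = pd.DataFrame(rows, index=pd.Index(sites["snp_id"], name="snp_id"), columns=samples)
    return GenotypeMatrix(calls=calls, sites=sites, n_multiallelic_skipped=n_skipped)


# ---------------------------------------------------------------------------
# Writers (canonical ordering: probes/SNPs and samples sorted)
# ---------------------------------------------------------------------------

def write_probe_matrix(pm: ProbeMatrix, path: str | Path) -> None:
    out = pm.values.sort_index().sort_index(axis=1)
    out.to_csv(path, sep="\t", index_label="probe_id", na_rep=MISSING)


def write_probe_annotation(ann: ProbeAnnotation, path: str | Path) -> None:
    ann.frame.sort_values(["gene_id", "probe_index"]).to_csv(path, sep="\t", index=False, na_rep=MISSING)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.frame.sort_values("sample_id").to_csv(path, sep="\t", index=False, na_rep=MISSING)


def write_genotype_matrix(gm: GenotypeMatrix, path: str | Path) -> None:
    sites = gm.sites.set_index("snp_id")
    calls = gm.calls.sort_index().sort_index(axis=1)
    out = calls.copy()
    # genotype codes print as integers, missing as '.'
    for col in out.columns:
        out[col] = out[col].map(lambda v: MISSING if pd.isna(v) else str(int(v)))
    out.insert(0, "pos", sites.loc[out.index, "pos"].astype(int))
    out.insert(0, "chrom", sites.loc[out.index, "chrom"])
    out.to_csv(path, sep="\t", index_label="snp_id")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a generic result table (TSV, '.' for missing, no index)."""
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)
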