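"""End-to-end pipeline orchestration with a reproducibility manifest.

The pipeline runs splicing index -> ISI -> sQTL mapping -> trans windows on
files on disk, writing one TSV per stage plus a JSON manifest (package
version, parameters, input checksums, seed) sufficient to reproduce the
outputs bit-for-bit.  Every filtered record is counted with a reason code,
because the headline numbers of this kind of analysis are counts of
survivors of filters.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import placsplice
from placsplice import io
from placsplice.isi import compute_isi
from placsplice.splice_index import compute_splice_index, max_si_per_gene
from placsplice.sqtl import filter_genotype_classes, map_sqtl
from placsplice.windows import build_windows, couples_from_sqtl, monte_carlo_null, select_bandmaster

log = logging.getLogger("placsplice")


@dataclass
class RunConfig:
    """Inputs, output directory and stage parameters of a full run."""

    matrix: str
    annotation: str
    samples: str
    genotypes: str
    output_dir: str
    group_a: str = "PE"
    group_b: str = "CTRL"
    batch_col: str | None = None
    si_p_threshold: float = 0.001
    si_threshold: float = 3.0
    isi_mode: str = "by_si"
    cis_window: int = 1_000_000
    min_per_class: int = 2
    alpha: float = 1e-4
    gap: int = 2000
    n_perm: int = 1000
    seed: int | None = None
    joint_fdr: bool = False
    genes: list[str] | None = field(default=None)  # optional restriction of the sQTL gene set

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        inputs = raw.get("inputs", {})
        params = raw.get("params", {})
        return cls(
            matrix=inputs["matrix"],
            annotation=inputs["annotation"],
            samples=inputs["samples"],
            genotypes=inputs["genotypes"],
            output_dir=raw["output_dir"],
            **params,
        )

    def validate(self) -> None:
        for name in ("matrix", "annotation", "samples", "genotypes"):
            p = getattr(self, name)
            if not Path(p).is_file():
                raise FileNotFoundError(f"input {name!r} not found: {p}")
        for name in ("si_p_threshold", "si_threshold", "cis_window", "alpha", "gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_perm > 0 and self.seed is None:
            raise ValueError("seed must be set whenever the Monte-Carlo stage runs")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest (also written to disk)."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "placsplice",
        "version": placsplice.__version__,
        "parameters": {k: v for k, v in vars(config).items()},
        "inputs": {
            name: {"path": str(getattr(config, name)), "sha256": _sha256(getattr(config, name))}
            for name in ("matrix", "annotation", "samples", "genotypes")
        },
        "stages": [],
        "filtered": {},
    }

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"].append(name)

    try:
        stage("load")
        matrix = io.read_probe_matrix(config.matrix)
        annotation = io.read_probe_annotation(config.annotation)
        sheet = io.read_sample_sheet(config.samples)
        genotypes = io.read_genotype_matrix(config.genotypes)

        stage("si")
        batch = None
        if config.batch_col:
            batch = sheet.frame.set_index("sample_id")[config.batch_col]
        si = compute_splice_index(
            matrix, annotation, sheet.samples_in_group(config.group_a), sheet.samples_in_group(config.group_b), batch=batch
        )
        io.write_table(si, out_dir / "si.tsv")
        io.write_table(max_si_per_gene(si), out_dir / "si_gene_summary.tsv")

        stage("isi")
        isi = compute_isi(matrix, annotation, selection=config.isi_mode, reference_si=si)
        if config.genes:
            isi = isi[isi["gene_id"].isin(set(config.genes))].reset_index(drop=True)
        io.write_table(isi, out_dir / "isi.tsv")

        stage("sqtl")
        n_before = len(genotypes.snps)
        gf = filter_genotype_classes(genotypes, min_per_class=config.min_per_class)
        manifest["filtered"]["snps_genotype_class"] = n_before - len(gf.snps)
        sqtl = map_sqtl(isi, gf, sheet, annotation, cis_window=config.cis_window, joint_fdr=config.joint_fdr)
        manifest["filtered"].update({f"pairs_{k}": v for k, v in sqtl.attrs.get("skipped", {}).items()})
        io.write_table(sqtl, out_dir / "sqtl.tsv")

        stage("windows")
        couples = couples_from_sqtl(sqtl, gf, alpha=config.alpha, stratum="trans")
        ws = build_windows(couples, gap=config.gap)
        io.write_table(ws.windows, out_dir / "windows.tsv")
        if config.n_perm > 0:
            null = monte_carlo_null(couples, gf.sites, gap=config.gap, n_perm=config.n_perm, seed=config.seed)
            pd.DataFrame({"perm": range(null.n_perm), "max_n_couples": null.max_lengths}).to_csv(
                out_dir / "null_max_lengths.tsv", sep="\t", index=False
            )
            manifest["null"] = {
                "observed_max": null.observed_max,
                "null_max": max(null.max_lengths) if null.max_lengths else None,
                "empirical_p": null.empirical_p,
            }
            bandmasters = select_bandmaster(ws, null)
            io.write_table(bandmasters, out_dir / "bandmasters.tsv")

        stage("report")
        manifest["outputs"] = {
            p.name: _sha256(p) for p in sorted(out_dir.glob("*.tsv"))
        }
    except Exception as exc:
        failing = manifest["stages"][-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline failed in stage {failing!r}: {exc}") from exc

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
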