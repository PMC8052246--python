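"""Group-level splicing index (SI) per probe.

The splicing index of a probe contrasts the probe's gene-normalized
intensity between two groups:

    SI = log2[ (probe_a / gene_a) / (probe_b / gene_b) ]

where probe_x is the group-mean probe intensity and gene_x the group-mean
gene intensity.  With log2 inputs this is computed equivalently (and more
safely) as a difference of differences:

    SI = (P_a - G_a) - (P_b - G_b)

P = group-mean probe log2 signal, G = gene-level log2 intensity (mean over
the gene's probes of the per-probe group means).  A positive SI means the
probe is relatively more included in group A than in group B.

Significance per probe comes from a Welch two-sample test on per-sample
probe-minus-gene log2 ratios; the per-gene summary is the signed SI of the
maximum-|SI| probe.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from placsplice.io import ProbeAnnotation, ProbeMatrix

_TINY_P = np.nextafter(0.0, 1.0)


def _as_values(matrix: ProbeMatrix | pd.DataFrame) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, ProbeMatrix) else matrix


def _sample_gene_means(values: pd.DataFrame, annotation: ProbeAnnotation) -> pd.DataFrame:
    """Per-sample gene-level log2 signal: mean over the gene's probes, one row per gene."""
    gene_of = annotation.gene_of()
    unmapped = values.index.difference(gene_of.index)
    if len(unmapped):
        raise ValueError(f"probe {unmapped[0]!r} absent from annotation")
    return values.groupby(values.index.map(gene_of)).mean()


def gene_intensity(
    matrix: ProbeMatrix | pd.DataFrame,
    annotation: ProbeAnnotation,
    samples: Iterable[str],
) -> pd.Series:
    """Gene-level log2 intensity over a sample set.

    Defined as the mean over the gene's probes of the mean over the given
    samples of the log2 signal (equivalently the grand mean of the gene's
    probe x sample block).
    """
    samples = list(samples)
    if not samples:
        raise ValueError("samples must be non-empty")
    values = _as_values(matrix)[samples]
    counts = annotation.frame.groupby("gene_id").size()
    if (counts < 1).any():
        raise ValueError("gene with zero probes")
    out = _sample_gene_means(values, annotation).mean(axis=1)
    out.index.name = "gene_id"
    return out


def _batch_center(values: pd.DataFrame, batch: pd.Series, group_a: list[str], group_b: list[str]) -> pd.DataFrame:
    """Per-probe mean-centering within each batch that contains both groups.

    A batch containing only one of the two groups is left untouched:
    centering it would absorb the group contrast into the correction.
    """
    values = values.copy()
    in_a, in_b = set(group_a), set(group_b)
    for _, members in batch.groupby(batch).groups.items():
        cols = [s for s in members if s in values.columns]
        if not cols:
            continue
        if not (in_a & set(cols) and in_b & set(cols)):
            continue
        block = values[cols]
        values[cols] = block.sub(block.mean(axis=1), axis=0)
    return values


def compute_splice_index(
    matrix: ProbeMatrix | pd.DataFrame,
    annotation: ProbeAnnotation,
    group_a: Sequence[str],
    group_b: Sequence[str],
    batch: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-probe splicing index of group A versus group B.

    Parameters
    ----------
    matrix
        Probes x samples log2 intensities.
    group_a, group_b
        Disjoint sample-id sets, each with at least two members.
    batch
        Optional sample_id -> batch label mapping; probes are mean-centered
        within every batch that contains samples of both groups before the
        contrast is formed.

    Returns
    -------
    DataFrame with columns probe_id, gene_id, probe_index, si, p_value,
    gene_log_fc (per-gene log2 intensity difference, A minus B).
    """
    group_a, group_b = list(group_a), list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least two samples (variance undefined otherwise)")
    values = _as_values(matrix)[group_a + group_b].astype(float)
    if batch is not None:
        missing = [s for s in group_a + group_b if s not in set(batch.index)]
        if missing:
            raise ValueError(f"batch labels missing for samples: {missing}")
        values = _batch_center(values, batch, group_a, group_b)

    gene_of = annotation.gene_of()
    gene_means = _sample_gene_means(values, annotation)  # gene x sample
    # per-sample probe-minus-gene log2 ratio
    ratios = values.to_numpy() - gene_means.reindex(values.index.map(gene_of)).to_numpy()
    ratios = pd.DataFrame(ratios, index=values.index, columns=values.columns)

    ra, rb = ratios[group_a].to_numpy(), ratios[group_b].to_numpy()
    si = ra.mean(axis=1) - rb.mean(axis=1)
    with warnings.catch_warnings():
        # constant probes trigger a scipy precision warning; they are mapped to p=1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(ra, rb, axis=1, equal_var=False).pvalue
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance, equal-mean probes carry no evidence
    p = np.clip(p, _TINY_P, 1.0)

    ga = gene_means[group_a].mean(axis=1)
    gb = gene_means[group_b].mean(axis=1)
    gene_log_fc = (ga - gb).reindex(values.index.map(gene_of)).to_numpy()

    ann = annotation.frame.set_index("probe_id")
    out = pd.DataFrame(
        {
            "probe_id": values.index,
            "gene_id": values.index.map(gene_of),
            "probe_index": ann.loc[values.index, "probe_index"].to_numpy(),
            "si": si,
            "p_value": p,
            "gene_log_fc": gene_log_fc,
        }
    )
    return out.reset_index(drop=True)


def max_si_per_gene(results: pd.DataFrame) -> pd.DataFrame:
    """Per-gene signed SI of the maximum-|SI| probe.

    Ties in |SI| are broken by the lowest probe_index so the output is
    deterministic.  Returns columns gene_id, max_si, max_si_p, max_probe_id.
    """
    if results.empty:
        return pd.DataFrame(columns=["gene_id", "max_si", "max_si_p", "max_probe_id"])
    r = results.assign(_abs=results["si"].abs())
    r = r.sort_values(["gene_id", "_abs", "probe_index"], ascending=[True, False, True], kind="mergesort")
    top = r.groupby("gene_id", sort=True).head(1)
    return pd.DataFrame(
        {
            "gene_id": top["gene_id"].to_numpy(),
            "max_si": top["si"].to_numpy(),
            "max_si_p": top["p_value"].to_numpy(),
            "max_probe_id": top["probe_id"].to_numpy(),
        }
    ).reset_index(drop=True)


def select_spliced(summaries: pd.DataFrame, mode: str, threshold: float) -> list[str]:
    """Genes passing the significance (``mode='p'``) or magnitude (``mode='si'``) filter."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if mode == "p":
        keep = summaries["max_si_p"] < threshold
    elif mode == "si":
        keep = summaries["max_si"].abs() > threshold
    else:
        raise ValueError(f"unknown mode {mode!r} (expected 'p' or 'si')")
    return sorted(summaries.loc[keep, "gene_id"])


def intersect_lists(list_a: Iterable[str], list_b: Iterable[str]) -> list[str]:
    """Genes present in both lists, stable-sorted by gene_id."""
    return sorted(set(list_a) & set(list_b))
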