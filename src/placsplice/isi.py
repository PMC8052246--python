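"""Per-sample, per-gene Individual Splicing Index (ISI).

For a gene with n probes and a fixed selected probe, the ISI of a sample is

    ISI = F_selected / geomean(F_1 ... F_n)

where F is the probe's log2 fluorescence.  Note the quotient is taken on
log2 values, not on linear intensities: the statistic is a ratio of log
signals, which is how it is used as the splicing phenotype downstream.
It is dimensionless and invariant to rescaling all of a gene's F values by
a common positive factor.

The selected probe is fixed per gene across samples (per-sample
re-selection would break comparability across genotype groups).  Two
selection rules are provided:

* ``by_si`` (default): the probe with the largest |SI| in a reference
  group contrast — the rule used when the gene list comes from a disease
  splicing screen;
* ``by_max_f``: the probe with the largest mean F across samples — the
  literal "max probe" reading; in this mode ISI >= 1 always.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import gmean

from placsplice.io import ProbeAnnotation, ProbeMatrix

SIGNAL_FLOOR = 1.0  # log2 units; values at/below this are rejected, not floored


def _select_by_max_f(values: pd.DataFrame, ann: pd.DataFrame) -> pd.Series:
    """Per gene, the probe with the largest mean F across samples (ties: lowest probe_index)."""
    mean_f = values.mean(axis=1)
    f = ann.assign(_mean=mean_f.reindex(ann["probe_id"]).to_numpy())
    f = f.sort_values(["gene_id", "_mean", "probe_index"], ascending=[True, False, True], kind="mergesort")
    top = f.groupby("gene_id", sort=True).head(1)
    return top.set_index("gene_id")["probe_id"]


def _select_by_si(reference_si: pd.DataFrame) -> pd.Series:
    """Per gene, the probe with the largest |SI| in the reference contrast."""
    r = reference_si.assign(_abs=reference_si["si"].abs())
    r = r.sort_values(["gene_id", "_abs", "probe_index"], ascending=[True, False, True], kind="mergesort")
    top = r.groupby("gene_id", sort=True).head(1)
    return top.set_index("gene_id")["probe_id"]


def compute_isi(
    matrix: ProbeMatrix | pd.DataFrame,
    annotation: ProbeAnnotation,
    selection: str = "by_si",
    reference_si: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Individual Splicing Index per gene and sample.

    Parameters
    ----------
    matrix
        Probes x samples log2 intensities; every value must exceed the
        signal floor (log2 = 1.0) for the geometric mean to be meaningful.
    selection
        ``"by_si"`` (requires ``reference_si``, the output of
        :func:`placsplice.splice_index.compute_splice_index`) or ``"by_max_f"``.

    Returns
    -------
    Long DataFrame with columns gene_id, sample_id, isi, selected_probe_id.
    The selected probe is identical across samples within a gene.
    """
    values = matrix.values if isinstance(matrix, ProbeMatrix) else matrix
    arr = values.to_numpy(dtype=float)
    if arr.size and arr.min() < SIGNAL_FLOOR:
        i, j = np.argwhere(arr < SIGNAL_FLOOR)[0]
        raise ValueError(
            f"log2 signal {arr[i, j]:.3g} below floor {SIGNAL_FLOOR} for probe "
            f"{values.index[i]!r}, sample {values.columns[j]!r}; apply a signal floor upstream"
        )
    ann = annotation.frame
    if selection == "by_max_f":
        selected = _select_by_max_f(values, ann)
    elif selection == "by_si":
        if reference_si is None:
            raise ValueError("selection 'by_si' requires reference_si")
        selected = _select_by_si(reference_si)
    else:
        raise ValueError(f"unknown selection {selection!r} (expected 'by_si' or 'by_max_f')")

    records = []
    for gene, probes in ann.groupby("gene_id")["probe_id"]:
        block = values.loc[list(probes)].to_numpy()
        denom = gmean(block, axis=0)
        sel = selected[gene]
        num = values.loc[sel].to_numpy()
        isi = num / denom
        for sample, v in zip(values.columns, isi):
            records.append((gene, sample, v, sel))
    return pd.DataFrame(records, columns=["gene_id", "sample_id", "isi", "selected_probe_id"])
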