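"""Cohort-level supporting analyses.

Covariate screening: per-probe F-test of a single-variable linear model of
the log2 signal on a sample covariate (disease status, gestational age,
birth weight, sex), used to quantify how much of a disease signature is
also covariate-associated.  Gene-list overlap: percentage overlap and a
2x2 contingency chi-square against a stated background gene universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from placsplice.io import ProbeMatrix, SampleSheet


def covariate_association(
    matrix: ProbeMatrix | pd.DataFrame,
    sheet: SampleSheet,
    variable: str,
) -> pd.Series:
    """Per-probe p-value of a one-variable linear model of log2 signal.

    ``variable`` is a sample-sheet column; the pseudo-variable ``disease``
    (CTRL vs any disease group) is derived from ``group``.  Numeric
    variables enter untransformed; categorical ones as indicator contrasts
    (for a binary variable the F equals the squared pooled-variance t).
    Samples with a missing covariate value are dropped.
    """
    values = matrix.values if isinstance(matrix, ProbeMatrix) else matrix
    f = sheet.frame.set_index("sample_id")
    if variable == "disease" and "disease" not in f.columns:
        x = (f["group"] != "CTRL").astype(float)
    elif variable in f.columns:
        x = f[variable]
    else:
        raise ValueError(f"variable {variable!r} not in sample sheet")
    samples = [s for s in values.columns if s in x.index and pd.notna(x.loc[s])]
    x = x.loc[samples]
    if x.nunique() < 2:
        raise ValueError(f"variable {variable!r} is constant")
    if pd.api.types.is_numeric_dtype(x):
        design = x.to_numpy(dtype=float)[:, None]
    else:
        design = pd.get_dummies(x, drop_first=True).to_numpy(dtype=float)

    y = values[samples].to_numpy(dtype=float).T  # samples x probes
    n = y.shape[0]
    X = np.column_stack([np.ones(n), design])
    k = np.linalg.matrix_rank(X)
    if n - k < 1:
        raise ValueError("not enough samples for the model")
    q, _ = np.linalg.qr(X)
    fitted = q @ (q.T @ y)
    rss_full = ((y - fitted) ** 2).sum(axis=0)
    rss_null = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
    df1, df2 = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        fstat = ((rss_null - rss_full) / df1) / (rss_full / df2)
    p = stats.f.sf(fstat, df1, df2)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.Series(p, index=values.index, name="p_value").rename_axis("probe_id")


def overlap_fraction(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """Percentage of ``set_a`` also present in ``set_b``; 0 (with warning) for empty a."""
    a, b = set(set_a), set(set_b)
    if not a:
        warnings.warn("overlap_fraction: empty reference set", stacklevel=2)
        return 0.0
    return 100.0 * len(a & b) / len(a)


@dataclass
class OverlapResult:
    """2x2 gene-list overlap against a background universe."""

    n_a: int
    n_b: int
    n_common: int
    background_n: int
    observed_pct: float
    expected_pct: float
    chi2: float
    p_value: float


def list_overlap_chi2(
    list_a: Iterable[str],
    list_b: Iterable[str],
    background_n: int,
    yates: bool = False,
) -> OverlapResult:
    """Contingency chi-square for the overlap of two gene lists.

    ``observed_pct`` is 100*|a&b|/|a|; ``expected_pct`` is the background
    rate 100*|b|/background_n.  The chi-square (df=1, no continuity
    correction unless ``yates``) is computed on the 2x2 table
    [[common, a-only], [b-only, neither]].
    """
    a, b = set(list_a), set(list_b)
    n_a, n_b, n_common = len(a), len(b), len(a & b)
    union = n_a + n_b - n_common
    if background_n < union:
        raise ValueError(f"background_n={background_n} smaller than list union ({union})")
    table = np.array(
        [
            [n_common, n_a - n_common],
            [n_b - n_common, background_n - n_a - n_b + n_common],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        chi2, p = 0.0, 1.0  # a zero margin leaves no association to test
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    observed_pct = 100.0 * n_common / n_a if n_a else 0.0
    expected_pct = 100.0 * n_b / background_n
    return OverlapResult(
        n_a=n_a,
        n_b=n_b,
        n_common=n_common,
        background_n=background_n,
        observed_pct=observed_pct,
        expected_pct=expected_pct,
        chi2=float(chi2),
        p_value=float(p),
    )
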