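"""Reference-based leukocyte deconvolution.

Cell-type fractions are estimated per sample by non-negative least squares
of the (signature-gene, row-scaled) mixture vector on reference cell-type
expression profiles, with the weights renormalized to sum to one. Signature
genes are chosen per cell type by a specificity score — the type's share of
the gene's row sum — a deliberately simple scheme adequate for fractional
composition estimates on CPM-scale data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from wolfscan.radiometrics import welch_t

__all__ = [
    "select_signature_genes",
    "estimate_proportions",
    "deconvolve",
    "compare_celltype_proportions",
    "ProportionEstimate",
]


@dataclass(frozen=True)
class ProportionEstimate:
    """Cell-type fractions for one sample (sum to 1) plus the fit residual."""

    sample_id: str
    fractions: pd.Series
    residual: float


def select_signature_genes(ref: pd.DataFrame, n_per_type: int = 50) -> List[str]:
    """Union of the n_per_type most type-specific genes per cell type.

    Specificity of gene g for type k is ref[g, k] / Σ_k ref[g, k]; genes with
    an all-zero row never score. If fewer genes exist than requested, all are
    returned with a warning.
    """
    if n_per_type < 1:
        raise ValueError("n_per_type must be >= 1")
    if ref.shape[1] < 2:
        raise ValueError("need at least 2 cell types")
    row_sum = ref.sum(axis=1)
    expressed = ref.loc[row_sum > 0]
    if len(expressed) <= n_per_type:
        warnings.warn("fewer genes than requested; returning all expressed genes")
        return list(expressed.index)
    spec = expressed.div(expressed.sum(axis=1), axis=0)
    chosen: List[str] = []
    for ct in ref.columns:
        order = spec[ct].sort_values(ascending=False, kind="stable")
        for g in order.index[:n_per_type]:
            if g not in chosen:
                chosen.append(g)
    return chosen


def estimate_proportions(
    mixture: pd.Series, ref: pd.DataFrame, sample_id: str = ""
) -> ProportionEstimate:
    """NNLS fit of one mixture vector on reference columns → fractions.

    ``mixture`` and ``ref`` must already be restricted to signature genes and
    row-scaled (see :func:`deconvolve`). Collinear reference columns trigger
    a warning and a clipped pseudo-inverse fallback.
    """
    a = ref.to_numpy(dtype=float)
    b = mixture.loc[ref.index].to_numpy(dtype=float)
    if not np.any(b > 0):
        raise ValueError("mixture vector is all zero")
    if np.linalg.matrix_rank(a) < a.shape[1]:
        warnings.warn("reference columns are collinear; using pseudo-inverse fallback")
        w = np.clip(np.linalg.pinv(a) @ b, 0.0, None)
        resid = float(np.linalg.norm(a @ w - b))
    else:
        w, resid = nnls(a, b)
    total = w.sum()
    if total == 0:
        raise ValueError("degenerate fit: all weights zero")
    fractions = pd.Series(w / total, index=ref.columns)
    return ProportionEstimate(sample_id=sample_id, fractions=fractions, residual=resid)


def deconvolve(
    mixtures: pd.DataFrame, ref: pd.DataFrame, n_per_type: int = 50
) -> pd.DataFrame:
    """Estimate fractions for every sample column of a CPM mixture matrix.

    Signature genes are selected on the reference; both matrices are
    restricted to the shared signature genes and each gene row is scaled by
    the reference row maximum so all features live on [0, 1] in the
    reference. Returns samples × cell-types fractions.
    """
    sig = [g for g in select_signature_genes(ref, n_per_type) if g in mixtures.index]
    if not sig:
        raise ValueError("no shared signature genes between mixture and reference")
    ref_s = ref.loc[sig]
    row_max = ref_s.max(axis=1)
    row_max[row_max == 0] = 1.0
    ref_s = ref_s.div(row_max, axis=0)
    mix_s = mixtures.loc[sig].div(row_max, axis=0)
    rows = {}
    for sample in mixtures.columns:
        est = estimate_proportions(mix_s[sample], ref_s, sample_id=str(sample))
        rows[sample] = est.fractions
    return pd.DataFrame(rows).T[ref.columns]


def compare_celltype_proportions(
    group_a: pd.DataFrame, group_b: pd.DataFrame
) -> pd.DataFrame:
    """Per-cell-type Welch t-test between two groups of fraction estimates.

    Inputs are samples × cell-types frames with matching columns.
    """
    if list(group_a.columns) != list(group_b.columns):
        raise ValueError("groups must share cell-type columns")
    rows = []
    for ct in group_a.columns:
        t, df, p = welch_t(group_a[ct].to_numpy(), group_b[ct].to_numpy())
        rows.append({"cell_type": ct, "t": t, "df": df, "p": p})
    return pd.DataFrame(rows)
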