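"""Dose-correlated expression screen, module eigengenes and trait models.

Counts are log₂(CPM+1)-normalized; transcripts are screened for correlation
with per-animal total dose rate (gene significance, Spearman by default with
the student asymptotic p-value); the dose-correlated set is the intersection
of the top-|r| quantile and the nominal p cut. Module eigengenes (first PC of
the standardized module submatrix) are tested against dose with nested
maximum-likelihood linear models compared by likelihood-ratio tests, and
pathway gene sets are projected onto principal components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "cpm_normalize",
    "filter_low_expression",
    "flag_outlier_samples",
    "gene_significance",
    "dose_correlated_set",
    "module_eigengene",
    "module_trait_tests",
    "lrt_nested",
    "pathway_pca",
    "ModuleTraitResult",
]


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """log₂(CPM + 1) with per-sample library size = column sum."""
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero library size for samples: {bad}")
    return np.log2(counts.div(lib, axis=1) * 1e6 + 1.0)


def filter_low_expression(counts: pd.DataFrame, mean_min: float = 10.0) -> pd.DataFrame:
    """Keep genes with cross-sample mean raw count strictly > mean_min."""
    if counts.shape[1] < 1:
        raise ValueError("need at least one sample")
    return counts.loc[counts.mean(axis=1) > mean_min]


def flag_outlier_samples(normalized: pd.DataFrame, k_sd: float = 2.5) -> List[str]:
    """Flag samples whose mean inter-sample correlation is k_sd SDs below the
    cohort mean of those means."""
    n = normalized.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    x = normalized.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(corr, np.nan)
    mean_cor = np.nanmean(corr, axis=0)
    thr = mean_cor.mean() - k_sd * mean_cor.std(ddof=1)
    return list(normalized.columns[mean_cor < thr])


def _correlations(
    x: np.ndarray, trait: np.ndarray, method: str
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-row correlation of x (genes × samples) with trait; (r, defined)."""
    if method == "spearman":
        x = np.apply_along_axis(stats.rankdata, 1, x)
        trait = stats.rankdata(trait)
    xm = x - x.mean(axis=1, keepdims=True)
    tm = trait - trait.mean()
    sx = np.sqrt((xm**2).sum(axis=1))
    st = np.sqrt((tm**2).sum())
    defined = (sx > 0) & (st > 0)
    r = np.full(x.shape[0], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        r[defined] = (xm @ tm)[defined] / (sx[defined] * st)
    return np.clip(r, -1.0, 1.0), defined


def correlation_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided student asymptotic p: t = r√(n−2)/√(1−r²) on n−2 df.

    |r| = 1 is reported as the smallest positive float rather than 0.
    """
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) >= 1.0, np.finfo(float).tiny, p)
    return np.where(np.isnan(r), np.nan, np.maximum(p, np.finfo(float).tiny))


def gene_significance(
    normalized: pd.DataFrame,
    trait: Sequence[float],
    method: str = "spearman",
    n_permutations: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene correlation with a trait plus the student asymptotic p-value.

    With ``n_permutations`` > 0 the p-value is instead the permutation
    probability of |r| at least as large under trait shuffling (with the +1
    correction), which avoids the t approximation at very small n.

    Returns a frame indexed by gene with columns r, p, defined; constant
    genes are marked undefined and carry NaN.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    trait = np.asarray(trait, dtype=float)
    n = normalized.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples")
    if np.var(trait) == 0:
        raise ValueError("trait has no variance")
    x = normalized.to_numpy(dtype=float)
    r, defined = _correlations(x, trait, method)
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(x.shape[0])
        for _ in range(n_permutations):
            r_perm, _ = _correlations(x, rng.permutation(trait), method)
            exceed += np.abs(r_perm) >= np.abs(r)
        p = (exceed + 1.0) / (n_permutations + 1.0)
        p[~defined] = np.nan
    else:
        p = correlation_pvalue(r, n)
    return pd.DataFrame({"r": r, "p": p, "defined": defined}, index=normalized.index)


def dose_correlated_set(
    gs: pd.DataFrame,
    quantile: float = 0.95,
    alpha: float = 0.05,
    signed: bool = False,
) -> List[str]:
    """Genes with |r| ≥ the empirical |r| quantile AND p < alpha (ties kept).

    ``signed=True`` thresholds signed r against the signed-r quantile
    instead, capturing only the positive tail.
    """
    if gs.empty:
        raise ValueError("empty gene-significance table")
    ok = gs["defined"] if "defined" in gs else gs["r"].notna()
    score = gs.loc[ok, "r"] if signed else gs.loc[ok, "r"].abs()
    if score.empty:
        return []
    thr = float(np.quantile(score.to_numpy(), quantile))
    full_score = gs["r"] if signed else gs["r"].abs()
    sel = gs.index[(ok) & (full_score >= thr) & (gs["p"] < alpha)]
    return list(sel)


def module_eigengene(
    normalized: pd.DataFrame, modules: Mapping[str, str]
) -> pd.DataFrame:
    """First PC of each module's standardized submatrix, one column per module.

    Genes are z-scored across samples; the eigengene is the leading right
    singular vector (unit norm over samples), sign-oriented so its mean
    correlation with member genes is positive. Modules with < 2 genes present
    are skipped with a warning.
    """
    modules = pd.Series(dict(modules))
    out = {}
    for label in sorted(modules.unique()):
        genes = [g for g in modules.index[modules == label] if g in normalized.index]
        if len(genes) < 2:
            warnings.warn(f"module {label!r} has < 2 genes present; skipped")
            continue
        x = normalized.loc[genes].to_numpy(dtype=float)
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (x - mu) / sd
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        member_cor = np.array([np.corrcoef(eig, row)[0, 1] for row in z if row.std() > 0])
        if member_cor.size and member_cor.mean() < 0:
            eig = -eig
        out[label] = eig
    return pd.DataFrame(out, index=normalized.columns)


def lrt_nested(ll_full: float, ll_reduced: float, df: int) -> Tuple[float, int, float]:
    """Likelihood-ratio χ² = 2Δll, its df, and the χ² tail p (p = 1 at df 0)."""
    chi2 = max(2.0 * (ll_full - ll_reduced), 0.0)
    if df == 0:
        return chi2, 0, 1.0
    return chi2, df, float(stats.chi2.sf(chi2, df))


class ModuleTraitResult(NamedTuple):
    cor: float
    cor_p: float
    lrt_chi2: float
    lrt_df: int
    lrt_p: float


def _design(traits: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(traits))]
    for term in terms:
        if term == "dose:age":
            cols.append(traits["dose_rate"].to_numpy(float) * traits["age"].to_numpy(float))
        elif term == "dose":
            cols.append(traits["dose_rate"].to_numpy(float))
        elif term == "sex":
            sex = traits["sex"].astype(str)
            cols.append((sex == sorted(sex.unique())[-1]).to_numpy(float))
        else:
            cols.append(traits[term].to_numpy(float))
    return np.column_stack(cols)


FULL_TERMS = ("dose", "age", "dose:age", "monocyte", "granulocyte", "sex")


def module_trait_tests(
    eigengene: Sequence[float],
    traits: pd.DataFrame,
    drop_terms: Sequence[str] = ("dose", "dose:age"),
) -> ModuleTraitResult:
    """Correlation and nested-model LRT of one eigengene against dose.

    The full ML linear model regresses the eigengene on dose rate, age, their
    interaction, monocyte and granulocyte fractions, and sex (fixed); the
    reduced model drops ``drop_terms`` (default: the dose terms). Returns the
    dose correlation with its student p plus the LRT χ², df and p.
    """
    y = np.asarray(eigengene, dtype=float)
    if len(y) != len(traits):
        raise ValueError("eigengene and traits must align")
    missing = set(drop_terms) - set(FULL_TERMS)
    if missing:
        raise ValueError(f"unknown terms to drop: {sorted(missing)}")

    x_full = _design(traits, FULL_TERMS)
    rank = np.linalg.matrix_rank(x_full)
    if rank < x_full.shape[1]:
        # locate offending columns by incremental rank growth
        names = ("intercept",) + FULL_TERMS
        bad, cur = [], np.empty((len(y), 0))
        for j, name in enumerate(names):
            cand = np.column_stack([cur, x_full[:, j]])
            if np.linalg.matrix_rank(cand) == cur.shape[1]:
                bad.append(name)
            else:
                cur = cand
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    reduced_terms = [t for t in FULL_TERMS if t not in set(drop_terms)]
    x_red = _design(traits, reduced_terms)

    fit_full = sm.OLS(y, x_full).fit()
    fit_red = sm.OLS(y, x_red).fit()
    chi2, df, p = lrt_nested(
        fit_full.llf, fit_red.llf, x_full.shape[1] - x_red.shape[1]
    )

    dose = traits["dose_rate"].to_numpy(float)
    r, _ = _correlations(y[None, :], dose, method="pearson")
    cor_p = float(correlation_pvalue(r, len(y))[0])
    return ModuleTraitResult(float(r[0]), cor_p, chi2, df, p)


def pathway_pca(
    normalized: pd.DataFrame, gene_set: Sequence[str]
) -> Tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on a pathway's genes (gene-centered).

    Returns per-sample PC1/PC2 scores and the variance-explained fractions of
    all components.
    """
    present = [g for g in gene_set if g in normalized.index]
    if len(present) < 2:
        raise ValueError("need at least 2 pathway genes present in the matrix")
    x = normalized.loc[present].to_numpy(dtype=float).T  # samples × genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u * s
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    k = min(2, scores.shape[1])
    cols = [f"PC{i+1}" for i in range(k)]
    return pd.DataFrame(scores[:, :k], index=normalized.columns, columns=cols), frac
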