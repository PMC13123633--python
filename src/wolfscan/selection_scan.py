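"""Lineage-specific selection scan: WC FST → branch lengths → PBS → PBE.

Per site, the pairwise Weir & Cockerham (1984) θ estimators among the focal,
sister and outgroup populations are transformed into Cavalli-Sforza branch
lengths T = −ln(1 − FST). The population branch statistic

    PBS = (T_focal,sister + T_focal,outgroup − T_sister,outgroup) / 2

measures focal-branch length at each locus. Population branch excess (PBE)
subtracts a locus-specific expectation scaled from the sister-outgroup branch:

    PBE_i = PBS_i − T_so,i × median(PBS) / median(T_so)

so loci whose focal branch merely tracks genome-wide differentiation score
near zero while focal-specific divergence stands out. Negative PBE values are
zeroed, the zeroed vector is z-scored, upper-tail normal p-values are taken
and Benjamini-Hochberg adjusted, and outliers are called on strict
−log10(p_adj) thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from wolfscan.coords import gap_to_interval, point_in_interval
from wolfscan.errors import DegenerateNullError, UndefinedStatisticError
from wolfscan.genotype_qc import MISSING, GenotypeMatrix

__all__ = [
    "SiteAlleleSummary",
    "allele_summaries",
    "wc_fst",
    "cs_transform",
    "pbs",
    "pbe",
    "pbe_pvalues",
    "call_outliers",
    "nearest_gene",
    "annotate_outliers",
    "GeneAnnotationHit",
    "PBEScan",
    "PBEScanResults",
]


class SiteAlleleSummary(NamedTuple):
    """Per-population per-site allele summary (arrays over sites)."""

    n: np.ndarray  # diploid sample count with data
    p: np.ndarray  # alt-allele frequency
    h: np.ndarray  # observed heterozygote fraction


def allele_summaries(gm: GenotypeMatrix, population: str) -> SiteAlleleSummary:
    """Summarize dosages of one population: n with data, p̂, and h̄ per site."""
    idx = gm.sample_index(population)
    if idx.size == 0:
        raise ValueError(f"no samples in population {population!r}")
    dos = gm.dosages[:, idx]
    ok = dos != MISSING
    n = ok.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(ok, dos, 0).sum(axis=1) / (2.0 * n)
        h = np.where(ok, dos == 1, False).sum(axis=1) / n
    p[n == 0] = np.nan
    h[n == 0] = np.nan
    return SiteAlleleSummary(n=n, p=p, h=h)


def wc_fst(pop1: SiteAlleleSummary, pop2: SiteAlleleSummary) -> np.ndarray:
    """Per-site Weir & Cockerham (1984) θ̂ for two diploid populations.

    Vectorized over sites. Returns NaN (undefined) where either population
    lacks data, the pooled sample is monomorphic, mean sample size is ≤ 1, or
    the variance-component denominator vanishes. Slightly negative estimates
    are a property of the estimator and are passed through.
    """
    n1, p1, h1 = pop1
    n2, p2, h2 = pop2
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1.0)) * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = a / denom

    undefined = (
        ~np.isfinite(theta)
        | (n1 < 1)
        | (n2 < 1)
        | (nbar <= 1)
        | (pbar <= 0)
        | (pbar >= 1)
        | (denom == 0)
    )
    theta = np.where(undefined, np.nan, theta)
    return theta


def cs_transform(fst: np.ndarray, cap: float = 1.0 - 1e-9) -> np.ndarray:
    """Cavalli-Sforza branch length T = −ln(1 − FST).

    FST is clamped to [0, cap] first: the transform is undefined at 1 and
    negative estimator noise would yield negative branch lengths. NaN
    (undefined FST) passes through.
    """
    f = np.asarray(fst, dtype=float)
    clamped = np.clip(f, 0.0, cap)
    out = -np.log1p(-clamped)
    return np.where(np.isnan(f), np.nan, out)


def pbs(t_fs: np.ndarray, t_fo: np.ndarray, t_so: np.ndarray) -> np.ndarray:
    """Population branch statistic: focal branch length at each locus."""
    return (np.asarray(t_fs) + np.asarray(t_fo) - np.asarray(t_so)) / 2.0


def pbe(pbs_vec: np.ndarray, t_so_vec: np.ndarray) -> np.ndarray:
    """Raw population branch excess with median-scaled expectation.

    Medians are taken over defined (non-NaN) loci only; the result is NaN
    wherever either input is NaN.
    """
    pbs_vec = np.asarray(pbs_vec, dtype=float)
    t_so_vec = np.asarray(t_so_vec, dtype=float)
    if pbs_vec.shape != t_so_vec.shape or pbs_vec.size < 1:
        raise ValueError("pbs and T_so vectors must have equal length >= 1")
    ok = ~(np.isnan(pbs_vec) | np.isnan(t_so_vec))
    if not ok.any():
        raise ValueError("no defined loci")
    med_tso = np.median(t_so_vec[ok])
    if med_tso == 0:
        raise DegenerateNullError(
            "median sister-outgroup branch length is 0; drop invariant sites"
        )
    med_pbs = np.median(pbs_vec[ok])
    out = pbs_vec - t_so_vec * (med_pbs / med_tso)
    out[~ok] = np.nan
    return out


def pbe_pvalues(
    pbe_raw: np.ndarray, method: str = "normal"
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Zero negatives, z-score, upper-tail p, BH adjustment.

    ``method="normal"`` (default) takes the upper-tail standard-normal
    probability of the z-score — the conventional device, even though the
    zeroed distribution is zero-inflated, so these p-values rank rather than
    calibrate. ``method="empirical"`` instead uses the rank-based empirical
    upper-tail probability (count of values ≥ x over m).

    Returns ``(pbe, z, p, p_adj)`` aligned with the input; NaN loci are
    excluded from the mean/sd and from the BH family (m = defined loci).
    """
    if method not in ("normal", "empirical"):
        raise ValueError("method must be 'normal' or 'empirical'")
    raw = np.asarray(pbe_raw, dtype=float)
    ok = ~np.isnan(raw)
    if ok.sum() < 2:
        raise ValueError("need at least 2 defined loci")
    zeroed = np.where(raw > 0, raw, 0.0)
    vals = zeroed[ok]
    sd = vals.std(ddof=1)
    if sd == 0:
        raise UndefinedStatisticError("zero variance after zeroing negatives")
    z = np.full_like(raw, np.nan)
    z[ok] = (vals - vals.mean()) / sd
    p = np.full_like(raw, np.nan)
    if method == "normal":
        p[ok] = stats.norm.sf(z[ok])
    else:
        m = vals.size
        # fraction of loci at least as extreme, including the locus itself
        order = stats.rankdata(-vals, method="max")
        p[ok] = order / m
    p_adj = np.full_like(raw, np.nan)
    p_adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    out_pbe = np.where(ok, zeroed, np.nan)
    return out_pbe, z, p, p_adj


def call_outliers(
    p_adj: np.ndarray, thr_outlier: float = 8.0, thr_extreme: float = 15.0
) -> np.ndarray:
    """Tier labels from −log10(p_adj) against two strict thresholds."""
    if thr_outlier <= 0 or thr_extreme < thr_outlier:
        raise ValueError("require 0 < thr_outlier <= thr_extreme")
    p_adj = np.asarray(p_adj, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        neglog = -np.log10(p_adj)
    tier = np.full(p_adj.shape, "none", dtype=object)
    tier[neglog > thr_outlier] = "outlier"
    tier[neglog > thr_extreme] = "extreme"
    tier[np.isnan(p_adj)] = "none"
    return tier


@dataclass(frozen=True)
class GeneAnnotationHit:
    """Nearest-annotation call for one site; ``gene`` None = no annotation."""

    chrom: str
    pos: int
    gene: Optional[str]
    relation: str  # exonic / intronic / upstream / downstream / intergenic
    distance: int  # bp; 0 iff within the gene


def nearest_gene(chrom: str, pos: int, annotations: pd.DataFrame) -> GeneAnnotationHit:
    """Assign a site to its most proximate gene.

    ``annotations`` columns: chrom, start, end (0-based half-open), strand,
    gene, feature ∈ {gene, exon}. Inside a gene interval the distance is 0 and
    the relation is exonic when the site falls in one of that gene's exon
    rows (or no exon rows exist — transcript-derived annotations), intronic
    otherwise. Outside, the relation is up/downstream of the nearest gene by
    strand; ties break toward the lower-coordinate gene.
    """
    ann = annotations[annotations["chrom"] == chrom]
    genes = ann[ann["feature"] == "gene"].sort_values(["start", "gene"])
    if genes.empty:
        return GeneAnnotationHit(chrom, pos, None, "intergenic", -1)

    inside = genes[
        [point_in_interval(pos, s, e) for s, e in zip(genes["start"], genes["end"])]
    ]
    if not inside.empty:
        row = inside.iloc[0]  # lower-coordinate gene on overlap
        exons = ann[(ann["feature"] == "exon") & (ann["gene"] == row["gene"])]
        if exons.empty:
            relation = "exonic"
        else:
            in_exon = any(
                point_in_interval(pos, s, e) for s, e in zip(exons["start"], exons["end"])
            )
            relation = "exonic" if in_exon else "intronic"
        return GeneAnnotationHit(chrom, pos, str(row["gene"]), relation, 0)

    gaps = np.array(
        [gap_to_interval(pos, s, e) for s, e in zip(genes["start"], genes["end"])]
    )
    best = int(np.argmin(gaps))  # argmin takes the first = lower-coordinate gene
    row = genes.iloc[best]
    before = pos - 1 < row["start"]
    if row["strand"] == "+":
        relation = "upstream" if before else "downstream"
    else:
        relation = "downstream" if before else "upstream"
    return GeneAnnotationHit(chrom, pos, str(row["gene"]), relation, int(gaps[best]))


def annotate_outliers(table: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Nearest-gene report for every non-'none' tier row of a PBE table."""
    hits = []
    for _, row in table[table["tier"] != "none"].iterrows():
        hit = nearest_gene(row["chrom"], int(row["pos"]), annotations)
        hits.append(
            {
                "chrom": row["chrom"],
                "pos": int(row["pos"]),
                "tier": row["tier"],
                "p_adj": row["p_adj"],
                "gene": hit.gene if hit.gene is not None else ".",
                "relation": hit.relation,
                "distance": hit.distance,
            }
        )
    return pd.DataFrame(
        hits, columns=["chrom", "pos", "tier", "p_adj", "gene", "relation", "distance"]
    )


class PBEScan:
    """Three-population selection scan over a QC'd genotype matrix.

    Parameters name the population labels in ``gm.samples``; ``fit`` runs the
    full FST → T → PBS → PBE → p-value chain and returns results.
    """

    def __init__(
        self,
        gm: GenotypeMatrix,
        focal: str = "focal",
        sister: str = "sister",
        outgroup: str = "outgroup",
    ):
        self.gm = gm
        self.focal = focal
        self.sister = sister
        self.outgroup = outgroup

    def fit(self, thr_outlier: float = 8.0, thr_extreme: float = 15.0) -> "PBEScanResults":
        gm = self.gm
        sf = allele_summaries(gm, self.focal)
        ss = allele_summaries(gm, self.sister)
        so = allele_summaries(gm, self.outgroup)

        fst_fs = wc_fst(sf, ss)
        fst_fo = wc_fst(sf, so)
        fst_so = wc_fst(ss, so)
        t_fs, t_fo, t_so = (cs_transform(f) for f in (fst_fs, fst_fo, fst_so))
        pbs_vec = pbs(t_fs, t_fo, t_so)
        pbe_raw = pbe(pbs_vec, t_so)
        pbe_z, z, p, p_adj = pbe_pvalues(pbe_raw)
        tier = call_outliers(p_adj, thr_outlier, thr_extreme)

        table = pd.DataFrame(
            {
                "chrom": gm.sites["chrom"].to_numpy(),
                "pos": gm.sites["pos"].to_numpy(),
                "fst_fs": fst_fs,
                "fst_fo": fst_fo,
                "fst_so": fst_so,
                "T_fs": t_fs,
                "T_fo": t_fo,
                "T_so": t_so,
                "pbs": pbs_vec,
                "pbe_raw": pbe_raw,
                "pbe": pbe_z,
                "z": z,
                "p": p,
                "p_adj": p_adj,
                "tier": tier,
            }
        )
        return PBEScanResults(table, thr_outlier, thr_extreme)


@dataclass
class PBEScanResults:
    """Per-site PBE table plus outlier tallies."""

    table: pd.DataFrame
    thr_outlier: float
    thr_extreme: float

    @property
    def n_sites(self) -> int:
        return len(self.table)

    @property
    def n_analyzed(self) -> int:
        return int((~self.table["pbe_raw"].isna()).sum())

    @property
    def n_outliers(self) -> int:
        return int((self.table["tier"] != "none").sum())

    @property
    def n_extreme(self) -> int:
        return int((self.table["tier"] == "extreme").sum())

    def summary(self) -> str:
        lines = [
            "PBE selection scan",
            f"  sites:      {self.n_sites}",
            f"  analyzed:   {self.n_analyzed}",
            f"  outliers (-log10 p_adj > {self.thr_outlier:g}): {self.n_outliers}",
            f"  extreme  (-log10 p_adj > {self.thr_extreme:g}): {self.n_extreme}",
        ]
        return "\n".join(lines)
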