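"""Genotype-matrix container, call/site filters and windowed LD pruning.

The filtering pipeline mirrors standard RNAseq-genotyping QC: per-call
depth/quality masking, then site-level filters (autosomal biallelic SNPs,
missingness, polymorphism), then optional annotation subsetting and greedy
windowed LD pruning. Stage order is enforced through flags on the matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import List, Sequence

import numpy as np
import pandas as pd

from wolfscan.errors import PipelineOrderError

__all__ = ["GenotypeMatrix", "mask_low_quality", "site_filters", "annotation_subset", "ld_prune"]

MISSING = -1  # sentinel dosage for a missing call


@dataclass
class GenotypeMatrix:
    """Sites × samples allele dosages with per-call depth/quality.

    ``sites`` columns: chrom, pos (1-based), ref, alt (comma-separated when
    multiallelic) and optionally ``annotation``. ``dosages`` holds alt-allele
    counts in {0, 1, 2} with -1 for missing. ``samples`` columns: sample_id,
    population.
    """

    sites: pd.DataFrame
    dosages: np.ndarray
    depth: np.ndarray
    quality: np.ndarray
    samples: pd.DataFrame
    masked: bool = False
    site_filtered: bool = False

    def __post_init__(self):
        n_sites, n_samples = self.dosages.shape
        if len(self.sites) != n_sites:
            raise ValueError("sites table does not match dosage rows")
        if len(self.samples) != n_samples:
            raise ValueError("samples table does not match dosage columns")
        if self.depth.shape != self.dosages.shape or self.quality.shape != self.dosages.shape:
            raise ValueError("depth/quality must match dosage shape")
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    def missing_fraction(self) -> np.ndarray:
        """Per-site fraction of missing calls."""
        if self.n_samples == 0:
            return np.zeros(self.n_sites)
        return (self.dosages == MISSING).mean(axis=1)

    def subset_sites(self, index: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(index, dtype=int)
        return replace(
            self,
            sites=self.sites.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[idx].copy(),
            depth=self.depth[idx].copy(),
            quality=self.quality[idx].copy(),
        )

    def sample_index(self, population: str) -> np.ndarray:
        return np.flatnonzero((self.samples["population"] == population).to_numpy())


def mask_low_quality(gm: GenotypeMatrix, dp_min: int = 8, gq_min: int = 20) -> GenotypeMatrix:
    """Set calls with DP ≤ dp_min or GQ ≤ gq_min to missing (strict DP>, GQ>)."""
    if dp_min < 0 or gq_min < 0:
        raise ValueError("thresholds must be >= 0")
    bad = (gm.depth <= dp_min) | (gm.quality <= gq_min)
    dosages = gm.dosages.copy()
    dosages[bad] = MISSING
    return replace(gm, dosages=dosages, masked=True)


def _is_biallelic_snp(sites: pd.DataFrame) -> np.ndarray:
    ref = sites["ref"].astype(str)
    alt = sites["alt"].astype(str)
    single_alt = ~alt.str.contains(",")
    return (
        single_alt & (ref.str.len() == 1) & (alt.str.len() == 1) & (alt != ".")
    ).to_numpy()


def site_filters(
    gm: GenotypeMatrix, max_missing: float = 0.20, autosomes: Sequence[str] = ()
) -> GenotypeMatrix:
    """Retain autosomal biallelic SNPs with missingness strictly below
    ``max_missing`` that remain polymorphic after masking."""
    if not gm.masked:
        raise PipelineOrderError("site_filters requires mask_low_quality first")
    autosomes = set(autosomes)
    if not autosomes:
        raise ValueError("autosome set must be non-empty")
    keep = _is_biallelic_snp(gm.sites)
    keep &= gm.sites["chrom"].isin(autosomes).to_numpy()
    keep &= gm.missing_fraction() < max_missing

    # polymorphic among non-missing calls
    dos = np.ma.masked_equal(gm.dosages, MISSING)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-missing rows
        poly = (dos.max(axis=1) != dos.min(axis=1)).filled(False)
    keep &= np.asarray(poly)

    out = gm.subset_sites(np.flatnonzero(keep))
    out.site_filtered = True
    return out


def annotation_subset(gm: GenotypeMatrix, tag: str) -> GenotypeMatrix:
    """Retain sites whose ``annotation`` equals ``tag`` (e.g. "synonymous")."""
    if not gm.site_filtered:
        raise PipelineOrderError("annotation_subset requires site_filters first")
    if "annotation" not in gm.sites.columns:
        raise ValueError("sites carry no annotation column")
    keep = np.flatnonzero((gm.sites["annotation"] == tag).to_numpy())
    if keep.size == 0:
        warnings.warn(f"no sites tagged {tag!r}; result is empty")
    out = gm.subset_sites(keep)
    out.site_filtered = True
    return out


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over pairwise-complete
    samples; 0 when < 2 complete shared samples or either is constant."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    if xv.std() == 0 or yv.std() == 0:
        return 0.0
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def _window_starts(n: int, window: int, step: int) -> List[int]:
    if n <= window:
        return [0] if n else []
    return list(range(0, n - 1, step))


def ld_prune(
    gm: GenotypeMatrix, window: int = 50, step: int = 10, r2_max: float = 0.1
) -> List[int]:
    """Greedy windowed LD pruning; returns the retained site indices.

    Within each window of ``window`` consecutive sites per chromosome
    (advancing by ``step``), violating pairs (r² > r2_max) are resolved by
    dropping the later-positioned site, first offending pair first, until no
    retained pair in the window violates.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if not (window > step > 0):
        raise ValueError("require window > step > 0")
    if not (0 < r2_max < 1):
        raise ValueError("require 0 < r2_max < 1")
    if not gm.site_filtered:
        raise PipelineOrderError("ld_prune requires site_filters first")

    kept = np.ones(gm.n_sites, dtype=bool)
    for _, grp in gm.sites.groupby("chrom", sort=False):
        chrom_idx = grp.index.to_numpy()
        for start in _window_starts(len(chrom_idx), window, step):
            win = chrom_idx[start : start + window]
            changed = True
            while changed:
                changed = False
                active = [i for i in win if kept[i]]
                for a_pos, i in enumerate(active):
                    for j in active[a_pos + 1 :]:
                        if _pairwise_r2(gm.dosages[i], gm.dosages[j]) > r2_max:
                            kept[j] = False  # drop the later-positioned site
                            changed = True
                            break
                    if changed:
                        break
    return list(np.flatnonzero(kept))
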