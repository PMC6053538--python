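"""SNP calling from read counts and the marker filtering cascade.

Calling: a site x individual cell needs depth >= 10; the within-individual
alternate read fraction then decides the call (below 30% -> reference
homozygote, above 70% -> alternate homozygote, otherwise heterozygote; the
30% boundary itself calls heterozygote).  Sites are SNPs only if at least
one individual is heterozygous.  Samples with more than 20% missing calls
are removed, then sites called in fewer than 95% of samples or lying on
unanchored scaffolds.  Branch-specific filters: Hardy-Weinberg exact test
with Benjamini-Hochberg FDR (retain adjusted p > 0.05), LD pruning (r^2
window or base-pair spacing), and population minor-allele-frequency tiers.
Every filter removes calls, never edits them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .simulate import GenotypeMatrix, SiteCallTable

__all__ = [
    "FilterConfig",
    "call_genotypes",
    "polymorphic_sites",
    "filter_samples",
    "filter_sites",
    "hwe_exact",
    "fdr_adjust",
    "ld_prune",
    "maf_tier",
    "subset_sites",
    "apply_filter_cascade",
]


@dataclass
class FilterConfig:
    min_depth: int = 10
    intra_maf: float = 0.30
    sample_missing_max: float = 0.20
    site_callrate_min: float = 0.95
    maf_tiers: tuple = (0.01, 0.05, 0.10, 0.15, 0.30, 0.40)
    hwe_alpha: float = 0.05
    ld_r2_max: float = 0.40
    ld_window: int = 50
    min_spacing: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.intra_maf <= 0.5:
            raise ValueError("intra_maf must lie in (0, 0.5]")
        for name in ("sample_missing_max", "site_callrate_min", "hwe_alpha", "ld_r2_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.min_depth < 0 or self.ld_window < 1 or self.min_spacing < 0:
            raise ValueError("thresholds out of range")


def call_genotypes(site_calls: SiteCallTable, cfg: FilterConfig | None = None) -> GenotypeMatrix:
    """Call genotypes from read counts.

    depth < ``min_depth`` -> missing; otherwise the alternate read fraction
    f decides: f < intra_maf -> -1, f > 1 - intra_maf -> +1, else 0
    (boundaries inclusive to the heterozygote).
    """
    cfg = cfg or FilterConfig()
    depth = site_calls.depth
    alt = site_calls.alt_reads
    codes = np.full(depth.shape, np.nan)
    ok = depth >= cfg.min_depth
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    codes[ok & (frac < cfg.intra_maf)] = -1.0
    codes[ok & (frac > 1.0 - cfg.intra_maf)] = 1.0
    codes[ok & (frac >= cfg.intra_maf) & (frac <= 1.0 - cfg.intra_maf)] = 0.0
    return GenotypeMatrix(codes=codes, samples=list(site_calls.samples), sites=site_calls.sites)


def polymorphic_sites(genotypes: GenotypeMatrix) -> np.ndarray:
    """True for sites where at least one non-missing call is heterozygous."""
    return np.nansum(genotypes.codes == 0.0, axis=0) > 0


def filter_samples(genotypes: GenotypeMatrix, cfg: FilterConfig | None = None) -> GenotypeMatrix:
    """Remove samples whose missing-call fraction exceeds the threshold."""
    cfg = cfg or FilterConfig()
    if genotypes.m == 0:
        return genotypes
    miss = np.isnan(genotypes.codes).mean(axis=1)
    keep = miss <= cfg.sample_missing_max
    return GenotypeMatrix(
        codes=genotypes.codes[keep],
        samples=[s for s, k in zip(genotypes.samples, keep) if k],
        sites=genotypes.sites,
    )


def filter_sites(
    genotypes: GenotypeMatrix,
    scaffold_anchored: dict | None = None,
    cfg: FilterConfig | None = None,
) -> GenotypeMatrix:
    """Remove sites called in too few samples and sites on unanchored
    scaffolds (``scaffold_anchored`` maps scaffold name -> bool; scaffolds
    absent from the map count as anchored)."""
    cfg = cfg or FilterConfig()
    if genotypes.n == 0:
        return genotypes
    callrate = 1.0 - np.isnan(genotypes.codes).mean(axis=0)
    keep = callrate >= cfg.site_callrate_min
    if scaffold_anchored is not None:
        anchored = genotypes.sites["scaffold"].map(lambda s: scaffold_anchored.get(s, True)).to_numpy()
        keep &= anchored
    return subset_sites(genotypes, keep)


def subset_sites(genotypes: GenotypeMatrix, mask: np.ndarray) -> GenotypeMatrix:
    return GenotypeMatrix(
        codes=genotypes.codes[:, mask],
        samples=list(genotypes.samples),
        sites=genotypes.sites.loc[mask].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test p-value for one site.

    Conditions on the observed allele counts and sums, over all feasible
    heterozygote counts of matching parity, the probabilities of tables no
    more probable than the observed one (two-sided exact test).  Returns a
    p-value in (0, 1].
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no data: all genotype counts are zero")
    na = 2 * n_aa + n_ab  # copies of allele a
    rare = min(na, 2 * n - na)
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(n_ab = h | n, na) up to a constant:
    #   n! / (naa! h! nbb!) * 2^h   with naa = (na - h) / 2
    n_rare_hom = (rare - hets) // 2
    n_common_hom = n - hets - n_rare_hom
    logp = (
        hets * np.log(2.0)
        - gammaln(n_rare_hom + 1)
        - gammaln(hets + 1)
        - gammaln(n_common_hom + 1)
    )
    logp -= logsumexp(logp)
    obs = n_ab
    p_obs = logp[np.searchsorted(hets, obs)]
    p = float(np.exp(logp[logp <= p_obs + 1e-12]).sum())
    return min(p, 1.0)


def hwe_exact_sites(genotypes: GenotypeMatrix) -> np.ndarray:
    """Exact HWE p-value per site (NaN where a site has no calls)."""
    codes = genotypes.codes
    out = np.full(genotypes.m, np.nan)
    for j in range(genotypes.m):
        col = codes[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        out[j] = hwe_exact(int((col == -1).sum()), int((col == 0).sum()), int((col == 1).sum()))
    return out


def fdr_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# LD pruning


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of genotype codes over pairwise-complete
    observations (composite genotypic r^2; phase is not used)."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return 0.0
    xv, yv = x[ok], y[ok]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = ((xv - xv.mean()) * (yv - yv.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_prune(
    genotypes: GenotypeMatrix,
    cfg: FilterConfig | None = None,
    mode: str = "r2-window",
) -> np.ndarray:
    """Greedy LD pruning mask (True = keep).

    ``r2-window``: scan sites in order within each scaffold; a site is
    dropped if its genotypic r^2 with any *kept* site among the previous
    ``ld_window`` markers exceeds ``ld_r2_max`` (the earlier site of an
    offending pair is always the one kept).  ``spacing``: greedy
    left-to-right retention requiring at least ``min_spacing`` bp between
    consecutive kept sites.  Positions must be sorted within scaffold.
    """
    cfg = cfg or FilterConfig()
    sites = genotypes.sites
    keep = np.zeros(genotypes.m, dtype=bool)
    for sc in pd.unique(sites["scaffold"]):
        idx = np.flatnonzero((sites["scaffold"] == sc).to_numpy())
        pos = sites["pos"].to_numpy()[idx]
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"positions not sorted within scaffold {sc!r}")
        if mode == "spacing":
            last = None
            for k, j in enumerate(idx):
                if last is None or pos[k] - last >= cfg.min_spacing:
                    keep[j] = True
                    last = pos[k]
        elif mode == "r2-window":
            kept_local: list[int] = []  # positions within idx of kept markers
            for k, j in enumerate(idx):
                window = [q for q in kept_local if k - q < cfg.ld_window]
                drop = any(
                    _pairwise_r2(genotypes.codes[:, idx[q]], genotypes.codes[:, j]) > cfg.ld_r2_max
                    for q in window
                )
                if not drop:
                    keep[j] = True
                    kept_local.append(k)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return keep


def maf_tier(genotypes: GenotypeMatrix, threshold: float) -> np.ndarray:
    """Mask of sites whose population minor-allele frequency strictly
    exceeds ``threshold`` (computed from non-missing calls)."""
    codes = genotypes.codes
    with np.errstate(invalid="ignore"):
        p = np.nanmean(codes + 1.0, axis=0) / 2.0  # alt-allele frequency
    maf = np.minimum(p, 1.0 - p)
    return np.where(np.isnan(maf), False, maf > threshold)


# ---------------------------------------------------------------------------
# cascade driver


def apply_filter_cascade(
    site_calls: SiteCallTable,
    scaffold_anchored: dict | None = None,
    cfg: FilterConfig | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Run calling -> polymorphism -> sample filter -> site filters and
    report per-stage counts.  Branch-specific filters (HWE, LD, maf tiers)
    are applied separately by the analyses that need them."""
    cfg = cfg or FilterConfig()
    stages = []
    g = call_genotypes(site_calls, cfg)
    stages.append({"stage": "called", "samples": g.n, "sites": g.m})
    g = subset_sites(g, polymorphic_sites(g))
    stages.append({"stage": "polymorphic", "samples": g.n, "sites": g.m})
    g = filter_samples(g, cfg)
    stages.append({"stage": "sample_missingness", "samples": g.n, "sites": g.m})
    g = filter_sites(g, scaffold_anchored, cfg)
    stages.append({"stage": "site_callrate_anchored", "samples": g.n, "sites": g.m})
    return g, pd.DataFrame(stages)
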