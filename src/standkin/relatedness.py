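"""Genomic and pedigree relatedness.

The realized genomic relationship matrix follows the VanRaden form

    G = (M - P) (M - P)' / (2 * sum_i p_i (1 - p_i))

with genotypes M coded -1 / 0 / +1 and the centering matrix P holding
2 (p_i - 0.5) in column i, p_i being the frequency of the +1-coded allele
at locus i.  (The minus sign is the only choice that centers M to mean
zero under Hardy-Weinberg; the coding makes centering orientation-
consistent, so p_i is the frequency of the allele coded +1, not folded to
the minor allele.)  The diagonal G_ii is 1 for a non-inbred individual
matching population frequencies, so genomic inbreeding is G_ii - 1:
positive means more homozygous than the population expectation.

Pedigree-expected relatedness A comes from the recursive tabular method:
A_ii = 1 + A_{sire,dam} / 2 and A_ij = (A_{j,sire(i)} + A_{j,dam(i)}) / 2,
giving the classical 0.5 (parent-offspring, full sibs), 0.25 (half sibs),
and 1 (parent vs its selfed offspring).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix, Pedigree, pedigree_pairs

__all__ = [
    "allele_freqs",
    "grm",
    "genomic_inbreeding",
    "pedigree_additive_matrix",
    "compare_realized_expected",
]


def allele_freqs(genotypes: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Frequency of the +1-coded allele per site, from non-missing calls."""
    codes = genotypes.codes if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes, float)
    if codes.size and np.isnan(codes).all(axis=0).any():
        raise ValueError("site with no non-missing calls")
    with np.errstate(invalid="ignore"):
        return np.nanmean(codes + 1.0, axis=0) / 2.0


def grm(
    genotypes: GenotypeMatrix | np.ndarray,
    freqs: np.ndarray | None = None,
    missing: str = "mean",
) -> np.ndarray:
    """VanRaden genomic relationship matrix.

    Parameters
    ----------
    genotypes
        n x m codes in {-1, 0, +1, NaN}.
    freqs
        +1-allele frequencies per locus.  Default: estimated in-sample,
        which reproduces the well-known downward bias of realized
        relatedness in samples of related individuals; pass known truth
        for simulation studies.
    missing
        "mean" imputes a missing code to its locus mean 2p - 1 (i.e., zero
        after centering); "pairwise" rescales each pair's cross-product by
        the complete-locus fraction.
    """
    codes = genotypes.codes if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes, float)
    if codes.ndim != 2:
        raise ValueError("genotypes must be 2-D")
    p = allele_freqs(codes) if freqs is None else np.asarray(freqs, float)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom == 0:
        raise ValueError("all sites monomorphic: zero scaling denominator")
    center = 2.0 * (p - 0.5)
    Z = codes - center[None, :]
    nanmask = np.isnan(Z)
    if missing == "mean":
        Z = np.where(nanmask, 0.0, Z)
        G = Z @ Z.T / denom
    elif missing == "pairwise":
        Zf = np.where(nanmask, 0.0, Z)
        obs = (~nanmask).astype(float)
        cross = Zf @ Zf.T
        counts = obs @ obs.T
        m = codes.shape[1]
        with np.errstate(invalid="ignore", divide="ignore"):
            G = cross * (m / np.maximum(counts, 1)) / denom
    else:
        raise ValueError(f"unknown missing-data mode {missing!r}")
    return (G + G.T) / 2.0


def genomic_inbreeding(G: np.ndarray) -> np.ndarray:
    """Genomic inbreeding per individual: G_ii - 1."""
    return np.diag(np.asarray(G)) - 1.0


def pedigree_additive_matrix(pedigree: Pedigree) -> pd.DataFrame:
    """Expected additive relationship matrix A by the tabular method.

    Founders are assumed unrelated and non-inbred.  Returns a DataFrame
    indexed by individual id (symmetric).
    """
    t = pedigree.table.sort_values("generation", kind="stable")
    ids = list(t["id"])
    idx = {iid: k for k, iid in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    sire = [t.iloc[k]["sire"] for k in range(n)]
    dam = [t.iloc[k]["dam"] for k in range(n)]
    for i in range(n):
        s = idx[sire[i]] if sire[i] is not None else None
        d = idx[dam[i]] if dam[i] is not None else None
        for j in range(i):
            a_js = A[j, s] if s is not None else 0.0
            a_jd = A[j, d] if d is not None else 0.0
            A[i, j] = A[j, i] = 0.5 * (a_js + a_jd)
        if s is not None and d is not None:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
    # back to the pedigree's own ordering
    order = [idx[iid] for iid in pedigree.ids]
    A = A[np.ix_(order, order)]
    return pd.DataFrame(A, index=pedigree.ids, columns=pedigree.ids)


def compare_realized_expected(
    G: np.ndarray,
    samples: list,
    pedigree: Pedigree,
    pairs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Summarize realized relatedness per pedigree-expected category.

    For every related pair (from ``pedigree_pairs`` unless given), reads
    the realized G entry and reports per category: pair count, expected
    value, mean, variance, and mean deviation (realized - expected).
    """
    if pairs is None:
        pairs = pedigree_pairs(pedigree)
    loc = {s: k for k, s in enumerate(samples)}
    rows = []
    for _, r in pairs.iterrows():
        if r["i"] in loc and r["j"] in loc:
            rows.append(
                {
                    "category": r["category"],
                    "expected": r["expected"],
                    "realized": float(G[loc[r["i"]], loc[r["j"]]]),
                }
            )
    df = pd.DataFrame(rows, columns=["category", "expected", "realized"])
    if df.empty:
        return pd.DataFrame(
            columns=["category", "n_pairs", "expected", "mean_realized", "var_realized", "mean_deviation"]
        )
    out = (
        df.groupby(["category", "expected"], as_index=False)
        .agg(n_pairs=("realized", "size"), mean_realized=("realized", "mean"), var_realized=("realized", "var"))
        .fillna({"var_realized": 0.0})
    )
    out["mean_deviation"] = out["mean_realized"] - out["expected"]
    return out[["category", "n_pairs", "expected", "mean_realized", "var_realized", "mean_deviation"]]
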