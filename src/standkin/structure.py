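"""Interspecific differentiation and two-cluster ancestry.

Per-locus Fst uses the Weir-Cockerham (1984) variance-components
estimator computed from genotype counts in the two labeled groups; between
two barely diverged sister species the per-locus distribution is L-shaped,
with mean well above median.  Species assignment uses a lightweight
maximum-likelihood admixture model for K = 2 fitted by EM (each allele
copy of individual i comes from cluster A with probability q_i and is the
alternate allele with the cluster's frequency); individuals are then
labeled purebred or admixed by thresholds on q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix

__all__ = ["per_locus_fst", "AdmixtureEM", "admixture_em", "assign_species"]


def per_locus_fst(genotypes: GenotypeMatrix | np.ndarray, labels) -> pd.DataFrame:
    """Weir-Cockerham per-locus Fst between two labeled groups.

    ``labels`` holds exactly two distinct group labels, one per individual.
    Returns a frame with per-locus variance components ``a`` (between
    populations), ``b`` (between individuals within), ``c`` (within
    individuals) and ``fst = a / (a + b + c)``; loci where the denominator
    is zero (monomorphic overall) get NaN.  Summaries: ``mean`` / ``median``
    over defined loci, and the pooled ratio-of-sums estimator, are in
    ``.attrs``.
    """
    codes = genotypes.codes if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes, float)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError("need exactly two group labels")
    r = 2
    stats = []
    for g in groups:
        sub = codes[labels == g]
        nonmiss = ~np.isnan(sub)
        n_i = nonmiss.sum(axis=0).astype(float)
        if (n_i == 0).any():
            raise ValueError("locus with no calls in one group")
        p_i = np.nansum(sub + 1.0, axis=0) / (2.0 * n_i)
        h_i = np.nansum(sub == 0.0, axis=0) / n_i  # observed het frequency
        stats.append((n_i, p_i, h_i))
    n1, p1, h1 = stats[0]
    n2, p2, h2 = stats[1]
    nsum = n1 + n2
    nbar = nsum / r
    nc = (nsum - (n1**2 + n2**2) / nsum) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / nsum
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / nsum
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
    c = hbar / 2.0
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(denom != 0, a / denom, np.nan)
    out = pd.DataFrame({"a": a, "b": b, "c": c, "fst": fst})
    ok = ~np.isnan(fst)
    out.attrs["mean"] = float(np.mean(fst[ok])) if ok.any() else float("nan")
    out.attrs["median"] = float(np.median(fst[ok])) if ok.any() else float("nan")
    ssum = float(denom[ok].sum())
    out.attrs["pooled"] = float(a[ok].sum() / ssum) if ok.any() and ssum != 0 else float("nan")
    return out


@dataclass
class AdmixtureEM:
    """Maximum-likelihood two-cluster admixture model fitted by EM.

    Each of an individual's two allele copies at a locus originates from
    cluster A with probability q_i (else cluster B) and is the alternate
    allele with that cluster's frequency.  The EM alternates expected
    cluster memberships of allele copies with updates of q and the cluster
    frequencies; the observed-data log-likelihood is non-decreasing.

    Attributes after ``fit``: ``q`` (per-individual cluster-A ancestry),
    ``freqs`` (2 x m cluster allele frequencies), ``loglik_trace``,
    ``converged``, ``flat_likelihood`` (True when the two clusters are
    indistinguishable and q is unidentifiable).
    """

    tol: float = 1e-8
    max_iter: int = 1000
    seed: int = 0
    q: np.ndarray = field(default=None, repr=False)
    freqs: np.ndarray = field(default=None, repr=False)
    loglik_trace: list = field(default_factory=list, repr=False)
    converged: bool = False
    flat_likelihood: bool = False

    def fit(self, genotypes: GenotypeMatrix | np.ndarray) -> "AdmixtureEM":
        codes = genotypes.codes if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes, float)
        g = codes + 1.0  # alt dosage 0/1/2, NaN missing
        n, m = g.shape
        obs = ~np.isnan(g)
        g0 = np.where(obs, g, 0.0)
        two = 2.0 * obs  # allele copies observed per cell
        rng = np.random.default_rng(self.seed)
        # initialize ancestry from the leading principal axis of the
        # centered dosage matrix (min-max scaled into (0, 1)), which puts
        # the two clusters at opposite ends and lets the EM converge in a
        # few dozen iterations; cluster frequencies start as q-weighted
        # allele frequencies
        base = np.where(obs.any(axis=0), g0.sum(axis=0) / np.maximum(two.sum(axis=0), 1), 0.5)
        Z = np.where(obs, g - 2 * base[None, :], 0.0)
        u, s, _ = np.linalg.svd(Z, full_matrices=False)
        scores = u[:, 0] * s[0]
        span = scores.max() - scores.min()
        if span > 0:
            q = 0.05 + 0.9 * (scores - scores.min()) / span
        else:
            q = rng.uniform(0.2, 0.8, size=n)
        w0 = (q[:, None] * two) / 2.0
        w1 = ((1 - q)[:, None] * two) / 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            f0 = (q[:, None] * g0).sum(axis=0) / np.maximum((2 * w0).sum(axis=0), 1e-9)
            f1 = ((1 - q)[:, None] * g0).sum(axis=0) / np.maximum((2 * w1).sum(axis=0), 1e-9)
        f = np.clip(np.vstack([f0, f1]), 0.01, 0.99)
        anchor = int(np.argmax(q))
        eps = 1e-9

        def loglik(q, f):
            pi = np.clip(
                q[:, None] * f[0][None, :] + (1 - q)[:, None] * f[1][None, :], eps, 1 - eps
            )
            return float(np.sum((g0 * np.log(pi) + (two - g0) * np.log(1 - pi))[obs]))

        def em_step(q, f):
            pi = np.clip(
                q[:, None] * f[0][None, :] + (1 - q)[:, None] * f[1][None, :], eps, 1 - eps
            )
            # responsibilities of cluster A for alt and ref allele copies
            rA_alt = q[:, None] * f[0][None, :] / pi
            rA_ref = q[:, None] * (1 - f[0])[None, :] / (1 - pi)
            altA = g0 * rA_alt
            refA = (two - g0) * rA_ref
            a_copies = altA + refA
            q_new = np.clip(a_copies.sum(axis=1) / np.maximum(two.sum(axis=1), 1), eps, 1 - eps)
            denomA = a_copies.sum(axis=0)
            denomB = two.sum(axis=0) - denomA
            f0 = altA.sum(axis=0) / np.maximum(denomA, eps)
            f1 = (g0 - altA).sum(axis=0) / np.maximum(denomB, eps)
            return q_new, np.clip(np.vstack([f0, f1]), eps, 1 - eps)

        # SQUAREM-accelerated EM: extrapolate through two plain EM steps,
        # falling back to the second EM iterate whenever the extrapolation
        # does not improve the likelihood, which keeps the trace monotone
        self.loglik_trace = [loglik(q, f)]
        for _ in range(self.max_iter):
            q1, f1_ = em_step(q, f)
            q2, f2_ = em_step(q1, f1_)
            r_q, r_f = q1 - q, f1_ - f
            v_q, v_f = (q2 - q1) - r_q, (f2_ - f1_) - r_f
            vnorm = np.sqrt((v_q**2).sum() + (v_f**2).sum())
            if vnorm > 0:
                alpha = -np.sqrt((r_q**2).sum() + (r_f**2).sum()) / vnorm
                alpha = min(alpha, -1.0)
                q_x = np.clip(q - 2 * alpha * r_q + alpha**2 * v_q, eps, 1 - eps)
                f_x = np.clip(f - 2 * alpha * r_f + alpha**2 * v_f, eps, 1 - eps)
                # stabilization step after the extrapolation
                q_x, f_x = em_step(q_x, f_x)
                ll_x = loglik(q_x, f_x)
                ll_2 = loglik(q2, f2_)
                if ll_x >= ll_2:
                    q, f, ll = q_x, f_x, ll_x
                else:
                    q, f, ll = q2, f2_, ll_2
            else:
                q, f = q2, f2_
                ll = loglik(q, f)
            self.loglik_trace.append(ll)
            if abs(ll - self.loglik_trace[-2]) < self.tol * (1.0 + abs(ll)):
                self.converged = True
                break
        # label anchoring: cluster A is the one favored by the individual
        # that started with the highest q
        if q[anchor] < 0.5:
            q = 1.0 - q
            f = f[::-1]
        self.q = q
        self.freqs = f
        # unidentifiable-q diagnostic: the two-cluster fit must beat the
        # one-cluster model (pooled frequencies, q irrelevant) by more than
        # its extra parameter count, else the likelihood is flat in q
        pooled = np.clip(base, eps, 1 - eps)
        ll_flat = float(
            np.sum((g0 * np.log(pooled)[None, :] + (two - g0) * np.log(1 - pooled)[None, :])[obs])
        )
        self.flat_likelihood = bool(self.loglik_trace[-1] - ll_flat < n + m)
        return self

    def assign(self, hi: float = 0.9, lo: float = 0.1) -> np.ndarray:
        if self.q is None:
            raise RuntimeError("call fit first")
        return assign_species(self.q, hi=hi, lo=lo)


def admixture_em(
    genotypes, K: int = 2, tol: float = 1e-6, max_iter: int = 1000, seed: int = 0
) -> AdmixtureEM:
    """Functional wrapper around :class:`AdmixtureEM` (K = 2 only)."""
    if K != 2:
        raise ValueError("only K = 2 is supported")
    return AdmixtureEM(tol=tol, max_iter=max_iter, seed=seed).fit(genotypes)


def assign_species(q: np.ndarray, hi: float = 0.9, lo: float = 0.1) -> np.ndarray:
    """Threshold ancestry proportions into labels: q >= hi -> "A",
    q <= lo -> "B", otherwise "admixed" (both boundaries inclusive)."""
    q = np.asarray(q, dtype=float)
    out = np.full(q.shape, "admixed", dtype=object)
    out[q >= hi] = "A"
    out[q <= lo] = "B"
    return out
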