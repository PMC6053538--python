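"""Enrichment-efficiency and reproducibility metrics.

On-target fraction (reads overlapping any capture target by at least one
base, or fully contained when requested), per-target breadth of coverage
and mean depth from a base-level pileup, replicate concordance of
per-individual call sets, cross-platform genotype concordance, and the
regression of per-sample on-target fraction on mean read length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from intervaltree import IntervalTree

__all__ = [
    "on_target_fraction",
    "breadth_and_depth",
    "replicate_concordance",
    "cross_platform_concordance",
    "readlen_ontarget_regression",
    "read_alignments_tsv",
    "read_alignments_sam",
]


def read_alignments_tsv(path) -> pd.DataFrame:
    """Read an alignment summary TSV: read_id, scaffold, start, end,
    read_length (0-based half-open intervals)."""
    df = pd.read_csv(path, sep="\t")
    required = {"read_id", "scaffold", "start", "end", "read_length"}
    if not required.issubset(df.columns):
        raise ValueError(f"alignment table needs columns {sorted(required)}")
    return df


def read_alignments_sam(path) -> pd.DataFrame:
    """Optional SAM ingestion (mapped primary alignments only)."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            rows.append(
                {
                    "read_id": rec.query_name,
                    "scaffold": rec.reference_name,
                    "start": rec.reference_start,
                    "end": rec.reference_end,
                    "read_length": rec.query_length or (rec.reference_end - rec.reference_start),
                }
            )
    return pd.DataFrame(rows, columns=["read_id", "scaffold", "start", "end", "read_length"])


def _target_trees(targets: pd.DataFrame) -> dict:
    trees: dict = {}
    for _, t in targets.iterrows():
        trees.setdefault(t["scaffold"], IntervalTree()).addi(int(t["start"]), int(t["end"]))
    return trees


def on_target_fraction(
    alignments: pd.DataFrame, targets: pd.DataFrame, containment: bool = False
) -> dict:
    """Fraction of reads on target and fraction of targets hit.

    A read is on target if it overlaps any target by >= 1 bp;
    ``containment=True`` demands the read lie fully inside one target.
    """
    if len(targets) == 0:
        raise ValueError("empty target set")
    trees = _target_trees(targets)
    n_on = 0
    hit = set()
    for _, r in alignments.iterrows():
        tree = trees.get(r["scaffold"])
        if tree is None:
            continue
        ivs = tree.overlap(int(r["start"]), int(r["end"]))
        if not ivs:
            continue
        if containment and not any(
            iv.begin <= int(r["start"]) and int(r["end"]) <= iv.end for iv in ivs
        ):
            continue
        n_on += 1
        hit.update((r["scaffold"], iv.begin, iv.end) for iv in ivs)
    n_reads = len(alignments)
    return {
        "n_reads": n_reads,
        "on_target_fraction": n_on / n_reads if n_reads else 0.0,
        "targets_hit_fraction": len(hit) / len(targets),
    }


def breadth_and_depth(alignments: pd.DataFrame, targets: pd.DataFrame) -> pd.DataFrame:
    """Per-target covered-base fraction (>= 1x) and mean depth.

    The pileup is computed with difference arrays per scaffold (exact, per
    base).  Pooled means live in the result's ``.attrs``.
    """
    spans: dict = {}
    for df in (targets, alignments):
        for _, r in df.iterrows():
            cur = spans.get(r["scaffold"], 0)
            spans[r["scaffold"]] = max(cur, int(r["end"]))
    diff = {nm: np.zeros(L + 1, dtype=np.int64) for nm, L in spans.items()}
    for _, r in alignments.iterrows():
        d = diff.get(r["scaffold"])
        if d is not None:
            d[int(r["start"])] += 1
            d[int(r["end"])] -= 1
    depth = {nm: np.cumsum(d[:-1]) for nm, d in diff.items()}
    rows = []
    for _, t in targets.iterrows():
        dv = depth.get(t["scaffold"])
        s, e = int(t["start"]), int(t["end"])
        seg = dv[s:e] if dv is not None else np.zeros(e - s, dtype=np.int64)
        rows.append(
            {
                "name": t.get("name", f"{t['scaffold']}:{s}-{e}"),
                "scaffold": t["scaffold"],
                "start": s,
                "end": e,
                "breadth": float((seg > 0).mean()) if len(seg) else 0.0,
                "mean_depth": float(seg.mean()) if len(seg) else 0.0,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out.attrs["mean_breadth"] = float(out["breadth"].mean())
        out.attrs["mean_depth"] = float(out["mean_depth"].mean())
    return out


def replicate_concordance(
    calls_a: np.ndarray,
    calls_b: np.ndarray,
    depth_a: np.ndarray | None = None,
    depth_b: np.ndarray | None = None,
    alleles_a: np.ndarray | None = None,
    alleles_b: np.ndarray | None = None,
    mono_depth: int = 20,
) -> dict:
    """Concordance report for one individual captured twice.

    ``calls_*`` are genotype codes over one shared site universe (-1 / 0 /
    +1 / NaN).  A replicate's SNPs are its heterozygous calls; common SNPs
    are sites heterozygous in both.  Among common SNPs, calls are
    "identical" unless the genotype codes or the optional per-site allele
    strings differ.  All-site similarity compares genotype codes at sites
    non-missing in both replicates with depth >= ``mono_depth`` in both
    (requires depths).  The report is symmetric in the two replicates.
    """
    a = np.asarray(calls_a, dtype=float)
    b = np.asarray(calls_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("replicates must share one site universe")
    het_a = a == 0.0
    het_b = b == 0.0
    common = het_a & het_b
    identical = common.copy()
    if alleles_a is not None and alleles_b is not None:
        identical &= np.asarray(alleles_a) == np.asarray(alleles_b)
    n_common = int(common.sum())
    n_identical = int(identical.sum())
    report = {
        "n_snps_a": int(het_a.sum()),
        "n_snps_b": int(het_b.sum()),
        "n_common": n_common,
        "n_identical": n_identical,
        "n_different": n_common - n_identical,
        "identical_fraction": n_identical / n_common if n_common else float("nan"),
    }
    if depth_a is not None and depth_b is not None:
        da = np.asarray(depth_a)
        db = np.asarray(depth_b)
        ok = ~np.isnan(a) & ~np.isnan(b) & (da >= mono_depth) & (db >= mono_depth)
        n_all = int(ok.sum())
        report["n_allsite"] = n_all
        report["allsite_similarity"] = float((a[ok] == b[ok]).mean()) if n_all else float("nan")
    return report


def cross_platform_concordance(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> dict:
    """Genotype concordance between two scoring methods.

    Both frames are sites x individuals genotype codes; the comparison
    runs over the shared sites and individuals.  Reports the comparison
    count |sites| x |individuals| (per call set) and the concordant
    fraction over pairs non-missing in both.
    """
    sites = calls_a.index.intersection(calls_b.index)
    inds = calls_a.columns.intersection(calls_b.columns)
    if len(sites) == 0 or len(inds) == 0:
        raise ValueError("empty site or individual intersection")
    a = calls_a.loc[sites, inds].to_numpy(dtype=float)
    b = calls_b.loc[sites, inds].to_numpy(dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    return {
        "n_sites": int(len(sites)),
        "n_individuals": int(len(inds)),
        "n_comparisons": int(len(sites) * len(inds)),
        "n_scored_pairs": int(ok.sum()),
        "concordant_fraction": float((a[ok] == b[ok]).mean()) if ok.any() else float("nan"),
    }


def readlen_ontarget_regression(read_length_means, on_target_fractions) -> dict:
    """OLS of per-sample on-target fraction on mean read length."""
    x = np.asarray(read_length_means, dtype=float)
    y = np.asarray(on_target_fractions, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least three samples")
    if x.std() == 0:
        raise ValueError("zero variance in read length")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return {
        "slope": float(res.params[1]),
        "intercept": float(res.params[0]),
        "r2": float(res.rsquared),
        "r2_adj": float(res.rsquared_adj),
        "pvalue": float(res.pvalues[1]),
    }
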