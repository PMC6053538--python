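"""Reading and writing genotype matrices as VCF.

Genotype codes map to diploid GT fields: -1 -> 0/0, 0 -> 0/1, +1 -> 1/1,
missing -> ./.  Reading goes through cyvcf2; writing emits minimal VCF 4.2
text (sites x samples with GT only), which round-trips codes, positions,
sample order, and missingness exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .simulate import GenotypeMatrix

_CODE_TO_GT = {-1.0: "0/0", 0.0: "0/1", 1.0: "1/1"}

_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_variants(genotypes: GenotypeMatrix, path) -> None:
    """Write a genotype matrix to an uncompressed VCF file."""
    sites = genotypes.sites
    with open(path, "w") as fh:
        fh.write(_HEADER)
        for sc in pd.unique(sites["scaffold"]) if len(sites) else []:
            fh.write(f"##contig=<ID={sc}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + [str(s) for s in genotypes.samples]) + "\n")
        codes = genotypes.codes
        for j in range(genotypes.m):
            row = sites.iloc[j]
            gts = [
                "./." if np.isnan(codes[i, j]) else _CODE_TO_GT[codes[i, j]]
                for i in range(genotypes.n)
            ]
            fh.write(
                "\t".join(
                    [
                        str(row["scaffold"]),
                        str(int(row["pos"]) + 1),  # VCF is 1-based
                        f"site{j + 1}",
                        str(row.get("ref", "A")),
                        str(row.get("alt", "C")),
                        ".",
                        "PASS",
                        ".",
                        "GT",
                    ]
                    + gts
                )
                + "\n"
            )


def read_variants(path) -> GenotypeMatrix:
    """Read a VCF file back into a genotype matrix.

    Raises ``ValueError`` naming the failing record number when a record
    cannot be parsed.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, site_rows = [], []
    k = 0
    try:
        for variant in vcf:
            k += 1
            gt = np.asarray(variant.gt_types, dtype=float)  # 0/1/2 dosage, 3 unknown
            codes = gt - 1.0
            codes[gt == 3] = np.nan
            rows.append(codes)
            site_rows.append(
                {
                    "scaffold": variant.CHROM,
                    "pos": variant.POS - 1,
                    "ref": variant.REF,
                    "alt": variant.ALT[0] if variant.ALT else ".",
                }
            )
    except Exception as exc:  # pragma: no cover - depends on malformed input
        raise ValueError(f"malformed VCF record at data line {k + 1}: {exc}") from exc
    codes = np.array(rows, dtype=float).T if rows else np.zeros((len(samples), 0))
    sites = pd.DataFrame(site_rows, columns=["scaffold", "pos", "ref", "alt"])
    return GenotypeMatrix(codes=codes, samples=samples, sites=sites)
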