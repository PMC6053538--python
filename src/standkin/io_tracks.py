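"""On-disk formats for genome annotation and interval tracks.

FASTA via Biopython; BED (0-based half-open, native) via pandas; GFF3
written as text (1-based inclusive on disk, converted back to 0-based
half-open on read through gffutils).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import ToyGenome

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_bed",
    "read_bed",
    "write_gff3",
    "read_gff3_genes",
    "write_genome",
    "read_genome",
]


def write_fasta(sequences: dict, path) -> None:
    records = [SeqRecord(Seq(s), id=nm, description="") for nm, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(df: pd.DataFrame, path, extra_cols: list | None = None) -> None:
    cols = ["scaffold", "start", "end"] + (extra_cols or [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, extra_cols: list | None = None) -> pd.DataFrame:
    names = ["scaffold", "start", "end"] + (extra_cols or [])
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(names)]
    df.columns = names
    return df


def write_gff3(genes: pd.DataFrame, exons: pd.DataFrame, path) -> None:
    """Write gene models as GFF3 (converting to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            fh.write(
                f"{g['scaffold']}\tstandkin\tgene\t{int(g['start']) + 1}\t{int(g['end'])}\t.\t"
                f"{g.get('strand', '+')}\t.\tID={g['gene_id']}\n"
            )
            sub = exons[exons["gene_id"] == g["gene_id"]]
            for k, (_, e) in enumerate(sub.iterrows()):
                fh.write(
                    f"{e['scaffold']}\tstandkin\texon\t{int(e['start']) + 1}\t{int(e['end'])}\t.\t"
                    f"{g.get('strand', '+')}\t.\tID={g['gene_id']}.e{k + 1};Parent={g['gene_id']}\n"
                )


def read_gff3_genes(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read gene/exon models from GFF3 back to 0-based half-open frames."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    genes, exons = [], []
    for g in db.features_of_type("gene"):
        genes.append(
            {
                "gene_id": g.id,
                "scaffold": g.seqid,
                "start": g.start - 1,
                "end": g.end,
                "strand": g.strand,
            }
        )
        for e in db.children(g, featuretype="exon", order_by="start"):
            exons.append(
                {"gene_id": g.id, "scaffold": e.seqid, "start": e.start - 1, "end": e.end}
            )
    return (
        pd.DataFrame(genes, columns=["gene_id", "scaffold", "start", "end", "strand"]),
        pd.DataFrame(exons, columns=["gene_id", "scaffold", "start", "end"]),
    )


def write_genome(genome: ToyGenome, prefix) -> dict:
    """Write a toy genome as FASTA + GFF3 + TE BED + anchoring TSV;
    returns the paths."""
    from pathlib import Path

    prefix = Path(prefix)
    paths = {
        "fasta": prefix.with_suffix(".fa"),
        "gff": prefix.with_suffix(".gff3"),
        "te": Path(str(prefix) + ".te.bed"),
        "anchored": Path(str(prefix) + ".anchored.tsv"),
    }
    write_fasta(genome.sequences, paths["fasta"])
    write_gff3(genome.genes, genome.exons, paths["gff"])
    write_bed(genome.te, paths["te"], extra_cols=["family"])
    pd.DataFrame(
        {"scaffold": list(genome.anchored), "anchored": [int(v) for v in genome.anchored.values()]}
    ).to_csv(paths["anchored"], sep="\t", index=False)
    return paths


def read_genome(fasta, gff, te_bed, anchored_tsv) -> ToyGenome:
    sequences = read_fasta(fasta)
    genes, exons = read_gff3_genes(gff)
    te = read_bed(te_bed, extra_cols=["family"])
    anch = pd.read_csv(anchored_tsv, sep="\t")
    anchored = dict(zip(anch["scaffold"], anch["anchored"].astype(bool)))
    return ToyGenome(sequences=sequences, genes=genes, exons=exons, te=te, anchored=anchored)
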