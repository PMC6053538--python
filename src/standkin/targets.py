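"""Capture-target selection and probe tiling on an annotated genome.

Rules: genes shorter than 1.5 kb contribute a single 150 bp exonic target;
longer genes are split into thirds and contribute two targets in the two
extreme thirds, one exonic and one spanning an intron-exon transition.
Intergenic targets come from a 100 kb sliding window: the 150 bp at the
window start is retained only if the window holds no previously selected
target, and is shifted downstream in 150 bp steps while it overlaps a
transposable element.  Candidates are then filtered on GC content
(30-60%, bounds inclusive) and on genome-wide repetitiveness (kept with
fewer than 10 approximate alignments at >= 90% identity, counted by a
k-mer-seeded scan over both strands).  Probes are 120 bp: one per 150 bp
target, two non-overlapping ones for targets of at least 240 bp.

All intervals are 0-based half-open, reported on the forward strand.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .simulate import ToyGenome

logger = logging.getLogger(__name__)

__all__ = [
    "select_genic_targets",
    "select_intergenic_targets",
    "filter_gc",
    "filter_repetitive",
    "design_probes",
    "probe_accounting",
    "gc_content",
    "GenomeMatcher",
]

TARGET_LEN = 150
PROBE_LEN = 120
LONG_GENE = 1500

_TARGET_COLS = ["name", "scaffold", "start", "end", "category", "gene_id"]


def _te_trees(genome: ToyGenome) -> dict:
    trees = {nm: IntervalTree() for nm in genome.sequences}
    for _, r in genome.te.iterrows():
        trees[r["scaffold"]].addi(int(r["start"]), int(r["end"]))
    return trees


def classify_interval(exons: list[tuple[int, int]], start: int, end: int) -> str:
    """Category of a genic interval given its gene's exons: fully exonic ->
    "exon", touching no exon -> "intron", otherwise "intron-exon"."""
    in_exon = sum(max(0, min(end, e) - max(start, s)) for s, e in exons)
    if in_exon == end - start:
        return "exon"
    if in_exon == 0:
        return "intron"
    return "intron-exon"


def select_genic_targets(genome: ToyGenome) -> pd.DataFrame:
    """Apply the gene-length rule to every gene model.

    Genes < 1.5 kb: one 150 bp target centered in the longest exon (genes
    whose exons cannot hold 150 bp are reported and skipped).  Genes >=
    1.5 kb: one exonic target in the first third and one intron-exon
    junction target in the last third (swapped when only the mirror
    arrangement is feasible; single-exon long genes fall back to a second
    exonic target in the opposite extreme third).
    """
    rows = []
    exon_map = {g: [] for g in genome.genes["gene_id"]}
    for _, e in genome.exons.iterrows():
        exon_map[e["gene_id"]].append((int(e["start"]), int(e["end"])))
    for _, gene in genome.genes.iterrows():
        gid, nm = gene["gene_id"], gene["scaffold"]
        gstart, gend = int(gene["start"]), int(gene["end"])
        L = gend - gstart
        exons = sorted(exon_map[gid])

        def exon_slot(lo: int, hi: int):
            """Leftmost 150 bp window fully inside an exon and [lo, hi)."""
            for s, e in exons:
                a, b = max(s, lo), min(e, hi)
                if b - a >= TARGET_LEN:
                    return a, a + TARGET_LEN
            return None

        def junction_slot(lo: int, hi: int):
            """A 150 bp window centered on an intron-exon boundary within
            [lo, hi), preferring the rightmost feasible boundary."""
            bounds = []
            for s, e in exons:
                if gstart < s:
                    bounds.append(s)  # intron -> exon transition
                if e < gend:
                    bounds.append(e)  # exon -> intron transition
            for b in sorted(set(bounds), reverse=True):
                a = b - TARGET_LEN // 2
                if a >= lo and a + TARGET_LEN <= hi:
                    return a, a + TARGET_LEN
            return None

        if L < LONG_GENE:
            best = max(exons, key=lambda se: se[1] - se[0], default=None)
            if best is None or best[1] - best[0] < TARGET_LEN:
                logger.warning("gene %s skipped: no exon long enough for %d bp", gid, TARGET_LEN)
                continue
            mid = (best[0] + best[1]) // 2
            a = mid - TARGET_LEN // 2
            rows.append((f"{gid}_t1", nm, a, a + TARGET_LEN, "exon", gid))
        else:
            third = L // 3
            first = (gstart, gstart + third)
            last = (gend - third, gend)
            ex1, ju_last = exon_slot(*first), junction_slot(*last)
            if ex1 is not None and ju_last is not None:
                placed = [(ex1, "first"), (ju_last, "last")]
            else:
                ju_first, ex_last = junction_slot(*first), exon_slot(*last)
                if ju_first is not None and ex_last is not None:
                    placed = [(ju_first, "first"), (ex_last, "last")]
                elif ex1 is not None and ex_last is not None:
                    logger.info("gene %s: no junction available, two exonic targets", gid)
                    placed = [(ex1, "first"), (ex_last, "last")]
                else:
                    feasible = [(s, w) for s, w in ((ex1, "first"), (ex_last, "last")) if s is not None]
                    if not feasible:
                        logger.warning("gene %s skipped: no placeable target", gid)
                        continue
                    logger.warning("gene %s: only one target placeable", gid)
                    placed = feasible[:1]
            for k, (slot, _which) in enumerate(placed):
                cat = classify_interval(exons, *slot)
                rows.append((f"{gid}_t{k + 1}", nm, slot[0], slot[1], cat, gid))
    return pd.DataFrame(rows, columns=_TARGET_COLS)


def select_intergenic_targets(
    genome: ToyGenome,
    existing_targets: pd.DataFrame | None = None,
    window: int = 100_000,
) -> pd.DataFrame:
    """One intergenic 150 bp target per empty 100 kb window.

    A window contributes nothing if an existing target overlaps it.  The
    candidate starts at the window start and is shifted downstream in
    150 bp steps while it overlaps a TE; a window saturated by TEs yields
    nothing (logged).
    """
    te = _te_trees(genome)
    existing = {nm: IntervalTree() for nm in genome.sequences}
    if existing_targets is not None:
        for _, t in existing_targets.iterrows():
            existing[t["scaffold"]].addi(int(t["start"]), int(t["end"]))
    rows = []
    k = 0
    for nm, seq in genome.sequences.items():
        L = len(seq)
        for wstart in range(0, L, window):
            wend = min(wstart + window, L)
            if existing[nm].overlap(wstart, wend):
                continue
            a = wstart
            while a + TARGET_LEN <= wend and te[nm].overlap(a, a + TARGET_LEN):
                a += TARGET_LEN
            if a + TARGET_LEN > wend:
                logger.info("window %s:%d-%d saturated by TEs, no target", nm, wstart, wend)
                continue
            k += 1
            rows.append((f"ig{k:05d}", nm, a, a + TARGET_LEN, "intergenic", ""))
    return pd.DataFrame(rows, columns=_TARGET_COLS)


def gc_content(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def target_sequence(genome: ToyGenome, row) -> str:
    return genome.sequences[row["scaffold"]][int(row["start"]) : int(row["end"])]


def filter_gc(
    targets: pd.DataFrame, genome: ToyGenome, low: float = 0.30, high: float = 0.60
) -> pd.DataFrame:
    """Keep targets with GC content in [low, high] (bounds inclusive);
    adds a ``gc`` column."""
    out = targets.copy()
    out["gc"] = [gc_content(target_sequence(genome, r)) for _, r in out.iterrows()]
    return out[(out["gc"] >= low) & (out["gc"] <= high)].reset_index(drop=True)


_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class GenomeMatcher:
    """Count approximate occurrences of a query in a genome.

    Matches are counted on both strands as distinct start positions where
    the full-length Hamming identity is at least ``min_identity``; seeding
    uses non-overlapping exact k-mers, so a true match is found whenever at
    least one of its ~L/k seed k-mers is mutation-free.
    """

    def __init__(self, genome: ToyGenome, k: int = 15):
        self.k = k
        parts, offsets = [], {}
        pos = 0
        for nm, seq in genome.sequences.items():
            offsets[nm] = pos
            parts.append(seq)
            parts.append("N" * k)  # separator so matches cannot straddle scaffolds
            pos += len(seq) + k
        self.offsets = offsets
        text = "".join(parts)
        self.codes = self._encode(text)
        self.kcodes = self._kmer_codes(self.codes, k)
        self.order = np.argsort(self.kcodes, kind="stable")
        self.sorted_codes = self.kcodes[self.order]

    @staticmethod
    def _encode(seq: str) -> np.ndarray:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        out = np.full(arr.shape, 4, dtype=np.int64)
        for v, b in enumerate(b"ACGT"):
            out[arr == b] = v
        return out

    @staticmethod
    def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
        n = codes.shape[0] - k + 1
        if n <= 0:
            return np.full(0, -1, dtype=np.int64)
        out = np.zeros(n, dtype=np.int64)
        bad = np.zeros(n, dtype=bool)
        for i in range(k):
            c = codes[i : i + n]
            out = (out << 2) | np.where(c < 4, c, 0)
            bad |= c >= 4
        out[bad] = -1
        return out

    def _seed_positions(self, kcode: int) -> np.ndarray:
        lo = np.searchsorted(self.sorted_codes, kcode, side="left")
        hi = np.searchsorted(self.sorted_codes, kcode, side="right")
        return self.order[lo:hi]

    def count_matches(self, query: str, min_identity: float = 0.9) -> int:
        total = 0
        for q in (query, revcomp(query)):
            total += self._count_one_strand(q, min_identity)
        return total

    def _count_one_strand(self, query: str, min_identity: float) -> int:
        L = len(query)
        qcodes = self._encode(query)
        max_mm = int(np.floor((1.0 - min_identity) * L))
        candidates = set()
        for off in range(0, L - self.k + 1, self.k):
            sub = qcodes[off : off + self.k]
            if (sub >= 4).any():
                continue
            kcode = 0
            for v in sub:
                kcode = (kcode << 2) | int(v)
            for p in self._seed_positions(kcode):
                start = int(p) - off
                if 0 <= start <= self.codes.shape[0] - L:
                    candidates.add(start)
        count = 0
        for start in candidates:
            window = self.codes[start : start + L]
            mm = int((window != qcodes).sum())
            if mm <= max_mm:
                count += 1
        return count


def filter_repetitive(
    targets: pd.DataFrame,
    genome: ToyGenome,
    max_hits: int = 10,
    min_identity: float = 0.9,
    k: int = 15,
    matcher: GenomeMatcher | None = None,
) -> pd.DataFrame:
    """Keep targets with fewer than ``max_hits`` approximate genome-wide
    alignments; adds a ``repeat_hits`` column."""
    matcher = matcher or GenomeMatcher(genome, k=k)
    out = targets.copy()
    out["repeat_hits"] = [
        matcher.count_matches(target_sequence(genome, r), min_identity) for _, r in out.iterrows()
    ]
    return out[out["repeat_hits"] < max_hits].reset_index(drop=True)


def design_probes(targets: pd.DataFrame, probe_len: int = PROBE_LEN) -> pd.DataFrame:
    """Tile 120 bp probes over targets.

    Targets of 150 bp can hold only one (centered) probe; only targets of
    at least 240 bp get two non-overlapping end-anchored probes.  Targets
    shorter than the probe get none (logged).
    """
    rows = []
    for _, t in targets.iterrows():
        L = int(t["end"]) - int(t["start"])
        if L < probe_len:
            logger.warning("target %s shorter than a probe (%d bp), none designed", t["name"], L)
            continue
        if L >= 2 * probe_len:
            starts = [int(t["start"]), int(t["end"]) - probe_len]
        else:
            starts = [int(t["start"]) + (L - probe_len) // 2]
        for i, a in enumerate(starts):
            rows.append(
                {
                    "probe_id": f"{t['name']}_p{i + 1}",
                    "target": t["name"],
                    "scaffold": t["scaffold"],
                    "start": a,
                    "end": a + probe_len,
                    "category": t["category"],
                }
            )
    return pd.DataFrame(
        rows, columns=["probe_id", "target", "scaffold", "start", "end", "category"]
    )


GENIC_CATEGORIES = ("exon", "intron", "intron-exon")


def probe_accounting(probes: pd.DataFrame, targets: pd.DataFrame) -> pd.DataFrame:
    """Per-category probe and target counts with totals and within-genic
    percentages (layout as in a capture-design summary table: intergenic,
    genic with its exon / intron / intron-exon breakdown, total)."""
    if len(probes) and not set(probes["target"]).issubset(set(targets["name"])):
        raise ValueError("probe references a target absent from the target set")
    pc = probes["category"].value_counts() if len(probes) else pd.Series(dtype=int)
    tc = targets["category"].value_counts() if len(targets) else pd.Series(dtype=int)
    genic_p = sum(int(pc.get(c, 0)) for c in GENIC_CATEGORIES)
    genic_t = sum(int(tc.get(c, 0)) for c in GENIC_CATEGORIES)
    rows = [
        {"sequence_type": "intergenic", "n_probes": int(pc.get("intergenic", 0)), "n_targets": int(tc.get("intergenic", 0)), "pct_of_genic_probes": np.nan},
        {"sequence_type": "genic", "n_probes": genic_p, "n_targets": genic_t, "pct_of_genic_probes": np.nan},
    ]
    for c in GENIC_CATEGORIES:
        rows.append(
            {
                "sequence_type": c,
                "n_probes": int(pc.get(c, 0)),
                "n_targets": int(tc.get(c, 0)),
                "pct_of_genic_probes": 100.0 * pc.get(c, 0) / genic_p if genic_p else np.nan,
            }
        )
    rows.append(
        {
            "sequence_type": "total",
            "n_probes": int(pc.get("intergenic", 0)) + genic_p,
            "n_targets": int(tc.get("intergenic", 0)) + genic_t,
            "pct_of_genic_probes": np.nan,
        }
    )
    return pd.DataFrame(rows)
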