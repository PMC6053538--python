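"""Capture-target selection, GC/repeat filters, probe tiling, accounting."""

import numpy as np
import pandas as pd
import pytest

import standkin as sk
from standkin import targets as tg


def _genome(seq_by_scaffold, genes=None, exons=None, te=None, anchored=None):
    genes = pd.DataFrame(genes or [], columns=["gene_id", "scaffold", "start", "end", "strand"])
    exons = pd.DataFrame(exons or [], columns=["gene_id", "scaffold", "start", "end"])
    te = pd.DataFrame(te or [], columns=["scaffold", "start", "end", "family"])
    anchored = anchored or {nm: True for nm in seq_by_scaffold}
    return sk.ToyGenome(
        sequences=seq_by_scaffold, genes=genes, exons=exons, te=te, anchored=anchored
    )


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestGenicSelection:
    def test_short_gene_single_exonic_target(self):
        rng = np.random.default_rng(0)
        seq = _random_seq(rng, 5000)
        g = _genome(
            {"sc1": seq},
            genes=[("g1", "sc1", 1000, 2200, "+")],
            exons=[("g1", "sc1", 1000, 1600), ("g1", "sc1", 1900, 2200)],
        )
        out = tg.select_genic_targets(g)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["category"] == "exon"
        assert row["end"] - row["start"] == 150
        # inside the longest exon
        assert 1000 <= row["start"] and row["end"] <= 1600

    def test_long_gene_two_targets_extreme_thirds(self):
        rng = np.random.default_rng(1)
        seq = _random_seq(rng, 10000)
        # 6000 bp gene with three exons; junctions exist in both thirds
        g = _genome(
            {"sc1": seq},
            genes=[("g1", "sc1", 2000, 8000, "+")],
            exons=[
                ("g1", "sc1", 2000, 3500),
                ("g1", "sc1", 4500, 5500),
                ("g1", "sc1", 6500, 8000),
            ],
        )
        out = tg.select_genic_targets(g)
        assert len(out) == 2
        cats = set(out["category"])
        assert cats == {"exon", "intron-exon"}
        third = 6000 // 3
        first_third = (2000, 2000 + third)
        last_third = (8000 - third, 8000)
        spans = [(r["start"], r["end"]) for _, r in out.iterrows()]
        assert any(s >= first_third[0] and e <= first_third[1] for s, e in spans)
        assert any(s >= last_third[0] and e <= last_third[1] for s, e in spans)

    def test_single_exon_long_gene_fallback(self):
        rng = np.random.default_rng(2)
        seq = _random_seq(rng, 8000)
        g = _genome(
            {"sc1": seq},
            genes=[("g1", "sc1", 1000, 5000, "+")],
            exons=[("g1", "sc1", 1000, 5000)],
        )
        out = tg.select_genic_targets(g)
        assert len(out) == 2
        assert set(out["category"]) == {"exon"}

    def test_no_exon_long_enough_skipped(self):
        rng = np.random.default_rng(3)
        seq = _random_seq(rng, 4000)
        g = _genome(
            {"sc1": seq},
            genes=[("g1", "sc1", 1000, 2000, "+")],
            exons=[("g1", "sc1", 1000, 1100), ("g1", "sc1", 1900, 2000)],
        )
        assert len(tg.select_genic_targets(g)) == 0

    def test_empty_gene_set(self):
        g = _genome({"sc1": "ACGT" * 1000})
        assert len(tg.select_genic_targets(g)) == 0


class TestIntergenicSelection:
    def test_te_free_scaffold_targets_at_window_starts(self):
        rng = np.random.default_rng(4)
        g = _genome({"sc1": _random_seq(rng, 300_000)})
        out = tg.select_intergenic_targets(g, window=100_000)
        assert list(out["start"]) == [0, 100_000, 200_000]
        assert (out["end"] - out["start"] == 150).all()

    def test_window_with_existing_target_skipped(self):
        rng = np.random.default_rng(5)
        g = _genome({"sc1": _random_seq(rng, 200_000)})
        existing = pd.DataFrame(
            [{"name": "t0", "scaffold": "sc1", "start": 50_000, "end": 50_150, "category": "exon", "gene_id": "g1"}]
        )
        out = tg.select_intergenic_targets(g, existing, window=100_000)
        assert list(out["start"]) == [100_000]

    def test_te_shift(self):
        rng = np.random.default_rng(6)
        g = _genome(
            {"sc1": _random_seq(rng, 100_000)},
            te=[("sc1", 0, 100, "fam1"), ("sc1", 200, 320, "fam1")],
        )
        out = tg.select_intergenic_targets(g, window=100_000)
        # 0 overlaps a TE, 150 overlaps the second TE, 450 is clear
        assert list(out["start"]) == [450]
        # no emitted target overlaps a TE interval
        for _, r in out.iterrows():
            for _, t in g.te.iterrows():
                assert r["end"] <= t["start"] or r["start"] >= t["end"]

    def test_saturated_window_yields_nothing(self):
        rng = np.random.default_rng(7)
        g = _genome({"sc1": _random_seq(rng, 1000)}, te=[("sc1", 0, 1000, "fam1")])
        assert len(tg.select_intergenic_targets(g, window=1000)) == 0


class TestGCFilter:
    def _targets(self, seqs):
        return pd.DataFrame(
            [
                {"name": f"t{i}", "scaffold": "sc1", "start": i * 150, "end": (i + 1) * 150,
                 "category": "intergenic", "gene_id": ""}
                for i in range(len(seqs))
            ]
        )

    def test_extremes_and_midrange(self):
        seqs = ["AT" * 75, "GC" * 75, ("GCA" + "T") * 37 + "GC"]  # gc 0, 1, ~0.5
        g = _genome({"sc1": "".join(seqs)})
        out = tg.filter_gc(self._targets(seqs), g)
        assert list(out["name"]) == ["t2"]

    def test_bounds_inclusive(self):
        # exactly 30% and 60% GC survive
        s30 = "G" * 45 + "A" * 105
        s60 = "G" * 90 + "A" * 60
        s29 = "G" * 44 + "A" * 106
        g = _genome({"sc1": s30 + s60 + s29})
        out = tg.filter_gc(self._targets([s30, s60, s29]), g)
        assert list(out["name"]) == ["t0", "t1"]

    def test_recount_oracle(self):
        rng = np.random.default_rng(8)
        seq = _random_seq(rng, 100 * 150)
        g = _genome({"sc1": seq})
        t = self._targets([None] * 100)
        out = tg.filter_gc(t, g)
        kept = set(out["name"])
        for i in range(100):
            sub = seq[i * 150 : (i + 1) * 150]
            gc = sum(c in "GC" for c in sub) / 150
            assert (f"t{i}" in kept) == (0.30 <= gc <= 0.60)


def brute_force_hits(genome, query, min_identity=0.9):
    """Exhaustive sliding-window approximate match count on both strands."""
    total = 0
    max_mm = int(np.floor((1 - min_identity) * len(query)))
    for q in (query, tg.revcomp(query)):
        qa = np.frombuffer(q.encode(), dtype=np.uint8)
        for seq in genome.sequences.values():
            sa = np.frombuffer(seq.encode(), dtype=np.uint8)
            n = len(sa) - len(qa) + 1
            if n <= 0:
                continue
            mm = np.zeros(n, dtype=np.int32)
            for off in range(len(qa)):
                mm += sa[off : off + n] != qa[off]
            total += int((mm <= max_mm).sum())
    return total


class TestRepeatFilter:
    def test_unique_sequence_kept(self):
        rng = np.random.default_rng(9)
        seq = _random_seq(rng, 100_000)
        g = _genome({"sc1": seq})
        t = pd.DataFrame(
            [{"name": "t0", "scaffold": "sc1", "start": 500, "end": 650, "category": "exon", "gene_id": "g"}]
        )
        out = tg.filter_repetitive(t, g)
        assert len(out) == 1 and out.iloc[0]["repeat_hits"] == 1

    def test_pasted_repeat_removed(self):
        rng = np.random.default_rng(10)
        unit = _random_seq(rng, 150)
        filler = [_random_seq(rng, 400) for _ in range(12)]
        seq = "".join(f + unit for f in filler)
        g = _genome({"sc1": seq})
        t = pd.DataFrame(
            [{"name": "t0", "scaffold": "sc1", "start": 400, "end": 550, "category": "exon", "gene_id": "g"}]
        )
        out = tg.filter_repetitive(t, g)
        assert len(out) == 0

    def test_matches_brute_force_on_planted_duplicates(self):
        rng = np.random.default_rng(11)
        base = _random_seq(rng, 60_000)
        queries = []
        pieces = [base]
        for i in range(6):
            unit = _random_seq(rng, 150)
            queries.append(unit)
            copies = i + 1
            for c in range(copies):
                mutated = list(unit)
                for pos in rng.choice(150, size=rng.integers(0, 6), replace=False):
                    mutated[pos] = "ACGT"[rng.integers(0, 4)]
                pieces.append("".join(mutated))
                pieces.append(_random_seq(rng, 300))
        seq = "".join(pieces)
        g = _genome({"sc1": seq})
        matcher = tg.GenomeMatcher(g)
        for q in queries:
            assert matcher.count_matches(q) == brute_force_hits(g, q)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(12)
        unit = _random_seq(rng, 150)
        seq = _random_seq(rng, 5000) + tg.revcomp(unit) + _random_seq(rng, 5000)
        g = _genome({"sc1": seq})
        assert tg.GenomeMatcher(g).count_matches(unit) == 1


class TestProbes:
    def _target(self, length, name="t0"):
        return pd.DataFrame(
            [{"name": name, "scaffold": "sc1", "start": 0, "end": length, "category": "exon", "gene_id": "g"}]
        )

    def test_150bp_target_single_probe(self):
        out = tg.design_probes(self._target(150))
        assert len(out) == 1
        assert out.iloc[0]["end"] - out.iloc[0]["start"] == 120

    def test_240bp_target_two_nonoverlapping(self):
        out = tg.design_probes(self._target(240))
        assert len(out) == 2
        a, b = out.sort_values("start").itertuples(index=False), None
        rows = out.sort_values("start").to_dict("records")
        assert rows[0]["end"] <= rows[1]["start"]

    def test_short_target_no_probe(self):
        assert len(tg.design_probes(self._target(100))) == 0

    def test_probe_within_target(self):
        for L in (120, 150, 239, 240, 400):
            out = tg.design_probes(self._target(L))
            assert (out["start"] >= 0).all() and (out["end"] <= L).all()

    def test_empty(self):
        assert len(tg.design_probes(self._target(150).iloc[0:0])) == 0


class TestAccounting:
    def _published_counts(self):
        """Category counts as in the capture-design summary of the oak
        assay (probes / targets)."""
        return {
            "intergenic": (10227, 4031),
            "exon": (11120, 4960),
            "intron": (6731, 2991),
            "intron-exon": (5853, 3495),
        }

    def _frames(self, counts):
        trows, prows = [], []
        t_i = 0
        for cat, (np_, nt) in counts.items():
            for k in range(nt):
                trows.append({"name": f"t{t_i}", "scaffold": "sc1", "start": 0, "end": 150,
                              "category": cat, "gene_id": ""})
                t_i += 1
            for k in range(np_):
                prows.append({"probe_id": f"{cat}_p{k}", "target": f"t{t_i - 1}",
                              "scaffold": "sc1", "start": 0, "end": 120, "category": cat})
        return pd.DataFrame(prows), pd.DataFrame(trows)

    def test_published_totals(self):
        probes, targets_df = self._frames(self._published_counts())
        acct = tg.probe_accounting(probes, targets_df)
        total = acct[acct["sequence_type"] == "total"].iloc[0]
        assert total["n_probes"] == 33931
        assert total["n_targets"] == 15477
        exon = acct[acct["sequence_type"] == "exon"].iloc[0]
        assert exon["pct_of_genic_probes"] == pytest.approx(46.91, abs=0.005)

    def test_conservation(self):
        rng = np.random.default_rng(13)
        counts = {c: (int(rng.integers(1, 50)), int(rng.integers(1, 30)))
                  for c in ("intergenic", "exon", "intron", "intron-exon")}
        probes, targets_df = self._frames(counts)
        acct = tg.probe_accounting(probes, targets_df).set_index("sequence_type")
        assert acct.loc["total", "n_probes"] == sum(v[0] for v in counts.values())
        assert (
            acct.loc["genic", "n_probes"]
            == acct.loc["exon", "n_probes"] + acct.loc["intron", "n_probes"] + acct.loc["intron-exon", "n_probes"]
        )

    def test_empty_all_zero(self):
        acct = tg.probe_accounting(pd.DataFrame(columns=["probe_id", "target", "category"]),
                                   pd.DataFrame(columns=["name", "category"]))
        assert (acct["n_probes"] == 0).all()

    def test_orphan_probe_rejected(self):
        probes = pd.DataFrame([{"probe_id": "p", "target": "ghost", "category": "exon"}])
        targets_df = pd.DataFrame([{"name": "t0", "category": "exon"}])
        with pytest.raises(ValueError):
            tg.probe_accounting(probes, targets_df)
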