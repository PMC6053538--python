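"""Configuration-driven orchestration of the full analysis.

Stages: ``simulate`` (toy genome, species frequencies, pedigree,
genotypes, read counts, fitness traits), ``design`` (capture targets and
probes), ``qc`` (enrichment and replicate metrics), ``filter`` (calling
and the filtering cascade), ``relate`` (LD pruning, HWE/FDR, maf tier,
GRM, inbreeding, pedigree comparison), ``structure`` (per-locus Fst and
two-cluster ancestry), ``fitness`` (inbreeding-depression regressions).
Each stage writes plain-text artifacts into the run directory and later
stages read them back, so stages can be re-run individually.  A manifest
records the seed, configuration, and a checksum per artifact; a run is
fully determined by its configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import filtering, io_tracks, qc, relatedness, simulate, structure, targets, vcfio
from .fitness import env_pca, fit_growth_lm, fit_offspring_glm

ALL_STAGES = ("simulate", "design", "qc", "filter", "relate", "structure", "fitness")

__all__ = ["RunConfig", "run_pipeline", "ALL_STAGES"]


def _default_sim() -> dict:
    return {
        "m": 2000,
        "fst": 0.07,
        "n_founders_a": 30,
        "n_founders_b": 30,
        "families": {
            "A": {"parent_offspring": 1, "full_sib": 1, "half_sib": 1, "selfed": 1},
            "B": {"parent_offspring": 1, "full_sib": 1, "half_sib": 1},
        },
        "mean_depth": 95.0,
        "depth_dispersion": 3.0,
        "error_rate": 0.005,
        "dropout": 0.02,
        "genome_length": 400_000,
        "n_genes": 40,
        "te_fraction": 0.25,
        "n_scaffolds": 4,
        "n_unanchored": 1,
        "gamma": -3.6,
        "beta1": 0.2,
        "alpha": 2.0,
        "n_reads": 8000,
        "on_target_frac": 0.25,
    }


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "standkin_run"
    stages: tuple = ALL_STAGES
    sim: dict = field(default_factory=_default_sim)
    filter: dict = field(default_factory=dict)  # FilterConfig overrides
    maf_tier: float = 0.01
    design: dict = field(default_factory=lambda: {"gc_min": 0.30, "gc_max": 0.60, "max_hits": 10, "window": 100_000})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        sim = dict(_default_sim())
        sim.update(raw.pop("sim", {}))
        design = dict(cfg.design)
        design.update(raw.pop("design", {}))
        fields = {**raw, "sim": sim, "design": design}
        if "stages" in fields:
            fields["stages"] = tuple(fields["stages"])
        return cls(**fields)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self) | {"stages": list(self.stages)}, fh, sort_keys=True)

    def filter_config(self) -> filtering.FilterConfig:
        return filtering.FilterConfig(**self.filter)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_matrix(arr: np.ndarray, samples, path: Path) -> None:
    pd.DataFrame(arr, index=samples).to_csv(path, sep="\t", header=False)


def _read_matrix(path: Path) -> tuple[np.ndarray, list]:
    df = pd.read_csv(path, sep="\t", header=None, index_col=0)
    return df.to_numpy(), list(df.index)


class _Stages:
    """Stage implementations; each reads its inputs from the run directory."""

    def __init__(self, cfg: RunConfig, out: Path):
        self.cfg = cfg
        self.out = out

    # -- simulate ----------------------------------------------------------
    def simulate(self) -> list[Path]:
        cfg, out, s = self.cfg, self.out, self.cfg.sim
        seed = self.cfg.seed
        genome = simulate.simulate_genome(
            length=s["genome_length"],
            n_genes=s["n_genes"],
            te_fraction=s["te_fraction"],
            n_scaffolds=s["n_scaffolds"],
            n_unanchored=s["n_unanchored"],
            seed=seed,
        )
        gpaths = io_tracks.write_genome(genome, out / "genome")
        freqs = simulate.simulate_species_freqs(s["m"], s["fst"], seed=seed + 1)
        ped = simulate.build_pedigree(
            s["n_founders_a"], s["n_founders_b"], s["families"], seed=seed + 2
        )
        anchored_lens = {nm: len(sq) for nm, sq in genome.sequences.items() if genome.anchored[nm]}
        # most markers on anchored scaffolds, a few on unanchored ones
        lens = {nm: len(sq) for nm, sq in genome.sequences.items()}
        sites = simulate.random_sites(s["m"], seed=seed + 3, scaffolds=lens)
        geno = simulate.drop_genotypes(ped, freqs, seed=seed + 4, sites=sites)
        reads = simulate.simulate_read_counts(
            geno,
            mean_depth=s["mean_depth"],
            depth_dispersion=s["depth_dispersion"],
            error_rate=s["error_rate"],
            dropout=s["dropout"],
            seed=seed + 5,
        )
        A = relatedness.pedigree_additive_matrix(ped)
        inb_true = np.diag(A.to_numpy()) - 1.0
        fitness = simulate.simulate_fitness(
            ped,
            inb_true,
            gamma=s["gamma"],
            beta1=s["beta1"],
            alpha=s["alpha"],
            seed=seed + 6,
        )
        ped_path = out / "pedigree.tsv"
        ped.table.to_csv(ped_path, sep="\t", index=False)
        vcf_path = out / "truth.vcf"
        vcfio.write_variants(geno, vcf_path)
        depth_path, alt_path = out / "depth.tsv", out / "alt_reads.tsv"
        _write_matrix(reads.depth, reads.samples, depth_path)
        _write_matrix(reads.alt_reads, reads.samples, alt_path)
        sites_path = out / "sites.tsv"
        geno.sites.to_csv(sites_path, sep="\t", index=False)
        fit_path = out / "fitness.tsv"
        fitness.to_csv(fit_path, sep="\t", index=False)
        freq_path = out / "species_freqs.tsv"
        pd.DataFrame(
            {"p_anc": freqs.p_anc, "p_a": freqs.p_a, "p_b": freqs.p_b}
        ).to_csv(freq_path, sep="\t", index=False)
        return list(gpaths.values()) + [
            ped_path, vcf_path, depth_path, alt_path, sites_path, fit_path, freq_path
        ]

    def _genome(self):
        out = self.out
        return io_tracks.read_genome(
            out / "genome.fa", out / "genome.gff3", out / "genome.te.bed", out / "genome.anchored.tsv"
        )

    # -- design ------------------------------------------------------------
    def design(self) -> list[Path]:
        d, out = self.cfg.design, self.out
        genome = self._genome()
        genic = targets.select_genic_targets(genome)
        inter = targets.select_intergenic_targets(genome, genic, window=d["window"])
        cand = pd.concat([genic, inter], ignore_index=True)
        kept = targets.filter_gc(cand, genome, low=d["gc_min"], high=d["gc_max"])
        kept = targets.filter_repetitive(kept, genome, max_hits=d["max_hits"])
        probes = targets.design_probes(kept)
        acct = targets.probe_accounting(probes, kept)
        paths = []
        for name, df, extra in (
            ("targets", kept, ["name", "category"]),
            ("probes", probes, ["probe_id", "category"]),
        ):
            p = out / f"{name}.bed"
            io_tracks.write_bed(df, p, extra_cols=extra)
            paths.append(p)
            fa = out / f"{name}.fa"
            io_tracks.write_fasta(
                {
                    r[extra[0]]: genome.sequences[r["scaffold"]][int(r["start"]) : int(r["end"])]
                    for _, r in df.iterrows()
                },
                fa,
            )
            paths.append(fa)
        acct_path = out / "probe_accounting.tsv"
        acct.to_csv(acct_path, sep="\t", index=False)
        paths.append(acct_path)
        return paths

    # -- qc ------------------------------------------------------------------
    def qc(self) -> list[Path]:
        cfg, out, s = self.cfg, self.out, self.cfg.sim
        genome = self._genome()
        tgt = io_tracks.read_bed(out / "targets.bed", extra_cols=["name", "category"])
        aln = simulate.simulate_alignments(
            genome, tgt, n_reads=s["n_reads"], on_target_frac=s["on_target_frac"], seed=cfg.seed + 7
        )
        aln_path = out / "alignments.tsv"
        aln.to_csv(aln_path, sep="\t", index=False)
        on = qc.on_target_fraction(aln, tgt)
        bd = qc.breadth_and_depth(aln, tgt)
        # replicate concordance: re-sequence the first individual
        depth, samples = _read_matrix(out / "depth.tsv")
        alt, _ = _read_matrix(out / "alt_reads.tsv")
        sites = pd.read_csv(out / "sites.tsv", sep="\t")
        truth = vcfio.read_variants(out / "truth.vcf")
        fcfg = cfg.filter_config()
        rep2 = simulate.simulate_read_counts(
            simulate.GenotypeMatrix(truth.codes[:1], truth.samples[:1], sites),
            mean_depth=s["mean_depth"],
            depth_dispersion=s["depth_dispersion"],
            error_rate=s["error_rate"],
            dropout=s["dropout"],
            seed=cfg.seed + 8,
        )
        calls1 = filtering.call_genotypes(
            simulate.SiteCallTable(depth[:1], alt[:1], samples[:1], sites), fcfg
        )
        calls2 = filtering.call_genotypes(rep2, fcfg)
        rep = qc.replicate_concordance(
            calls1.codes[0], calls2.codes[0], depth[0], rep2.depth[0]
        )
        report = {
            "on_target": on,
            "mean_breadth": bd.attrs.get("mean_breadth"),
            "mean_depth": bd.attrs.get("mean_depth"),
            "replicate": rep,
        }
        qc_path = out / "qc.json"
        qc_path.write_text(json.dumps(report, indent=2, sort_keys=True))
        bd_path = out / "target_coverage.tsv"
        bd.to_csv(bd_path, sep="\t", index=False)
        return [aln_path, qc_path, bd_path]

    # -- filter ---------------------------------------------------------------
    def filter(self) -> list[Path]:
        out = self.out
        depth, samples = _read_matrix(out / "depth.tsv")
        alt, _ = _read_matrix(out / "alt_reads.tsv")
        sites = pd.read_csv(out / "sites.tsv", sep="\t")
        anch = pd.read_csv(out / "genome.anchored.tsv", sep="\t")
        anchored = dict(zip(anch["scaffold"], anch["anchored"].astype(bool)))
        table = simulate.SiteCallTable(depth, alt, samples, sites)
        geno, stages = filtering.apply_filter_cascade(table, anchored, self.cfg.filter_config())
        vcf_path = out / "genotypes.vcf"
        vcfio.write_variants(geno, vcf_path)
        st_path = out / "filter_stages.tsv"
        stages.to_csv(st_path, sep="\t", index=False)
        return [vcf_path, st_path]

    # -- relate ---------------------------------------------------------------
    def relate(self) -> list[Path]:
        cfg, out = self.cfg, self.out
        geno = vcfio.read_variants(out / "genotypes.vcf")
        fcfg = cfg.filter_config()
        keep = filtering.ld_prune(geno, fcfg, mode="r2-window")
        geno = filtering.subset_sites(geno, keep)
        pvals = filtering.hwe_exact_sites(geno)
        padj = filtering.fdr_adjust(pvals)
        geno = filtering.subset_sites(geno, np.where(np.isnan(padj), False, padj > fcfg.hwe_alpha))
        geno = filtering.subset_sites(geno, filtering.maf_tier(geno, cfg.maf_tier))
        G = relatedness.grm(geno)
        inb = relatedness.genomic_inbreeding(G)
        ped = self._pedigree()
        A = relatedness.pedigree_additive_matrix(ped)
        cmp_df = relatedness.compare_realized_expected(G, geno.samples, ped)
        paths = []
        for name, df in (
            ("grm", pd.DataFrame(G, index=geno.samples, columns=geno.samples)),
            ("pedigree_A", A),
            ("relatedness_compare", cmp_df),
            ("inbreeding", pd.DataFrame({"id": geno.samples, "genomic_inbreeding": inb})),
        ):
            p = out / f"{name}.tsv"
            df.to_csv(p, sep="\t", index=name in ("grm", "pedigree_A"))
            paths.append(p)
        return paths

    def _pedigree(self) -> simulate.Pedigree:
        t = pd.read_csv(self.out / "pedigree.tsv", sep="\t")
        for col in ("sire", "dam"):
            t[col] = t[col].astype(object).where(t[col].notna(), None)
        return simulate.Pedigree(t)

    # -- structure -------------------------------------------------------------
    def structure(self) -> list[Path]:
        cfg, out = self.cfg, self.out
        geno = vcfio.read_variants(out / "genotypes.vcf")
        fcfg = cfg.filter_config()
        keep = filtering.ld_prune(geno, fcfg, mode="spacing")
        pruned = filtering.subset_sites(geno, keep)
        padj = filtering.fdr_adjust(filtering.hwe_exact_sites(pruned))
        pruned = filtering.subset_sites(
            pruned, np.where(np.isnan(padj), False, padj > fcfg.hwe_alpha)
        )
        em = structure.AdmixtureEM(seed=cfg.seed + 9).fit(pruned)
        labels = em.assign()
        pure = labels != "admixed"
        fst = None
        if pure.sum() >= 2 and len(set(labels[pure])) == 2:
            sub = simulate.GenotypeMatrix(
                geno.codes[pure], [s for s, k in zip(geno.samples, pure) if k], geno.sites
            )
            # keep loci with calls in both groups
            callable_mask = np.ones(sub.m, dtype=bool)
            for lab in ("A", "B"):
                callable_mask &= (~np.isnan(sub.codes[labels[pure] == lab])).sum(axis=0) > 0
            sub = filtering.subset_sites(sub, callable_mask)
            fst = structure.per_locus_fst(sub, labels[pure])
        q_path = out / "ancestry.tsv"
        pd.DataFrame({"id": geno.samples, "q": em.q, "label": labels}).to_csv(
            q_path, sep="\t", index=False
        )
        paths = [q_path]
        summary = {"converged": em.converged, "flat_likelihood": em.flat_likelihood}
        if fst is not None:
            fst_path = out / "fst.tsv"
            fst.to_csv(fst_path, sep="\t", index=False)
            paths.append(fst_path)
            summary |= {
                "fst_mean": fst.attrs["mean"],
                "fst_median": fst.attrs["median"],
                "fst_pooled": fst.attrs["pooled"],
            }
        sum_path = out / "structure.json"
        sum_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
        paths.append(sum_path)
        return paths

    # -- fitness ----------------------------------------------------------------
    def fitness(self) -> list[Path]:
        out = self.out
        fit = pd.read_csv(out / "fitness.tsv", sep="\t")
        inb = pd.read_csv(out / "inbreeding.tsv", sep="\t")
        df = fit.merge(inb, on="id", how="inner")
        env_cols = [c for c in df.columns if c.startswith("env") and c != "env_factor_true"]
        x1 = env_pca(df[env_cols].to_numpy())
        I = df["genomic_inbreeding"].to_numpy()
        glm = fit_offspring_glm(df["offspring_count"].to_numpy(), x1, I)
        lm = fit_growth_lm(
            df["circumference"].to_numpy(), x1, I, df["age_at_cut"].to_numpy()
        )
        report = {
            "offspring_glm": {
                "coefficients": glm.coefficients.to_dict(),
                "stderr": glm.stderr.to_dict(),
                "pvalues": glm.pvalues.to_dict(),
            },
            "growth_lm": {
                "coefficients": lm.coefficients.to_dict(),
                "stderr": lm.stderr.to_dict(),
                "pvalues": lm.pvalues.to_dict(),
                "r2_adj": lm.r2_adj,
            },
            "n": int(len(df)),
        }
        p = out / "fitness_glm.json"
        p.write_text(json.dumps(report, indent=2, sort_keys=True))
        return [p]


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns the manifest (also written to
    ``manifest.json`` in the run directory)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = _Stages(config, out)
    manifest: dict = {
        "seed": config.seed,
        "config": asdict(config) | {"stages": list(config.stages)},
        "stages": {},
    }
    for name in config.stages:
        if name not in ALL_STAGES:
            raise ValueError(f"unknown stage {name!r}")
        try:
            paths = getattr(stages, name)()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {p.name: _sha256(p) for p in paths}
    from . import __version__

    manifest["version"] = __version__
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
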