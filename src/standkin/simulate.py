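"""Synthetic mixed-stand generator with known ground truth.

Everything the downstream pipeline consumes can be produced here: per-site
allele frequencies for two partially diverged species (Balding-Nichols
model, so the per-locus Fst distribution is L-shaped at low divergence), a
pedigree with the four relationship categories found in natural
regeneration (selfed parent-offspring, parent-offspring, full-sib,
half-sib), genotypes by Mendelian gene dropping, read counts with
overdispersed depth, fitness traits with a tunable inbreeding effect, and a
small annotated genome (genes with exon/intron structure, a transposable-
element track, anchored and unanchored scaffolds) for capture-target
design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesFrequencies",
    "Pedigree",
    "GenotypeMatrix",
    "SiteCallTable",
    "ToyGenome",
    "simulate_species_freqs",
    "build_pedigree",
    "pedigree_pairs",
    "drop_genotypes",
    "simulate_read_counts",
    "simulate_fitness",
    "simulate_genome",
    "simulate_alignments",
    "random_sites",
]

MISSING = np.nan


@dataclass
class SpeciesFrequencies:
    """Per-site alternate-allele frequencies in two species.

    Attributes
    ----------
    p_anc : ndarray
        Ancestral (shared) allele frequency per site.
    p_a, p_b : ndarray
        Frequency of the alternate allele in species A and B.
    fst_nominal : float
        Divergence parameter of the Balding-Nichols draw, in [0, 1).
    """

    p_anc: np.ndarray
    p_a: np.ndarray
    p_b: np.ndarray
    fst_nominal: float

    @property
    def m(self) -> int:
        return self.p_anc.shape[0]

    def __post_init__(self) -> None:
        for arr in (self.p_anc, self.p_a, self.p_b):
            if arr.shape != self.p_anc.shape:
                raise ValueError("frequency arrays must share one length")
            if arr.size and (arr.min() < 0 or arr.max() > 1):
                raise ValueError("allele frequencies must lie in [0, 1]")


@dataclass
class Pedigree:
    """Individuals with zero, one, or two known parents.

    ``table`` has columns ``id, sire, dam, species, generation``; unknown
    parents are ``None``.  Parents always precede offspring in generation
    order; a selfed individual has ``sire == dam``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"id", "sire", "dam", "species", "generation"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"pedigree table needs columns {sorted(required)}")
        known = set(self.table["id"])
        if len(known) != len(self.table):
            raise ValueError("duplicate individual ids")
        gen = dict(zip(self.table["id"], self.table["generation"]))
        for _, row in self.table.iterrows():
            for par in (row["sire"], row["dam"]):
                if par is not None:
                    if par not in known:
                        raise ValueError(f"unknown parent {par!r} of {row['id']!r}")
                    if gen[par] >= row["generation"]:
                        raise ValueError("parents must precede offspring in generation order")

    @property
    def ids(self) -> list:
        return list(self.table["id"])

    @property
    def n(self) -> int:
        return len(self.table)

    def founders(self) -> list:
        t = self.table
        return list(t.loc[t["sire"].isna() & t["dam"].isna(), "id"])


@dataclass
class GenotypeMatrix:
    """n x m genotype codes: -1 / 0 / +1 for the two homozygotes and the
    heterozygote, NaN for missing.  +1 is the alternate-allele homozygote
    throughout the package."""

    codes: np.ndarray
    samples: list
    sites: pd.DataFrame  # columns: scaffold, pos, ref, alt

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (individuals x sites)")
        if self.codes.shape != (len(self.samples), len(self.sites)):
            raise ValueError("codes shape does not match samples/sites")
        ok = np.isnan(self.codes) | np.isin(self.codes, (-1.0, 0.0, 1.0))
        if not ok.all():
            raise ValueError("genotype codes must be -1, 0, +1, or NaN")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def m(self) -> int:
        return self.codes.shape[1]

    def missing_rate(self) -> float:
        return float(np.isnan(self.codes).mean()) if self.codes.size else 0.0


@dataclass
class SiteCallTable:
    """Per individual x site read depth and alternate-allele read counts."""

    depth: np.ndarray
    alt_reads: np.ndarray
    samples: list
    sites: pd.DataFrame

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        self.alt_reads = np.asarray(self.alt_reads)
        if self.depth.shape != self.alt_reads.shape:
            raise ValueError("depth and alt_reads must have the same shape")
        if (self.alt_reads > self.depth).any() or (self.depth < 0).any():
            raise ValueError("need 0 <= alt_reads <= depth")


@dataclass
class ToyGenome:
    """A small annotated genome: sequences, gene models, TE track, scaffold
    anchoring flags.  All intervals are 0-based half-open."""

    sequences: dict  # scaffold -> str
    genes: pd.DataFrame  # gene_id, scaffold, start, end, strand
    exons: pd.DataFrame  # gene_id, scaffold, start, end
    te: pd.DataFrame  # scaffold, start, end, family
    anchored: dict  # scaffold -> bool

    def __post_init__(self) -> None:
        for df, what in ((self.genes, "gene"), (self.exons, "exon"), (self.te, "TE")):
            for _, r in df.iterrows():
                L = len(self.sequences[r["scaffold"]])
                if not (0 <= r["start"] < r["end"] <= L):
                    raise ValueError(f"{what} interval outside sequence bounds")
        gene_span = {r["gene_id"]: (r["start"], r["end"]) for _, r in self.genes.iterrows()}
        for _, r in self.exons.iterrows():
            s, e = gene_span[r["gene_id"]]
            if r["start"] < s or r["end"] > e:
                raise ValueError("exon outside its gene")
        if set(self.anchored) != set(self.sequences):
            raise ValueError("anchoring flags must cover all scaffolds")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


# ---------------------------------------------------------------------------
# species allele frequencies


def simulate_species_freqs(m: int, fst: float, seed: int) -> SpeciesFrequencies:
    """Draw per-site allele frequencies for two species under the
    Balding-Nichols model.

    An ancestral frequency ``p`` is drawn per site (uniform on
    [0.05, 0.95]); each species' frequency is then a Beta draw with mean
    ``p`` and variance ``fst * p * (1 - p)``.  At ``fst = 0`` the two
    species are identical to the ancestor.  The realized per-locus Fst
    distribution is strongly L-shaped at low ``fst``: most loci barely
    differentiated, a thin tail of strongly differentiated ones.
    """
    if not 0 <= fst < 1:
        raise ValueError("fst must lie in [0, 1)")
    if m < 0:
        raise ValueError("m must be non-negative")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.05, 0.95, size=m)
    if fst == 0:
        p_a = p_anc.copy()
        p_b = p_anc.copy()
    else:
        scale = (1.0 - fst) / fst
        a = p_anc * scale
        b = (1.0 - p_anc) * scale
        p_a = rng.beta(a, b)
        p_b = rng.beta(a, b)
    return SpeciesFrequencies(p_anc=p_anc, p_a=p_a, p_b=p_b, fst_nominal=float(fst))


# ---------------------------------------------------------------------------
# pedigree construction

#: founders required per family of each category
_FAMILY_FOUNDERS = {"parent_offspring": 2, "full_sib": 2, "half_sib": 3, "selfed": 1}
#: offspring produced per family of each category
_FAMILY_OFFSPRING = {"parent_offspring": 1, "full_sib": 2, "half_sib": 2, "selfed": 1}


def build_pedigree(
    n_founders_a: int,
    n_founders_b: int,
    offspring_spec: dict | None = None,
    seed: int = 0,
) -> Pedigree:
    """Build a two-species stand pedigree.

    ``offspring_spec`` maps species label ("A"/"B") to a dict of family
    counts with keys ``parent_offspring``, ``full_sib``, ``half_sib``,
    ``selfed``.  Each family uses fresh founders of that species (so the
    expected relatedness of the produced pairs is exactly 0.5 / 0.5 / 0.25
    / 1 with no side relationships).  Founders left over stay unrelated
    background trees.
    """
    offspring_spec = offspring_spec or {}
    rng = np.random.default_rng(seed)
    rows = []
    founder_pool = {"A": [], "B": []}
    for sp, nf in (("A", n_founders_a), ("B", n_founders_b)):
        for i in range(nf):
            fid = f"{sp}_F{i + 1:03d}"
            rows.append({"id": fid, "sire": None, "dam": None, "species": sp, "generation": 0})
            founder_pool[sp].append(fid)

    for sp, fams in offspring_spec.items():
        if sp not in founder_pool:
            raise ValueError(f"unknown species label {sp!r}")
        need = sum(_FAMILY_FOUNDERS[cat] * cnt for cat, cnt in fams.items())
        if need > len(founder_pool[sp]):
            raise ValueError(
                f"species {sp}: {need} founders required for the requested "
                f"families but only {len(founder_pool[sp])} available"
            )
        pool = list(founder_pool[sp])
        rng.shuffle(pool)
        k = 0
        for cat, cnt in fams.items():
            if cat not in _FAMILY_FOUNDERS:
                raise ValueError(f"unknown family category {cat!r}")
            for j in range(cnt):
                take = _FAMILY_FOUNDERS[cat]
                parents = pool[: take]
                pool = pool[take:]
                tag = f"{sp}_{cat}{j + 1}"
                if cat == "selfed":
                    (p,) = parents
                    rows.append(
                        {"id": f"{tag}_o1", "sire": p, "dam": p, "species": sp, "generation": 1}
                    )
                elif cat == "parent_offspring":
                    s, d = parents
                    rows.append(
                        {"id": f"{tag}_o1", "sire": s, "dam": d, "species": sp, "generation": 1}
                    )
                elif cat == "full_sib":
                    s, d = parents
                    for o in (1, 2):
                        rows.append(
                            {"id": f"{tag}_o{o}", "sire": s, "dam": d, "species": sp, "generation": 1}
                        )
                else:  # half_sib: one shared parent, two different mates
                    shared, mate1, mate2 = parents
                    rows.append(
                        {"id": f"{tag}_o1", "sire": shared, "dam": mate1, "species": sp, "generation": 1}
                    )
                    rows.append(
                        {"id": f"{tag}_o2", "sire": shared, "dam": mate2, "species": sp, "generation": 1}
                    )
                k += take
    table = pd.DataFrame(rows, columns=["id", "sire", "dam", "species", "generation"])
    table["sire"] = table["sire"].astype(object).where(table["sire"].notna(), None)
    table["dam"] = table["dam"].astype(object).where(table["dam"].notna(), None)
    return Pedigree(table)


def pedigree_pairs(pedigree: Pedigree) -> pd.DataFrame:
    """Enumerate related pairs with their relationship category and
    pedigree-expected additive relatedness (assuming unrelated, non-inbred
    founders, as the generator guarantees).

    Returns a frame with columns ``i, j, category, expected``.  Categories:
    ``selfed_parent_offspring`` (1.0), ``parent_offspring`` (0.5),
    ``full_sib`` (0.5), ``half_sib`` (0.25).
    """
    t = pedigree.table
    pairs = []
    parents = {r["id"]: (r["sire"], r["dam"]) for _, r in t.iterrows()}
    offspring = [(r["id"], r["sire"], r["dam"]) for _, r in t.iterrows() if r["sire"] is not None]
    for oid, s, d in offspring:
        if s == d:
            pairs.append({"i": s, "j": oid, "category": "selfed_parent_offspring", "expected": 1.0})
        else:
            pairs.append({"i": s, "j": oid, "category": "parent_offspring", "expected": 0.5})
            pairs.append({"i": d, "j": oid, "category": "parent_offspring", "expected": 0.5})
    for a in range(len(offspring)):
        for b in range(a + 1, len(offspring)):
            ia, sa, da = offspring[a]
            ib, sb, db = offspring[b]
            shared = {sa, da} & {sb, db}
            if {sa, da} == {sb, db} and sa != da:
                pairs.append({"i": ia, "j": ib, "category": "full_sib", "expected": 0.5})
            elif len(shared) == 1 and sa != da and sb != db:
                pairs.append({"i": ia, "j": ib, "category": "half_sib", "expected": 0.25})
    return pd.DataFrame(pairs, columns=["i", "j", "category", "expected"])


# ---------------------------------------------------------------------------
# gene dropping


def random_sites(m: int, seed: int = 0, scaffolds: dict | None = None) -> pd.DataFrame:
    """Site metadata for simulated markers: scaffold, position, ref/alt.

    With no ``scaffolds`` mapping (name -> length) all sites go on one
    scaffold with ~200 bp mean spacing; otherwise sites are spread over
    scaffolds proportionally to length.
    """
    rng = np.random.default_rng(seed)
    if scaffolds is None:
        scaffolds = {"sc1": max(1, m) * 200}
    names = list(scaffolds)
    lengths = np.array([scaffolds[s] for s in names], dtype=float)
    counts = rng.multinomial(m, lengths / lengths.sum()) if m else np.zeros(len(names), int)
    frames = []
    bases = np.array(list("ACGT"))
    for name, cnt in zip(names, counts):
        if cnt == 0:
            continue
        pos = np.sort(rng.choice(scaffolds[name], size=min(cnt, scaffolds[name]), replace=False))
        ref = rng.choice(bases, size=len(pos))
        alt = np.array([rng.choice(bases[bases != r]) for r in ref])
        frames.append(pd.DataFrame({"scaffold": name, "pos": pos, "ref": ref, "alt": alt}))
    if not frames:
        return pd.DataFrame(columns=["scaffold", "pos", "ref", "alt"])
    return pd.concat(frames, ignore_index=True)


def drop_genotypes(
    pedigree: Pedigree,
    freqs: SpeciesFrequencies,
    seed: int = 0,
    sites: pd.DataFrame | None = None,
    return_origins: bool = False,
):
    """Mendelian gene dropping through a pedigree.

    Founders draw each haplotype Bernoulli from their species' allele
    frequency (Hardy-Weinberg); an ``admixed`` founder draws one haplotype
    from each species.  Every offspring allele is a copy of one uniformly
    chosen parental allele per locus, so alleles are conserved: each
    non-founder allele traces back to a founder allele.

    With ``return_origins=True`` also returns ``(haplotypes, origins)``
    where ``origins`` tags every allele with the integer id of the founder
    haplotype it descends from (2n x m each).
    """
    rng = np.random.default_rng(seed)
    t = pedigree.table.sort_values("generation", kind="stable")
    m = freqs.m
    ids = list(t["id"])
    index = {iid: k for k, iid in enumerate(ids)}
    haps = np.zeros((2 * len(ids), m), dtype=np.int8)
    origins = np.zeros((2 * len(ids), m), dtype=np.int32)
    next_tag = 0
    for _, row in t.iterrows():
        k = index[row["id"]]
        if row["sire"] is None:
            sp = row["species"]
            if sp == "A":
                ps = (freqs.p_a, freqs.p_a)
            elif sp == "B":
                ps = (freqs.p_b, freqs.p_b)
            elif sp == "admixed":
                ps = (freqs.p_a, freqs.p_b)
            else:
                raise ValueError(f"unknown species label {sp!r} for founder {row['id']!r}")
            for h, p in enumerate(ps):
                haps[2 * k + h] = rng.random(m) < p
                origins[2 * k + h] = next_tag
                next_tag += 1
        else:
            for h, par in enumerate((row["sire"], row["dam"])):
                pk = index[par]
                pick = rng.integers(0, 2, size=m)  # which parental haplotype per locus
                src = np.where(pick == 0, 2 * pk, 2 * pk + 1)
                cols = np.arange(m)
                haps[2 * k + h] = haps[src, cols]
                origins[2 * k + h] = origins[src, cols]
    codes = (haps[0::2].astype(np.int16) + haps[1::2]) - 1
    if sites is None:
        sites = random_sites(m, seed=seed + 1)
    # restore the pedigree's original ordering
    order = [index[iid] for iid in pedigree.ids]
    gm = GenotypeMatrix(
        codes=codes[order].astype(float), samples=list(pedigree.ids), sites=sites.reset_index(drop=True)
    )
    if return_origins:
        hap_order = np.array([[2 * k, 2 * k + 1] for k in order]).ravel()
        return gm, haps[hap_order], origins[hap_order]
    return gm


# ---------------------------------------------------------------------------
# read counts


def simulate_read_counts(
    genotypes: GenotypeMatrix,
    mean_depth: float = 95.0,
    depth_dispersion: float = 3.0,
    error_rate: float = 0.005,
    dropout: float = 0.02,
    seed: int = 0,
) -> SiteCallTable:
    """Simulate per-site read depths and alternate-allele read counts.

    Depth is negative-binomial with mean ``mean_depth`` and variance
    ``mean_depth + mean_depth**2 / depth_dispersion`` (capture runs show
    large depth variation, so the default dispersion is small).  A fraction
    ``dropout`` of individual x site cells gets depth 0 (failed capture).
    Given the true genotype, each read carries the alternate allele with
    probability ``error_rate`` (hom-ref), ``0.5`` (het), or
    ``1 - error_rate`` (hom-alt).
    """
    if mean_depth < 0:
        raise ValueError("mean_depth must be >= 0")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    n, m = genotypes.codes.shape
    if mean_depth == 0:
        depth = np.zeros((n, m), dtype=np.int64)
    else:
        k = float(depth_dispersion)
        p = k / (k + mean_depth)
        depth = rng.negative_binomial(k, p, size=(n, m))
    if dropout > 0:
        depth[rng.random((n, m)) < dropout] = 0
    prob = np.full((n, m), 0.5)
    prob[genotypes.codes == -1] = error_rate
    prob[genotypes.codes == 1] = 1.0 - error_rate
    prob[np.isnan(genotypes.codes)] = error_rate  # treat as ref if truly unknown
    alt = rng.binomial(depth, prob)
    return SiteCallTable(depth=depth, alt_reads=alt, samples=list(genotypes.samples), sites=genotypes.sites)


# ---------------------------------------------------------------------------
# fitness traits


def simulate_fitness(
    pedigree: Pedigree,
    inbreeding_true: np.ndarray,
    gamma: float = -3.6,
    beta1: float = 0.2,
    alpha: float = 2.0,
    env_loadings: tuple = (0.8, 0.7, 0.6, 0.5, 0.4),
    noise: float = 20.0,
    seed: int = 0,
    age_range: tuple = (78, 102),
    circ_alpha: float = 60.0,
    circ_beta1: float = 5.0,
    circ_gamma: float = -30.0,
    circ_age: float = 1.5,
) -> pd.DataFrame:
    """Simulate fitness proxies with a tunable inbreeding effect.

    Reproductive success (offspring count) is Poisson with log-mean
    ``alpha + beta1 * X + gamma * I`` where ``X`` is a latent environment
    factor and ``I`` the true inbreeding.  Five environmental covariates
    load on ``X`` (their first principal axis recovers it).  Stem
    circumference (cm) is Gaussian:
    ``circ_alpha + circ_beta1 * X + circ_gamma * I + circ_age * age`` plus
    noise, with felling age uniform on ``age_range`` (years).
    """
    inbreeding_true = np.asarray(inbreeding_true, dtype=float)
    n = pedigree.n
    if inbreeding_true.shape != (n,):
        raise ValueError("need one inbreeding value per individual")
    rng = np.random.default_rng(seed)
    loadings = np.asarray(env_loadings, dtype=float)
    factor = rng.normal(size=n)
    env = factor[:, None] * loadings[None, :] + rng.normal(size=(n, len(loadings))) * np.sqrt(
        np.clip(1.0 - loadings**2, 0.0, None)
    )
    eta = alpha + beta1 * factor + gamma * inbreeding_true
    if not np.isfinite(eta).all():
        raise ValueError("non-finite linear predictor")
    offspring = rng.poisson(np.exp(eta))
    age = rng.integers(age_range[0], age_range[1] + 1, size=n)
    circ = (
        circ_alpha
        + circ_beta1 * factor
        + circ_gamma * inbreeding_true
        + circ_age * age
        + (rng.normal(size=n) * noise if noise > 0 else 0.0)
    )
    out = pd.DataFrame(
        {
            "id": pedigree.ids,
            "offspring_count": offspring,
            "circumference": circ,
            "age_at_cut": age,
            "inbreeding_true": inbreeding_true,
            "env_factor_true": factor,
        }
    )
    for j in range(len(loadings)):
        out[f"env{j + 1}"] = env[:, j]
    return out


# ---------------------------------------------------------------------------
# toy genome


def _random_sequence(rng, length: int, block: int = 1000) -> np.ndarray:
    """DNA as a byte array; GC content varies by ~1 kb block (Beta(6,6)),
    giving a realistic spread for the 30-60% GC filter to act on."""
    n_blocks = (length + block - 1) // block
    gc = rng.beta(6, 6, size=n_blocks)
    seq = np.empty(length, dtype="S1")
    letters_at = np.array([b"A", b"C", b"G", b"T"])
    for i in range(n_blocks):
        lo, hi = i * block, min((i + 1) * block, length)
        g = gc[i]
        probs = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
        seq[lo:hi] = rng.choice(letters_at, size=hi - lo, p=probs)
    return seq


def simulate_genome(
    length: int = 2_000_000,
    n_genes: int = 120,
    te_fraction: float = 0.3,
    n_scaffolds: int = 5,
    seed: int = 0,
    n_unanchored: int = 1,
    gene_length_range: tuple = (600, 6000),
    max_exons: int = 4,
) -> ToyGenome:
    """Generate a small annotated genome for capture-target design.

    Genes (non-overlapping, exon-first and exon-last structure, 1 to
    ``max_exons`` exons) and a TE track covering approximately
    ``te_fraction`` of the sequence.  TE intervals carry one of three
    family sequences pasted into the scaffold, so the genome is genuinely
    repetitive where the track says it is.  The last ``n_unanchored``
    scaffolds are flagged unanchored.
    """
    if n_scaffolds < 1:
        raise ValueError("need at least one scaffold")
    if not 0 <= n_unanchored < n_scaffolds:
        raise ValueError("n_unanchored must leave at least one anchored scaffold")
    if not 0 <= te_fraction < 0.9:
        raise ValueError("te_fraction must lie in [0, 0.9)")
    rng = np.random.default_rng(seed)
    # scaffold lengths: roughly equal with +-20% jitter
    w = rng.uniform(0.8, 1.2, size=n_scaffolds)
    lens = np.maximum((length * w / w.sum()).astype(int), 1000)
    names = [f"sc{i + 1}" for i in range(n_scaffolds)]
    seqs = {nm: _random_sequence(rng, int(L)) for nm, L in zip(names, lens)}

    # genes: rejection placement, >=500 bp apart
    genes, exons = [], []
    occupied = {nm: [] for nm in names}
    glo, ghi = gene_length_range
    attempts = 0
    gi = 0
    while gi < n_genes and attempts < 50 * n_genes:
        attempts += 1
        nm = names[rng.integers(0, n_scaffolds)]
        L = int(np.exp(rng.uniform(np.log(glo), np.log(ghi))))
        if L + 1000 > len(seqs[nm]):
            continue
        start = int(rng.integers(500, len(seqs[nm]) - L - 500))
        end = start + L
        if any(not (end + 500 <= s or start >= e + 500) for s, e in occupied[nm]):
            continue
        occupied[nm].append((start, end))
        gid = f"g{gi + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append({"gene_id": gid, "scaffold": nm, "start": start, "end": end, "strand": strand})
        # partition into alternating exon/intron, exon first and last
        n_ex = int(rng.integers(1, max_exons + 1))
        n_seg = 2 * n_ex - 1
        while n_seg * 130 > L:  # segments must each fit >=130 bp
            n_ex -= 1
            n_seg = 2 * n_ex - 1
        cuts = np.sort(rng.choice(np.arange(130, L - 129), size=n_seg - 1, replace=False)) if n_seg > 1 else np.array([], int)
        bounds = np.concatenate([[0], cuts, [L]])
        # enforce minimum segment length by even fallback when jittered cuts collide
        if n_seg > 1 and np.diff(bounds).min() < 80:
            bounds = np.linspace(0, L, n_seg + 1).astype(int)
        for s_i in range(0, n_seg, 2):
            exons.append(
                {
                    "gene_id": gid,
                    "scaffold": nm,
                    "start": start + int(bounds[s_i]),
                    "end": start + int(bounds[s_i + 1]),
                }
            )
        gi += 1
    if gi < n_genes:
        raise ValueError("infeasible packing: could not place all genes")

    # TE track: paste family sequences outside genes until coverage reached
    families = {f"fam{f + 1}": _random_sequence(rng, 900) for f in range(3)}
    te_rows = []
    target_cov = te_fraction * sum(len(s) for s in seqs.values())
    covered = 0
    te_occupied = {nm: list(occupied[nm]) for nm in names}
    attempts = 0
    while covered < target_cov and attempts < 200000:
        attempts += 1
        nm = names[rng.integers(0, n_scaffolds)]
        L = int(rng.integers(200, 1500))
        if L >= len(seqs[nm]):
            continue
        start = int(rng.integers(0, len(seqs[nm]) - L))
        end = start + L
        if any(not (end <= s or start >= e) for s, e in te_occupied[nm]):
            continue
        fam = list(families)[rng.integers(0, 3)]
        tile = np.resize(families[fam], L)
        seqs[nm][start:end] = tile
        te_occupied[nm].append((start, end))
        te_rows.append({"scaffold": nm, "start": start, "end": end, "family": fam})
        covered += L
    if covered < target_cov * 0.9:
        raise ValueError("infeasible packing: TE fraction unreachable with the gene layout")

    anchored = {nm: True for nm in names}
    for nm in names[len(names) - n_unanchored :] if n_unanchored else []:
        anchored[nm] = False
    return ToyGenome(
        sequences={nm: b"".join(seqs[nm]).decode() for nm in names},
        genes=pd.DataFrame(genes, columns=["gene_id", "scaffold", "start", "end", "strand"]),
        exons=pd.DataFrame(exons, columns=["gene_id", "scaffold", "start", "end"]).sort_values(
            ["gene_id", "start"], ignore_index=True
        ),
        te=pd.DataFrame(te_rows, columns=["scaffold", "start", "end", "family"]).sort_values(
            ["scaffold", "start"], ignore_index=True
        ),
        anchored=anchored,
    )


# ---------------------------------------------------------------------------
# read alignment summaries (for capture QC)


def simulate_alignments(
    genome: ToyGenome,
    targets: pd.DataFrame,
    n_reads: int = 20000,
    on_target_frac: float = 0.25,
    read_length_range: tuple = (140, 190),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a read-alignment summary table (id, scaffold, start, end,
    read_length) for enrichment QC: a fraction of reads lands overlapping a
    random capture target, the rest map uniformly over the genome."""
    rng = np.random.default_rng(seed)
    names = list(genome.sequences)
    lens = {nm: len(genome.sequences[nm]) for nm in names}
    probs = np.array([lens[nm] for nm in names], dtype=float)
    probs /= probs.sum()
    rows = []
    tg = targets.reset_index(drop=True)
    for i in range(n_reads):
        rl = int(rng.integers(read_length_range[0], read_length_range[1] + 1))
        if len(tg) and rng.random() < on_target_frac:
            t = tg.iloc[int(rng.integers(0, len(tg)))]
            lo = max(0, int(t["start"]) - rl + 1)
            hi = min(lens[t["scaffold"]] - rl, int(t["end"]) - 1)
            start = int(rng.integers(lo, max(lo + 1, hi + 1)))
            nm = t["scaffold"]
        else:
            nm = names[int(rng.choice(len(names), p=probs))]
            start = int(rng.integers(0, max(1, lens[nm] - rl)))
        rows.append(
            {"read_id": f"r{i + 1}", "scaffold": nm, "start": start, "end": start + rl, "read_length": rl}
        )
    return pd.DataFrame(rows, columns=["read_id", "scaffold", "start", "end", "read_length"])
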