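"""Synthetic outbred F2 intercross generator.

Emulates the data structure of a RADseq cross between two self-incompatible,
potentially heterozygous parents (a lowland "b" and an alpine "r" species):
~1000 RAD loci of <=1.5 kb along 8 chromosomes, up to four segregating
haplotypes per locus, ~57% polymorphic loci, an F2 of 216 produced by
intercrossing two full-sib F1s, additive multi-QTL quantitative traits, one
monogenic dominant trait (trichome suppression), one transmission-ratio
distortion region, and distance-dependent missingness plus genotyping error.

Crossovers are placed as a Poisson process on the cM scale with no
interference (Haldane).  One seeded generator drives every stochastic step
in documented order: parents, F1s, F2 meioses, phenotypes, observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import MISSING, SnpMatrix

ORIGIN_B, ORIGIN_R = 0, 1
NUCS = np.array(list("ACGT"))


@dataclass
class QtlSpec:
    trait: str
    chrom: str
    pos_cm: float
    additive: float  # effect of one b allele; positive = b increases trait
    dominance: float = 0.0


@dataclass
class TrdSpec:
    chrom: str = "Chr1"
    pos_cm: float = 26.0
    s: float = 0.0  # gametic selection coefficient against the b allele


def default_qtl() -> list[QtlSpec]:
    return [
        QtlSpec("PlHt", "Chr2", 20.0, 0.50),
        QtlSpec("PlHt", "Chr8", 30.0, 0.50),
        QtlSpec("LfLW", "Chr1", 10.0, 0.40, 0.40),  # fully dominant b allele
        QtlSpec("LfLW", "Chr5", 25.0, 0.45),
        QtlSpec("LfLW", "Chr7", 40.0, 0.45),
        QtlSpec("BrIn", "Chr2", 35.0, 0.50),
        QtlSpec("BrIn", "Chr8", 15.0, -0.50),  # transgressive: opposite sign
    ]


@dataclass
class SimConfig:
    n_chrom: int = 8
    chrom_cm: float = 52.25       # 418 cM map / 8 groups
    chrom_bp: int = 65_212_500    # 521.7 Mb genome / 8
    n_rad_loci: int = 1000
    polymorphic_fraction: float = 0.57
    snps_per_locus_mean: float = 3.0  # truncated Poisson, >= 1
    max_snps_per_locus: int = 8
    locus_len_bp: int = 630       # mean RAD locus span
    n_f2: int = 216
    parent_het: float = 0.4       # per-parent heterozygosity at polymorphic loci
    qtl: list[QtlSpec] = field(default_factory=default_qtl)
    residual_sd: float = 1.0
    trichome_chrom: str = "Chr8"
    trichome_cm: float = 43.6     # b allele = dominant trichome suppressor
    trd: TrdSpec = field(default_factory=lambda: TrdSpec(s=0.2))
    missing_rate: float = 0.1     # missingness at the distal end of a locus
    error_rate: float = 0.01      # per-SNP genotype miscall probability (F2)
    noise_parents: bool = False   # apply error/missingness to parents and F1s
    even_spacing: bool = False    # place loci evenly instead of uniformly
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.trd.s <= 1.0:
            raise ValueError("TRD selection coefficient must be in [0, 1]")
        if not 0.0 <= self.polymorphic_fraction <= 1.0:
            raise ValueError("polymorphic fraction must be in [0, 1]")
        names = self.chrom_names
        for q in self.qtl:
            if q.chrom not in names or not 0 <= q.pos_cm <= self.chrom_cm:
                raise ValueError(f"QTL {q.trait} off the map: {q.chrom}:{q.pos_cm}")

    @property
    def chrom_names(self) -> list[str]:
        return [f"Chr{i + 1}" for i in range(self.n_chrom)]


# ---------------------------------------------------------------------------
# haploid genomes as founder-id mosaics


class FounderChrom:
    def __init__(self, founder: int):
        self.founder = founder

    def founder_at(self, pos_cm: np.ndarray) -> np.ndarray:
        return np.full(len(pos_cm), self.founder, dtype=np.int8)


class RecombinantChrom:
    """A gamete chromosome: mosaic of the two parental copies."""

    def __init__(self, copy0, copy1, breaks_cm: np.ndarray, start: int):
        self.copies = (copy0, copy1)
        self.breaks = breaks_cm
        self.start = start

    def founder_at(self, pos_cm: np.ndarray) -> np.ndarray:
        k = (self.start + np.searchsorted(self.breaks, pos_cm)) % 2
        a = self.copies[0].founder_at(pos_cm)
        b = self.copies[1].founder_at(pos_cm)
        return np.where(k == 0, a, b).astype(np.int8)


Diploid = list[tuple[object, object]]  # per chromosome: (maternal, paternal)


def _meiosis(individual: Diploid, chrom_cm: float, rng: np.random.Generator) -> list:
    gamete = []
    for mat, pat in individual:
        n_x = rng.poisson(chrom_cm / 100.0)
        breaks = np.sort(rng.uniform(0.0, chrom_cm, n_x))
        start = int(rng.integers(2))
        gamete.append(RecombinantChrom(mat, pat, breaks, start))
    return gamete


# ---------------------------------------------------------------------------
# genome layout and founder haplotypes


@dataclass
class SimGenome:
    config: SimConfig
    loci: pd.DataFrame  # locus, chrom, chrom_idx, start, end, cm, polymorphic, n_snps, anchor_left
    snp_offsets: list[np.ndarray]
    founder_haps: list[np.ndarray | None]  # per locus, (4, m) 0/1; None if monomorphic
    ref: list[np.ndarray]
    alt: list[np.ndarray]

    def loci_on(self, chrom: str) -> pd.DataFrame:
        return self.loci[self.loci["chrom"] == chrom]


def _locus_positions(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = np.full(cfg.n_chrom, cfg.n_rad_loci // cfg.n_chrom)
    per_chrom[: cfg.n_rad_loci % cfg.n_chrom] += 1
    rows = []
    for ci, (name, k) in enumerate(zip(cfg.chrom_names, per_chrom)):
        if cfg.even_spacing:
            bp = np.linspace(0, cfg.chrom_bp - cfg.locus_len_bp, k + 2)[1:-1]
            bp = bp.astype(np.int64)
        else:
            bp = np.sort(rng.integers(0, cfg.chrom_bp - cfg.locus_len_bp, k))
        for p in bp:
            rows.append((name, ci, int(p)))
    df = pd.DataFrame(rows, columns=["chrom", "chrom_idx", "start"])
    df["end"] = df["start"] + cfg.locus_len_bp
    df["cm"] = df["start"] / cfg.chrom_bp * cfg.chrom_cm
    df["locus"] = df["chrom"] + ":" + df["start"].astype(str)
    return df


def simulate_parents(config: SimConfig, rng: np.random.Generator | None = None):
    """Draw founder haplotypes, the two parents, and two full-sib F1s.

    Each parent is heterozygous at a configurable fraction of polymorphic
    loci, so a locus can carry one to four distinct haplotypes across the
    four founder chromosomes.  The F1s are two independent meioses of each
    parent.  Returns (genome, parents, f1s) where parents/f1s map sample id
    to a diploid founder-mosaic genome.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cfg = config
    loci = _locus_positions(cfg, rng)
    n_loci = len(loci)
    loci["polymorphic"] = rng.random(n_loci) < cfg.polymorphic_fraction
    snp_offsets: list[np.ndarray] = []
    founder_haps: list[np.ndarray | None] = []
    refs, alts, n_snps, anchor_left = [], [], [], []
    for poly in loci["polymorphic"]:
        if not poly:
            snp_offsets.append(np.empty(0, dtype=np.int64))
            founder_haps.append(None)
            refs.append(np.empty(0, dtype="U1"))
            alts.append(np.empty(0, dtype="U1"))
            n_snps.append(0)
            anchor_left.append(True)
            continue
        m = _trunc_poisson(cfg.snps_per_locus_mean, cfg.max_snps_per_locus, rng)
        offs = np.sort(rng.choice(cfg.locus_len_bp, size=m, replace=False))
        haps = _founder_haplotypes(m, cfg.parent_het, rng)
        ref_idx = rng.integers(0, 4, m)
        alt_shift = rng.integers(1, 4, m)
        snp_offsets.append(offs)
        founder_haps.append(haps)
        refs.append(NUCS[ref_idx])
        alts.append(NUCS[(ref_idx + alt_shift) % 4])
        n_snps.append(m)
        anchor_left.append(bool(rng.integers(2)))
    loci["n_snps"] = n_snps
    loci["anchor_left"] = anchor_left
    genome = SimGenome(cfg, loci, snp_offsets, founder_haps, refs, alts)

    parents = {
        "PB": [(FounderChrom(0), FounderChrom(1)) for _ in range(cfg.n_chrom)],
        "PR": [(FounderChrom(2), FounderChrom(3)) for _ in range(cfg.n_chrom)],
    }
    f1s = {}
    for name in ("F1a", "F1b"):
        gb = _meiosis(parents["PB"], cfg.chrom_cm, rng)
        gr = _meiosis(parents["PR"], cfg.chrom_cm, rng)
        f1s[name] = list(zip(gb, gr))  # maternal from b, paternal from r
    return genome, parents, f1s


def _trunc_poisson(mean: float, cap: int, rng: np.random.Generator) -> int:
    while True:
        m = int(rng.poisson(mean))
        if 1 <= m <= cap:
            return m


def _founder_haplotypes(m: int, het: float, rng: np.random.Generator) -> np.ndarray:
    """Four founder haplotype vectors (B1, B2, R1, R2), each of length m.

    Within-parent heterozygosity is Bernoulli(het); vectors are drawn
    uniformly, so haplotypes may be shared between parents (in which case
    their origin is unresolvable downstream, as in real data).  The locus is
    guaranteed polymorphic overall.
    """
    while True:
        hb = rng.integers(0, 2, (2, m), dtype=np.int8)
        hr = rng.integers(0, 2, (2, m), dtype=np.int8)
        if rng.random() >= het:
            hb[1] = hb[0]
        elif np.array_equal(hb[0], hb[1]):
            continue
        if rng.random() >= het:
            hr[1] = hr[0]
        elif np.array_equal(hr[0], hr[1]):
            continue
        haps = np.vstack([hb, hr])
        if not (haps == haps[0]).all():
            return haps


# ---------------------------------------------------------------------------
# F2 generation


@dataclass
class TruthSet:
    """Pre-noise truth: founder origins, haplotypes, QTL genotypes."""

    genome: SimGenome
    f2_ids: list[str]
    founder_mat: np.ndarray  # (n_f2, n_loci) founder ids of the maternal copy
    founder_pat: np.ndarray
    f1_founders: dict[str, np.ndarray]  # sample -> (2, n_loci)
    species_code: np.ndarray  # (n_f2, n_loci), 0 bb / 1 br / 2 rr
    qtl_x: dict[str, np.ndarray]  # trait -> (n_f2, n_qtl) b-allele count - 1
    qtl_z: dict[str, np.ndarray]
    trichome_b: np.ndarray  # (n_f2,) bool: carries >=1 b allele at trichome locus
    trd_locus: str | None

    def haplotype_pair(self, ind: int, locus: int) -> tuple[tuple, tuple] | None:
        haps = self.genome.founder_haps[locus]
        if haps is None:
            return None
        a = tuple(haps[self.founder_mat[ind, locus]])
        b = tuple(haps[self.founder_pat[ind, locus]])
        return (a, b)


def _eval_diploid(ind: Diploid, genome: SimGenome) -> np.ndarray:
    """Founder ids of both copies at every locus; shape (2, n_loci)."""
    out = np.empty((2, len(genome.loci)), dtype=np.int8)
    for ci, chrom in enumerate(genome.config.chrom_names):
        sel = genome.loci["chrom_idx"].to_numpy() == ci
        cm = genome.loci.loc[sel, "cm"].to_numpy()
        mat, pat = ind[ci]
        out[0, sel] = mat.founder_at(cm)
        out[1, sel] = pat.founder_at(cm)
    return out


def _founder_at_point(ind: Diploid, chrom_idx: int, cm: float) -> tuple[int, int]:
    mat, pat = ind[chrom_idx]
    p = np.array([cm])
    return int(mat.founder_at(p)[0]), int(pat.founder_at(p)[0])


def simulate_f2(f1a: Diploid, f1b: Diploid, n: int, config: SimConfig,
                genome: SimGenome, rng: np.random.Generator) -> tuple[list, TruthSet]:
    """Intercross the two F1s to produce n F2 individuals plus the truth set.

    Transmission-ratio distortion is applied as gamete-stage rejection
    sampling: a gamete carrying the b allele at the TRD locus is discarded
    with probability s and the meiosis redrawn.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = config
    chrom_idx = {c: i for i, c in enumerate(cfg.chrom_names)}
    trd_ci, trd_cm, s = chrom_idx[cfg.trd.chrom], cfg.trd.pos_cm, cfg.trd.s

    def draw_gamete(parent: Diploid):
        while True:
            g = _meiosis(parent, cfg.chrom_cm, rng)
            if s == 0.0:
                return g
            fid = g[trd_ci].founder_at(np.array([trd_cm]))[0]
            if fid >= 2 or rng.random() >= s:  # founders 0,1 carry the b allele
                return g

    f2: list[Diploid] = []
    for _ in range(n):
        gm = draw_gamete(f1a)
        gp = draw_gamete(f1b)
        f2.append(list(zip(gm, gp)))

    n_loci = len(genome.loci)
    founder_mat = np.empty((n, n_loci), dtype=np.int8)
    founder_pat = np.empty((n, n_loci), dtype=np.int8)
    for i, ind in enumerate(f2):
        fids = _eval_diploid(ind, genome)
        founder_mat[i] = fids[0]
        founder_pat[i] = fids[1]
    species = (founder_mat // 2 + founder_pat // 2).astype(np.int8)

    qtl_x: dict[str, np.ndarray] = {}
    qtl_z: dict[str, np.ndarray] = {}
    traits = sorted({q.trait for q in cfg.qtl})
    for trait in traits:
        specs = [q for q in cfg.qtl if q.trait == trait]
        x = np.empty((n, len(specs)))
        z = np.empty((n, len(specs)))
        for j, q in enumerate(specs):
            ci = chrom_idx[q.chrom]
            for i, ind in enumerate(f2):
                fm, fp = _founder_at_point(ind, ci, q.pos_cm)
                nb = (fm < 2) + (fp < 2)
                x[i, j] = nb - 1
                z[i, j] = 1.0 if nb == 1 else 0.0
        qtl_x[trait] = x
        qtl_z[trait] = z

    tri_ci = chrom_idx[cfg.trichome_chrom]
    trichome_b = np.empty(n, dtype=bool)
    for i, ind in enumerate(f2):
        fm, fp = _founder_at_point(ind, tri_ci, cfg.trichome_cm)
        trichome_b[i] = (fm < 2) or (fp < 2)

    loci_trd = genome.loci_on(cfg.trd.chrom)
    trd_locus = None
    if s > 0 and len(loci_trd):
        j = (loci_trd["cm"] - trd_cm).abs().idxmin()
        trd_locus = genome.loci.loc[j, "locus"]

    f2_ids = [f"F2_{i + 1:04d}" for i in range(n)]
    f1_founders = {}
    truth = TruthSet(genome, f2_ids, founder_mat, founder_pat, f1_founders,
                     species, qtl_x, qtl_z, trichome_b, trd_locus)
    return f2, truth


def simulate_phenotypes(truth: TruthSet, config: SimConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Additive(+dominance) quantitative traits and the monogenic trichome trait.

    trait = sum over QTL of (a*x + d*z) + N(0, sigma^2), with x in {-1,0,1}
    counting b alleles and z the heterozygote indicator.  Trichome trait:
    glabrous (1) iff the individual carries >=1 b allele at the trichome
    locus (dominant suppressor from the lowland parent).
    """
    cfg = config
    n = len(truth.f2_ids)
    data = {}
    for trait in sorted(truth.qtl_x):
        specs = [q for q in cfg.qtl if q.trait == trait]
        a = np.array([q.additive for q in specs])
        d = np.array([q.dominance for q in specs])
        g = truth.qtl_x[trait] @ a + truth.qtl_z[trait] @ d
        data[trait] = g + rng.normal(0.0, cfg.residual_sd, n)
    data["Tri_glabrous"] = truth.trichome_b.astype(int)
    return pd.DataFrame(data, index=pd.Index(truth.f2_ids, name="individual"))


# ---------------------------------------------------------------------------
# SNP observation layer


def emit_snp_observations(parents: dict, f1s: dict, f2: list, truth: TruthSet,
                          config: SimConfig, rng: np.random.Generator) -> SnpMatrix:
    """Expand haplotypes to SNP calls with coverage-shaped missingness and error.

    Missingness per SNP is missing_rate * (distance from the locus anchor end
    / locus span), mimicking read coverage decaying away from the restriction
    site; genotype errors flip a call to one of the other two codes.  Noise
    is applied to F2 individuals (and to parents/F1s if noise_parents).
    """
    cfg = config
    genome = truth.genome
    sample_genomes = {**parents, **f1s}
    names = ["PB", "PR", "F1a", "F1b"] + truth.f2_ids
    roles = {"PB": "parentB", "PR": "parentR", "F1a": "F1a", "F1b": "F1b"}
    roles.update({i: "F2" for i in truth.f2_ids})

    founders = {}
    for nm in ("PB", "PR", "F1a", "F1b"):
        founders[nm] = _eval_diploid(sample_genomes[nm], genome)
        if nm.startswith("F1"):
            truth.f1_founders[nm] = founders[nm]

    chroms, poss, refs, alts, rows = [], [], [], [], []
    n_samples = len(names)
    loci = genome.loci
    for li in range(len(loci)):
        haps = genome.founder_haps[li]
        if haps is None:
            continue
        offs = genome.snp_offsets[li]
        m = len(offs)
        geno = np.empty((m, n_samples), dtype=np.int8)
        for j, nm in enumerate(names):
            if nm in founders:
                fm, fp = founders[nm][0, li], founders[nm][1, li]
            else:
                fm = truth.founder_mat[j - 4, li]
                fp = truth.founder_pat[j - 4, li]
            geno[:, j] = haps[fm] + haps[fp]
        # noise
        noisy = slice(0, n_samples) if cfg.noise_parents else slice(4, n_samples)
        sub = geno[:, noisy]
        if cfg.error_rate > 0:
            flips = rng.random(sub.shape) < cfg.error_rate
            if flips.any():
                shift = rng.integers(1, 3, size=int(flips.sum()))
                sub[flips] = (sub[flips] + shift) % 3
        if cfg.missing_rate > 0:
            frac = _anchor_distance_fraction(offs, bool(loci["anchor_left"].iloc[li]))
            p_miss = cfg.missing_rate * frac
            drop = rng.random(sub.shape) < p_miss[:, None]
            sub[drop] = MISSING
        geno[:, noisy] = sub
        start = int(loci["start"].iloc[li])
        for k in range(m):
            chroms.append(loci["chrom"].iloc[li])
            poss.append(start + int(offs[k]))
            refs.append(genome.ref[li][k])
            alts.append(genome.alt[li][k])
            rows.append(geno[k])
    mat = SnpMatrix(np.array(chroms), np.array(poss, dtype=np.int64),
                    np.array(refs), np.array(alts),
                    np.array(rows, dtype=np.int8), names, roles)
    order = np.lexsort((mat.pos, mat.chrom))
    mat.chrom, mat.pos = mat.chrom[order], mat.pos[order]
    mat.ref, mat.alt, mat.geno = mat.ref[order], mat.alt[order], mat.geno[order]
    return mat


def _anchor_distance_fraction(offsets: np.ndarray, anchor_left: bool) -> np.ndarray:
    if len(offsets) == 1:
        return np.array([0.5])
    span = offsets.max() - offsets.min()
    frac = (offsets - offsets.min()) / span
    return frac if anchor_left else 1.0 - frac


def simulate_cross(config: SimConfig):
    """Full generator: returns (genome, truth, snp_matrix, phenotypes)."""
    rng = np.random.default_rng(config.seed)
    genome, parents, f1s = simulate_parents(config, rng)
    f2, truth = simulate_f2(f1s["F1a"], f1s["F1b"], config.n_f2, config, genome, rng)
    phen = simulate_phenotypes(truth, config, rng)
    mat = emit_snp_observations(parents, f1s, f2, truth, config, rng)
    return genome, truth, mat, phen


# ---------------------------------------------------------------------------
# landscape and family-structure generators for the morphology pipeline


def simulate_landscape(n_populations: tuple[int, int] = (10, 8),
                       admixture_intercept: float = 0.35,
                       admixture_slope: float = -0.02,
                       admixture_sd: float = 0.05,
                       morph_extremes: tuple[float, float] = (2.0, -2.0),
                       morph_slope: float = 0.15,
                       morph_sd: float = 0.2,
                       region_km: float = 30.0,
                       sympatric_pair: bool = True,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Site table for the distance-to-heterospecific regressions.

    Populations of the two species are scattered over a square region;
    admixture declines linearly with distance to the nearest heterospecific
    population and the morphology index becomes more extreme with distance,
    both plus Gaussian noise.  With sympatric_pair, one population of each
    species shares a site (distance 0; the analysis floors it at 0.1 km).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n_b, n_r = n_populations
    if n_b < 2 or n_r < 2:
        raise ValueError("need >=2 populations per species")
    species = ["barrelieri"] * n_b + ["rupestre"] * n_r
    xy = rng.uniform(0, region_km, (n_b + n_r, 2))
    if sympatric_pair:
        xy[n_b] = xy[0]
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1) ** 0.5
    hetero = np.array([[s1 != s2 for s2 in species] for s1 in species])
    dist = np.where(hetero, d2, np.inf).min(axis=1)
    admix = admixture_intercept + admixture_slope * dist \
        + rng.normal(0, admixture_sd, len(dist))
    admix = np.clip(admix, 0.0, 1.0)
    mu_b, mu_r = morph_extremes
    morph = np.where(np.array(species) == "barrelieri",
                     mu_b - morph_slope * (region_km / 2 - dist),
                     mu_r + morph_slope * (region_km / 2 - dist))
    morph = morph + rng.normal(0, morph_sd, len(dist))
    return pd.DataFrame({
        "population": [f"{s[:3]}-{i}" for i, s in enumerate(species)],
        "species": species, "x_km": xy[:, 0], "y_km": xy[:, 1],
        "dist_km": dist, "admixture": admix, "morph_index": morph,
    })


def simulate_maternal_families(h2: float, n_families: int, n_offspring: int,
                               rng: np.random.Generator,
                               total_sd: float = 1.0) -> pd.DataFrame:
    """Offspring values with a maternal-family intraclass correlation of h2."""
    sb = total_sd * np.sqrt(h2)
    sw = total_sd * np.sqrt(1.0 - h2)
    fam_eff = rng.normal(0, sb, n_families)
    rows = []
    for f in range(n_families):
        vals = fam_eff[f] + rng.normal(0, sw, n_offspring)
        rows += [(f"fam{f}", v) for v in vals]
    return pd.DataFrame(rows, columns=["family", "value"])


def simulate_species_characters(n_per_class: tuple[int, int],
                                characters: Sequence[str],
                                separation: float,
                                rng: np.random.Generator,
                                correlated: bool = False) -> tuple[pd.DataFrame, pd.Series]:
    """Two-class character table for discriminant training tests.

    Class means differ by `separation` SDs along every character (spherical
    within-class covariance unless correlated).
    """
    n_b, n_r = n_per_class
    p = len(characters)
    if correlated:
        a = rng.normal(0, 0.4, (p, p))
        cov = np.eye(p) + a @ a.T * 0.3
    else:
        cov = np.eye(p)
    xb = rng.multivariate_normal(np.full(p, separation / 2), cov, n_b)
    xr = rng.multivariate_normal(np.full(p, -separation / 2), cov, n_r)
    df = pd.DataFrame(np.vstack([xb, xr]), columns=list(characters))
    labels = pd.Series(["barrelieri"] * n_b + ["rupestre"] * n_r)
    return df, labels
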