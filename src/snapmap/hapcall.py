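"""Haplotype-level genotype calling for RAD loci in an outbred F2.

SNPs are binned into RAD loci by single-linkage chaining (pairwise gap <=
1.5 kb), the set of <=4 segregating haplotypes per locus is inferred from
co-segregation of the binned SNPs in the F2 (recombination within a locus is
assumed negligible), each haplotype's parental origin is resolved against
the parent and F1 genotypes, and every F2 individual receives a locus
genotype plus a species-origin code (bb/br/rr).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .core_io import MISSING, RadLocusGenotypes, SnpMatrix

logger = logging.getLogger("snapmap")


@dataclass
class SnpBin:
    """A chained group of SNPs forming one putative RAD locus."""

    chrom: str
    indices: np.ndarray  # row indices into the SnpMatrix, ordered by pos
    start: int
    end: int  # half-open: last pos + 1

    @property
    def span(self) -> int:
        return self.end - self.start


def bin_snps(chrom: np.ndarray, pos: np.ndarray, window: int = 1500) -> list[SnpBin]:
    """Single-linkage chaining: a new bin starts when the gap to the previous
    SNP exceeds `window`; bins never span chromosomes.  Input must be sorted
    by (chrom, pos)."""
    order = np.lexsort((pos, chrom))
    if not np.array_equal(order, np.arange(len(pos))):
        raise ValueError("SNPs must be sorted by (chrom, pos)")
    bins: list[SnpBin] = []
    cur: list[int] = []
    for i in range(len(pos)):
        if cur and (chrom[i] != chrom[cur[-1]] or pos[i] - pos[cur[-1]] > window):
            bins.append(_make_bin(chrom, pos, cur))
            cur = []
        cur.append(i)
    if cur:
        bins.append(_make_bin(chrom, pos, cur))
    return bins


def _make_bin(chrom, pos, idx) -> SnpBin:
    return SnpBin(str(chrom[idx[0]]), np.array(idx),
                  int(pos[idx[0]]), int(pos[idx[-1]]) + 1)


# ---------------------------------------------------------------------------
# haplotype inference


def _decompositions(g: tuple[int, ...]) -> list[tuple[tuple, tuple]]:
    """All unordered haplotype pairs (h1, h2) with h1 + h2 == g elementwise."""
    het = [i for i, v in enumerate(g) if v == 1]
    base1 = [1 if v == 2 else 0 for v in g]
    base2 = list(base1)
    out = []
    seen = set()
    for bits in itertools.product((0, 1), repeat=len(het)):
        h1, h2 = list(base1), list(base2)
        for i, b in zip(het, bits):
            h1[i], h2[i] = b, 1 - b
        key = (tuple(h1), tuple(h2)) if tuple(h1) <= tuple(h2) else (tuple(h2), tuple(h1))
        if key not in seen:
            seen.add(key)
            out.append(key)
    return out


def _minimal_haplotype_sets(classes: list[tuple[int, ...]], max_haps: int = 4
                            ) -> list[frozenset]:
    """All minimal sets of <=max_haps haplotypes explaining every genotype class."""
    classes = sorted(set(classes), key=lambda g: (sum(v == 1 for v in g), g))
    solutions: set[frozenset] = set()
    visited: set[tuple[int, frozenset]] = set()

    def rec(idx: int, haps: frozenset) -> None:
        state = (idx, haps)
        if state in visited:
            return
        visited.add(state)
        if idx == len(classes):
            solutions.add(haps)
            return
        for h1, h2 in _decompositions(classes[idx]):
            new = haps | {h1, h2}
            if len(new) <= max_haps:
                rec(idx + 1, new)

    rec(0, frozenset())
    if not solutions:
        return []
    k = min(len(s) for s in solutions)
    return [s for s in solutions if len(s) == k]


def infer_haplotypes(bin_geno: np.ndarray, min_support: int = 2,
                     max_haps: int = 4) -> tuple[list[tuple[int, ...]], np.ndarray, str | None]:
    """Infer the segregating haplotypes of one bin from F2 co-segregation.

    bin_geno: (n_individuals, n_snps) int8 codes {0,1,2,-1}.  Finds the
    minimal set of <=4 haplotypes (SNP-allele vectors) such that every
    well-supported complete multi-SNP genotype is the sum of two haplotypes,
    then assigns each individual its unordered haplotype pair.  Genotype
    classes seen in fewer than min_support individuals are treated as
    possible genotyping errors: they do not drive the set search, and their
    carriers are called only if consistent with the inferred set.

    Returns (haplotypes, diplotypes (n, 2) of haplotype indices with -1 for
    missing/ambiguous, flag) where flag is None, 'ambiguous' (several minimal
    sets fit equally) or 'inconsistent' (no set of <=4 explains the data).
    """
    n, m = bin_geno.shape
    diplo = np.full((n, 2), -1, dtype=np.int8)
    complete = (bin_geno != MISSING).all(axis=1)
    if not complete.any():
        return [], diplo, "inconsistent"
    rows = [tuple(int(v) for v in r) for r in bin_geno[complete]]
    counts: dict[tuple, int] = {}
    for r in rows:
        counts[r] = counts.get(r, 0) + 1
    core = [g for g, c in counts.items() if c >= min_support]
    if not core:
        core = list(counts)
    sets = _minimal_haplotype_sets(core, max_haps)
    if not sets:
        return [], diplo, "inconsistent"
    if len(sets) > 1:
        return [], diplo, "ambiguous"
    haps = sorted(sets[0])
    hap_arr = np.array(haps, dtype=np.int8)  # (k, m)
    pairs = [(i, j) for i in range(len(haps)) for j in range(i, len(haps))]
    pair_sums = np.array([hap_arr[i] + hap_arr[j] for i, j in pairs])  # (P, m)
    observed = bin_geno != MISSING  # (n, m)
    # consistent[p, i]: pair p matches individual i at all observed SNPs
    eq = pair_sums[:, None, :] == bin_geno[None, :, :]
    consistent = (eq | ~observed[None, :, :]).all(axis=2)
    consistent &= observed.any(axis=1)[None, :]
    n_fit = consistent.sum(axis=0)
    unique = n_fit == 1
    which = consistent.argmax(axis=0)
    for i in np.nonzero(unique)[0]:
        diplo[i] = pairs[which[i]]
    return haps, diplo, None


# ---------------------------------------------------------------------------
# parental origin


def _compatible(h: tuple[int, ...], parent_row: np.ndarray) -> bool:
    """Could h be one of this parent's two haplotypes?  At homozygous SNPs the
    haplotype allele must match; heterozygous and missing SNPs constrain
    nothing."""
    for allele, g in zip(h, parent_row):
        if g == 0 and allele != 0:
            return False
        if g == 2 and allele != 1:
            return False
    return True


def assign_parental_origin(haplotypes: list[tuple[int, ...]],
                           parent_b: np.ndarray, parent_r: np.ndarray,
                           f1_rows: np.ndarray | None = None
                           ) -> tuple[list[str | None], str | None]:
    """Label each haplotype b (lowland parent), r (alpine parent) or None.

    A haplotype compatible with exactly one fully typed parent is assigned
    that origin; compatible with both, or undecidable because of missing
    parent data, -> None.  A haplotype incompatible with both fully typed
    parents flags the locus inconsistent, as does an F1 genotype that cannot
    be formed from one b and one r gamete.
    """
    b_complete = bool((parent_b != MISSING).all())
    r_complete = bool((parent_r != MISSING).all())
    origins: list[str | None] = []
    flag = None
    for h in haplotypes:
        in_b = _compatible(h, parent_b)
        in_r = _compatible(h, parent_r)
        if in_b and not in_r and b_complete:
            origins.append("b")
        elif in_r and not in_b and r_complete:
            origins.append("r")
        elif not in_b and not in_r:
            if b_complete and r_complete:
                flag = "inconsistent"
            origins.append(None)
        else:
            origins.append(None)
    if f1_rows is not None and flag is None:
        for row in np.atleast_2d(f1_rows):
            if (row == MISSING).any():
                continue
            ok = any(
                (_compatible(p, parent_b) and _compatible(q, parent_r))
                or (_compatible(q, parent_b) and _compatible(p, parent_r))
                for p, q in _decompositions(tuple(int(v) for v in row))
            )
            if not ok:
                flag = "inconsistent"
                break
    return origins, flag


def recode_species_origin(diplotypes: np.ndarray,
                          origins: list[str | None]) -> np.ndarray:
    """Collapse haplotype pairs to species-origin codes bb(0)/br(1)/rr(2);
    any unknown origin in the pair -> missing."""
    n = len(diplotypes)
    code = np.full(n, MISSING, dtype=np.int8)
    val = {"b": 0, "r": 1}
    for i, (a, b) in enumerate(diplotypes):
        if a < 0 or b < 0:
            continue
        oa, ob = origins[a], origins[b]
        if oa in val and ob in val:
            code[i] = val[oa] + val[ob]
    return code


# ---------------------------------------------------------------------------
# locus-level pipeline


def call_loci(mat: SnpMatrix, window: int = 1500, min_support: int = 2
              ) -> list[RadLocusGenotypes]:
    """Bin, phase, origin-assign and species-code every RAD locus.

    Loci flagged ambiguous or inconsistent are returned with empty calls so
    the caller can count and drop them.
    """
    f2_cols = mat.f2_columns
    pb = mat.columns_for_role("parentB")
    pr = mat.columns_for_role("parentR")
    f1 = mat.columns_for_role("F1a") + mat.columns_for_role("F1b")
    if not (pb and pr):
        raise ValueError("dataset lacks parentB/parentR samples")
    loci = []
    for b in bin_snps(mat.chrom, mat.pos, window):
        sub = mat.geno[b.indices]  # (m, n_samples)
        f2_geno = sub[:, f2_cols].T
        haps, diplo, flag = infer_haplotypes(f2_geno, min_support=min_support)
        origins: list[str | None] = []
        if flag is None:
            origins, oflag = assign_parental_origin(
                haps, sub[:, pb[0]], sub[:, pr[0]],
                sub[:, f1].T if f1 else None)
            flag = oflag
        species = (recode_species_origin(diplo, origins) if flag is None
                   else np.full(len(f2_cols), MISSING, dtype=np.int8))
        loci.append(RadLocusGenotypes(
            chrom=b.chrom, start=b.start, end=b.end,
            snp_pos=mat.pos[b.indices].copy(), haplotypes=haps,
            origins=origins, diplotypes=diplo, species_code=species,
            flag=flag))
    n_bad = sum(1 for l in loci if l.flag)
    if n_bad:
        logger.info("flagged %d/%d loci (ambiguous or inconsistent)", n_bad, len(loci))
    return loci


def filter_loci(loci: list[RadLocusGenotypes], max_missing: float = 0.25
                ) -> list[RadLocusGenotypes]:
    """Drop flagged loci and loci with F2 species-code missingness >= max_missing
    (strictly-less-than retention rule)."""
    kept = [l for l in loci
            if l.flag is None
            and np.mean(l.species_code == MISSING) < max_missing]
    logger.info("retained %d/%d loci at <%.0f%% missing",
                len(kept), len(loci), 100 * max_missing)
    return kept


def informative_loci(loci: list[RadLocusGenotypes]) -> list[RadLocusGenotypes]:
    """Loci whose F2-segregating haplotypes all resolve to parental origins."""
    return [l for l in loci if l.origin_informative]


def flag_low_coverage_individuals(loci: list[RadLocusGenotypes],
                                  k_singletons: int | None = 5
                                  ) -> tuple[np.ndarray, np.ndarray]:
    """Flag F2 individuals whose genotype vector implies too many singleton
    double recombinants (genotype differing from both physical neighbours).

    Such patterns indicate coverage too low for reliable heterozygote calls.
    k_singletons=None disables flagging.  Returns (flags, singleton counts).
    """
    order = sorted(range(len(loci)), key=lambda i: (loci[i].chrom, loci[i].start))
    codes = np.array([loci[i].species_code for i in order])  # (n_loci, n_f2)
    chroms = np.array([loci[i].chrom for i in order])
    n_f2 = codes.shape[1] if len(codes) else 0
    counts = np.zeros(n_f2, dtype=int)
    for j in range(n_f2):
        for chrom in np.unique(chroms):
            g = codes[chroms == chrom, j]
            g = g[g != MISSING]
            if len(g) < 3:
                continue
            mid, left, right = g[1:-1], g[:-2], g[2:]
            counts[j] += int(np.sum((mid != left) & (mid != right)))
    if k_singletons is None:
        return np.zeros(n_f2, dtype=bool), counts
    return counts >= k_singletons, counts
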