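"""Linkage-map estimation and genome-distribution statistics.

Two-point recombination fractions are estimated by maximum likelihood over
the two-locus species-origin genotype table of the F2 (both F1s are br at
every locus with known phase, so gamete types have probabilities (1-r)/2 and
r/2).  Markers are grouped by single linkage at a LOD threshold, ordered by
greedy seriation minimizing the sum of adjacent recombination fractions, and
spaced with the Kosambi map function.  Also here: the Chakravarti
genome-coverage estimate, the transmission-ratio-distortion scan, the
marker-spacing and polymorphism-clustering randomness tests, and
restriction-site utilities (SbfI density, motif GC).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .core_io import MISSING, GeneticMap, TrdResult

LN10 = np.log(10.0)


# ---------------------------------------------------------------------------
# map function


def kosambi(r: float | np.ndarray) -> float | np.ndarray:
    """Kosambi map distance in cM: d = 25 ln((1+2r)/(1-2r)); r must be < 0.5."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must be in [0, 0.5)")
    d = 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inv(d: float | np.ndarray) -> float | np.ndarray:
    """Exact inverse: r = tanh(d/50) / 2."""
    r = 0.5 * np.tanh(np.asarray(d, dtype=float) / 50.0)
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# two-point estimation


@dataclass
class TwoPointEstimate:
    r: float
    lod: float
    n_informative: int  # phase-resolvable meioses (up to 2 per F2)
    k_recombinant: int  # recombinants among the resolvable meioses


def _class_logprobs(r: float) -> np.ndarray:
    """log P of the 9 two-locus genotype classes (row A x col B, bb/br/rr)."""
    c = 1.0 - r
    p = np.array([
        c * c / 4, r * c / 2, r * r / 4,
        r * c / 2, (c * c + r * r) / 2, r * c / 2,
        r * r / 4, r * c / 2, c * c / 4,
    ])
    with np.errstate(divide="ignore"):
        return np.log(p)


# per-class resolvable meioses and recombinants among them
_MEIOSES = np.array([2, 2, 2, 2, 0, 2, 2, 2, 2])
_RECOMB = np.array([0, 1, 2, 1, 0, 1, 2, 1, 0])


def two_point(g_a: np.ndarray, g_b: np.ndarray) -> TwoPointEstimate:
    """ML recombination fraction and LOD (vs r=0.5) between two species-coded
    loci.  Individuals missing either locus are ignored; pairs with no typed
    individuals raise ValueError."""
    ok = (g_a != MISSING) & (g_b != MISSING)
    if not ok.any():
        raise ValueError("no individual typed at both loci")
    idx = g_a[ok].astype(np.int64) * 3 + g_b[ok]
    counts = np.bincount(idx, minlength=9).astype(float)
    return _two_point_counts(counts)


def _two_point_counts(counts: np.ndarray) -> TwoPointEstimate:
    n_inf = int(counts @ _MEIOSES)
    k = int(counts @ _RECOMB)
    nz = counts > 0
    ll = lambda r: float(counts[nz] @ _class_logprobs(r)[nz])
    recomb_evidence = counts @ (_RECOMB > 0) > 0
    if not recomb_evidence:
        r_hat = 0.0  # boundary MLE: only concordant/double-het classes seen
    else:
        res = optimize.minimize_scalar(lambda r: -ll(r), bounds=(1e-9, 0.5 - 1e-9),
                                       method="bounded",
                                       options={"xatol": 1e-10})
        r_hat = float(res.x)
        if ll(0.5 - 1e-12) >= ll(r_hat):
            r_hat = 0.5
    lod = max(0.0, (ll(min(r_hat, 0.5 - 1e-12)) - ll(0.5 - 1e-12)) / LN10)
    return TwoPointEstimate(min(r_hat, 0.5), lod, n_inf, k)


def two_point_matrix(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs r and LOD for a (n_loci, n_f2) species-code matrix."""
    n = len(codes)
    r = np.full((n, n), 0.5)
    lod = np.zeros((n, n))
    for i in range(n):
        r[i, i] = 0.0
        for j in range(i + 1, n):
            try:
                est = two_point(codes[i], codes[j])
            except ValueError:
                continue
            r[i, j] = r[j, i] = est.r
            lod[i, j] = lod[j, i] = est.lod
    return r, lod


# ---------------------------------------------------------------------------
# grouping and ordering


def group_markers(lod: np.ndarray, lod_min: float = 6.0) -> list[np.ndarray]:
    """Single-linkage components of the graph with edges at LOD >= lod_min."""
    n = len(lod)
    ii, jj = np.nonzero(lod >= lod_min)
    graph = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    return [np.nonzero(labels == c)[0] for c in range(n_comp)]


def _sarf(order: list[int], r: np.ndarray) -> float:
    return float(sum(r[order[i], order[i + 1]] for i in range(len(order) - 1)))


def order_markers(members: np.ndarray, r: np.ndarray, lod: np.ndarray,
                  lod_min: float = 10.0) -> tuple[list[int], np.ndarray]:
    """Greedy seriation of one linkage group.

    Seeds with the highest-LOD pair and inserts remaining markers at the
    position minimizing the sum of adjacent recombination fractions (SARF).
    Round 1 admits markers whose best linkage to a placed marker reaches
    lod_min; round 2 relaxes to all markers.  A single-marker insertion
    polish runs until no SARF improvement.  Returns (ordered indices into the
    full matrices, cumulative Kosambi cM positions).
    """
    members = list(members)
    if len(members) == 1:
        return members, np.zeros(1)
    sub_r = r[np.ix_(members, members)]
    sub_lod = lod[np.ix_(members, members)]
    m = len(members)
    iu = np.triu_indices(m, 1)
    seed = int(np.argmax(sub_lod[iu]))
    order = [iu[0][seed], iu[1][seed]]
    placed = set(order)
    for threshold in (lod_min, -np.inf):
        while len(placed) < m:
            cand = [i for i in range(m) if i not in placed
                    and max(sub_lod[i, j] for j in placed) >= threshold]
            if not cand:
                break
            best = max(cand, key=lambda i: max(sub_lod[i, j] for j in placed))
            trials = [order[:pos] + [best] + order[pos:]
                      for pos in range(len(order) + 1)]
            order = min(trials, key=lambda o: _sarf(o, sub_r))
            placed.add(best)
    order = _polish(order, sub_r)
    cm = np.concatenate([[0.0], np.cumsum([
        kosambi(min(sub_r[order[i], order[i + 1]], 0.5 - 1e-9))
        for i in range(len(order) - 1)])])
    return [members[i] for i in order], cm


def _polish(order: list[int], r: np.ndarray, max_rounds: int = 20) -> list[int]:
    best = _sarf(order, r)
    for _ in range(max_rounds):
        improved = False
        for i in range(len(order)):
            marker = order[i]
            rest = order[:i] + order[i + 1:]
            for pos in range(len(order)):
                trial = rest[:pos] + [marker] + rest[pos:]
                s = _sarf(trial, r)
                if s < best - 1e-12:
                    order, best, improved = trial, s, True
                    break
            if improved:
                break
        if not improved:
            return order
    return order


def build_map(codes: np.ndarray, marker_ids: list[str], chroms: np.ndarray,
              bps: np.ndarray, lod_group: float = 6.0,
              lod_order: float = 10.0) -> GeneticMap:
    """Group, order and space a species-coded locus matrix into a GeneticMap."""
    r, lod = two_point_matrix(codes)
    groups = group_markers(lod, lod_group)
    rows = []
    gid = 0
    for members in sorted(groups, key=lambda g: (chroms[g[0]], bps[g[0]])):
        gid += 1
        ordered, cm = order_markers(members, r, lod, lod_order)
        for idx, pos in zip(ordered, cm):
            rows.append((marker_ids[idx], gid, float(pos),
                         str(chroms[idx]), int(bps[idx])))
    table = pd.DataFrame(rows, columns=["marker", "group", "cm", "chrom", "bp"])
    return GeneticMap(table, lod_group, lod_order)


# ---------------------------------------------------------------------------
# genome coverage (Chakravarti et al. method-of-moments inflation)


def genome_coverage(gmap: GeneticMap) -> tuple[float, float]:
    """Estimated genome length (cM) and map coverage fraction.

    Each group's observed length is inflated by (m+1)/(m-1) for m markers;
    groups with <3 markers contribute their observed length unchanged.
    """
    observed = 0.0
    inflated = 0.0
    for g in gmap.groups:
        sub = gmap.group_table(g)
        length = float(sub["cm"].max() - sub["cm"].min())
        m = len(sub)
        observed += length
        inflated += length * (m + 1) / (m - 1) if m >= 3 else length
    if inflated == 0:
        return 0.0, 1.0
    return inflated, observed / inflated


# ---------------------------------------------------------------------------
# transmission ratio distortion


def trd_scan(codes: np.ndarray, marker_ids: list[str],
             gmap: GeneticMap | None = None, alpha: float = 0.05) -> TrdResult:
    """Per-locus allele and gamete-phase distortion tests.

    (i) allele test: b-allele count vs Binomial(2n, 1/2) by chi-square (1 df);
    (ii) phase test: genotype counts vs p^2 / 2pq / q^2 from the observed
    allele frequency (1 df) - consistency with distortion arising in the
    haploid (gamete) phase of the F1.  Locus flagging is Bonferroni-corrected
    on the allele test; if a map is given, the fraction of map cM inside
    flagged marker intervals is reported.
    """
    rows = []
    n_loci = len(codes)
    bonf = alpha / max(n_loci, 1)
    for mid, g in zip(marker_ids, codes):
        g = g[g != MISSING]
        n_bb = int(np.sum(g == 0))
        n_br = int(np.sum(g == 1))
        n_rr = int(np.sum(g == 2))
        n = n_bb + n_br + n_rr
        if n == 0:
            rows.append((mid, 0, 0, np.nan, np.nan, 0, 0, 0, np.nan, np.nan, False))
            continue
        b = 2 * n_bb + n_br
        n_al = 2 * n
        chi_a = 2 * (b - n_al / 2) ** 2 / (n_al / 2)
        p_a = float(stats.chi2.sf(chi_a, 1))
        p_hat = b / n_al
        exp = np.array([p_hat ** 2, 2 * p_hat * (1 - p_hat), (1 - p_hat) ** 2]) * n
        obs = np.array([n_bb, n_br, n_rr], dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = (obs - exp) ** 2 / exp
        chi_p = float(np.nansum(np.where(exp > 0, terms, 0.0)))
        p_p = float(stats.chi2.sf(chi_p, 1))
        rows.append((mid, b, n_al, chi_a, p_a, n_bb, n_br, n_rr, chi_p, p_p,
                     p_a < bonf))
    table = pd.DataFrame(rows, columns=[
        "marker", "b_count", "n_alleles", "chi2_allele", "p_allele",
        "n_bb", "n_br", "n_rr", "chi2_phase", "p_phase", "flagged"])
    flagged = table.loc[table["flagged"], "marker"].tolist()
    frac = _flagged_map_fraction(table, gmap) if gmap is not None else None
    return TrdResult(table, alpha, bonf, flagged, frac)


def _flagged_map_fraction(table: pd.DataFrame, gmap: GeneticMap) -> float:
    """cM inside intervals around flagged markers (half-way to each unflagged
    neighbour) as a fraction of total map length."""
    flagged = set(table.loc[table["flagged"], "marker"])
    total = gmap.total_length_cm
    if total == 0 or not flagged:
        return 0.0
    affected = 0.0
    for g in gmap.groups:
        sub = gmap.group_table(g).sort_values("cm")
        cm = sub["cm"].to_numpy()
        is_f = sub["marker"].isin(flagged).to_numpy()
        for i in np.nonzero(is_f)[0]:
            left = (cm[i] - cm[i - 1]) / 2 if i > 0 else 0.0
            right = (cm[i + 1] - cm[i]) / 2 if i < len(cm) - 1 else 0.0
            affected += left + right
    return affected / total


# ---------------------------------------------------------------------------
# spatial randomness of loci along the genome


def spacing_randomness_test(positions: np.ndarray, n_sim: int = 10_000,
                            seed: int | None = None
                            ) -> tuple[float, float | None]:
    """Are inter-locus physical gaps exponential (i.e. loci randomly placed)?

    Kolmogorov-Smirnov distance between the empirical gap distribution and
    Exponential(mean = observed mean); p by parametric bootstrap with the
    mean re-estimated per simulation (estimated-parameter, Lilliefors-type
    null).  n_sim=0 returns the statistic with p=None.
    """
    positions = np.sort(np.asarray(positions, dtype=float))
    if len(positions) < 10:
        raise ValueError("need >=10 loci")
    gaps = np.diff(positions)
    d_obs = _ks_exponential(gaps)
    if n_sim == 0:
        return d_obs, None
    rng = np.random.default_rng(seed)
    sims = rng.exponential(gaps.mean(), size=(n_sim, len(gaps)))
    d_sim = np.array([_ks_exponential(s) for s in sims])
    p = (1 + np.sum(d_sim >= d_obs)) / (n_sim + 1)
    return d_obs, float(p)


def _ks_exponential(gaps: np.ndarray) -> float:
    x = np.sort(gaps)
    cdf = 1.0 - np.exp(-x / x.mean())
    n = len(x)
    up = np.arange(1, n + 1) / n - cdf
    lo = cdf - np.arange(0, n) / n
    return float(max(up.max(), lo.max()))


def polymorphism_clustering_test(flags: np.ndarray) -> tuple[float, int, float]:
    """Chi-square test of gap counts (fixed loci between successive polymorphic
    loci) against Geometric(pi) with pi the observed polymorphic fraction.
    Tail bins are pooled so every expected count is >=5; df = bins - 2.
    Returns (chi2, df, p).  Degenerate all-polymorphic input returns p=1."""
    flags = np.asarray(flags, dtype=bool)
    poly_idx = np.nonzero(flags)[0]
    if len(poly_idx) < 2:
        raise ValueError("need >=2 polymorphic loci")
    gaps = np.diff(poly_idx) - 1
    pi = flags.mean()
    if pi >= 1.0:
        return 0.0, 0, 1.0
    n = len(gaps)
    # geometric pmf on {0, 1, ...}: P(g) = pi * (1-pi)^g
    max_g = int(gaps.max())
    probs = [pi * (1 - pi) ** g for g in range(max_g + 1)]
    probs.append(max(0.0, 1.0 - sum(probs)))  # tail > max_g
    obs = np.bincount(gaps, minlength=max_g + 2).astype(float)
    exp = np.array(probs) * n
    # pool from the tail until every expected count is >=5
    while len(exp) > 2 and exp[-1] < 5:
        exp[-2] += exp[-1]
        obs[-2] += obs[-1]
        exp, obs = exp[:-1], obs[:-1]
    if len(exp) < 3:
        return 0.0, 0, 1.0
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    df = len(exp) - 2
    return chi2, df, float(stats.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# restriction-site utilities


IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG",
    "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
    "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

SBFI_MOTIF = "CCTGCAGG"


def _motif_regex(motif: str) -> str:
    out = []
    for ch in motif.upper():
        if ch not in IUPAC:
            raise ValueError(f"non-IUPAC character {ch!r} in motif")
        opts = IUPAC[ch]
        out.append(opts if len(opts) == 1 else f"[{opts}]")
    return "".join(out)


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def find_sites(sequence: str, motif: str = SBFI_MOTIF) -> np.ndarray:
    """0-based start positions of motif matches on both strands, overlapping
    matches included, palindromic double-counts removed."""
    seq = sequence.upper()
    hits = set()
    for pat in {_motif_regex(motif), _motif_regex(reverse_complement(motif))}:
        hits.update(m.start(1) for m in re.finditer(f"(?=({pat}))", seq))
    return np.array(sorted(hits), dtype=np.int64)


def window_density(positions: np.ndarray, seq_len: int, window: int,
                   step: int | None = None) -> pd.DataFrame:
    """Sliding-window site counts: columns start, end, count, density (per bp)."""
    step = step or window
    rows = []
    for start in range(0, max(seq_len - window, 0) + 1, step):
        end = start + window
        count = int(np.sum((positions >= start) & (positions < end)))
        rows.append((start, end, count, count / window))
    return pd.DataFrame(rows, columns=["start", "end", "count", "density"])


def motif_gc(motif: str) -> float:
    """GC fraction of a motif string (S counts as G/C)."""
    up = motif.upper()
    if any(ch not in IUPAC for ch in up):
        raise ValueError("non-IUPAC characters in motif")
    return sum(ch in "GCS" for ch in up) / len(up)
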