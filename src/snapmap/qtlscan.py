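"""Interval-mapping QTL scan on species-origin genotypes.

Genotype probabilities on a 1 cM grid come from a forward-backward HMM over
each linkage group (Kosambi-derived transitions, emission error rate eps);
the scan itself is Haley-Knott regression of phenotype on the expected
additive score x = p(bb) - p(rr) (positive = two lowland b alleles) and the
dominance score z = p(br).  Genome-wide significance is the empirical
(1-alpha) quantile of max-LOD over genotype-phenotype permutations; multi-QTL
models are built by forward selection with backward elimination in an
additive-only model space.  Also here: LOD-drop support intervals, effect /
PVE estimation, and the between-population QTL-reuse binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MISSING, GeneticMap, Qtl, QtlScanResult
from .linkmap import kosambi_inv

PRIOR = np.array([0.25, 0.5, 0.25])  # F2 expectation bb/br/rr


@dataclass
class GenotypeProbabilities:
    """Per-group genotype probabilities on marker + grid positions."""

    groups: list[int]
    positions: list[np.ndarray]        # cM per group
    probs: list[np.ndarray]            # (n_ind, n_pos, 3) per group
    is_marker: list[np.ndarray]
    step: float
    eps: float

    @property
    def n_individuals(self) -> int:
        return self.probs[0].shape[0]

    def table(self) -> pd.DataFrame:
        rows = []
        for g, pos in zip(self.groups, self.positions):
            rows += [(g, float(p)) for p in pos]
        return pd.DataFrame(rows, columns=["group", "cm"])

    def subset(self, individuals: np.ndarray) -> "GenotypeProbabilities":
        return GenotypeProbabilities(self.groups, self.positions,
                                     [p[individuals] for p in self.probs],
                                     self.is_marker, self.step, self.eps)

    def xz_at(self, group: int, cm: float) -> tuple[np.ndarray, np.ndarray]:
        gi = self.groups.index(group)
        pi = int(np.argmin(np.abs(self.positions[gi] - cm)))
        p = self.probs[gi][:, pi, :]
        return p[:, 0] - p[:, 2], p[:, 1]


def _transition(r: float) -> np.ndarray:
    c = 1.0 - r
    return np.array([
        [c * c, 2 * r * c, r * r],
        [r * c, c * c + r * r, r * c],
        [r * r, 2 * r * c, c * c],
    ])


def genotype_probs(gmap: GeneticMap, codes: dict[str, np.ndarray],
                   step: float = 1.0, eps: float = 0.001) -> GenotypeProbabilities:
    """Forward-backward genotype probabilities at 1 cM (default) intervals.

    codes maps marker id -> int8 species codes (0 bb / 1 br / 2 rr / -1
    missing) over the F2.  Missing genotypes emit uniformly; at a typed
    marker with eps=0 all mass sits on the observed genotype.
    """
    n = len(next(iter(codes.values())))
    groups, positions, probs, marker_flags = [], [], [], []
    for g in gmap.groups:
        sub = gmap.group_table(g).sort_values("cm")
        mpos = sub["cm"].to_numpy()
        grid = np.arange(mpos.min(), mpos.max() + step / 2, step)
        pos = np.concatenate([mpos, grid])
        emit_marker = np.concatenate([np.ones(len(mpos), bool),
                                      np.zeros(len(grid), bool)])
        marker_row = np.concatenate([np.arange(len(mpos)),
                                     np.full(len(grid), -1)])
        order = np.argsort(pos, kind="stable")
        pos, emit_marker, marker_row = pos[order], emit_marker[order], marker_row[order]

        emissions = np.ones((len(pos), n, 3))
        geno = np.stack([codes[m] for m in sub["marker"]])  # (n_markers, n)
        for k in np.nonzero(emit_marker)[0]:
            gk = geno[marker_row[k]]
            e = np.full((n, 3), eps / 2)
            typed = gk != MISSING
            e[typed, :] = eps / 2
            e[np.nonzero(typed)[0], gk[typed]] = 1.0 - eps
            e[~typed, :] = 1.0
            emissions[k] = e

        trans = [_transition(float(kosambi_inv(pos[k + 1] - pos[k])))
                 for k in range(len(pos) - 1)]
        post = _forward_backward(emissions, trans)
        groups.append(g)
        positions.append(pos)
        probs.append(post)
        marker_flags.append(emit_marker)
    return GenotypeProbabilities(groups, positions, probs, marker_flags, step, eps)


def _forward_backward(emissions: np.ndarray, trans: list[np.ndarray]) -> np.ndarray:
    n_pos, n, _ = emissions.shape
    alpha = np.empty((n_pos, n, 3))
    a = PRIOR[None, :] * emissions[0]
    alpha[0] = _norm_rows(a)
    for k in range(1, n_pos):
        a = (alpha[k - 1] @ trans[k - 1]) * emissions[k]
        alpha[k] = _norm_rows(a)
    beta = np.ones((n, 3))
    post = np.empty_like(alpha)
    post[-1] = _norm_rows(alpha[-1] * beta)
    for k in range(n_pos - 2, -1, -1):
        beta = (emissions[k + 1] * beta) @ trans[k].T
        beta /= np.maximum(beta.sum(1, keepdims=True), 1e-300)
        post[k] = _norm_rows(alpha[k] * beta)
    return np.swapaxes(post, 0, 1)  # (n, n_pos, 3)


def _norm_rows(a: np.ndarray) -> np.ndarray:
    s = a.sum(axis=-1, keepdims=True)
    s = np.where(s <= 0, 1.0, s)
    out = a / s
    out[(a.sum(axis=-1) <= 0)] = PRIOR
    return out


# ---------------------------------------------------------------------------
# Haley-Knott regression scan


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of Y (n, k) on X (n, p) per column."""
    q, _ = np.linalg.qr(X)
    proj = q.T @ Y
    return np.maximum((Y * Y).sum(0) - (proj * proj).sum(0), 1e-300)


def scanone(gp: GenotypeProbabilities, phenotype: np.ndarray,
            covariates: np.ndarray | None = None) -> np.ndarray:
    """LOD profile over all grid positions (concatenated across groups).

    phenotype may be (n,) or (n, k) for k phenotypes scanned at once (used
    for permutations); no missing values allowed (subset individuals first).
    LOD = (n/2) log10(RSS0/RSS1) with RSS0 from the covariate-only model.
    """
    Y = np.atleast_2d(np.asarray(phenotype, dtype=float).T).T
    if np.isnan(Y).any():
        raise ValueError("phenotype contains missing values; subset first")
    n = Y.shape[0]
    if np.any(Y.std(axis=0) == 0):
        raise ValueError("phenotype has zero variance")
    X0 = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates])
    rss0 = _rss(X0, Y)
    lods = []
    for gi in range(len(gp.groups)):
        p = gp.probs[gi]
        for k in range(p.shape[1]):
            x = p[:, k, 0] - p[:, k, 2]
            z = p[:, k, 1]
            rss1 = _rss(np.column_stack([X0, x, z]), Y)
            lods.append(n / 2 * np.log10(rss0 / rss1))
    out = np.array(lods)  # (n_pos, k)
    return out[:, 0] if out.shape[1] == 1 and np.asarray(phenotype).ndim == 1 else out


def permutation_threshold(gp: GenotypeProbabilities, phenotype: np.ndarray,
                          n_perm: int = 1000, alpha: float = 0.05,
                          seed: int | None = None) -> float:
    """Genome-wide LOD threshold: the empirical (1-alpha) quantile of max LOD
    over genotype-phenotype permutations."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    y = np.asarray(phenotype, dtype=float)
    perms = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
    lods = scanone(gp, perms)
    return float(np.quantile(lods.max(axis=0), 1.0 - alpha))


# ---------------------------------------------------------------------------
# multi-QTL model


def _design(gp: GenotypeProbabilities, model: list[tuple[int, float]]) -> np.ndarray:
    cols = []
    for group, cm in model:
        x, z = gp.xz_at(group, cm)
        cols += [x, z]
    return np.column_stack(cols) if cols else np.empty((gp.n_individuals, 0))


def fit_qtl(gp: GenotypeProbabilities, model: list[tuple[int, float]],
            phenotype: np.ndarray) -> dict:
    """Joint additive+dominance fit of all model QTL.

    Returns additive effects (positive = b allele increases the trait),
    dominance deviations, per-QTL drop-one PVE and total PVE.  QTL closer
    than 1 cM on the same group are rejected as collinear.
    """
    if not model:
        raise ValueError("empty model")
    for i, (g1, p1) in enumerate(model):
        for g2, p2 in model[i + 1:]:
            if g1 == g2 and abs(p1 - p2) < 1.0:
                raise ValueError(f"collinear QTL at group {g1}: {p1} vs {p2} cM")
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    X = np.column_stack([np.ones(n), _design(gp, model)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss_full = float(np.sum((y - X @ beta) ** 2))
    rss0 = float(np.sum((y - y.mean()) ** 2))
    pve_total = 1.0 - rss_full / rss0
    additive = beta[1::2]
    dominance = beta[2::2]
    pve = []
    for j in range(len(model)):
        keep = [0] + [1 + 2 * k + c for k in range(len(model)) if k != j
                      for c in (0, 1)]
        rss_j = float(_rss(X[:, keep], y[:, None])[0])
        pve.append((rss_j - rss_full) / rss0)
    return {"additive": additive, "dominance": dominance,
            "pve": np.array(pve), "pve_total": pve_total,
            "rss": rss_full, "rss0": rss0}


def stepwise_additive(gp: GenotypeProbabilities, phenotype: np.ndarray,
                      threshold: float, max_qtl: int = 10,
                      exclusion_cm: float = 10.0) -> list[tuple[int, float]]:
    """Forward inclusion / backward elimination of additive QTL.

    At each forward step the genome is rescanned conditional on the current
    model (its x/z columns as covariates); the best position is added while
    its conditional LOD exceeds the threshold.  Positions within
    exclusion_cm of a model QTL on the same group are not proposed.
    Backward elimination drops QTL whose drop-one LOD falls below the
    threshold, iterating to stability.
    """
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    pos_table = gp.table()
    model: list[tuple[int, float]] = []
    for _ in range(max_qtl + len(pos_table)):
        cov = _design(gp, model)
        lod = scanone(gp, y, covariates=cov if model else None)
        mask = np.ones(len(lod), bool)
        for g, cm in model:
            near = (pos_table["group"] == g) & \
                   (np.abs(pos_table["cm"] - cm) < exclusion_cm)
            mask &= ~near.to_numpy()
        lod = np.where(mask, lod, -np.inf)
        best = int(np.argmax(lod))  # ties -> lower cM (first occurrence)
        if lod[best] <= threshold or len(model) >= max_qtl:
            break
        model.append((int(pos_table["group"].iloc[best]),
                      float(pos_table["cm"].iloc[best])))
        model = _backward(gp, model, y, threshold)
    return sorted(model)


def _backward(gp: GenotypeProbabilities, model: list, y: np.ndarray,
              threshold: float) -> list:
    n = len(y)
    while len(model) > 1:
        X = np.column_stack([np.ones(n), _design(gp, model)])
        rss_full = float(_rss(X, y[:, None])[0])
        drops = []
        for j in range(len(model)):
            keep = [0] + [1 + 2 * k + c for k in range(len(model)) if k != j
                          for c in (0, 1)]
            rss_j = float(_rss(X[:, keep], y[:, None])[0])
            drops.append(n / 2 * np.log10(rss_j / rss_full))
        worst = int(np.argmin(drops))
        if drops[worst] >= threshold:
            break
        model = model[:worst] + model[worst + 1:]
    return model


def lod_interval(positions: np.ndarray, lod: np.ndarray, peak: int,
                 drop: float) -> tuple[float, float]:
    """LOD-drop support interval on one linkage group: the outermost grid
    positions with LOD >= LOD(peak) - drop, clipped at the group ends."""
    if drop not in (1, 2):
        raise ValueError("drop must be 1 or 2")
    qual = np.nonzero(lod >= lod[peak] - drop)[0]
    return float(positions[qual.min()]), float(positions[qual.max()])


def scan_trait(gp: GenotypeProbabilities, phenotype: np.ndarray, trait: str,
               alpha: float = 0.05, n_perm: int = 1000,
               seed: int | None = None,
               threshold: float | None = None) -> QtlScanResult:
    """Full single-trait pipeline: permutation threshold, stepwise model,
    joint effect/PVE estimation and LOD-drop intervals."""
    y = np.asarray(phenotype, dtype=float)
    if threshold is None:
        threshold = permutation_threshold(gp, y, n_perm, alpha, seed)
    model = stepwise_additive(gp, y, threshold)
    pos_table = gp.table()
    lod = scanone(gp, y)
    result = QtlScanResult(trait, pos_table, lod, threshold, alpha, n_perm)
    if not model:
        return result
    fit = fit_qtl(gp, model, y)
    result.pve_total = fit["pve_total"]
    starts = np.cumsum([0] + [len(p) for p in gp.positions])
    for j, (g, cm) in enumerate(model):
        gi = gp.groups.index(g)
        seg = slice(starts[gi], starts[gi + 1])
        glod = lod[seg]
        gpos = gp.positions[gi]
        # profile peak nearest to the model position
        peak = int(np.argmin(np.abs(gpos - cm)))
        result.qtl.append(Qtl(
            trait=trait, group=g, pos_cm=cm,
            additive=float(fit["additive"][j]),
            dominance=float(fit["dominance"][j]),
            pve=float(fit["pve"][j]), lod=float(glod[peak]),
            interval_1lod=lod_interval(gpos, glod, peak, 1),
            interval_2lod=lod_interval(gpos, glod, peak, 2)))
    return result


# ---------------------------------------------------------------------------
# QTL reuse between mapping populations


def qtl_overlap_binomial(k: int, n: int, coverage: float) -> float:
    """Exact upper-tail binomial probability P(X >= k), X ~ Binomial(n,
    coverage): the chance that k of n QTL fall in previously identified
    intervals covering the given genome fraction if QTL were placed at
    random."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must be in [0, 1]")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, coverage))


def project_intervals(qtl_positions: list[tuple[str, float]],
                      reference_intervals: list[tuple[str, float, float]],
                      genome_length: float) -> tuple[int, float]:
    """Count QTL whose physical position falls in any reference interval
    (half-open [start, end)); coverage = merged interval length / genome
    length.  Overlapping reference intervals are merged before summing."""
    merged: dict[str, list[list[float]]] = {}
    for chrom, start, end in sorted(reference_intervals):
        ivs = merged.setdefault(chrom, [])
        if ivs and start <= ivs[-1][1]:
            ivs[-1][1] = max(ivs[-1][1], end)
        else:
            ivs.append([start, end])
    total = sum(e - s for ivs in merged.values() for s, e in ivs)
    k = sum(
        any(s <= pos < e for s, e in merged.get(chrom, []))
        for chrom, pos in qtl_positions)
    return k, total / genome_length
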