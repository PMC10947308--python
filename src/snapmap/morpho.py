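"""Morphological pipeline: discriminant morphology index, PCA, heritability,
segregation and pooling checks, and distance-to-heterospecific regressions.

The morphology index is a Fisher linear discriminant trained on normalized
character values of the least-admixed field plants of each species: each
character is weighted so the two species are maximally separated along a
single axis, oriented so the lowland species (A. barrelieri) scores
positive, and scaled to unit pooled within-class variance.  New samples are
normalized with the training set's means and SDs so the index is a fixed
function of raw characters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import IndexWeights

#: characters log-transformed before normalization (right-skewed measures)
LOG_CHARACTERS = ("PlHt", "BrIn", "LfA", "NFl")

#: published field-trained discriminant weights for the Antirrhinum
#: barrelieri / rupestre morphology index (pedicel length is not included in
#: the index).  Shipped for applying the index to new normalized data.
REFERENCE_INDEX_WEIGHTS = {
    "PlHt": 0.84, "IntL": 0.62, "BrIn": -0.09, "LfLW": 0.04, "LfA": 0.26,
    "NFl": 1.35, "FlL": 0.28, "SepL": -0.62, "PetAn": 0.46, "PetL": 0.17,
}


def normalize_characters(table: pd.DataFrame,
                         log_chars: tuple[str, ...] = LOG_CHARACTERS,
                         reference_stats: tuple[pd.Series, pd.Series] | None = None
                         ) -> tuple[pd.DataFrame, tuple[pd.Series, pd.Series]]:
    """Z-score characters (natural-log transforming flagged ones first).

    With reference_stats=(means, sds) from a training table, those statistics
    are used instead of the table's own, so a trained index can be applied to
    new samples.  Returns (z table, (means, sds) actually used).
    """
    if len(table) < 2 and reference_stats is None:
        raise ValueError("need >=2 individuals to self-normalize")
    x = table.astype(float).copy()
    for c in x.columns:
        if c in log_chars:
            x[c] = np.log(x[c])
    if reference_stats is None:
        mean, sd = x.mean(), x.std(ddof=1)
    else:
        mean, sd = reference_stats
        mean, sd = mean[x.columns], sd[x.columns]
    if (sd <= 0).any():
        bad = list(sd.index[sd <= 0])
        raise ValueError(f"zero standard deviation in characters: {bad}")
    return (x - mean) / sd, (mean, sd)


def train_discriminant(z: pd.DataFrame, labels: pd.Series,
                       positive_class: str = "barrelieri",
                       log_chars: tuple[str, ...] = LOG_CHARACTERS,
                       training_stats: tuple[pd.Series, pd.Series] | None = None
                       ) -> IndexWeights:
    """Fisher linear discriminant weights w ~ S_pooled^-1 (mu_pos - mu_neg).

    Oriented so the positive class's training-mean index is positive and
    scaled so the pooled within-class index variance is 1.  A singular
    pooled covariance falls back to ridge regularization
    (lambda = 1e-6 * trace)."""
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    if positive_class not in classes:
        raise ValueError(f"positive_class {positive_class!r} not in labels")
    neg = [c for c in classes if c != positive_class][0]
    xp = z[labels.to_numpy() == positive_class].to_numpy(float)
    xn = z[labels.to_numpy() == neg].to_numpy(float)
    if len(xp) < 2 or len(xn) < 2:
        raise ValueError("need >=2 individuals per class")
    sp = np.cov(xp, rowvar=False)
    sn = np.cov(xn, rowvar=False)
    n1, n2 = len(xp), len(xn)
    pooled = ((n1 - 1) * sp + (n2 - 1) * sn) / (n1 + n2 - 2)
    diff = xp.mean(0) - xn.mean(0)
    try:
        if np.linalg.cond(pooled) > 1e10:
            raise np.linalg.LinAlgError("ill-conditioned")
        w = np.linalg.solve(pooled, diff)
    except np.linalg.LinAlgError:
        lam = 1e-6 * np.trace(pooled)
        w = np.linalg.solve(pooled + lam * np.eye(len(diff)), diff)
    within_var = float(w @ pooled @ w)
    w = w / np.sqrt(within_var)
    if (xp.mean(0) @ w) < (xn.mean(0) @ w):
        w = -w
    if training_stats is None:
        mean = pd.Series(0.0, index=z.columns)
        sd = pd.Series(1.0, index=z.columns)
    else:
        mean, sd = training_stats
    return IndexWeights(list(z.columns), mean.to_numpy(float),
                        sd.to_numpy(float), w, log_chars, positive_class)


def morphology_index(z: pd.DataFrame, weights: IndexWeights | dict[str, float]
                     ) -> pd.Series:
    """Index = sum of w_i * z_i over the weighted characters.

    Rows missing any weighted character get a missing index (no imputation).
    """
    if isinstance(weights, IndexWeights):
        wmap = dict(zip(weights.characters, weights.weights))
    else:
        wmap = dict(weights)
    chars = list(wmap)
    missing_cols = [c for c in chars if c not in z.columns]
    if missing_cols:
        raise ValueError(f"characters absent from table: {missing_cols}")
    sub = z[chars].astype(float)
    idx = sub.to_numpy() @ np.array([wmap[c] for c in chars])
    out = pd.Series(idx, index=z.index, name="morph_index")
    out[sub.isna().any(axis=1)] = np.nan
    return out


def pca_characters(z: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of the character correlation matrix.

    Returns (loadings, variance fractions); loadings[:, k] is PCk+1,
    sign-fixed so its largest-magnitude loading is positive.  Eigenvalues sum
    to the number of characters."""
    if z.shape[1] < 2:
        raise ValueError("need >=2 characters")
    corr = np.corrcoef(z.to_numpy(float), rowvar=False)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    for k in range(vecs.shape[1]):
        if vecs[np.argmax(np.abs(vecs[:, k])), k] < 0:
            vecs[:, k] = -vecs[:, k]
    return vecs, vals / vals.sum()


def heritability_by_mother(values: np.ndarray, families: np.ndarray) -> float:
    """Intraclass correlation from a one-way random-effects ANOVA.

    h = sigma2_between / (sigma2_between + sigma2_within), with the
    unbalanced-design coefficient n0 = (N - sum n_i^2 / N) / (k - 1) for the
    between-family mean square.  Clipped to [0, 1]."""
    values = np.asarray(values, dtype=float)
    families = np.asarray(families)
    fams, inv = np.unique(families, return_inverse=True)
    k = len(fams)
    if k < 2:
        raise ValueError("need >=2 families")
    n_i = np.bincount(inv).astype(float)
    if n_i.max() < 2:
        raise ValueError("need >=2 offspring in at least one family")
    N = len(values)
    grand = values.mean()
    means = np.bincount(inv, weights=values) / n_i
    ssb = float(np.sum(n_i * (means[np.arange(k)] - grand) ** 2))
    ssw = float(np.sum((values - means[inv]) ** 2))
    msb = ssb / (k - 1)
    msw = ssw / (N - k) if N > k else 0.0
    n0 = (N - np.sum(n_i ** 2) / N) / (k - 1)
    sigma_b = (msb - msw) / n0
    total = sigma_b + msw
    if total <= 0:
        return 0.0
    return float(np.clip(sigma_b / total, 0.0, 1.0))


def segregation_test(n_dominant: int, n_total: int,
                     ratio: tuple[int, int] = (3, 1)) -> tuple[float, float]:
    """1-df goodness-of-fit chi-square of a dominant:recessive count against
    an expected Mendelian ratio (default 3:1)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    frac = ratio[0] / sum(ratio)
    exp = np.array([frac, 1 - frac]) * n_total
    obs = np.array([n_dominant, n_total - n_dominant], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return chi2, float(stats.chi2.sf(chi2, 1))


def pooling_check(table_a: pd.DataFrame, table_b: pd.DataFrame,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Welch t-tests on means and F-tests on variances per character, with a
    Bonferroni-corrected verdict on pooling the two sub-populations.

    Returns a per-character table plus attrs 'poolable' and 'corrected_alpha';
    poolable iff no test is significant at alpha / n_characters."""
    chars = [c for c in table_a.columns if c in table_b.columns]
    if not chars:
        raise ValueError("tables share no characters")
    corrected = alpha / len(chars)
    rows = []
    for c in chars:
        a = table_a[c].dropna().to_numpy(float)
        b = table_b[c].dropna().to_numpy(float)
        t, p_t = stats.ttest_ind(a, b, equal_var=False)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        if va >= vb:
            f, dfn, dfd = va / vb, len(a) - 1, len(b) - 1
        else:
            f, dfn, dfd = vb / va, len(b) - 1, len(a) - 1
        p_f = min(1.0, 2 * stats.f.sf(f, dfn, dfd))
        rows.append((c, float(t), float(p_t), float(f), float(p_f)))
    out = pd.DataFrame(rows, columns=["character", "t", "p_t", "F", "p_F"])
    out.attrs["corrected_alpha"] = corrected
    out.attrs["poolable"] = bool(
        (out["p_t"] >= corrected).all() and (out["p_F"] >= corrected).all())
    return out


def intermediate_morphology(site_table: pd.DataFrame,
                            value_col: str = "morph_index") -> pd.Series:
    """Admixture-analogous morphology measure per population.

    The index is oriented barrelieri-positive, so the most extreme (most
    species-typical) barrelieri population has the species maximum and the
    most extreme rupestre population the species minimum.  Subtracting each
    barrelieri value from the species maximum, and the species minimum from
    each rupestre value, maps the most extreme population of each species to
    exactly 0 and scores populations higher the closer their morphology is
    to the other species - analogous to a genetic admixture proportion.
    """
    v = site_table[value_col]
    sp = site_table["species"]
    out = pd.Series(np.nan, index=site_table.index, name="intermediate")
    rup = sp == "rupestre"
    bar = sp == "barrelieri"
    out[bar] = v[bar].max() - v[bar]
    out[rup] = v[rup] - v[rup].min()
    return out


def distance_regressions(site_table: pd.DataFrame,
                         distance_floor_km: float = 0.1) -> dict[str, dict]:
    """OLS of (i) population admixture and (ii) the intermediate-morphology
    transform onto distance to the nearest heterospecific population.

    Distances are floored at 0.1 km (sympatric mixed sites).  Requires >=3
    populations per species.  Returns slope/intercept/p/r2 per response.
    """
    counts = site_table["species"].value_counts()
    if (counts < 3).any() or len(counts) < 2:
        raise ValueError("need >=3 populations of each species")
    d = np.maximum(site_table["dist_km"].to_numpy(float), distance_floor_km)
    out = {}
    responses = {"admixture": site_table["admixture"].to_numpy(float),
                 "intermediate_morphology":
                     intermediate_morphology(site_table).to_numpy(float)}
    for name, y in responses.items():
        if np.allclose(y, y[0]):
            out[name] = {"slope": 0.0, "intercept": float(y[0]),
                         "p": 1.0, "r2": 0.0}
            continue
        res = stats.linregress(d, y)
        out[name] = {"slope": float(res.slope), "intercept": float(res.intercept),
                     "p": float(res.pvalue), "r2": float(res.rvalue ** 2)}
    return out


def outlier_locus_percent(n_outliers: int, n_total: int) -> float:
    """Percentage of genotyped loci flagged as between-species outliers
    (e.g. the F_ST-biased AFLP loci sufficient to separate the species)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_outliers / n_total
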