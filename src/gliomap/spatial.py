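"""Spatial association of regional tumor frequency with transcriptomic and
receptor maps.

The association between a regional frequency vector y (square-rooted and
z-scored to reduce skewness) and a region x gene expression matrix X
(columns z-scored) is summarized by the singular value decomposition of
their cross-covariance X'y / (R-1): the left singular vectors are gene
loadings, the singular values measure captured covariance. With a single
response the cross-covariance is rank one, so component 1 is the normalized
vector X'y and its singular value is ||X'y|| / (R-1); multi-column responses
use the full SVD. Significance is assessed against spatial-autocorrelation-
preserving surrogate maps (variogram-matching nulls on the region
centroids), never against naive permutations, because neighbouring regions
are not exchangeable. Gene ranking, permutation-based gene-set enrichment
and Spearman receptor correlations (with the same spatial nulls) follow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr
from sklearn.base import BaseEstimator

from .space import ValidationError
from .stats import bh_adjust

logger = logging.getLogger("gliomap")


# ---------------------------------------------------------------------------
# inputs
# ---------------------------------------------------------------------------

def prepare_xy(expression: pd.DataFrame, regional_frequency: np.ndarray
               ) -> tuple[pd.DataFrame, np.ndarray]:
    """Response y = z-scored sqrt(frequency); X columns z-scored (ddof=1).

    Regions with any missing expression value are dropped pairwise (logged).
    """
    f = np.asarray(regional_frequency, dtype=float)
    if len(expression) != f.size:
        raise ValidationError("expression rows do not match frequency length")
    if np.any(f < 0):
        raise ValidationError("negative frequency")
    keep = ~expression.isna().any(axis=1).to_numpy()
    if not keep.all():
        logger.info("dropped %d region(s) with missing expression",
                    int((~keep).sum()))
    x = expression.loc[keep]
    f = f[keep]
    y = np.sqrt(f)
    sd = y.std(ddof=1)
    if sd == 0:
        raise ValidationError("constant frequency: z-score undefined")
    y = (y - y.mean()) / sd
    xv = x.to_numpy(float)
    xsd = xv.std(axis=0, ddof=1)
    if np.any(xsd == 0):
        raise ValidationError("constant expression column")
    xv = (xv - xv.mean(axis=0)) / xsd
    return pd.DataFrame(xv, index=x.index, columns=x.columns), y


# ---------------------------------------------------------------------------
# cross-covariance PLS
# ---------------------------------------------------------------------------

@dataclass
class PLSResult:
    singular_values: np.ndarray  # nonincreasing, >= 0
    gene_loadings: pd.DataFrame  # genes x components, unit-norm columns (U)
    region_scores: np.ndarray  # regions x components (X @ U)
    covariance_explained: np.ndarray  # fractions summing to 1
    spin_p: np.ndarray | None = None
    n_null: int = 0
    seed: int | None = None
    config: dict = field(default_factory=dict)


class CrossCovariancePLS(BaseEstimator):
    """Partial-least-squares association via SVD of the cross-covariance.

    The cross-covariance is computed with 1/(R-1) scaling on z-scored
    inputs, so singular values are comparable across runs.

    Attributes after :meth:`fit`: ``singular_values_``, ``gene_loadings_``,
    ``region_scores_``, ``covariance_explained_``, ``result_``.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y) -> "CrossCovariancePLS":
        genes = list(X.columns) if isinstance(X, pd.DataFrame) else None
        xv = np.asarray(X, dtype=float)
        yv = np.asarray(y, dtype=float)
        if yv.ndim == 1:
            yv = yv[:, None]
        r = xv.shape[0]
        if r < 10:
            raise ValidationError("need at least 10 regions")
        if yv.shape[0] != r:
            raise ValidationError("X and y row mismatch")
        if not (np.all(np.isfinite(xv)) and np.all(np.isfinite(yv))):
            raise ValidationError("non-finite input")
        c = (xv.T @ yv) / (r - 1)  # genes x responses
        u, s, _vt = np.linalg.svd(c, full_matrices=False)
        k = self.n_components or s.size
        if k > s.size:
            raise ValidationError(
                f"n_components={k} exceeds the {s.size} available components")
        u, s = u[:, :k], s[:k]
        total = float((c**2).sum())
        explained = (s**2) / total if total > 0 else np.zeros(k)
        self.singular_values_ = s
        self.gene_loadings_ = pd.DataFrame(
            u, index=genes if genes is not None else np.arange(u.shape[0]),
            columns=[f"PLS{i+1}" for i in range(k)])
        self.region_scores_ = xv @ u
        self.covariance_explained_ = explained
        self.result_ = PLSResult(
            singular_values=s, gene_loadings=self.gene_loadings_,
            region_scores=self.region_scores_, covariance_explained=explained)
        return self

    def transform(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.gene_loadings_.to_numpy()


def pls_cross_covariance(X, y, n_components: int | None = None) -> PLSResult:
    """Functional wrapper over :class:`CrossCovariancePLS`."""
    return CrossCovariancePLS(n_components=n_components).fit(X, y).result_


# ---------------------------------------------------------------------------
# spatial nulls
# ---------------------------------------------------------------------------

def _variogram(values: np.ndarray, bin_idx: np.ndarray, iu: tuple,
               n_bins: int) -> np.ndarray:
    sq = 0.5 * (values[iu[0]] - values[iu[1]]) ** 2
    return np.bincount(bin_idx, weights=sq, minlength=n_bins) / \
        np.maximum(np.bincount(bin_idx, minlength=n_bins), 1)


def spatial_null_maps(regional_map: np.ndarray, centroids: np.ndarray,
                      n_null: int = 1000, seed: int = 0, n_bins: int = 8,
                      match_fraction: float = 0.5) -> np.ndarray:
    """Variogram-matching surrogate maps (n_null x R).

    Each surrogate permutes the map, smooths it over the centroid-distance
    Gaussian kernel at each length scale of a small grid, regresses the
    target variogram onto the smoothed permutation's variogram (the
    intercept realized as a white-noise nugget), keeps the best-matching
    scale, and rescales to the original mean and variance. The variogram is
    matched over the shortest ``match_fraction`` of region pairs, split into
    ``n_bins`` equal-count distance bins: short-range autocorrelation is
    what random-alignment significance is sensitive to, while the long-range
    variogram of a nonstationary map (e.g. a focal frequency field) is not
    reproducible by a stationary surrogate and is deliberately left free.

    Surrogates preserve the value distribution's mean and variance exactly
    and the short-range autocorrelation approximately, while destroying the
    alignment with any fixed map.
    """
    x = np.asarray(regional_map, dtype=float)
    r = x.size
    if r < 20:
        raise ValidationError("need at least 20 regions for spatial nulls")
    if n_null < 100:
        raise ValidationError("n_null must be >= 100")
    if np.ptp(x) == 0:
        raise ValidationError("constant map has no spatial structure")
    rng = np.random.default_rng(seed)
    cent = np.asarray(centroids, dtype=float)
    d = np.linalg.norm(cent[:, None, :] - cent[None, :, :], axis=-1)
    iu = np.triu_indices(r, k=1)
    dv = d[iu]
    sel = dv <= np.quantile(dv, match_fraction)
    iu_sel = (iu[0][sel], iu[1][sel])
    edges = np.quantile(dv[sel], np.linspace(0, 1, n_bins + 1))
    bin_idx = np.clip(np.searchsorted(edges, dv[sel], side="right") - 1,
                      0, n_bins - 1)
    v0 = _variogram(x, bin_idx, iu_sel, n_bins)

    kernels = []
    for lam in np.quantile(dv, [0.02, 0.05, 0.1, 0.15, 0.25, 0.4, 0.6, 0.9]):
        w = np.exp(-(d**2) / (2.0 * max(lam, 1e-12) ** 2))
        w /= w.sum(axis=1, keepdims=True)
        kernels.append(w)

    mu, sd = x.mean(), x.std()
    out = np.empty((n_null, r))
    for i in range(n_null):
        perm = rng.permutation(x)
        noise = rng.normal(size=r)
        noise = (noise - noise.mean()) / noise.std()
        best, best_err = None, np.inf
        for w in kernels:
            s = w @ perm
            ssd = s.std()
            if ssd == 0:
                continue
            s = (s - s.mean()) / ssd
            # v0 ~ a * v_smooth + b; the intercept b becomes a white nugget
            vs = _variogram(s, bin_idx, iu_sel, n_bins)
            design = np.column_stack([vs, np.ones(n_bins)])
            (a, b), *_ = np.linalg.lstsq(design, v0, rcond=None)
            a, b = max(a, 0.0), max(b, 0.0)
            cand = np.sqrt(a) * s + np.sqrt(b) * noise
            csd = cand.std()
            if csd == 0:
                continue
            cand = (cand - cand.mean()) / csd
            err = float(((_variogram(cand, bin_idx, iu_sel, n_bins) - v0) ** 2).sum())
            if err < best_err:
                best, best_err = cand * sd + mu, err
        out[i] = best
    return out


def spin_pvalue(pls: PLSResult, X, null_maps: np.ndarray,
                n_components: int | None = None, seed: int | None = None
                ) -> PLSResult:
    """Attach spatial-null p-values to a fitted PLS result.

    Surrogate maps of the response are passed through the same sqrt +
    z-score preparation implied by their construction (the surrogates are
    already on the prepared scale), PLS is refit per surrogate, and per
    component k the p-value is ``(1 + #{null S_k >= observed S_k}) /
    (n_null + 1)``.
    """
    xv = np.asarray(X, dtype=float)
    r = xv.shape[0]
    nulls = np.asarray(null_maps, dtype=float)
    k = n_components or pls.singular_values.size
    s_null = np.empty((nulls.shape[0], k))
    for i, ymap in enumerate(nulls):
        sd = ymap.std(ddof=1)
        yz = (ymap - ymap.mean()) / sd
        c = (xv.T @ yz) / (r - 1)
        s = np.linalg.svd(c[:, None], compute_uv=False)
        s_full = np.zeros(k)
        s_full[: s.size] = s[:k]
        s_null[i] = s_full
    n_null = nulls.shape[0]
    p = (1.0 + (s_null >= pls.singular_values[None, :k]).sum(axis=0)) / (n_null + 1)
    return PLSResult(
        singular_values=pls.singular_values, gene_loadings=pls.gene_loadings,
        region_scores=pls.region_scores,
        covariance_explained=pls.covariance_explained,
        spin_p=p, n_null=n_null, seed=seed, config=pls.config)


# ---------------------------------------------------------------------------
# gene ranking and enrichment
# ---------------------------------------------------------------------------

def rank_genes(pls: PLSResult, component: int = 1) -> pd.Series:
    """Genes ordered descending by signed loading on a component (ties by id)."""
    if not (1 <= component <= pls.gene_loadings.shape[1]):
        raise ValidationError(f"component {component} out of range")
    col = pls.gene_loadings.iloc[:, component - 1]
    order = sorted(col.index, key=lambda g: (-col[g], g))
    return col.loc[order]


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # name, n_genes, statistic, p, q
    skipped: list = field(default_factory=list)


def gene_set_enrichment(loadings: pd.Series, gene_sets: dict[str, list],
                        n_perm: int = 2000, seed: int = 0,
                        min_size: int = 5) -> EnrichmentResult:
    """Competitive gene-set enrichment on per-gene loadings.

    Per set, the statistic is the two-sample (Welch) t between member and
    non-member loadings; the two-sided p-value comes from set-size-preserving
    random resampling of gene labels, with Benjamini-Hochberg adjustment
    across sets.
    """
    rng = np.random.default_rng(seed)
    background = loadings.index.to_numpy()
    vals = loadings.to_numpy(float)
    pos = {g: i for i, g in enumerate(background)}
    rows, skipped = [], []
    for name, members in gene_sets.items():
        idx = np.array([pos[g] for g in members if g in pos], dtype=int)
        if idx.size < min_size:
            logger.warning("set %s: only %d background gene(s), skipped",
                           name, idx.size)
            skipped.append(name)
            continue
        if idx.size >= vals.size:
            logger.warning("set %s covers the whole background, skipped", name)
            skipped.append(name)
            continue
        t_obs = _welch_t(vals, idx)
        t_null = np.empty(n_perm)
        for b in range(n_perm):
            t_null[b] = _welch_t(vals, rng.choice(vals.size, size=idx.size,
                                                  replace=False))
        p = (1.0 + (np.abs(t_null) >= abs(t_obs)).sum()) / (n_perm + 1)
        rows.append({"name": name, "n_genes": int(idx.size),
                     "statistic": t_obs, "p": p})
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = np.maximum(bh_adjust(table["p"].to_numpy()),
                                table["p"].to_numpy())
    return EnrichmentResult(table=table, skipped=skipped)


def _welch_t(vals: np.ndarray, idx: np.ndarray) -> float:
    member = np.zeros(vals.size, dtype=bool)
    member[idx] = True
    a, b = vals[member], vals[~member]
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    return float((a.mean() - b.mean()) / np.sqrt(va + vb))


# ---------------------------------------------------------------------------
# receptor maps
# ---------------------------------------------------------------------------

def receptor_correlation(tumor_regional: np.ndarray, receptor_regional: np.ndarray,
                         centroids: np.ndarray, n_null: int = 1000,
                         seed: int = 0,
                         null_maps: np.ndarray | None = None
                         ) -> tuple[float, float]:
    """Spearman correlation of a regional tumor-frequency vector with a
    receptor map, with a two-sided spatial-surrogate p-value (only the tumor
    map is surrogate-randomized)."""
    t = np.asarray(tumor_regional, dtype=float)
    rcp = np.asarray(receptor_regional, dtype=float)
    if t.size != rcp.size:
        raise ValidationError("length mismatch")
    if np.ptp(t) == 0 or np.ptp(rcp) == 0:
        raise ValidationError("correlation with a constant vector is undefined")
    rho = float(spearmanr(t, rcp).statistic)
    if null_maps is None:
        null_maps = spatial_null_maps(t, centroids, n_null=n_null, seed=seed)
    rr = rankdata(rcp)
    rho_null = np.array([
        float(np.corrcoef(rankdata(m), rr)[0, 1]) for m in null_maps])
    p = (1.0 + (np.abs(rho_null) >= abs(rho)).sum()) / (null_maps.shape[0] + 1)
    return rho, p
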