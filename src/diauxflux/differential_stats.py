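"""Differential abundance and multivariate phase discrimination.

Per-feature covariate-adjusted ordinary least squares on log2
intensities (with optional limma-style empirical-Bayes variance
moderation), volcano classification at raw p and fold-change thresholds,
strain correlation profiling with hierarchical clustering, and
orthogonal projections to latent structures discriminant analysis
(OPLS-DA) in the Trygg-Wold formulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from scipy.special import digamma, polygamma

from .metabolomics_preprocess import PeakTable

# ---------------------------------------------------------------------------
# Linear model


@dataclass
class DiffResult:
    """Per-feature linear-model output.

    ``table`` columns: coef_log2 (signed contrast coefficient on the
    log2 scale), sign, fold_change (2**|coef|, linear scale), p_raw,
    and p_moderated when moderation was requested.
    """

    table: pd.DataFrame
    contrast: str
    covariates: tuple[str, ...]

    def significant(self, p_threshold: float = 0.1,
                    use_moderated: bool = False) -> set[str]:
        col = "p_moderated" if use_moderated else "p_raw"
        return set(self.table.index[self.table[col] < p_threshold])


def _log2_with_offset(X: np.ndarray) -> np.ndarray:
    """log2 transform; zeros are offset by half the per-feature minimum
    positive value (features with no positive value become all-zero)."""
    out = np.empty_like(X, dtype=float)
    for i in range(X.shape[0]):
        row = X[i].astype(float)
        pos = row[row > 0]
        if len(pos) == 0:
            out[i] = 0.0
            continue
        offset = pos.min() / 2.0
        out[i] = np.log2(np.where(row > 0, row, offset))
    return out


def _design_matrix(meta: pd.DataFrame, contrast_col: str, contrast_level,
                   covariates: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(meta))]
    names = ["intercept"]
    cols.append((meta[contrast_col] == contrast_level).to_numpy(dtype=float))
    names.append(f"{contrast_col}[{contrast_level}]")
    for cov in covariates:
        levels = sorted(meta[cov].astype(str).unique())
        for lev in levels[1:]:
            cols.append((meta[cov].astype(str) == lev).to_numpy(dtype=float))
            names.append(f"{cov}[{lev}]")
    return np.column_stack(cols), names


def fit_linear_model(
    table: PeakTable,
    contrast: str = "phase",
    covariates: tuple[str, ...] = ("batch",),
    strain: str | None = None,
    reference: str = "WT",
    phase: str | None = None,
    moderate: bool = False,
) -> DiffResult:
    """Per-feature OLS of log2 intensity on the contrast plus covariates.

    ``contrast="phase"`` tests post vs pre over study samples (strain and
    batch are natural covariates for the across-shift analysis);
    ``contrast="strain"`` tests ``strain`` vs ``reference``, optionally
    restricted to one ``phase``, with batch as covariate.  The contrast
    coefficient is tested with a t-test; ``moderate=True`` additionally
    shrinks the per-feature residual variances toward a pooled
    inverse-chi-square prior (the limma scheme), gaining degrees of
    freedom for small replicate counts.
    """
    meta = table.sample_meta
    keep = meta["class"] == "sample"
    if contrast == "phase":
        contrast_col, contrast_level = "phase", "post"
    elif contrast == "strain":
        if strain is None:
            raise ValueError("strain contrast requires a strain")
        contrast_col, contrast_level = "strain", strain
        keep &= meta["strain"].isin([strain, reference])
        if phase is not None:
            keep &= meta["phase"] == phase
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    meta = meta[keep]
    if (meta[contrast_col] == contrast_level).sum() < 2 or \
            (meta[contrast_col] != contrast_level).sum() < 2:
        raise ValueError("each contrast group needs >= 2 samples")
    covariates = tuple(c for c in covariates
                       if c != contrast_col and meta[c].astype(str).nunique() > 1)

    X, names = _design_matrix(meta, contrast_col, contrast_level, covariates)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "confounded design: the contrast is collinear with the covariates "
            f"(design columns: {names})")

    Y = _log2_with_offset(table.intensities[meta.index].to_numpy()).T  # samples x features
    n, p = X.shape
    df_resid = n - p
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y
    resid = Y - X @ B
    s2 = (resid**2).sum(axis=0) / df_resid
    c_idx = 1  # contrast column
    se = np.sqrt(np.maximum(s2, 1e-300) * XtX_inv[c_idx, c_idx])
    coef = B[c_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se
    p_raw = 2 * stats.t.sf(np.abs(t), df_resid)
    p_raw = np.where(np.isfinite(t), p_raw, 1.0)

    out = pd.DataFrame({
        "coef_log2": coef,
        "sign": np.sign(coef),
        "fold_change": 2.0 ** np.abs(coef),
        "p_raw": p_raw,
    }, index=table.intensities.index)
    if moderate:
        s2_post, df_prior = squeeze_variances(s2, df_resid)
        se_mod = np.sqrt(s2_post * XtX_inv[c_idx, c_idx])
        with np.errstate(divide="ignore", invalid="ignore"):
            t_mod = coef / se_mod
        df_total = df_resid + df_prior
        p_mod = 2 * stats.t.sf(np.abs(t_mod), df_total)
        out["p_moderated"] = np.where(np.isfinite(t_mod), p_mod, 1.0)
    return DiffResult(table=out, contrast=contrast_col, covariates=covariates)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (limma's approach)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return y


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of residual variances (limma squeezeVar).

    Fits a scaled inverse-chi-square prior (d0, s0^2) to the observed
    variances by moment matching on the log scale and returns the
    posterior variances ``(d0 s0^2 + df s^2)/(d0 + df)`` together with
    the prior degrees of freedom d0.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-300)
    z = np.log(s2)
    e = z - digamma(df / 2) + np.log(df / 2)
    e_mean = e.mean()
    e_var = np.var(e, ddof=1) - polygamma(1, df / 2)
    if e_var <= 0:
        return np.full_like(s2, np.exp(e_mean)), np.inf
    d0 = 2 * _trigamma_inverse(e_var)
    s0_sq = np.exp(e_mean + digamma(d0 / 2) - np.log(d0 / 2))
    s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    return s2_post, d0


def volcano_classify(diff: DiffResult, p_threshold: float = 0.1,
                     fc_threshold: float = 1.5,
                     use_moderated: bool = False) -> set[str]:
    """Features with raw p strictly below and fold change strictly above
    the thresholds (the volcano-plot significance region)."""
    col = "p_moderated" if use_moderated else "p_raw"
    t = diff.table
    mask = (t[col] < p_threshold) & (t["fold_change"] > fc_threshold)
    return set(t.index[mask])


# ---------------------------------------------------------------------------
# Correlation profiles


@dataclass
class CorrelationProfiles:
    group_means: pd.DataFrame       # features x groups
    correlations: pd.DataFrame      # groups x groups, Pearson r
    group_linkage: np.ndarray       # scipy linkage on 1 - r
    feature_linkage: np.ndarray     # scipy linkage, Euclidean on z-scores
    group_labels: list


def correlation_profiles(table: PeakTable,
                         group_by: tuple[str, ...] = ("strain", "phase"),
                         linkage_method: str = "average") -> CorrelationProfiles:
    """Replicate-averaged profiles, Pearson clustering of groups, and a
    Euclidean dendrogram of standardized features.

    Groups whose averaged profile has zero variance (correlation
    undefined) are dropped with a warning.
    """
    meta = table.sample_meta
    study = meta[meta["class"] == "sample"]
    keys = study.groupby(list(group_by), sort=True).groups
    if len(keys) < 2:
        raise ValueError("correlation profiling needs >= 2 groups")
    means = {}
    for key, idx in keys.items():
        label = key if isinstance(key, str) else "/".join(map(str, key))
        prof = table.intensities[idx].mean(axis=1)
        if prof.std() == 0:
            import warnings
            warnings.warn(f"group {label} has zero variance; dropped")
            continue
        means[label] = prof
    gm = pd.DataFrame(means)
    corr = gm.corr(method="pearson")
    gdist = squareform(1.0 - corr.to_numpy(), checks=False)
    glink = linkage(gdist, method=linkage_method)
    z = gm.sub(gm.mean(axis=1), axis=0)
    sd = gm.std(axis=1).replace(0.0, 1.0)
    z = z.div(sd, axis=0)
    flink = linkage(pdist(z.to_numpy(), metric="euclidean"), method=linkage_method)
    return CorrelationProfiles(group_means=gm, correlations=corr,
                               group_linkage=glink, feature_linkage=flink,
                               group_labels=list(gm.columns))


# ---------------------------------------------------------------------------
# OPLS-DA


@dataclass
class OplsModel:
    """One-predictive-component OPLS-DA model (Trygg-Wold).

    Scores/loadings for the single predictive component and ``k``
    orthogonal components; the predictive scores are orthogonal to every
    orthogonal score vector.  Classification is nearest class mean on the
    predictive score.
    """

    w_pred: np.ndarray          # predictive weight (features,)
    p_pred: np.ndarray          # predictive loading
    t_pred: np.ndarray          # predictive scores (samples,)
    W_orth: np.ndarray          # features x k
    P_orth: np.ndarray
    T_orth: np.ndarray          # samples x k
    classes: tuple
    class_means: dict           # class -> mean predictive score
    class_ellipses: dict        # class -> (center(2,), cov(2,2)) in score plane
    variance_explained: dict
    x_mean: np.ndarray
    x_scale: np.ndarray

    def transform(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predictive and orthogonal scores for new samples."""
        Xc = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        T_orth = np.zeros((Xc.shape[0], self.W_orth.shape[1]))
        for k in range(self.W_orth.shape[1]):
            t_o = Xc @ self.W_orth[:, k]
            Xc = Xc - np.outer(t_o, self.P_orth[:, k])
            T_orth[:, k] = t_o
        return Xc @ self.w_pred, T_orth

    def predict(self, X: np.ndarray) -> np.ndarray:
        t, _ = self.transform(X)
        labels = np.array(self.classes, dtype=object)
        centers = np.array([self.class_means[c] for c in self.classes])
        return labels[np.argmin(np.abs(t[:, None] - centers[None, :]), axis=1)]


def fit_opls_da(X: np.ndarray, y: np.ndarray, n_orthogonal: int = 1,
                scale: bool = False) -> OplsModel:
    """Fit OPLS-DA: strip y-orthogonal variation, then one PLS component.

    ``y`` holds two class labels; each class needs >= 3 samples.  With
    ``n_orthogonal=0`` the predictive component equals the one-component
    PLS solution.  95% confidence ellipses per class are computed in the
    (predictive, first orthogonal) score plane from the within-class
    score covariance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = tuple(sorted(pd.unique(y).tolist(), key=str))
    if len(classes) != 2:
        raise ValueError("OPLS-DA requires exactly two classes")
    for c in classes:
        if (y == c).sum() < 3:
            raise ValueError(f"class {c!r} has fewer than 3 samples")
    if n_orthogonal >= min(X.shape) or n_orthogonal >= np.linalg.matrix_rank(X):
        raise ValueError("n_orthogonal must be below the rank of X")

    yy = np.where(y == classes[1], 1.0, -1.0)
    yy = yy - yy.mean()
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1) if scale else np.ones(X.shape[1])
    x_scale = np.where(x_scale > 0, x_scale, 1.0)
    Xc = (X - x_mean) / x_scale
    total_ss = (Xc**2).sum()

    w = Xc.T @ yy
    w /= np.linalg.norm(w)
    W_orth = np.zeros((X.shape[1], n_orthogonal))
    P_orth = np.zeros((X.shape[1], n_orthogonal))
    T_orth = np.zeros((X.shape[0], n_orthogonal))
    for k in range(n_orthogonal):
        t = Xc @ w
        p = Xc.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            W_orth = W_orth[:, :k]
            P_orth = P_orth[:, :k]
            T_orth = T_orth[:, :k]
            break
        w_o /= norm
        t_o = Xc @ w_o
        p_o = Xc.T @ t_o / (t_o @ t_o)
        Xc = Xc - np.outer(t_o, p_o)
        W_orth[:, k], P_orth[:, k], T_orth[:, k] = w_o, p_o, t_o

    t_pred = Xc @ w
    p_pred = Xc.T @ t_pred / (t_pred @ t_pred)

    var = {"predictive": float((np.outer(t_pred, p_pred)**2).sum() / total_ss)}
    for k in range(T_orth.shape[1]):
        var[f"orthogonal_{k + 1}"] = float(
            (np.outer(T_orth[:, k], P_orth[:, k])**2).sum() / total_ss)

    class_means = {c: float(t_pred[y == c].mean()) for c in classes}
    ellipses = {}
    if T_orth.shape[1] > 0:
        plane = np.column_stack([t_pred, T_orth[:, 0]])
    else:
        plane = np.column_stack([t_pred, np.zeros_like(t_pred)])
    chi2_95 = stats.chi2.ppf(0.95, df=2)
    for c in classes:
        pts = plane[y == c]
        center = pts.mean(axis=0)
        cov = np.cov(pts.T) * chi2_95
        ellipses[c] = (center, cov)

    return OplsModel(w_pred=w, p_pred=p_pred, t_pred=t_pred,
                     W_orth=W_orth, P_orth=P_orth, T_orth=T_orth,
                     classes=classes, class_means=class_means,
                     class_ellipses=ellipses, variance_explained=var,
                     x_mean=x_mean, x_scale=x_scale)


def select_discriminating_features(
    model: OplsModel,
    diff: DiffResult,
    feature_ids: list[str],
    p_threshold: float = 0.05,
    top_n: int = 25,
) -> list[str]:
    """Top features by |predictive loading| that the linear model also
    calls significant (raw p strictly below ``p_threshold``).

    ``feature_ids`` names the columns of the matrix the OPLS model was
    fitted on, in order.  Returns at most ``top_n`` ids, ranked.
    """
    if len(feature_ids) != len(model.p_pred):
        raise ValueError("feature_ids length does not match the OPLS model")
    loading = pd.Series(np.abs(model.p_pred), index=feature_ids)
    pvals = diff.table["p_raw"].reindex(feature_ids)
    qualifying = loading[(pvals < p_threshold) & (loading > 0)]
    ranked = qualifying.sort_values(ascending=False)
    if len(ranked) < top_n:
        import warnings
        warnings.warn(f"only {len(ranked)} features qualify (requested {top_n})")
    return list(ranked.index[:top_n])
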