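"""Quantification-level processing and covariate correction for TMT data.

Implements the path from reporter-ion intensities to analysis-ready
log2 relative abundance: reference-ratio quantification, missingness and
plex-completeness filters, Tukey median polish, feature-space KNN
imputation, and empirical-Bayes removal of loading-mass and plex
effects, plus the diagnostic scan that quantifies how many features a
covariate touches.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import OmicsMatrix, ReporterIntensityTable


def relative_abundance(table: ReporterIntensityTable) -> OmicsMatrix:
    """log2(sample / reference-channel) abundance, zero-centered per feature.

    Features whose reference intensity is zero (ratio undefined) are
    returned as all-NA rows. Zero sample intensities become NA in that
    channel only.
    """
    ref = table.intensities[table.reference_channel]
    x = table.intensities.drop(columns=[table.reference_channel]).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.log2(x.to_numpy() / ref.to_numpy()[:, None])
    ratios[~np.isfinite(ratios)] = np.nan
    bad_ref = (ref.to_numpy() <= 0) | ~np.isfinite(ref.to_numpy())
    ratios[bad_ref, :] = np.nan
    out = pd.DataFrame(ratios, index=x.index, columns=x.columns)
    out = out.sub(out.mean(axis=1, skipna=True), axis=0)
    return OmicsMatrix(out, modality="protein")


def filter_missingness(
    m: OmicsMatrix, max_missing_frac: float = 0.5
) -> OmicsMatrix:
    """Keep features present in at least ``1 - max_missing_frac`` of samples.

    The boundary is inclusive: a feature missing in exactly half the
    samples survives the default filter. Row order is preserved and
    values are untouched.
    """
    frac = m.values.isna().mean(axis=1)
    return m.with_values(m.values.loc[frac <= max_missing_frac])


def median_polish(
    m: OmicsMatrix,
    max_iter: int = 50,
    tol: float = 1e-8,
    mode: str = "polish",
) -> OmicsMatrix:
    """Tukey's median polish: residuals after removing row/column medians.

    ``mode="polish"`` alternates row- and column-median sweeps until the
    largest median removed falls below ``tol`` (full two-way polish);
    ``mode="center"`` performs a single row sweep then a single column
    sweep (per-axis median centering). NA entries are ignored by every
    median and remain NA. The median of an even count is the mean of the
    middle pair.
    """
    x = m.values.to_numpy(dtype=float).copy()
    if np.isnan(x).all(axis=1).any() or np.isnan(x).all(axis=0).any():
        raise ValueError("median polish requires no all-NA rows or columns")
    if mode not in {"polish", "center"}:
        raise ValueError("mode must be 'polish' or 'center'")

    n_sweeps = 1 if mode == "center" else max_iter
    converged = mode == "center"
    for _ in range(n_sweeps):
        rmed = np.nanmedian(x, axis=1)
        x -= rmed[:, None]
        cmed = np.nanmedian(x, axis=0)
        x -= cmed[None, :]
        if mode == "polish":
            delta = max(np.abs(rmed).max(), np.abs(cmed).max())
            if delta < tol:
                converged = True
                break
    if not converged:
        warnings.warn(
            "median polish did not converge; returning current residuals",
            stacklevel=2,
        )
    return m.with_values(
        pd.DataFrame(x, index=m.features, columns=m.samples)
    )


def plex_completeness_filter(
    m: OmicsMatrix, annotation: pd.DataFrame, max_missing_plexes: int = 0
) -> OmicsMatrix:
    """Keep features observed in enough TMT plexes.

    A plex counts as missing for a feature iff every sample of that plex
    is NA. ``max_missing_plexes=0`` is the strict rule (at least one
    measurement in every plex); larger values relax it (e.g. 10 of 21
    plexes allowed missing for phosphosites).
    """
    missing = set(m.samples) - set(annotation.index)
    if missing:
        raise ValueError(f"samples without plex annotation: {sorted(missing)[:3]}")
    plex = annotation.loc[m.samples, "plex"]
    observed = m.values.notna()
    # per-(feature, plex): any observation?
    per_plex = observed.T.groupby(plex.to_numpy()).any().T
    n_missing = (~per_plex).sum(axis=1)
    return m.with_values(m.values.loc[n_missing <= max_missing_plexes])


def knn_impute(m: OmicsMatrix, k: int = 10) -> OmicsMatrix:
    """Impute NAs from the k nearest feature rows.

    Distance between two features is the Euclidean distance over the
    samples where both are observed; a candidate neighbor must be
    observed at the target sample. Features with no eligible neighbor
    fall back to their own row mean. Observed entries are untouched.
    """
    if m.values.size == 0:
        raise ValueError("cannot impute an empty matrix")
    x = m.values.to_numpy(dtype=float)
    obs = ~np.isnan(x)
    if not obs.any(axis=1).all():
        raise ValueError("every feature needs at least one observed value")
    if not np.isnan(x).any():
        return m.copy()

    x0 = np.where(obs, x, 0.0)
    # pairwise squared Euclidean over co-observed samples
    sq = x0**2
    cross = x0 @ x0.T
    a2 = sq @ obs.T.astype(float)  # sum_i x_f^2 over co-observed with g
    b2 = obs.astype(float) @ sq.T
    d2 = a2 + b2 - 2 * cross
    shared = obs.astype(float) @ obs.T.astype(float)
    d2[shared == 0] = np.inf
    np.fill_diagonal(d2, np.inf)

    out = x.copy()
    row_means = np.nanmean(x, axis=1)
    for f, j in zip(*np.where(~obs)):
        eligible = obs[:, j] & np.isfinite(d2[f])
        if not eligible.any():
            out[f, j] = row_means[f]
            continue
        cand = np.flatnonzero(eligible)
        order = cand[np.argsort(d2[f, cand], kind="stable")][:k]
        out[f, j] = x[order, j].mean()
    return m.with_values(pd.DataFrame(out, index=m.features, columns=m.samples))


def _covariate_design(
    annotation: pd.DataFrame, covariates: list[str], samples: pd.Index
) -> pd.DataFrame:
    """Standardized continuous + centered one-hot categorical design.

    Columns are centered so that subtracting fitted covariate effects
    preserves each feature's mean. Constant covariates are dropped with a
    warning.
    """
    ann = annotation.loc[samples]
    cols = {}
    for cov in covariates:
        if cov not in ann.columns:
            raise ValueError(f"covariate {cov!r} not in annotation")
        v = ann[cov]
        if pd.api.types.is_numeric_dtype(v) and v.nunique() > 2:
            sd = v.std(ddof=1)
            if sd == 0 or np.isnan(sd):
                warnings.warn(f"dropping constant covariate {cov!r}", stacklevel=3)
                continue
            cols[cov] = (v - v.mean()) / sd
        else:
            levels = pd.Categorical(v)
            if len(levels.categories) < 2:
                warnings.warn(f"dropping constant covariate {cov!r}", stacklevel=3)
                continue
            dummies = pd.get_dummies(v, prefix=cov, drop_first=True).astype(float)
            for c in dummies.columns:
                cols[c] = dummies[c] - dummies[c].mean()
    return pd.DataFrame(cols, index=samples)


def eb_covariate_correction(
    m: OmicsMatrix,
    annotation: pd.DataFrame,
    covariates: list[str] = ("loading_mass", "plex"),
    shrink: bool = True,
) -> OmicsMatrix:
    """Remove covariate effects with empirical-Bayes shrunken regressions.

    Per feature, an OLS fit of abundance on the (centered) covariate
    design yields coefficients b_f with standard errors. Each coefficient
    is shrunk toward its across-feature mean with weight
    tau^2 / (tau^2 + se_f^2), where tau^2 is the method-of-moments
    estimate of the between-feature coefficient variance. The shrunken
    fitted covariate effect is subtracted; feature means are retained.
    With ``shrink=False`` this is plain per-feature residualization.

    NA entries are tolerated (the fit uses observed samples) and stay NA.
    """
    D = _covariate_design(annotation, list(covariates), m.samples)
    if D.shape[1] == 0:
        return m.copy()
    d = D.to_numpy()
    x = m.values.to_numpy(dtype=float)
    nan_mask = np.isnan(x)
    p = d.shape[1]

    if not nan_mask.any():
        coefs, ses = _ols_all(x, d)
    else:
        coefs = np.zeros((x.shape[0], p))
        ses = np.full((x.shape[0], p), np.inf)
        for f in range(x.shape[0]):
            ok = ~nan_mask[f]
            if ok.sum() <= p + 1:
                continue
            cf, se = _ols_all(x[f : f + 1, ok], d[ok])
            coefs[f], ses[f] = cf[0], se[0]

    if shrink:
        prior_mean = coefs.mean(axis=0)
        se2 = ses**2
        finite = np.isfinite(se2)
        mean_se2 = np.where(
            finite.any(axis=0), np.nanmean(np.where(finite, se2, np.nan), axis=0), 0.0
        )
        tau2 = np.maximum(coefs.var(axis=0, ddof=1) - mean_se2, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = tau2 / (tau2 + se2)
        w[~np.isfinite(w)] = 0.0
        coefs = prior_mean + w * (coefs - prior_mean)

    fitted = coefs @ d.T
    out = x - fitted
    out[nan_mask] = np.nan
    return m.with_values(pd.DataFrame(out, index=m.features, columns=m.samples))


def _ols_all(x: np.ndarray, d: np.ndarray):
    """OLS of every row of x on design d (with implicit intercept).

    d's columns are centered, so the intercept equals the row mean and
    the slope fit can use centered data. Returns (coefs, ses), each
    features x covariates.
    """
    n, p = d.shape
    dc = d - d.mean(axis=0)
    xc = x - x.mean(axis=1, keepdims=True)
    gram = dc.T @ dc
    ginv = np.linalg.pinv(gram)
    coefs = xc @ dc @ ginv.T
    resid = xc - coefs @ dc.T
    dof = max(n - p - 1, 1)
    s2 = (resid**2).sum(axis=1) / dof
    ses = np.sqrt(np.outer(s2, np.diag(ginv)))
    return coefs, ses


def covariate_effect_scan(
    m: OmicsMatrix,
    annotation: pd.DataFrame,
    covariate: str,
    alpha: float = 0.05,
):
    """Fraction of features significantly affected by one covariate.

    Continuous covariates use the per-feature regression t-test (via the
    Pearson correlation over observed samples); categorical covariates a
    one-way Welch-free ANOVA. P-values are BH-adjusted across features.

    Returns ``(pvalues, adjusted, significant_fraction)``.
    """
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples")
    v = annotation.loc[m.samples, covariate]
    if v.nunique() < 2:
        raise ValueError(f"covariate {covariate!r} is constant")
    x = m.values.to_numpy(dtype=float)

    if pd.api.types.is_numeric_dtype(v) and v.nunique() > 2:
        z = v.to_numpy(dtype=float)
        pvals = _corr_test(x, z)
    else:
        groups = pd.Categorical(v)
        pvals = np.ones(x.shape[0])
        for f in range(x.shape[0]):
            vals = [
                x[f, np.asarray(groups.codes) == c][
                    ~np.isnan(x[f, np.asarray(groups.codes) == c])
                ]
                for c in range(len(groups.categories))
            ]
            vals = [g for g in vals if len(g) >= 2]
            if len(vals) < 2:
                pvals[f] = np.nan
                continue
            pvals[f] = stats.f_oneway(*vals).pvalue

    pser = pd.Series(pvals, index=m.features, name="p")
    ok = pser.notna()
    adj = pd.Series(np.nan, index=m.features, name="p_adj")
    if ok.any():
        adj[ok] = multipletests(pser[ok], method="fdr_bh")[1]
    frac = float((adj[ok] < alpha).mean()) if ok.any() else np.nan
    return pser, adj, frac


def _corr_test(x: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Per-row Pearson correlation t-test against z, NA-tolerant."""
    obs = ~np.isnan(x)
    n = obs.sum(axis=1)
    zx = np.where(obs, z[None, :], np.nan)
    xm = np.nanmean(x, axis=1, keepdims=True)
    zm = np.nanmean(zx, axis=1, keepdims=True)
    xc = np.where(obs, x - xm, 0.0)
    zc = np.where(obs, zx - zm, 0.0)
    num = (xc * zc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (zc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / den
    r = np.clip(r, -1.0, 1.0)
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(dof / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), np.maximum(dof, 1))
    p[dof < 1] = np.nan
    p[~np.isfinite(t)] = 0.0  # |r| == 1 exactly
    return p


def apply_global_loading_normalization(
    phospho: OmicsMatrix, global_matrix: OmicsMatrix
) -> OmicsMatrix:
    """Apply global-proteome per-sample median offsets to the phospho data.

    Loading normalization factors are derived from median-centering the
    global proteome (per-sample median offset) and the same factors are
    subtracted from the phosphosite matrix, so both modalities share one
    loading correction.
    """
    offsets = global_matrix.values.median(axis=0, skipna=True)
    out = phospho.values.sub(offsets[phospho.samples], axis=1)
    return phospho.with_values(out)
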