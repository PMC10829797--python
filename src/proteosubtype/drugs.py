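"""Ex vivo drug-response stratification and cohort enrichment statistics.

Drugs are filtered by assay coverage and by the sensitivity criterion
(AUC < 100 in enough samples), then AUC is tested against mutations,
subtypes (one-vs-rest), and subtype x mutation interactions with
Welch's unequal-variance t-test under joint Benjamini-Hochberg control.
Fisher's exact test measures subtype enrichment of binary annotations;
Kaplan-Meier curves and the k-group log-rank test compare survival.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Welch t sign convention: positive = group of interest more resistant
#: (higher AUC) than the rest. Mirrors the heat-matrix shading legend.
T_SIGN_CONVENTION = "positive t: group has higher AUC (more resistant)"


def filter_drugs(
    table: pd.DataFrame,
    min_tested: int = 100,
    min_sensitive: int = 10,
    sens_threshold: float = 100.0,
) -> pd.DataFrame:
    """Keep drugs tested widely enough with enough sensitive samples.

    A drug survives iff it has >= ``min_tested`` non-NA AUCs and at
    least ``min_sensitive`` samples strictly below ``sens_threshold``
    (the "sensitive" criterion, AUC < 100). Values of retained columns
    are untouched.
    """
    tested = table.notna().sum(axis=0)
    sensitive = (table < sens_threshold).sum(axis=0)
    keep = (tested >= min_tested) & (sensitive >= min_sensitive)
    return table.loc[:, keep]


def _welch(a: np.ndarray, b: np.ndarray):
    """Welch t (a vs b, positive = a higher) with Welch-Satterthwaite df."""
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def welch_association(
    table: pd.DataFrame,
    groups: pd.DataFrame,
    min_group: int = 2,
    bh_scope: str = "joint",
) -> pd.DataFrame:
    """Welch t-tests of AUC for each (drug, binary grouping) pair.

    ``groups`` holds one boolean/0-1 column per contrast (mutation flags
    or one-vs-rest subtype indicators from :func:`subtype_indicators`).
    Cells whose in/out group has fewer than ``min_group`` assayed
    samples are NA. BH adjustment spans the whole family
    (``bh_scope="joint"``) or each drug separately (``"per_drug"``).
    """
    if bh_scope not in {"joint", "per_drug"}:
        raise ValueError("bh_scope must be 'joint' or 'per_drug'")
    groups = groups.loc[table.index].astype(bool)
    rows = []
    for drug in table.columns:
        auc = table[drug]
        for name in groups.columns:
            g = groups[name]
            a = auc[g].dropna().to_numpy()
            b = auc[~g].dropna().to_numpy()
            if len(a) < min_group or len(b) < min_group:
                t = p = np.nan
            else:
                t, p = _welch(a, b)
            rows.append(
                {
                    "drug": drug,
                    "group": name,
                    "t": t,
                    "p": p,
                    "n_group": len(a),
                    "n_rest": len(b),
                    "mean_group": a.mean() if len(a) else np.nan,
                    "mean_rest": b.mean() if len(b) else np.nan,
                }
            )
    cols = ["drug", "group", "t", "p", "n_group", "n_rest", "mean_group", "mean_rest"]
    out = pd.DataFrame(rows, columns=cols)
    out["p_adj"] = np.nan
    if bh_scope == "joint":
        ok = out["p"].notna()
        if ok.any():
            out.loc[ok, "p_adj"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    else:
        for drug, idx in out.groupby("drug").groups.items():
            sub = out.loc[idx]
            ok = sub["p"].notna()
            if ok.any():
                out.loc[sub.index[ok], "p_adj"] = multipletests(
                    sub.loc[ok, "p"], method="fdr_bh"
                )[1]
    out["significant"] = out["p_adj"] < 0.05
    out.attrs["t_sign"] = T_SIGN_CONVENTION
    return out


def subtype_indicators(labels: pd.Series) -> pd.DataFrame:
    """One-vs-rest boolean indicator columns, one per subtype."""
    return pd.DataFrame(
        {f"subtype{c}": labels == c for c in sorted(labels.unique())},
        index=labels.index,
    )


def fisher_enrichment(
    labels: pd.Series, annotation: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Two-sided Fisher exact enrichment of each annotation per cluster.

    For each (cluster, binary annotation) the 2x2 table is membership vs
    annotation over samples with a non-NA flag. Empty margins give NA.
    """
    rows = []
    for cluster in sorted(labels.unique()):
        in_c = labels == cluster
        for name in annotation.columns:
            flag = annotation[name].loc[labels.index]
            ok = flag.notna()
            a = int((in_c & ok & (flag == 1)).sum())
            b = int((in_c & ok & (flag == 0)).sum())
            c = int((~in_c & ok & (flag == 1)).sum())
            d = int((~in_c & ok & (flag == 0)).sum())
            tab = np.array([[a, b], [c, d]])
            if tab.sum() == 0:
                odds = p = np.nan
            else:
                # zero margins (e.g. constant annotation) give p = 1
                odds, p = stats.fisher_exact(tab, alternative="two-sided")
            rows.append(
                {
                    "cluster": cluster,
                    "annotation": name,
                    "odds_ratio": odds,
                    "p": p,
                    "significant": (p < alpha) if not np.isnan(p) else False,
                    "n_cluster_pos": a,
                }
            )
    return pd.DataFrame(rows)


def significance_stars(p_adj: float) -> str:
    """Stars by order of magnitude: 0.01 -> '*', 0.001 -> '**', etc."""
    if not np.isfinite(p_adj) or p_adj > 0.01:
        return ""
    return "*" * max(int(np.floor(-np.log10(p_adj))) - 1, 0)


def interaction_analysis(
    table: pd.DataFrame,
    labels: pd.Series,
    mutation: pd.Series,
    min_group: int = 2,
) -> pd.DataFrame:
    """Within-subtype mutant-vs-wild-type Welch tests per drug.

    Detects subtype x mutation interactions: a drug whose mutation effect
    exists only inside one subtype shows up as a significant cell there
    and nowhere else. BH adjustment spans the full (drug, subtype)
    family; stars annotate adjusted p by order of magnitude.
    """
    labels = labels.loc[table.index]
    mutation = mutation.loc[table.index]
    rows = []
    for drug in table.columns:
        for subtype in sorted(labels.unique()):
            sel = labels == subtype
            mut = table.loc[sel & (mutation == 1), drug].dropna().to_numpy()
            wt = table.loc[sel & (mutation == 0), drug].dropna().to_numpy()
            if len(mut) < min_group or len(wt) < min_group:
                t = p = np.nan
            else:
                t, p = _welch(mut, wt)
            rows.append(
                {
                    "drug": drug,
                    "subtype": subtype,
                    "t": t,
                    "p": p,
                    "n_mut": len(mut),
                    "n_wt": len(wt),
                }
            )
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "p_adj"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["significant"] = out["p_adj"] < 0.05
    out["stars"] = out["p_adj"].map(significance_stars)
    return out


def km_logrank(annotation: pd.DataFrame, labels: pd.Series) -> dict:
    """Kaplan-Meier curves per subtype and the k-group log-rank test.

    Uses ``survival_time`` / ``survival_event`` columns; subtypes with
    no samples are excluded. Returns the fitted curves, the chi-square
    statistic (k - 1 df), and its p-value.
    """
    labels = labels.loc[annotation.index]
    time = annotation["survival_time"].astype(float)
    event = annotation["survival_event"].astype(int)
    if (time < 0).any():
        raise ValueError("survival times must be nonnegative")
    curves = {}
    for subtype in sorted(labels.unique()):
        sel = labels == subtype
        if not sel.any():
            continue
        kmf = KaplanMeierFitter(label=f"subtype{subtype}")
        kmf.fit(time[sel], event_observed=event[sel])
        curves[subtype] = kmf
    res = multivariate_logrank_test(time, labels, event)
    return {
        "curves": curves,
        "statistic": float(res.test_statistic),
        "p": float(res.p_value),
        "df": len(curves) - 1,
    }
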