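"""Subtype functional characterization: preranked GSEA and KSEA.

Both methods consume a per-subtype ranked list built by mean-centering
every feature and averaging the centered values within the subtype.
GSEA uses the weighted Kolmogorov-Smirnov running-sum enrichment score
with gene-set (feature-label) permutation significance; KSEA is the
kinase z-statistic comparing a kinase's substrate phosphosites to the
background of all quantified sites. P-values are Benjamini-Hochberg
adjusted within each analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import OmicsMatrix


def subtype_rank_vector(
    m: OmicsMatrix, labels: pd.Series, subtype
) -> pd.Series:
    """Per-feature mean of feature-centered values within one subtype.

    Sorted descending; positive scores mark features elevated in the
    subtype relative to the cohort mean.
    """
    labels = labels.loc[m.samples]
    members = labels[labels == subtype].index
    if len(members) == 0:
        raise ValueError(f"subtype {subtype!r} has no samples")
    centered = m.values.sub(m.values.mean(axis=1, skipna=True), axis=0)
    score = centered[members].mean(axis=1, skipna=True)
    return score.sort_values(ascending=False)


def enrichment_score(
    ranked: pd.Series, members: set | list, weight: float = 1.0
) -> float:
    """Weighted KS running-sum enrichment score for one set.

    Walking the descending ranked list, hits increment the running sum by
    |score|^weight (normalized over hits), misses decrement by
    1/(N - N_hits); the ES is the running-sum value of maximal absolute
    deviation from zero. ES in [-1, 1].
    """
    ranked = ranked.sort_values(ascending=False)
    ids = ranked.index
    hit = ids.isin(set(members))
    n, nh = len(ids), int(hit.sum())
    if nh == 0 or nh == n:
        raise ValueError("set must be a proper nonempty subset of the list")
    w = np.abs(ranked.to_numpy()) ** weight
    wh = np.where(hit, w, 0.0)
    denom = wh.sum()
    if denom == 0:  # all member scores exactly zero: fall back to counts
        wh = hit.astype(float)
        denom = wh.sum()
    running = np.cumsum(wh / denom - (~hit) / (n - nh))
    return float(running[np.abs(running).argmax()])


def _es_from_positions(pos: np.ndarray, w_sorted: np.ndarray, n: int) -> float:
    """ES evaluated only at hit positions (O(m) per set).

    ``pos`` are sorted 0-based positions of the hits in the ranked list;
    ``w_sorted`` are |score|^weight in list order. The running sum is
    piecewise linear-down between hits, so its extrema occur just before
    or at hit positions.
    """
    m = len(pos)
    wh = w_sorted[pos]
    denom = wh.sum()
    if denom == 0:
        wh = np.ones(m)
        denom = float(m)
    cum_hit = np.cumsum(wh) / denom
    miss = 1.0 / (n - m)
    at_hit = cum_hit - (pos + 1 - np.arange(1, m + 1)) * miss
    before_hit = cum_hit - wh / denom - (pos - np.arange(m)) * miss
    # the running sum decreases linearly between hits and ends at 0, so
    # its extrema occur at a hit or immediately before one
    cand = np.concatenate([at_hit, before_hit])
    return float(cand[np.abs(cand).argmax()])


def gsea_preranked(
    ranked: pd.Series,
    sets: dict[str, list],
    n_perm: int = 1000,
    weight: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA over a collection of feature sets.

    Significance is by feature-label permutation: the null ES of a set of
    size m is the ES of m features drawn at random from the list. The
    reported p is two-sided on |ES| with the +1 permutation correction;
    NES = ES / mean |null ES|. BH adjustment runs across all scored
    sets. Sets outside [min_size, max_size] after intersection with the
    ranked ids are skipped.
    """
    ranked = ranked.sort_values(ascending=False)
    ids = ranked.index
    n = len(ids)
    w_sorted = np.abs(ranked.to_numpy()) ** weight
    pos_of = {f: i for i, f in enumerate(ids)}
    rng = np.random.default_rng(seed)

    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for name, members in sets.items():
        pos = np.array(sorted(pos_of[f] for f in members if f in pos_of))
        m = len(pos)
        if not min_size <= m <= max_size or m == n:
            continue
        es = _es_from_positions(pos, w_sorted, n)
        if m not in null_cache:
            null = np.empty(n_perm)
            for i in range(n_perm):
                rpos = np.sort(rng.choice(n, size=m, replace=False))
                null[i] = _es_from_positions(rpos, w_sorted, n)
            null_cache[m] = null
        null = null_cache[m]
        p = (1 + (np.abs(null) >= abs(es)).sum()) / (n_perm + 1)
        nes = es / max(np.abs(null).mean(), 1e-12)
        rows.append(
            {"term": name, "es": es, "nes": nes, "size": m, "p": float(p)}
        )
    out = pd.DataFrame(rows, columns=["term", "es", "nes", "size", "p"])
    if not out.empty:
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["fdr"] = []
    return out


def ksea(
    scores: pd.Series, kinase_substrates: dict[str, list]
) -> pd.DataFrame:
    """Kinase-substrate enrichment z-scores.

    For each kinase with m quantified substrate sites,
    z = (mean substrate score - mean all-site score) * sqrt(m) / sd(all
    site scores); two-sided normal p; BH across kinases. Kinases with no
    quantified substrate are omitted; a zero background SD yields NaN.
    """
    scores = scores.dropna()
    m_p = scores.mean()
    delta = scores.std(ddof=1)
    rows = []
    for kin, subs in kinase_substrates.items():
        present = scores.index.intersection(pd.Index(subs))
        m = len(present)
        if m == 0:
            continue
        m_s = scores[present].mean()
        if delta == 0 or np.isnan(delta):
            z, p = np.nan, np.nan
        else:
            z = (m_s - m_p) * np.sqrt(m) / delta
            p = 2 * stats.norm.sf(abs(z))
        rows.append(
            {"kinase": kin, "z": z, "m": m, "mean_substrate": m_s, "p": p}
        )
    out = pd.DataFrame(rows, columns=["kinase", "z", "m", "mean_substrate", "p"])
    if not out.empty and out["p"].notna().any():
        ok = out["p"].notna()
        out["fdr"] = np.nan
        out.loc[ok, "fdr"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    else:
        out["fdr"] = np.nan
    return out
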