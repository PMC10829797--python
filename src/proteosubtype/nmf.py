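"""Multiomic subtype discovery by signed-split consensus NMF.

Per-feature z-scored modalities are stacked and split by sign into a
nonnegative matrix (twice as many rows), factorized X ~ WH by
multiplicative-update NMF under the generalized Kullback-Leibler
divergence, restarted from random initializations to build a consensus
co-clustering matrix A per rank k, and the rank is selected by the
cophenetic correlation of A's average-linkage dendrogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform

from .types import ConsensusResult, NMFFactorization, OmicsMatrix, SignedSplitMatrix

_EPS = 1e-12


def standardize_and_split(matrices: list[OmicsMatrix]) -> SignedSplitMatrix:
    """Z-score each feature, then split into positive/negative parts.

    Every feature row is standardized to mean 0, sd 1 (zero-variance
    features are dropped with a warning), then replaced by two
    nonnegative rows: max(x, 0) and max(-x, 0). Modalities are stacked
    row-wise; all matrices must be imputed (no NA) and share the sample
    set of the first matrix.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    samples = matrices[0].samples
    blocks, meta = [], []
    for m in matrices:
        if m.values.isna().any().any():
            raise ValueError(f"{m.modality or 'matrix'} contains NA; impute first")
        if set(m.samples) != set(samples):
            raise ValueError("matrices must share the same sample set")
        x = m.values[samples].to_numpy(dtype=float)
        sd = x.std(axis=1, ddof=1)
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"dropping {(~keep).sum()} zero-variance features "
                f"from {m.modality or 'matrix'}",
                stacklevel=2,
            )
        x = x[keep]
        z = (x - x.mean(axis=1, keepdims=True)) / sd[keep][:, None]
        blocks += [np.maximum(z, 0.0), np.maximum(-z, 0.0)]
        feats = m.features[keep]
        meta.append(
            pd.DataFrame(
                {"feature": feats, "sign": 1, "modality": m.modality or ""}
            )
        )
        meta.append(
            pd.DataFrame(
                {"feature": feats, "sign": -1, "modality": m.modality or ""}
            )
        )
    # interleave per modality: positive block then negative block
    X = np.vstack(blocks)
    row_meta = pd.concat(meta, ignore_index=True)
    return SignedSplitMatrix(X=X, row_meta=row_meta, samples=samples)


def kl_divergence(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Generalized KL divergence D(X || WH) = sum x log(x/y) - x + y."""
    Y = W @ H + _EPS
    pos = X > 0
    d = float(Y.sum() - X.sum())
    d += float((X[pos] * np.log(X[pos] / Y[pos])).sum())
    return d


def nmf_factorize(
    X: SignedSplitMatrix | np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> NMFFactorization:
    """Multiplicative-update NMF under generalized KL divergence.

    W and H are initialized uniform-random scaled by sqrt(mean(X)/k) and
    updated with the classic Lee-Seung/Brunet rules, which guarantee a
    non-increasing objective. Stops when the relative objective change
    drops below ``tol`` or after ``max_iter`` sweeps. Deterministic
    given ``seed``.
    """
    A = X.X if isinstance(X, SignedSplitMatrix) else np.asarray(X, dtype=float)
    if (A < 0).any():
        raise ValueError("NMF input must be nonnegative")
    n, m = A.shape
    if not 0 < k < min(n, m):
        raise ValueError(f"k must satisfy 0 < k < min(dim) = {min(n, m)}")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(A.mean(), _EPS) / k)
    W = rng.uniform(_EPS, 1.0, size=(n, k)) * scale
    H = rng.uniform(_EPS, 1.0, size=(k, m)) * scale

    objective = [kl_divergence(A, W, H)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        R = A / (W @ H + _EPS)
        W *= (R @ H.T) / (H.sum(axis=1)[None, :] + _EPS)
        R = A / (W @ H + _EPS)
        H *= (W.T @ R) / (W.sum(axis=0)[:, None] + _EPS)
        obj = kl_divergence(A, W, H)
        objective.append(obj)
        prev = objective[-2]
        if abs(prev - obj) <= tol * max(abs(prev), _EPS):
            converged = True
            break
    return NMFFactorization(
        W=W, H=H, objective=objective, n_iter=it, seed=seed, converged=converged
    )


def assign_clusters(f: NMFFactorization) -> np.ndarray:
    """Label each sample by the H row with the maximal membership.

    Ties resolve to the lowest row index; labels are 1..k. A sample whose
    H column is entirely zero cannot be assigned.
    """
    H = f.H
    if (H.max(axis=0) <= 0).any():
        bad = int(np.flatnonzero(H.max(axis=0) <= 0)[0])
        raise ValueError(f"sample column {bad} has an all-zero H column")
    return H.argmax(axis=0) + 1


def consensus_cluster(
    X: SignedSplitMatrix,
    k: int,
    n_runs: int = 50,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> ConsensusResult:
    """Average co-clustering over NMF restarts; labels from cutting A.

    Run seeds are ``seed + run_index``. A[i, j] is the fraction of
    successful runs in which samples i and j share an argmax-H cluster.
    Final labels come from average-linkage hierarchical clustering of
    1 - A cut into k clusters (consistent with the cophenetic statistic).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    n = len(X.samples)
    C = np.zeros((n, n))
    ok_runs = 0
    for r in range(n_runs):
        try:
            f = nmf_factorize(X, k, seed=seed + r, max_iter=max_iter, tol=tol)
            labels = assign_clusters(f)
        except ValueError as e:  # pragma: no cover - degenerate run
            warnings.warn(f"NMF run {r} failed ({e}); excluded", stacklevel=2)
            continue
        C += labels[:, None] == labels[None, :]
        ok_runs += 1
    if ok_runs == 0:
        raise RuntimeError("all NMF runs failed")
    A = C / ok_runs
    np.fill_diagonal(A, 1.0)
    A_df = pd.DataFrame(A, index=X.samples, columns=X.samples)

    dist = squareform(1.0 - A, checks=False)
    Z = linkage(dist, method="average")
    labels = pd.Series(
        fcluster(Z, t=k, criterion="maxclust"), index=X.samples, name="subtype"
    )
    coph = _cophenetic_from_linkage(Z, dist)
    return ConsensusResult(
        k=k, A=A_df, cophenetic_corr=coph, labels=labels, n_runs=ok_runs
    )


def _cophenetic_from_linkage(Z: np.ndarray, dist: np.ndarray) -> float:
    if np.allclose(dist, dist[0] if dist.size else 0.0):
        return float("nan")
    corr, _ = cophenet(Z, dist)
    return float(corr)


def cophenetic_correlation(c: ConsensusResult) -> float:
    """Cophenetic correlation of the consensus dissimilarity 1 - A.

    Pearson correlation between the off-diagonal distances 1 - A and the
    cophenetic (ultrametric) distances induced by average-linkage
    hierarchical clustering of 1 - A; near 1 means the dendrogram splits
    cleanly into the consensus blocks. NaN for a constant A.
    """
    dist = squareform(1.0 - c.A.to_numpy(), checks=False)
    if dist.size == 0:
        return float("nan")
    Z = linkage(dist, method="average")
    return _cophenetic_from_linkage(Z, dist)


@dataclass
class KSelection:
    """Model-order scan: cophenetic correlation across candidate ranks."""

    k_best: int
    curve: pd.Series  # index k, value cophenetic correlation
    results: dict[int, ConsensusResult]


def select_k(
    X: SignedSplitMatrix,
    k_range=range(2, 9),
    n_runs: int = 50,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> KSelection:
    """Pick the rank maximizing the cophenetic correlation.

    Each candidate k gets its own consensus run (seeds offset by
    1000 * k so ranks do not share NMF initializations). Ties break to
    the smaller k.
    """
    results: dict[int, ConsensusResult] = {}
    vals = {}
    for k in k_range:
        res = consensus_cluster(
            X, k, n_runs=n_runs, seed=seed + 1000 * k, max_iter=max_iter, tol=tol
        )
        results[k] = res
        vals[k] = res.cophenetic_corr
    curve = pd.Series(vals, name="cophenetic_corr").sort_index()
    finite = curve.dropna()
    if finite.empty:
        raise RuntimeError("cophenetic correlation undefined for every k")
    k_best = int(finite.index[np.argmax(finite.to_numpy())])
    # argmax returns the first max -> smaller k on ties (index sorted)
    return KSelection(k_best=k_best, curve=curve, results=results)
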