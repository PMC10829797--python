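"""Core data carriers shared across the pipeline.

Conventions
-----------
- Abundance matrices are features x samples DataFrames of log2 relative
  abundance; ``NaN`` marks a missing measurement.
- Sample annotations are plain DataFrames indexed by sample id with, at
  minimum, columns ``plex`` (categorical batch) and ``loading_mass``
  (continuous, micrograms); mutation flags are 0/1 columns, survival is
  ``survival_time`` (days) + ``survival_event`` (1 = death observed).
- Drug response tables are samples x drugs DataFrames of dose-response
  AUC values in [1, 300] (lower = more sensitive); ``NaN`` = not assayed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AUC_MIN = 1.0
AUC_MAX = 300.0


@dataclass
class OmicsMatrix:
    """Feature x sample abundance matrix with a modality tag.

    ``values`` holds log2 relative abundances (rows = features, columns =
    samples); missing measurements are ``NaN``.
    """

    values: pd.DataFrame
    modality: str = ""

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        if not self.values.columns.is_unique:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        self.values = self.values.astype(float)

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(self.values.copy(), self.modality)

    def with_values(self, values: pd.DataFrame) -> "OmicsMatrix":
        return OmicsMatrix(values, self.modality)


@dataclass
class ReporterIntensityTable:
    """Raw TMT reporter-ion intensities for one plex.

    ``intensities`` is features x channels (nonnegative);
    ``reference_channel`` names the pooled-reference column used as the
    denominator of relative abundance.
    """

    intensities: pd.DataFrame
    reference_channel: str
    plex: str = ""

    def __post_init__(self) -> None:
        if self.reference_channel not in self.intensities.columns:
            raise ValueError(
                f"reference channel {self.reference_channel!r} not in table"
            )
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("reporter intensities must be nonnegative")


@dataclass
class SignedSplitMatrix:
    """Nonnegative matrix produced by splitting z-scored features by sign.

    Each original feature contributes a positive-part row and a
    negative-part row; ``row_meta`` records (feature, sign, modality) per
    row of ``X``.
    """

    X: np.ndarray
    row_meta: pd.DataFrame  # columns: feature, sign (+1/-1), modality
    samples: pd.Index

    def __post_init__(self) -> None:
        if (self.X < 0).any():
            raise ValueError("signed-split matrix must be nonnegative")
        if self.X.shape[0] != len(self.row_meta):
            raise ValueError("row_meta does not match X rows")
        if self.X.shape[1] != len(self.samples):
            raise ValueError("samples do not match X columns")


@dataclass
class NMFFactorization:
    """One NMF run X ~ WH with its optimization trace."""

    W: np.ndarray
    H: np.ndarray
    objective: list[float] = field(default_factory=list)
    n_iter: int = 0
    seed: int | None = None
    converged: bool = True

    @property
    def k(self) -> int:
        return self.W.shape[1]


@dataclass
class ConsensusResult:
    """Consensus clustering of samples at a fixed rank k.

    ``A`` is the samples x samples average co-clustering (adjacency)
    matrix over NMF restarts; ``labels`` are 1..k from an average-linkage
    cut of 1 - A.
    """

    k: int
    A: pd.DataFrame
    cophenetic_corr: float
    labels: pd.Series
    n_runs: int

    def __post_init__(self) -> None:
        a = self.A.to_numpy()
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValueError("consensus matrix must be symmetric")
        if a.size and (a.min() < -1e-12 or a.max() > 1 + 1e-12):
            raise ValueError("consensus entries must lie in [0, 1]")


def validate_drug_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a samples x drugs AUC table against the [1, 300] contract."""
    vals = table.to_numpy(dtype=float)
    obs = vals[~np.isnan(vals)]
    if obs.size and (obs.min() < AUC_MIN - 1e-9 or obs.max() > AUC_MAX + 1e-9):
        raise ValueError("AUC values must lie in [1, 300]")
    return table
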