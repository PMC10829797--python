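"""Synthetic multiomic AML-like cohorts with known ground truth.

The generator plants ``k_true`` molecular subtypes shared across three
modalities (mRNA, global proteome, phosphoproteome) and layers on the
technical structure the downstream pipeline must undo:

- per-(feature, plex) additive batch offsets,
- a continuous per-feature loading-mass slope,
- missingness that is partly random and partly intensity-dependent
  (low-abundance measurements drop out more often),
- subtype-enriched binary mutations,
- sparse per-drug AUC responses shifted by subtype and/or mutation,
- subtype-dependent exponential survival with independent censoring.

Everything is deterministic given ``SyntheticConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .types import AUC_MAX, AUC_MIN, OmicsMatrix

MODALITIES = ("mrna", "protein", "phospho")
_FEATURE_PREFIX = {"mrna": "MRNA", "protein": "PROT", "phospho": "PHOS"}

#: Loading mass is drawn uniformly on this range (micrograms).
LOADING_MASS_RANGE = (30.0, 70.0)


@dataclass
class DrugSpec:
    """Generative recipe for one drug's AUC column.

    ``subtype_shift`` maps subtype (1..k) to an additive AUC shift;
    ``mutation_shift`` maps mutation gene name to a shift applied to
    carriers. Resulting AUCs are clamped to [1, 300].
    """

    name: str
    baseline: float = 150.0
    subtype_shift: dict[int, float] = field(default_factory=dict)
    mutation_shift: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 25.0
    fraction_assayed: float = 0.85


def default_drug_specs() -> list[DrugSpec]:
    """Drug panel emulating the cohort's headline response patterns.

    A BCL2-inhibitor-like drug is sensitive in subtype 2, an
    HDAC-inhibitor-like drug in subtype 3, a multikinase inhibitor is
    shifted both by subtype 2 and by FLT3-ITD, one drug responds to
    FLT3-ITD only, and the remainder carry no planted signal.
    """
    specs = [
        DrugSpec("venetoclax_like", 190.0, {2: -80.0}, {}, 25.0, 0.85),
        DrugSpec("panobinostat_like", 200.0, {3: -90.0}, {}, 25.0, 0.85),
        DrugSpec(
            "sorafenib_like", 180.0, {2: -50.0}, {"FLT3_ITD": -40.0}, 25.0, 0.85
        ),
        DrugSpec("quizartinib_like", 170.0, {}, {"FLT3_ITD": -70.0}, 25.0, 0.85),
    ]
    specs += [
        DrugSpec(f"inert_{i}", 150.0, {}, {}, 30.0, 0.8) for i in range(1, 5)
    ]
    return specs


def default_mutation_rates() -> dict[str, list[float]]:
    """Per-subtype Bernoulli mutation rates (index = subtype - 1)."""
    return {
        "FLT3_ITD": [0.15, 0.60, 0.25, 0.15],
        "NPM1": [0.10, 0.15, 0.10, 0.50],
        "NRAS": [0.10, 0.10, 0.15, 0.30],
        "TP53": [0.10, 0.08, 0.10, 0.08],
    }


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the reference cohort geometry: 160 samples with all
    three modalities, four planted subtypes, unit subtype effect against
    unit residual noise, 8 TMT plexes with 0.3-unit batch offsets, and a
    loading-mass slope drawn N(0, 0.6) per feature over a 30-70 ug mass
    range so that nearly all features carry a detectable mass effect
    before correction.
    """

    n_samples: int = 160
    k_true: int = 4
    n_features: dict[str, int] = field(
        default_factory=lambda: {"mrna": 100, "protein": 100, "phospho": 100}
    )
    subtype_effect_sd: float = 1.0
    noise_sd: float = 1.0
    n_plexes: int = 8
    plex_offset_sd: float = 0.3
    loading_mass_slope_sd: float = 0.6
    missing_rate: float = 0.05
    mnar_strength: float = 0.15
    mutation_rates: dict[str, list[float]] = field(
        default_factory=default_mutation_rates
    )
    drug_specs: list[DrugSpec] = field(default_factory=default_drug_specs)
    #: per-subtype multiplicative hazards (index = subtype - 1); baseline
    #: exponential with 500-day median, censoring U(0, 1500) days.
    survival_hazards: list[float] = field(
        default_factory=lambda: [1.0, 1.8, 1.3, 0.4]
    )
    seed: int = 0

    def validate(self) -> None:
        if self.k_true < 2:
            raise ValueError("k_true must be >= 2")
        if self.n_samples < self.k_true:
            raise ValueError("need at least one sample per subtype")
        if self.n_plexes < 1:
            raise ValueError("n_plexes must be >= 1")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.mnar_strength < 0:
            raise ValueError("mnar_strength must be nonnegative")
        for mod, n in self.n_features.items():
            if mod not in MODALITIES:
                raise ValueError(f"unknown modality {mod!r}")
            if n < 1:
                raise ValueError(f"n_features[{mod!r}] must be positive")
        for gene, rates in self.mutation_rates.items():
            if len(rates) != self.k_true:
                raise ValueError(f"mutation_rates[{gene!r}] needs k_true entries")
            if any(not 0.0 <= r <= 1.0 for r in rates):
                raise ValueError(f"mutation_rates[{gene!r}] outside [0, 1]")
        if len(self.survival_hazards) != self.k_true:
            raise ValueError("survival_hazards needs one entry per subtype")
        for spec in self.drug_specs:
            if not 0.0 < spec.fraction_assayed <= 1.0:
                raise ValueError(f"{spec.name}: fraction_assayed in (0, 1]")
            if spec.noise_sd < 0:
                raise ValueError(f"{spec.name}: noise_sd must be nonnegative")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its planted ground truth."""

    omics: dict[str, OmicsMatrix]
    annotation: pd.DataFrame
    drugs: pd.DataFrame  # samples x drugs, NaN = not assayed
    truth_labels: pd.Series  # planted subtype 1..k per sample
    truth_effects: dict[str, pd.DataFrame]  # modality -> features x subtypes
    config: SyntheticConfig

    @property
    def samples(self) -> pd.Index:
        return self.annotation.index


def _sample_ids(n: int) -> pd.Index:
    return pd.Index([f"S{i + 1:04d}" for i in range(n)], name="sample")


def _feature_ids(modality: str, n: int) -> pd.Index:
    pref = _FEATURE_PREFIX[modality]
    return pd.Index([f"{pref}_{i + 1:05d}" for i in range(n)], name="feature")


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort under ``config``.

    Each modality is built as subtype mean + plex offset + slope x
    (loading mass - mean mass) + N(0, noise_sd), then thinned by an
    MCAR + intensity-dependent (MNAR) missingness mechanism.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, k = config.n_samples, config.k_true
    samples = _sample_ids(n)

    # balanced subtypes, shuffled
    labels = np.tile(np.arange(1, k + 1), n // k + 1)[:n]
    rng.shuffle(labels)
    truth_labels = pd.Series(labels, index=samples, name="subtype")

    # round-robin plex assignment; uniform loading mass
    plex = np.array([f"plex{(i % config.n_plexes) + 1:02d}" for i in range(n)])
    mass = rng.uniform(*LOADING_MASS_RANGE, size=n)

    omics: dict[str, OmicsMatrix] = {}
    truth_effects: dict[str, pd.DataFrame] = {}
    for mod in MODALITIES:
        f = config.n_features[mod]
        features = _feature_ids(mod, f)
        mu = rng.normal(0.0, config.subtype_effect_sd, size=(f, k))
        plex_levels = sorted(set(plex))
        offsets = rng.normal(
            0.0, config.plex_offset_sd, size=(f, len(plex_levels))
        )
        plex_idx = np.array([plex_levels.index(p) for p in plex])
        slope = rng.normal(0.0, config.loading_mass_slope_sd, size=f)

        x = (
            mu[:, labels - 1]
            + offsets[:, plex_idx]
            + slope[:, None] * (mass - mass.mean())[None, :]
            + rng.normal(0.0, config.noise_sd, size=(f, n))
        )
        x = _apply_missingness(
            x, config.missing_rate, config.mnar_strength, rng
        )
        omics[mod] = OmicsMatrix(
            pd.DataFrame(x, index=features, columns=samples), modality=mod
        )
        truth_effects[mod] = pd.DataFrame(
            mu, index=features, columns=[f"subtype{i + 1}" for i in range(k)]
        )

    annotation = pd.DataFrame(
        {"plex": plex, "loading_mass": mass}, index=samples
    )
    for gene, rates in config.mutation_rates.items():
        p = np.asarray(rates)[labels - 1]
        annotation[gene] = (rng.uniform(size=n) < p).astype(int)

    time, event = _generate_survival(labels, config.survival_hazards, rng)
    annotation["survival_time"] = time
    annotation["survival_event"] = event

    mut = annotation[list(config.mutation_rates)]
    drugs = generate_drug_response(
        truth_labels, mut, config.drug_specs, seed=int(rng.integers(2**31))
    )

    return SyntheticCohort(
        omics=omics,
        annotation=annotation,
        drugs=drugs,
        truth_labels=truth_labels,
        truth_effects=truth_effects,
        config=config,
    )


def _apply_missingness(
    x: np.ndarray, missing_rate: float, mnar_strength: float, rng
) -> np.ndarray:
    """Delete entries MCAR at ``missing_rate`` plus a logistic MNAR term.

    The MNAR probability rises toward ``mnar_strength`` for low-abundance
    entries (standardized within the matrix), emulating intensity-
    dependent dropout of reporter-ion quantification.
    """
    if missing_rate == 0 and mnar_strength == 0:
        return x
    scale = x.std() or 1.0
    z = (x - x.mean()) / scale
    p = missing_rate + mnar_strength * expit(-z - 1.0)
    p = np.clip(p, 0.0, 1.0)
    out = x.copy()
    out[rng.uniform(size=x.shape) < p] = np.nan
    # keep every feature observable at least once
    all_na = np.isnan(out).all(axis=1)
    if all_na.any():
        j = rng.integers(x.shape[1], size=int(all_na.sum()))
        out[np.flatnonzero(all_na), j] = x[np.flatnonzero(all_na), j]
    return out


def _generate_survival(labels, hazards, rng, median_days: float = 500.0):
    lam0 = np.log(2.0) / median_days
    lam = lam0 * np.asarray(hazards)[labels - 1]
    death = rng.exponential(1.0 / lam)
    censor = rng.uniform(0.0, 1500.0, size=len(labels))
    time = np.minimum(death, censor)
    event = (death <= censor).astype(int)
    return time, event


def generate_drug_response(
    truth_labels: pd.Series,
    mutations: pd.DataFrame,
    drug_specs: list[DrugSpec],
    seed: int,
) -> pd.DataFrame:
    """Build a sparse samples x drugs AUC table from generative specs.

    AUC = clamp(baseline + subtype shift + mutation shifts + noise,
    1, 300); each drug is assayed on a random ``fraction_assayed`` subset
    of samples (the remainder are NaN).
    """
    if not drug_specs:
        raise ValueError("drug_specs must be nonempty")
    rng = np.random.default_rng(seed)
    n = len(truth_labels)
    cols = {}
    for spec in drug_specs:
        auc = np.full(n, spec.baseline, dtype=float)
        for subtype, shift in spec.subtype_shift.items():
            auc[truth_labels.to_numpy() == subtype] += shift
        for gene, shift in spec.mutation_shift.items():
            auc[mutations[gene].to_numpy() == 1] += shift
        auc += rng.normal(0.0, spec.noise_sd, size=n)
        auc = np.clip(auc, AUC_MIN, AUC_MAX)
        assayed = rng.uniform(size=n) < spec.fraction_assayed
        auc[~assayed] = np.nan
        cols[spec.name] = auc
    return pd.DataFrame(cols, index=truth_labels.index)


def generate_pathway_resources(
    feature_ids,
    n_sets: int = 20,
    set_size: tuple[int, int] = (5, 30),
    n_kinases: int = 10,
    substrates_per_kinase: tuple[int, int] = (5, 20),
    seed: int = 0,
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Random gene sets and a kinase->substrate map over given features.

    Sets may overlap; every kinase maps to at least one substrate site.
    Deterministic given ``seed``.
    """
    ids = list(feature_ids)
    lo, hi = set_size
    if hi > len(ids):
        raise ValueError("requested set size exceeds feature count")
    rng = np.random.default_rng(seed)
    sets = {}
    for i in range(n_sets):
        m = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(ids), size=m, replace=False)
        sets[f"SET_{i + 1:03d}"] = [ids[j] for j in sorted(members)]
    klo, khi = substrates_per_kinase
    if khi > len(ids):
        raise ValueError("requested substrate count exceeds feature count")
    kinases = {}
    for i in range(n_kinases):
        m = int(rng.integers(max(1, klo), khi + 1))
        members = rng.choice(len(ids), size=m, replace=False)
        kinases[f"KIN_{i + 1:03d}"] = [ids[j] for j in sorted(members)]
    return sets, kinases


@dataclass
class ResistanceTrajectory:
    """Cell-line-like samples interpolating between two subtype profiles."""

    omics: dict[str, OmicsMatrix]
    stages: pd.Series  # stage index 0..n_stages-1 per sample


def generate_resistance_trajectory(
    cohort: SyntheticCohort,
    from_subtype: int,
    to_subtype: int,
    n_stages: int = 4,
    n_reps: int = 4,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> ResistanceTrajectory:
    """Emulate a drug-resistance time course drifting between subtypes.

    Stage s of ``n_stages`` has mean profile
    (1 - t) * mu_from + t * mu_to with t = s / (n_stages - 1), plus low
    within-stage noise (cell lines are homogeneous relative to patients).
    No batch or loading-mass structure is added.
    """
    k = cohort.config.k_true
    if not (1 <= from_subtype <= k and 1 <= to_subtype <= k):
        raise ValueError("subtypes must lie in 1..k_true")
    if n_stages < 2:
        raise ValueError("n_stages must be >= 2")
    rng = np.random.default_rng(seed)
    n_cols = n_stages * n_reps
    cols = pd.Index(
        [f"CL_stage{s}_rep{r + 1}" for s in range(n_stages) for r in range(n_reps)],
        name="sample",
    )
    stages = pd.Series(
        np.repeat(np.arange(n_stages), n_reps), index=cols, name="stage"
    )
    t = stages.to_numpy() / (n_stages - 1)
    omics = {}
    for mod, eff in cohort.truth_effects.items():
        mu_from = eff.iloc[:, from_subtype - 1].to_numpy()
        mu_to = eff.iloc[:, to_subtype - 1].to_numpy()
        x = (
            np.outer(mu_from, 1 - t)
            + np.outer(mu_to, t)
            + rng.normal(0.0, noise_sd, size=(len(eff), n_cols))
        )
        omics[mod] = OmicsMatrix(
            pd.DataFrame(x, index=eff.index, columns=cols), modality=mod
        )
    return ResistanceTrajectory(omics=omics, stages=stages)
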