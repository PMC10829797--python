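"""End-to-end pipeline driver: simulate -> preprocess -> subtype ->
classify -> enrich -> stratify -> model-drugs, with a reproducibility
manifest (seeds, parameters, output checksums).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classifier, drug_model, drugs, enrichment, io, nmf, preprocess
from .synthetic import SyntheticConfig, generate_cohort

log = logging.getLogger("proteosubtype")

_ALL_STAGES = (
    "simulate",
    "preprocess",
    "subtype",
    "classify",
    "enrich",
    "stratify",
    "model_drugs",
)


@dataclass
class PipelineConfig:
    """Configuration for a full run; every stochastic stage has a seed."""

    out_dir: str = "proteosubtype_run"
    stages: list[str] = field(default_factory=lambda: list(_ALL_STAGES))
    seed: int = 0
    # simulate
    simulate: dict = field(default_factory=dict)  # SyntheticConfig overrides
    # subtype
    k_min: int = 2
    k_max: int = 8
    n_runs: int = 30
    nmf_max_iter: int = 300
    # classify
    alpha: float = 0.9
    # enrich
    n_perm: int = 1000
    # stratify
    min_tested: int = 100
    min_sensitive: int = 10
    # model-drugs
    model_kind: str = "en"
    cv_repeats: int = 5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute enabled stages in dependency order; return the manifest.

    A failed stage aborts with a stage-tagged error; outputs already
    written are preserved. Rerunning with the same config reproduces
    byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "stages_run": [],
        "outputs": {},
    }
    state: dict = {}
    for stage in _ALL_STAGES:
        if stage not in config.stages:
            continue
        log.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](config, out, state)
        except Exception as e:
            _write_manifest(out, manifest)
            raise RuntimeError(f"stage {stage!r} failed: {e}") from e
        manifest["stages_run"].append(stage)
    for p in sorted(out.glob("*.tsv")):
        manifest["outputs"][p.name] = _checksum(p)
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _stage_simulate(config: PipelineConfig, out: Path, state: dict) -> None:
    cfg = SyntheticConfig(seed=config.seed, **config.simulate)
    cohort = generate_cohort(cfg)
    state["cohort"] = cohort
    for mod, m in cohort.omics.items():
        io.write_matrix(m, out / f"{mod}.tsv")
    io.write_annotation(cohort.annotation, out / "annotation.tsv")
    io.write_drug_table(cohort.drugs, out / "drugs.tsv")
    io.write_labels(cohort.truth_labels, out / "truth_labels.tsv")


def _stage_preprocess(config: PipelineConfig, out: Path, state: dict) -> None:
    cohort = state["cohort"]
    corrected = {}
    for mod, m in cohort.omics.items():
        m = preprocess.filter_missingness(m, 0.5)
        m = preprocess.knn_impute(m, k=10)
        m = preprocess.eb_covariate_correction(
            m, cohort.annotation, ["loading_mass", "plex"]
        )
        corrected[mod] = m
        io.write_matrix(m, out / f"{mod}_corrected.tsv")
    state["corrected"] = corrected


def _stage_subtype(config: PipelineConfig, out: Path, state: dict) -> None:
    corrected = state["corrected"]
    split = nmf.standardize_and_split(list(corrected.values()))
    sel = nmf.select_k(
        split,
        k_range=range(config.k_min, config.k_max + 1),
        n_runs=config.n_runs,
        seed=config.seed,
        max_iter=config.nmf_max_iter,
    )
    state["selection"] = sel
    state["labels"] = sel.results[sel.k_best].labels
    sel.curve.rename_axis("k").to_frame().to_csv(out / "cophenetic_curve.tsv", sep="\t")
    sel.results[sel.k_best].A.to_csv(out / "consensus_matrix.tsv", sep="\t")
    io.write_labels(state["labels"], out / "subtype_labels.tsv")


def _stage_classify(config: PipelineConfig, out: Path, state: dict) -> None:
    corrected = state["corrected"]
    from .types import OmicsMatrix

    prot = pd.concat(
        [corrected["protein"].values, corrected["phospho"].values]
    )
    X = OmicsMatrix(prot, "protein+phospho")
    model = classifier.fit_multinomial_elasticnet(
        X, state["labels"], alpha=config.alpha, seed=config.seed
    )
    state["classifier"] = model
    state["classifier_matrix"] = X
    (out / "classifier_model.json").write_text(json.dumps(model.to_dict()))
    sig = classifier.extract_signature(model)
    sig.assign(classes=sig["classes"].map(lambda c: ";".join(map(str, c)))).to_csv(
        out / "classifier_signature.tsv", sep="\t", index=False
    )


def _stage_enrich(config: PipelineConfig, out: Path, state: dict) -> None:
    from .synthetic import generate_pathway_resources

    corrected = state["corrected"]
    labels = state["labels"]
    def _resources(features):
        hi = max(3, min(30, len(features) // 2))
        lo = min(5, hi)
        return generate_pathway_resources(
            features, set_size=(lo, hi),
            substrates_per_kinase=(lo, hi), seed=config.seed,
        )

    sets, _ = _resources(corrected["protein"].features)
    _, kin = _resources(corrected["phospho"].features)
    gsea_frames, ksea_frames = [], []
    for subtype in sorted(labels.unique()):
        ranked = enrichment.subtype_rank_vector(
            corrected["protein"], labels, subtype
        )
        res = enrichment.gsea_preranked(
            ranked, sets, n_perm=config.n_perm, seed=config.seed
        )
        gsea_frames.append(res.assign(subtype=subtype))
        phos_rank = enrichment.subtype_rank_vector(
            corrected["phospho"], labels, subtype
        )
        ksea_frames.append(enrichment.ksea(phos_rank, kin).assign(subtype=subtype))
    pd.concat(gsea_frames).to_csv(out / "gsea.tsv", sep="\t", index=False)
    pd.concat(ksea_frames).to_csv(out / "ksea.tsv", sep="\t", index=False)


def _stage_stratify(config: PipelineConfig, out: Path, state: dict) -> None:
    cohort = state["cohort"]
    labels = state["labels"]
    table = drugs.filter_drugs(
        cohort.drugs,
        min_tested=config.min_tested,
        min_sensitive=config.min_sensitive,
    )
    groups = drugs.subtype_indicators(labels)
    mut_cols = [c for c in cohort.annotation.columns if cohort.annotation[c].isin([0, 1]).all()]
    groups = pd.concat([groups, cohort.annotation[mut_cols].astype(bool)], axis=1)
    assoc = drugs.welch_association(table, groups)
    assoc.to_csv(out / "drug_associations.tsv", sep="\t", index=False)
    heat = assoc.pivot(index="drug", columns="group", values="t")
    heat.to_csv(out / "drug_association_heat.tsv", sep="\t")
    fisher = drugs.fisher_enrichment(labels, cohort.annotation[mut_cols])
    fisher.to_csv(out / "cluster_enrichment.tsv", sep="\t", index=False)
    surv = drugs.km_logrank(cohort.annotation, labels)
    pd.DataFrame(
        [{"statistic": surv["statistic"], "p": surv["p"], "df": surv["df"]}]
    ).to_csv(out / "survival_logrank.tsv", sep="\t", index=False)
    state["drug_table"] = table


def _stage_model_drugs(config: PipelineConfig, out: Path, state: dict) -> None:
    table = state.get("drug_table", state["cohort"].drugs)
    X = state["classifier_matrix"]
    rows = []
    for drug in table.columns:
        rep = drug_model.repeated_cv_evaluate(
            X,
            table[drug],
            model_kind=config.model_kind,
            repeats=config.cv_repeats,
            seed=config.seed,
        )
        sig = drug_model.final_signature(
            X, table[drug], model_kind=config.model_kind, drug=drug, seed=config.seed
        )
        rows.append(
            {
                "drug": drug,
                "mean_r": rep["r"].mean(),
                "sd_r": rep["r"].std(),
                "n_cv_rows": len(rep),
                "n_signature_features": len(sig),
            }
        )
    pd.DataFrame(rows).to_csv(out / "drug_models.tsv", sep="\t", index=False)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "subtype": _stage_subtype,
    "classify": _stage_classify,
    "enrich": _stage_enrich,
    "stratify": _stage_stratify,
    "model_drugs": _stage_model_drugs,
}
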