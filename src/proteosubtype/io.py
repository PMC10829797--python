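"""TSV input/output shared by all stages.

Dialect: omics matrices are wide TSVs (first column = feature id, header
row = sample ids, ``NA`` or empty = missing); annotations are one row
per sample; drug tables travel in long format (sample, drug, auc) since
they are sparse. Round-trips are identity up to float formatting.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import OmicsMatrix

_NA_VALUES = ["NA", ""]


def read_matrix(path, modality: str = "") -> OmicsMatrix:
    """Read a wide features x samples TSV into an :class:`OmicsMatrix`."""
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=_NA_VALUES, keep_default_na=False
    )
    if not df.index.is_unique:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate feature id {dup!r}")
    if not df.columns.is_unique:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    try:
        df = df.astype(float)
    except ValueError as e:
        raise ValueError(f"{path}: non-numeric matrix entry ({e})") from e
    return OmicsMatrix(df, modality=modality)


def write_matrix(m: OmicsMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", na_rep="NA", float_format="%.12g")


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=_NA_VALUES, keep_default_na=False
    )
    if not df.index.is_unique:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    return df


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", na_rep="NA")


def read_drug_table(path) -> pd.DataFrame:
    """Read a long-format (sample, drug, auc) TSV into a wide table."""
    long = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False)
    required = {"sample", "drug", "auc"}
    if not required <= set(long.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    if long.duplicated(["sample", "drug"]).any():
        bad = long[long.duplicated(["sample", "drug"])].iloc[0]
        raise ValueError(f"{path}: duplicate (sample, drug) = {bad['sample']}, {bad['drug']}")
    wide = long.pivot(index="sample", columns="drug", values="auc")
    wide.columns.name = None
    return wide.astype(float)


def write_drug_table(table: pd.DataFrame, path) -> None:
    long = (
        table.stack(future_stack=True)
        .rename("auc")
        .rename_axis(["sample", "drug"])
        .reset_index()
        .dropna(subset=["auc"])
    )
    long.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_labels(path) -> pd.Series:
    df = read_annotation(path)
    return df.iloc[:, 0]


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("subtype").to_frame().to_csv(path, sep="\t")


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets in GMT format (name, description, members...)."""
    sets = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{i}: GMT line needs >= 3 fields")
        sets[parts[0]] = [p for p in parts[2:] if p]
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    lines = [
        "\t".join([name, "synthetic"] + list(members))
        for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_kinase_map(path) -> dict[str, list[str]]:
    """Two-column TSV (kinase, substrate site) into kinase -> sites."""
    df = pd.read_csv(path, sep="\t")
    kin_col, sub_col = df.columns[:2]
    out: dict[str, list[str]] = {}
    for kin, grp in df.groupby(kin_col):
        out[str(kin)] = list(grp[sub_col].astype(str))
    return out


def write_kinase_map(kin: dict[str, list[str]], path) -> None:
    rows = [(k, s) for k, subs in kin.items() for s in subs]
    pd.DataFrame(rows, columns=["kinase", "substrate"]).to_csv(
        path, sep="\t", index=False
    )
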