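"""Readers and writers for every file format the tool touches.

Formats: delimited sample tables (CSV/TSV, header row, first column = sample
ID), GMT feature-set files, adjustment-map CSVs, split-plan CSVs, and YAML
run configs.  All round-trips are lossless; delimiters are chosen from the
file extension (``.csv`` comma, ``.tsv``/``.txt`` tab).
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .table import (
    TARGET_KEY,
    AdjustedTable,
    AdjustmentMap,
    FeatureSetCollection,
    TableError,
)


def _delimiter(path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return ","
    if suffix in (".tsv", ".txt"):
        return "\t"
    raise TableError(f"cannot infer delimiter from extension {suffix!r}")


# ---------------------------------------------------------------------------
# sample tables


def read_table(path, role_spec: dict[str, tuple[str, str]]) -> AdjustedTable:
    """Read a delimited table and attach the declared roles and kinds.

    ``role_spec`` maps every data column name to a ``(role, kind)`` pair.
    The first file column is the sample ID.  Missing declared columns,
    duplicate sample IDs, and non-numeric values in non-nominal columns are
    rejected with the offending column/row named.
    """
    df = pd.read_csv(path, sep=_delimiter(path), index_col=0)
    missing = [c for c in role_spec if c not in df.columns]
    if missing:
        raise TableError(f"declared columns absent from {path}: {missing}")
    extra = [c for c in df.columns if c not in role_spec]
    if extra:
        raise TableError(f"columns in {path} lack a role declaration: {extra}")
    roles = {c: role_spec[c][0] for c in df.columns}
    kinds = {c: role_spec[c][1] for c in df.columns}
    return AdjustedTable(df, roles, kinds)


def write_table(table: AdjustedTable, path) -> None:
    table.df.to_csv(path, sep=_delimiter(path), index_label="sample_id")


def write_role_spec(table: AdjustedTable, path) -> None:
    """Sidecar role/kind declaration, so a written table can be re-read."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["column", "role", "kind"])
        for col in table.df.columns:
            w.writerow([col, table.roles[col], table.kinds[col]])


def read_role_spec(path) -> dict[str, tuple[str, str]]:
    spec: dict[str, tuple[str, str]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            spec[row["column"]] = (row["role"], row["kind"])
    return spec


# ---------------------------------------------------------------------------
# GMT feature sets


def read_feature_sets(path) -> FeatureSetCollection:
    """Parse a GMT file: one set per line, tab-separated name, description,
    then member feature IDs.  Members absent from any particular table are
    tolerated here; intersection happens at selection time."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise TableError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields; "
                    "need name, description, and at least one member"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise TableError(f"{path}:{lineno}: set {name!r} has no members")
            if name in sets:
                raise TableError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = (description, members)
    return FeatureSetCollection(sets)


def write_feature_sets(collection: FeatureSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            fh.write(
                "\t".join([name, collection.description(name), *collection.members(name)])
                + "\n"
            )


# ---------------------------------------------------------------------------
# adjustment maps


def read_adjustment_map(path, table: AdjustedTable) -> AdjustmentMap:
    """Parse an adjustment-map CSV: each line names an adjusted column then
    its covariate columns.  The reserved row name ``TARGET`` declares target
    adjustment.  An empty file yields an empty map (classic mode)."""
    entries: list[tuple[str, list[str]]] = []
    adjust_target = False
    target_covs: list[str] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            row = [f.strip() for f in row if f.strip()]
            if not row:
                continue
            name, *covs = row
            if name == TARGET_KEY:
                adjust_target = True
                target_covs = covs
            else:
                entries.append((name, covs))
    amap = AdjustmentMap(entries, adjust_target, target_covs)
    amap.validate(table)
    return amap


def write_adjustment_map(amap: AdjustmentMap, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        for name, covs in amap.entries:
            w.writerow([name, *covs])
        if amap.adjust_target:
            w.writerow([TARGET_KEY, *amap.target_covariates])


# ---------------------------------------------------------------------------
# split plans


def write_split_plan(plan, path) -> None:
    """Serialize a SplitPlan so independent runs can share identical splits.

    Long format: one row per (split, row) pair with a train/test flag.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["split", "row", "is_train"])
        for i, (train, test) in enumerate(plan.splits):
            for r in train:
                w.writerow([i, r, 1])
            for r in test:
                w.writerow([i, r, 0])
        w.writerow(["#meta", plan.scheme, plan.seed])
        w.writerow(["#meta_frac", plan.train_fraction, ""])


def read_split_plan(path):
    from .preprocess import SplitPlan  # avoid circular import at module load

    rows_by_split: dict[int, tuple[list[int], list[int]]] = {}
    scheme, seed, train_fraction = "shuffle", 0, 0.75
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        next(reader)  # header
        for row in reader:
            if row[0] == "#meta":
                scheme, seed = row[1], int(row[2])
            elif row[0] == "#meta_frac":
                train_fraction = float(row[1])
            else:
                i, r, flag = int(row[0]), int(row[1]), int(row[2])
                train, test = rows_by_split.setdefault(i, ([], []))
                (train if flag == 1 else test).append(r)
    splits = [
        (np.asarray(train, dtype=int), np.asarray(test, dtype=int))
        for _, (train, test) in sorted(rows_by_split.items())
    ]
    return SplitPlan(splits=splits, train_fraction=train_fraction, scheme=scheme, seed=seed)


# ---------------------------------------------------------------------------
# run configuration


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
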