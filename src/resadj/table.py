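"""Tabular data model: samples-by-columns tables with per-column roles and kinds.

The central container is :class:`AdjustedTable`, a thin wrapper around a
:class:`pandas.DataFrame` that records, for every column, a *role* (what the
column is for: feature, covariate, split indicator, per-split residual target,
or target) and a *kind* (its statistical type: continuous, binary, ordinal, or
nominal).  Roles and kinds drive every downstream decision — which estimator
residualizes a column, which columns an estimator may see, and which column
holds the correct adjusted target for a given cross-validation split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROLES = ("feature", "covariate", "indicator", "residual_target", "target")
KINDS = ("continuous", "binary", "ordinal", "nominal")

#: reserved column-name prefixes appended by the target pre-processor
INDICATOR_FMT = "__split{i}_indicator"
RESIDUAL_FMT = "__split{i}_residual"
FULL_RESIDUAL = "__full_residual"

#: reserved name for the target row in adjustment-map files
TARGET_KEY = "TARGET"


class TableError(ValueError):
    """Raised when a table, role spec, or referenced column is invalid."""


@dataclass
class AdjustedTable:
    """A samples-by-variables table with column roles and kinds.

    Parameters
    ----------
    df : DataFrame indexed by unique sample IDs; all non-nominal columns numeric.
    roles : mapping column name -> role (one of ``ROLES``).
    kinds : mapping column name -> kind (one of ``KINDS``).
    """

    df: pd.DataFrame
    roles: dict[str, str]
    kinds: dict[str, str]

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.df.index.has_duplicates:
            dups = self.df.index[self.df.index.duplicated()].tolist()
            raise TableError(f"duplicate sample IDs: {dups[:5]}")
        for col in self.df.columns:
            if col not in self.roles:
                raise TableError(f"column {col!r} has no declared role")
            if col not in self.kinds:
                raise TableError(f"column {col!r} has no declared kind")
        for col, role in self.roles.items():
            if col not in self.df.columns:
                raise TableError(f"declared column {col!r} absent from table")
            if role not in ROLES:
                raise TableError(f"column {col!r}: unknown role {role!r}")
            kind = self.kinds[col]
            if kind not in KINDS:
                raise TableError(f"column {col!r}: unknown kind {kind!r}")
            if kind != "nominal":
                vals = self.df[col]
                if not pd.api.types.is_numeric_dtype(vals):
                    bad = vals.index[pd.to_numeric(vals, errors="coerce").isna()]
                    raise TableError(
                        f"non-numeric values in {kind} column {col!r} "
                        f"(rows {list(bad[:5])})"
                    )
                # residual_target columns are legitimately unpopulated on
                # rows outside their split (indicator -1)
                if role != "residual_target" and vals.isna().any():
                    bad = vals.index[vals.isna()].tolist()
                    raise TableError(
                        f"missing values in column {col!r} (rows {bad[:5]})"
                    )
        n_target = sum(r == "target" for r in self.roles.values())
        n_resid = sum(r == "residual_target" for r in self.roles.values())
        if n_target > 1:
            raise TableError(f"{n_target} target columns declared; at most one allowed")
        if n_target == 0 and n_resid == 0 and any(
            r == "feature" for r in self.roles.values()
        ):
            # a pure-feature table (e.g. after resAdjTransformer) is legal;
            # only a table that claims to carry an outcome must have one
            pass

    # -- accessors ----------------------------------------------------------

    @property
    def sample_ids(self) -> list:
        return self.df.index.tolist()

    @property
    def m(self) -> int:
        """Sample count."""
        return len(self.df)

    @property
    def n(self) -> int:
        """Feature count."""
        return len(self.columns_with_role("feature"))

    def role_of(self, col: str) -> str:
        return self.roles[col]

    def kind_of(self, col: str) -> str:
        return self.kinds[col]

    def columns_with_role(self, *roles: str) -> list[str]:
        return [c for c in self.df.columns if self.roles[c] in roles]

    @property
    def feature_names(self) -> list[str]:
        return self.columns_with_role("feature")

    @property
    def covariate_names(self) -> list[str]:
        return self.columns_with_role("covariate")

    @property
    def target_name(self) -> str | None:
        cols = self.columns_with_role("target")
        return cols[0] if cols else None

    def values(self, col: str) -> np.ndarray:
        return self.df[col].to_numpy()

    # -- construction helpers ------------------------------------------------

    def copy(self) -> "AdjustedTable":
        return AdjustedTable(self.df.copy(), dict(self.roles), dict(self.kinds))

    def with_column(
        self, name: str, values, role: str, kind: str
    ) -> "AdjustedTable":
        """Return a copy with one column appended (or replaced)."""
        df = self.df.copy()
        df[name] = np.asarray(values)
        roles = {**self.roles, name: role}
        kinds = {**self.kinds, name: kind}
        return AdjustedTable(df, roles, kinds)

    def drop_columns(self, names) -> "AdjustedTable":
        names = list(names)
        df = self.df.drop(columns=names)
        roles = {c: r for c, r in self.roles.items() if c not in names}
        kinds = {c: k for c, k in self.kinds.items() if c not in names}
        return AdjustedTable(df, roles, kinds)

    def subset_rows(self, rows) -> "AdjustedTable":
        """Positional row subset, preserving order of ``rows``."""
        return AdjustedTable(
            self.df.iloc[np.asarray(rows, dtype=int)], dict(self.roles), dict(self.kinds)
        )


@dataclass
class AdjustmentMap:
    """Which variables are residualized on which covariate columns.

    ``entries`` pairs an adjusted column name with its covariate list;
    ``adjust_target``/``target_covariates`` describe the target separately
    because the target's residuals follow a different (per-split, appended
    column) path than in-pipeline feature residuals.
    """

    entries: list[tuple[str, list[str]]] = field(default_factory=list)
    adjust_target: bool = False
    target_covariates: list[str] = field(default_factory=list)

    def validate(self, table: AdjustedTable) -> None:
        for name, covs in self.entries:
            if name not in table.df.columns:
                raise TableError(f"adjustment map references unknown column {name!r}")
            if not covs:
                raise TableError(f"adjusted column {name!r} lists no covariates")
            for c in covs:
                if c not in table.df.columns:
                    raise TableError(
                        f"adjustment map references unknown covariate {c!r}"
                    )
                if c == name:
                    raise TableError(f"column {name!r} cannot adjust itself")
                if table.role_of(c) != "covariate":
                    raise TableError(
                        f"column {c!r} used as covariate but has role "
                        f"{table.role_of(c)!r}"
                    )
        if self.adjust_target:
            if not self.target_covariates:
                raise TableError("adjust_target set but no target covariates listed")
            for c in self.target_covariates:
                if c not in table.df.columns:
                    raise TableError(
                        f"adjustment map references unknown covariate {c!r}"
                    )
                if table.role_of(c) != "covariate":
                    raise TableError(
                        f"target covariate {c!r} has role {table.role_of(c)!r}"
                    )

    @property
    def adjusted_feature_names(self) -> list[str]:
        return [name for name, _ in self.entries]

    def covariates_for(self, name: str) -> list[str]:
        for entry_name, covs in self.entries:
            if entry_name == name:
                return covs
        raise KeyError(name)

    def is_empty(self) -> bool:
        return not self.entries and not self.adjust_target


@dataclass
class FeatureSetCollection:
    """Named sets of feature IDs (pathway-style groupings, GMT semantics)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise TableError(f"feature set {name!r} is empty")

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> list[str]:
        return list(self.sets[name][1])

    def description(self, name: str) -> str:
        return self.sets[name][0]
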