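"""Binary encodings for nominal variables.

Nominal covariates cannot enter a regression directly; they are replaced by
numeric binary columns first.  Two schemes are provided:

* ``one_hot_drop_first`` — the classic dummy coding: N categories become
  N - 1 indicator columns, the reference (first) category mapping to all
  zeros.  Suitable for small N.
* ``base2_binary`` — categories are assigned ordinal codes 1..N and each
  code is written in base 2 across ceil(log2(N + 1)) bit columns, most
  significant bit first.  Far more compact for high-cardinality variables
  (41 categories fit in 6 columns).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


class EncodingError(ValueError):
    pass


@dataclass
class EncodingSpec:
    column: str
    method: str  # "one_hot_drop_first" | "base2_binary"
    category_order: list | None = None

    def __post_init__(self) -> None:
        if self.method not in ("one_hot_drop_first", "base2_binary"):
            raise EncodingError(f"unknown encoding method {self.method!r}")


def _categories(values, spec: EncodingSpec) -> list:
    """Category list in reproducible order.

    An explicit ``category_order`` is used in full — declared-but-unobserved
    categories keep their position and code, so encodings agree across data
    subsets.  Without one, categories are taken in first-appearance order.
    """
    seen = list(pd.unique(np.asarray(values)))
    if spec.category_order is not None:
        order = list(spec.category_order)
        missing = [c for c in seen if c not in order]
        if missing:
            raise EncodingError(
                f"column {spec.column!r}: observed categories {missing} "
                "absent from the declared category_order"
            )
        return order
    return seen


def one_hot_encode(values, spec: EncodingSpec) -> pd.DataFrame:
    """Dummy-code a nominal vector into N - 1 binary columns.

    The first category in order is the dropped reference; each row has at
    most one 1 across the emitted columns.
    """
    values = np.asarray(values)
    cats = _categories(values, spec)
    if len(cats) < 2:
        raise EncodingError(
            f"column {spec.column!r}: {len(cats)} distinct category(ies); "
            "a constant column cannot be encoded"
        )
    out = {}
    for cat in cats[1:]:
        out[f"{spec.column}__oh_{cat}"] = (values == cat).astype(int)
    return pd.DataFrame(out)


def binary_encode(values, spec: EncodingSpec) -> pd.DataFrame:
    """Base-2 encode a nominal vector.

    Categories get ordinal codes 1..N; each code is written in binary over
    b = ceil(log2(N + 1)) columns, most significant bit first, named
    ``{column}__bit{k}`` with k = 0 the most significant.
    """
    values = np.asarray(values)
    cats = _categories(values, spec)
    n = len(cats)
    if n < 2:
        raise EncodingError(
            f"column {spec.column!r}: {n} distinct category(ies); "
            "a constant column cannot be encoded"
        )
    n_bits = math.ceil(math.log2(n + 1))
    code_of = {cat: i + 1 for i, cat in enumerate(cats)}
    codes = np.array([code_of[v] for v in values])
    out = {}
    for k in range(n_bits):
        shift = n_bits - 1 - k  # bit 0 is the most significant
        out[f"{spec.column}__bit{k}"] = (codes >> shift) & 1
    return pd.DataFrame(out)


def decode_binary(bits: pd.DataFrame) -> np.ndarray:
    """Inverse of :func:`binary_encode` up to the ordinal code (1..N)."""
    arr = bits.to_numpy()
    n_bits = arr.shape[1]
    weights = 2 ** np.arange(n_bits - 1, -1, -1)
    return arr @ weights


def encode_column(values, spec: EncodingSpec) -> pd.DataFrame:
    if spec.method == "one_hot_drop_first":
        return one_hot_encode(values, spec)
    return binary_encode(values, spec)
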