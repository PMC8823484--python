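"""Reading and writing the package's tabular formats.

The response CSV has one header row, a person-id column, item columns named
``item_1..item_k`` and any number of covariate columns.  Cells may be coded
yes/no (raw answers, scored through a :class:`~difkit.scale.ScaleKey`) or 0/1
(already scored).  All outputs are plain TSV/CSV/JSON so every table the
package writes can be read back by the package.
"""

from __future__ import annotations

import json
import re

import numpy as np
import pandas as pd

from .exceptions import ParseError, SchemaError
from .irt import ItemParameters
from .scale import ResponseMatrix, ScaleKey, score_responses

__all__ = [
    "read_responses_csv",
    "write_cohort_csv",
    "write_item_parameters",
    "read_item_parameters",
]

_ITEM_RE = re.compile(r"^item_(\d+)$")


def split_item_columns(df: pd.DataFrame):
    """Partition columns into ordered item columns and covariate columns."""
    items = [(int(m.group(1)), c) for c in df.columns if (m := _ITEM_RE.match(str(c)))]
    items.sort()
    item_cols = [c for _, c in items]
    expected = [f"item_{j}" for j in range(1, len(item_cols) + 1)]
    if item_cols != expected:
        raise SchemaError(f"item columns must be contiguous item_1..item_k; found {item_cols}")
    other = [c for c in df.columns if c not in set(item_cols)]
    return item_cols, other


def read_responses_csv(
    path,
    key: ScaleKey | None = None,
    id_column: str = "person_id",
    scored: bool = False,
):
    """Read a response CSV into ``(ResponseMatrix, covariate DataFrame)``.

    With ``scored=False`` cells are raw yes/no answers and ``key`` must be
    given so they can be reverse-keyed into 0/1 scores; with ``scored=True``
    cells are already 0/1 symptom indicators.
    """
    df = pd.read_csv(path, dtype=object)
    if id_column not in df.columns:
        raise SchemaError(f"missing id column {id_column!r}")
    df = df.set_index(id_column)
    item_cols, cov_cols = split_item_columns(df)
    if not item_cols:
        raise SchemaError("no item_<j> columns found")
    if key is not None and len(item_cols) != key.n_items:
        raise SchemaError(
            f"found {len(item_cols)} item columns but the key defines {key.n_items}"
        )
    items = df[item_cols]
    if scored:
        values = items.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
        raw_nonmissing = items.notna().to_numpy()
        if np.any(raw_nonmissing & np.isnan(values)):
            raise ParseError("scored cells must be numeric 0/1 or empty")
        rm = ResponseMatrix(
            values,
            df.index.to_numpy(),
            np.array(item_cols, dtype=object),
            scored=True,
        )
    else:
        if key is None:
            raise SchemaError("a scale key is required to score raw yes/no answers")
        rm = score_responses(items, key, person_ids=df.index.to_numpy())
    return rm, df[cov_cols]


def write_cohort_csv(rm: ResponseMatrix, covariates: pd.DataFrame, path) -> None:
    """Write a scored cohort plus covariates as a standard response CSV."""
    out = pd.DataFrame(
        rm.values, index=pd.Index(rm.person_ids, name="person_id"), columns=rm.item_ids
    )
    with pd.option_context("future.no_silent_downcasting", True):
        out = out.astype("Int64")  # keeps 0/1 integral, blanks for missing
    for col in covariates.columns:
        out[col] = covariates[col].to_numpy()
    out.to_csv(path)


def write_item_parameters(params: ItemParameters, tsv_path=None, json_path=None) -> None:
    if tsv_path is not None:
        params.to_tsv(tsv_path)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(params.to_json(), fh, indent=1, sort_keys=True)


def read_item_parameters(json_path) -> ItemParameters:
    with open(json_path) as fh:
        return ItemParameters.from_json(json.load(fh))
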