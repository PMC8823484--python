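"""Scale definition, response scoring and total-score computation.

A dichotomous screening scale is described by a :class:`ScaleKey`: the number
of items, which items are reverse-keyed (a "no" endorses the symptom), and the
severity bands that partition the total-score range.  The default key is the
15-item Geriatric Depression Scale short form, where items 1, 5, 7, 11 and 13
are reverse-keyed and totals are banded normal (0-4), mild (5-8), moderate
(9-11) and severe (12-15).

Raw yes/no answers are scored into a :class:`ResponseMatrix` of 0/1 symptom
indicators; totals and severity labels are computed on complete cases only
(listwise deletion -- partially answered questionnaires are dropped, never
prorated or imputed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .exceptions import ParseError, SchemaError, StateError

__all__ = [
    "ScaleKey",
    "ResponseMatrix",
    "score_responses",
    "unscore_responses",
    "total_scores",
    "corrected_total",
]

#: default cell codings accepted for raw answers
YES_VALUES = frozenset({"yes", "y", "1", 1, True})
NO_VALUES = frozenset({"no", "n", "0", 0, False})
MISSING_VALUES = frozenset({"", "na", "nan", None})


@dataclass(frozen=True)
class ScaleKey:
    """Definition of a dichotomous scale.

    Parameters
    ----------
    n_items:
        Number of items (>= 2).
    reverse_items:
        1-based indices of reverse-keyed items (a "no" answer scores 1).
    severity_bands:
        Ordered ``(label, lo, hi)`` triples with inclusive bounds that are
        contiguous, non-overlapping and cover ``0..n_items`` exactly.
    """

    n_items: int
    reverse_items: frozenset = field(default_factory=frozenset)
    severity_bands: tuple = ()

    def __post_init__(self):
        if self.n_items < 2:
            raise ValueError("a scale needs at least 2 items")
        object.__setattr__(self, "reverse_items", frozenset(int(i) for i in self.reverse_items))
        if not self.reverse_items <= set(range(1, self.n_items + 1)):
            raise ValueError(
                f"reverse_items {sorted(self.reverse_items)} outside 1..{self.n_items}"
            )
        bands = tuple((str(l), int(lo), int(hi)) for l, lo, hi in self.severity_bands)
        object.__setattr__(self, "severity_bands", bands)
        if bands:
            expected = 0
            for label, lo, hi in bands:
                if lo != expected or hi < lo:
                    raise ValueError("severity bands must be contiguous and ordered")
                expected = hi + 1
            if expected != self.n_items + 1:
                raise ValueError(
                    f"severity bands must cover 0..{self.n_items} exactly"
                )

    @classmethod
    def gds15(cls) -> "ScaleKey":
        """The 15-item Geriatric Depression Scale short-form key."""
        return cls(
            n_items=15,
            reverse_items=frozenset({1, 5, 7, 11, 13}),
            severity_bands=(
                ("normal", 0, 4),
                ("mild", 5, 8),
                ("moderate", 9, 11),
                ("severe", 12, 15),
            ),
        )

    def severity(self, total: int) -> str:
        """Severity label for a total score (total function on ``0..n_items``)."""
        if not 0 <= total <= self.n_items:
            raise ValueError(f"total {total} outside 0..{self.n_items}")
        if not self.severity_bands:
            raise ValueError("scale key has no severity bands")
        for label, lo, hi in self.severity_bands:
            if lo <= total <= hi:
                return label
        raise AssertionError("severity bands validated contiguous; unreachable")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_items": self.n_items,
            "reverse_items": sorted(self.reverse_items),
            "severity_bands": [list(b) for b in self.severity_bands],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScaleKey":
        return cls(
            n_items=d["n_items"],
            reverse_items=frozenset(d.get("reverse_items", ())),
            severity_bands=tuple(tuple(b) for b in d.get("severity_bands", ())),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ScaleKey":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ResponseMatrix:
    """n persons x k items of 0/1 responses with a missing mask.

    ``values`` is a float array where missing cells are NaN; every non-missing
    cell is 0.0 or 1.0.  ``scored`` records whether reverse-keying has been
    applied (raw yes/no patterns are also stored 0/1, with 1 = "yes").
    Item identifiers are 1-based item numbers rendered as ``item_<j>``.
    """

    values: np.ndarray
    person_ids: np.ndarray
    item_ids: np.ndarray
    scored: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SchemaError("values must be a 2-d matrix")
        n, k = self.values.shape
        if n < 1 or k < 2:
            raise SchemaError("need at least 1 person and 2 items")
        finite = self.values[~np.isnan(self.values)]
        if not np.all((finite == 0) | (finite == 1)):
            raise ParseError("non-missing cells must be 0 or 1")
        self.person_ids = np.asarray(self.person_ids)
        self.item_ids = np.asarray(self.item_ids)
        if len(self.person_ids) != n or len(self.item_ids) != k:
            raise SchemaError("id lengths do not match the matrix shape")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def complete_rows(self) -> np.ndarray:
        """Boolean mask of persons with no missing item."""
        return ~np.any(self.missing_mask, axis=1)

    def complete_cases(self) -> "ResponseMatrix":
        keep = self.complete_rows()
        return ResponseMatrix(
            self.values[keep], self.person_ids[keep], self.item_ids, self.scored
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.person_ids, columns=self.item_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scored: bool = False) -> "ResponseMatrix":
        return cls(df.to_numpy(dtype=float), df.index.to_numpy(), df.columns.to_numpy(), scored)


def _default_item_ids(k: int) -> np.ndarray:
    return np.array([f"item_{j}" for j in range(1, k + 1)], dtype=object)


def _coerce_raw(cell, yes_values, no_values):
    """Map a raw cell to 1 (yes), 0 (no) or NaN (missing)."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return np.nan
    key = cell.strip().lower() if isinstance(cell, str) else cell
    if key in MISSING_VALUES:
        return np.nan
    if key in yes_values:
        return 1.0
    if key in no_values:
        return 0.0
    raise ParseError(f"unrecognized answer {cell!r}; expected yes/no/missing")


def score_responses(
    raw_answers,
    key: ScaleKey,
    person_ids=None,
    yes_values=YES_VALUES,
    no_values=NO_VALUES,
) -> ResponseMatrix:
    """Score raw yes/no answers into 0/1 symptom indicators.

    A cell scores 1 iff the answer is "yes" on a regular item or "no" on a
    reverse-keyed item; missing propagates.
    """
    if isinstance(raw_answers, pd.DataFrame):
        if person_ids is None:
            person_ids = raw_answers.index.to_numpy()
        raw = raw_answers.to_numpy()
    else:
        raw = np.asarray(raw_answers, dtype=object)
    if raw.ndim != 2:
        raise SchemaError("raw answers must be a 2-d table")
    n, k = raw.shape
    if k != key.n_items:
        raise SchemaError(f"answer table has {k} columns but the key defines {key.n_items} items")
    if person_ids is None:
        person_ids = np.arange(1, n + 1)

    yes = np.empty((n, k))
    for i in range(n):
        for j in range(k):
            yes[i, j] = _coerce_raw(raw[i, j], yes_values, no_values)
    scored = yes.copy()
    for j in range(k):
        if (j + 1) in key.reverse_items:
            scored[:, j] = 1.0 - yes[:, j]  # NaN propagates
    return ResponseMatrix(scored, np.asarray(person_ids), _default_item_ids(k), scored=True)


def unscore_responses(rm: ResponseMatrix, key: ScaleKey) -> np.ndarray:
    """Invert scoring back to the raw yes(1)/no(0) pattern (NaN preserved)."""
    if not rm.scored:
        raise StateError("matrix is not scored")
    if rm.n_items != key.n_items:
        raise SchemaError("matrix/key item count mismatch")
    raw = rm.values.copy()
    for j in range(rm.n_items):
        if (j + 1) in key.reverse_items:
            raw[:, j] = 1.0 - raw[:, j]
    return raw


def total_scores(
    rm: ResponseMatrix, key: ScaleKey = None, missing_policy: str = "listwise"
) -> pd.DataFrame:
    """Per-person totals and severity labels under listwise deletion.

    Persons with any missing item are dropped (incomplete questionnaires are
    removed, not prorated).  Returns a DataFrame indexed by person id with
    columns ``total`` and, when a key with bands is given, ``severity``.
    """
    if not rm.scored:
        raise StateError("total_scores requires a scored matrix")
    if missing_policy != "listwise":
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    cc = rm.complete_cases()
    totals = cc.values.sum(axis=1).astype(int)
    out = pd.DataFrame({"total": totals}, index=pd.Index(cc.person_ids, name="person_id"))
    if key is not None and key.severity_bands:
        out["severity"] = [key.severity(t) for t in totals]
    return out


def corrected_total(rm: ResponseMatrix, removed_items) -> pd.DataFrame:
    """Totals over the items that survive DIF-based removal.

    ``removed_items`` are 1-based item indices; removing every item is an
    error.  The same listwise missing policy as :func:`total_scores` applies,
    so the retained person set is unchanged.
    """
    if not rm.scored:
        raise StateError("corrected_total requires a scored matrix")
    removed = {int(i) for i in removed_items}
    if not removed <= set(range(1, rm.n_items + 1)):
        raise ValueError(f"removed items {sorted(removed)} outside 1..{rm.n_items}")
    keep = [j for j in range(rm.n_items) if (j + 1) not in removed]
    if not keep:
        raise ValueError("cannot remove every item from the scale")
    cc = rm.complete_cases()
    totals = cc.values[:, keep].sum(axis=1).astype(int)
    return pd.DataFrame(
        {"corrected_total": totals}, index=pd.Index(cc.person_ids, name="person_id")
    )
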