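"""Subject-level ordinal response data: reading, validation, filtering, fusion.

The data model is deliberately categorical: item responses are *labels* drawn
from a declared :class:`OrdinalScale`, never numbers. Ordering comes solely
from the declared label sequence, and a distinguished ``missing_code``
(conventionally ``"0"`` for "no answer") marks non-response. All downstream
entropy statistics are computed on contingency tables built over the full
declared label set, so levels that happen to be unobserved in a subset are
retained as structural zero rows/columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .entropy import ContingencyTable
from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
UNSPECIFIED = "unspecified"


@dataclass(frozen=True)
class OrdinalScale:
    """An ordered categorical rating scale.

    Parameters
    ----------
    labels : sequence of str
        Category labels in their declared ordinal order, e.g. ``("1", "2",
        "3", "4")`` for strongly disagree … strongly agree.
    missing_code : str
        Label treated as non-response; must not be a member of ``labels``.
    polarity : {"positive", "negative", "unspecified"}
        Whether agreement indicates high or low standing on the underlying
        trait. Metadata only: it drives display colouring and trend
        expectations, never any reordering of the values.
    """

    labels: tuple[str, ...]
    missing_code: str = "0"
    polarity: str = UNSPECIFIED

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 2:
            raise SchemaError("an ordinal scale needs at least two labels")
        if len(set(labels)) != len(labels) or any(not x for x in labels):
            raise SchemaError(f"scale labels must be unique and nonempty: {labels}")
        if self.missing_code in labels:
            raise SchemaError(
                f"missing code {self.missing_code!r} collides with a scale label"
            )
        if self.polarity not in (POSITIVE, NEGATIVE, UNSPECIFIED):
            raise SchemaError(f"unknown polarity {self.polarity!r}")

    @property
    def n_levels(self) -> int:
        return len(self.labels)


def likert4(polarity: str = UNSPECIFIED) -> OrdinalScale:
    """The four-point agreement scale used throughout: labels 1..4, 0 missing."""
    return OrdinalScale(("1", "2", "3", "4"), missing_code="0", polarity=polarity)


@dataclass(frozen=True)
class FusedVariable:
    """Bookkeeping for a composite covariate built from two source items."""

    source_a: str
    source_b: str
    name: str
    levels: tuple[str, ...]


@dataclass
class ResponseTable:
    """Subjects × items matrix of ordinal labels plus covariate columns.

    ``data`` holds one row per subject; item columns contain scale labels (as
    strings) or the item's missing code, covariate columns are free-form.
    """

    data: pd.DataFrame
    items: dict[str, OrdinalScale]
    covariates: tuple[str, ...] = ()
    fused: tuple[FusedVariable, ...] = ()

    def __post_init__(self) -> None:
        self.covariates = tuple(self.covariates)
        missing_cols = [c for c in list(self.items) + list(self.covariates) if c not in self.data.columns]
        if missing_cols:
            raise SchemaError(f"declared columns absent from data: {missing_cols}")
        self.data = self.data.copy()
        for item in self.items:
            self.data[item] = self.data[item].astype("string").astype(object)
        self._validate_labels()

    def _validate_labels(self) -> None:
        problems = []
        for item, scale in self.items.items():
            allowed = set(scale.labels) | {scale.missing_code}
            bad = ~self.data[item].isin(allowed)
            if bad.any():
                rows = list(self.data.index[bad][:10])
                values = sorted(set(self.data.loc[bad, item]))
                problems.append(f"{item}: labels {values} outside scale at rows {rows}")
        if problems:
            raise ValidationError("invalid response labels: " + "; ".join(problems))

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(self.items)

    def is_missing(self, item: str) -> pd.Series:
        scale = self._scale(item)
        return self.data[item] == scale.missing_code

    def _scale(self, item: str) -> OrdinalScale:
        try:
            return self.items[item]
        except KeyError:
            raise SchemaError(f"unknown item {item!r}") from None


@dataclass(frozen=True)
class ResponseSchema:
    """Declared layout of a response CSV: item columns, scales, covariates."""

    items: Mapping[str, OrdinalScale]
    covariates: tuple[str, ...] = ()

    @classmethod
    def likert(
        cls,
        item_ids: Sequence[str],
        covariates: Sequence[str] = (),
        n_levels: int = 4,
        missing_code: str = "0",
        polarity: Mapping[str, str] | None = None,
    ) -> "ResponseSchema":
        labels = tuple(str(i) for i in range(1, n_levels + 1))
        polarity = dict(polarity or {})
        items = {
            i: OrdinalScale(labels, missing_code, polarity.get(i, UNSPECIFIED))
            for i in item_ids
        }
        return cls(items=items, covariates=tuple(covariates))


def read_responses(path: str | Path, schema: ResponseSchema) -> ResponseTable:
    """Read and validate a subject-per-row CSV against a declared schema.

    Raises
    ------
    SchemaError
        If a declared item or covariate column is absent.
    ValidationError
        If any cell holds a label outside its item's scale (offending rows
        are named in the message).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in list(schema.items) + list(schema.covariates) if c not in df.columns]
    if missing:
        raise SchemaError(f"CSV {path} lacks declared columns: {missing}")
    return ResponseTable(df, dict(schema.items), tuple(schema.covariates))


def write_responses(table: ResponseTable, path: str | Path) -> Path:
    """Write a response table back to CSV with the same conventions read_responses expects."""
    path = Path(path)
    table.data.to_csv(path, index=False)
    return path


def filter_subjects(
    table: ResponseTable,
    conditions: Mapping[str, object] | None = None,
    missing_policy: str = "pairwise",
    return_report: bool = False,
):
    """Subset subjects by covariate conditions and apply a missingness policy.

    ``conditions`` maps covariate name to either a single value, a set/list of
    admissible values, or a ``(lo, hi)`` tuple for an inclusive numeric range
    (e.g. ``{"country": "US", "age": (15, 18), "gender": {"m", "f"}}``).

    ``missing_policy`` is ``"pairwise"`` (keep everyone; crosstabs drop
    missing per item pair) or ``"listwise"`` (drop any subject with a missing
    response on any item). Counts removed per condition are logged and, with
    ``return_report=True``, returned as a dict alongside the table.
    """
    if missing_policy not in ("pairwise", "listwise"):
        raise ValidationError(f"unknown missing policy {missing_policy!r}")
    df = table.data
    report: dict[str, int] = {}
    keep = pd.Series(True, index=df.index)
    for cov, cond in (conditions or {}).items():
        if cov not in table.covariates:
            raise SchemaError(f"predicate references unknown covariate {cov!r}")
        col = df[cov]
        if isinstance(cond, tuple) and len(cond) == 2:
            numeric = pd.to_numeric(col, errors="coerce")
            ok = (numeric >= cond[0]) & (numeric <= cond[1])
        elif isinstance(cond, (set, frozenset, list)):
            ok = col.astype(str).isin({str(v) for v in cond})
        else:
            ok = col.astype(str) == str(cond)
        removed = int((keep & ~ok).sum())
        report[cov] = removed
        keep &= ok
        logger.info("filter %s=%r removed %d subjects (%d remain)", cov, cond, removed, int(keep.sum()))
    out = df[keep]
    if missing_policy == "listwise" and table.items:
        any_missing = pd.Series(False, index=out.index)
        for item, scale in table.items.items():
            any_missing |= out[item] == scale.missing_code
        report["listwise_missing"] = int(any_missing.sum())
        logger.info("listwise deletion removed %d subjects", int(any_missing.sum()))
        out = out[~any_missing]
    result = ResponseTable(out.reset_index(drop=True), dict(table.items), table.covariates, table.fused)
    return (result, report) if return_report else result


def crosstab(table: ResponseTable, item_x: str, item_y: str) -> ContingencyTable:
    """Cross-tabulate covariate ``item_x`` against response ``item_y``.

    Subjects missing either item are excluded from this pair only (pairwise
    deletion). Counts cover the full declared label sets, so unobserved
    levels appear as zero rows/columns.
    """
    scale_x = table._scale(item_x)
    scale_y = table._scale(item_y)
    ok = ~(table.is_missing(item_x) | table.is_missing(item_y))
    sub = table.data[ok]
    if len(sub) == 0:
        raise ValidationError(
            f"no subjects contribute to the pair ({item_x}, {item_y}) after missing-data exclusion"
        )
    ct = pd.crosstab(sub[item_x], sub[item_y])
    ct = ct.reindex(index=scale_x.labels, columns=scale_y.labels, fill_value=0)
    return ContingencyTable(
        x_levels=scale_x.labels,
        y_levels=scale_y.labels,
        counts=ct.to_numpy(dtype=np.int64),
        x_name=item_x,
        y_name=item_y,
    )


FUSE_SEP = "-"


def fuse(table: ResponseTable, item_a: str, item_b: str) -> ResponseTable:
    """Add a composite covariate whose levels are all ``a-b`` label pairs.

    Two four-level items yield the sixteen lexicographic levels ``1-1, 1-2,
    …, 4-4``; a subject's fused value is missing whenever either source
    response is missing. Unobserved composite levels remain in the scale.
    """
    scale_a = table._scale(item_a)
    scale_b = table._scale(item_b)
    if item_a == item_b:
        warnings.warn(
            f"fusing item {item_a!r} with itself: diagnostic use only",
            UserWarning,
            stacklevel=2,
        )
    name = f"{item_a}{FUSE_SEP}{item_b}"
    levels = tuple(f"{a}{FUSE_SEP}{b}" for a in scale_a.labels for b in scale_b.labels)
    missing = "|".join(sorted({scale_a.missing_code, scale_b.missing_code})) or "NA"
    fused_scale = OrdinalScale(levels, missing_code=missing)
    vals = table.data[item_a].astype(str) + FUSE_SEP + table.data[item_b].astype(str)
    vals[table.is_missing(item_a) | table.is_missing(item_b)] = missing
    df = table.data.copy()
    df[name] = vals
    items = dict(table.items)
    items[name] = fused_scale
    fused_meta = table.fused + (FusedVariable(item_a, item_b, name, levels),)
    return ResponseTable(df, items, table.covariates, fused_meta)


DEFAULT_AGE_BINS: tuple[tuple[float, float], ...] = (
    (15, 18),
    (18, 25),
    (25, 35),
    (35, 50),
    (50, 70),
)


def add_age_bins(
    table: ResponseTable,
    column: str = "age",
    bins: Iterable[tuple[float, float]] = DEFAULT_AGE_BINS,
    out_column: str = "age_bin",
) -> ResponseTable:
    """Attach an age-bin covariate for stratified displays.

    The first bin is closed on both ends (the late-adolescent 15–18 group);
    subsequent bins are half-open ``(lo, hi]``. Ages outside every bin map to
    the empty string and are naturally excluded by covariate filters.
    """
    if column not in table.covariates:
        raise SchemaError(f"unknown covariate {column!r}")
    bins = list(bins)
    age = pd.to_numeric(table.data[column], errors="coerce")
    labels = pd.Series("", index=table.data.index, dtype=object)
    for i, (lo, hi) in enumerate(bins):
        inside = (age >= lo) & (age <= hi) if i == 0 else (age > lo) & (age <= hi)
        labels[inside & (labels == "")] = f"{lo:g}-{hi:g}"
    df = table.data.copy()
    df[out_column] = labels
    return ResponseTable(df, dict(table.items), table.covariates + (out_column,), table.fused)
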