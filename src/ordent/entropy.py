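"""Entropy statistics on contingency tables.

All measures are plug-in estimates computed from a Kx×Ky table of counts for
a covariate item X (rows) and a response item Y (columns):

* ``shannon_entropy`` — H of a count vector, −Σ p log p with 0·log 0 ≡ 0;
* ``row_conditional_entropy`` — the profile H(Y|X=x), one value per covariate
  level, the unit of the ordinal displays;
* ``conditional_entropy`` — H(Y|X) = Σ_x p(x) H(Y|X=x), the p(x)-weighted sum
  of the row entropies;
* ``rescaled_conditional_entropy`` — H(Y|X)/H(Y) in [0, 1], base-invariant;
* ``mutual_conditional_entropy`` — the mean of H(Y|X)/H(Y) and H(X|Y)/H(X),
  a symmetric association strength where LOWER means stronger association.

Rows with no observations contribute H(Y|X=x) = 0 and carry an explicit
``empty`` flag so that displays can distinguish "no data" from genuinely
concentrated responses. The log base defaults to natural log (nats); ratio
measures are base-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .errors import DegenerateDistributionError, ValidationError

__all__ = [
    "ContingencyTable",
    "EntropyProfile",
    "EntropySummary",
    "shannon_entropy",
    "row_conditional_entropy",
    "conditional_entropy",
    "entropy_summary",
    "rescaled_conditional_entropy",
    "mutual_conditional_entropy",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of a (covariate X, response Y) item pair over declared levels.

    Levels are ordered label tuples fixed by the declared scales, so zero
    rows and columns are representable. Margins p(x), p(y) and the joint
    p(x, y) are derived properties.
    """

    x_levels: tuple[str, ...]
    y_levels: tuple[str, ...]
    counts: np.ndarray
    x_name: str = "X"
    y_name: str = "Y"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "x_levels", tuple(str(v) for v in self.x_levels))
        object.__setattr__(self, "y_levels", tuple(str(v) for v in self.y_levels))
        if counts.ndim != 2 or counts.shape != (len(self.x_levels), len(self.y_levels)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match levels "
                f"({len(self.x_levels)}, {len(self.y_levels)})"
            )
        if (counts < 0).any():
            raise ValidationError("negative counts in contingency table")
        if counts.sum() == 0:
            raise ValidationError("contingency table has zero total count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def p_x(self) -> np.ndarray:
        """Row-margin proportions, the estimated marginal distribution of X."""
        return self.row_totals / self.total

    @property
    def p_y(self) -> np.ndarray:
        """Column-margin proportions, the estimated marginal distribution of Y."""
        return self.col_totals / self.total

    @property
    def p_xy(self) -> np.ndarray:
        """Joint proportions."""
        return self.counts / self.total

    @property
    def empty_rows(self) -> np.ndarray:
        """Boolean mask of covariate levels with no observations."""
        return self.row_totals == 0

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(
            x_levels=self.y_levels,
            y_levels=self.x_levels,
            counts=self.counts.T,
            x_name=self.y_name,
            y_name=self.x_name,
        )


@dataclass
class EntropyProfile:
    """Per-level conditional entropies H(Y|X=x) across covariate levels."""

    response: str
    covariate: str
    levels: tuple[str, ...]
    h_given_x: np.ndarray
    n_per_level: np.ndarray
    base: Optional[float] = None  # None = natural log (nats)
    empty: np.ndarray = field(default=None)  # type: ignore[assignment]
    ci_lo: Optional[np.ndarray] = None
    ci_hi: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.h_given_x = np.asarray(self.h_given_x, dtype=float)
        self.n_per_level = np.asarray(self.n_per_level)
        if self.empty is None:
            self.empty = self.n_per_level == 0


@dataclass(frozen=True)
class EntropySummary:
    """H(Y), H(Y|X) and their base-free ratio for one item pair."""

    response: str
    covariate: str
    h_y: float
    h_y_given_x: float
    ratio: float
    base: Optional[float] = None


def _check_base(base: Optional[float]) -> None:
    if base is not None and base <= 1:
        raise ValidationError(f"log base must exceed 1, got {base}")


def shannon_entropy(counts, base: Optional[float] = None) -> float:
    """Shannon entropy −Σ p log p of a nonnegative count (or proportion) vector.

    ``base=None`` gives nats; ``base=2`` gives bits. Zero-count categories
    contribute nothing (0·log 0 ≡ 0). An all-zero vector has no underlying
    distribution and raises :class:`DegenerateDistributionError`.
    """
    _check_base(base)
    v = np.asarray(counts, dtype=float)
    if (v < 0).any():
        raise ValidationError("negative counts")
    if v.sum() == 0:
        raise DegenerateDistributionError("entropy of an all-zero count vector is undefined")
    return float(stats.entropy(v, base=base))


def row_conditional_entropy(ct: ContingencyTable, base: Optional[float] = None) -> EntropyProfile:
    """The profile H(Y|X=x): entropy of each row-normalised distribution.

    Empty rows (covariate levels with no observations) map to 0 and are
    flagged in the returned profile's ``empty`` mask.
    """
    _check_base(base)
    n = ct.row_totals
    occupied = n > 0
    h = np.zeros(len(ct.x_levels))
    if occupied.any():
        h[occupied] = stats.entropy(ct.counts[occupied].astype(float), base=base, axis=1)
    return EntropyProfile(
        response=ct.y_name,
        covariate=ct.x_name,
        levels=ct.x_levels,
        h_given_x=h,
        n_per_level=n,
        base=base,
    )


def conditional_entropy(ct: ContingencyTable, base: Optional[float] = None) -> float:
    """H(Y|X) = Σ_x p(x) H(Y|X=x), the row-margin-weighted sum of row entropies.

    Empty rows have weight p(x) = 0 and contribute nothing.
    """
    profile = row_conditional_entropy(ct, base=base)
    return float(np.dot(ct.p_x, profile.h_given_x))


def entropy_summary(ct: ContingencyTable, base: Optional[float] = None) -> EntropySummary:
    """H(Y), H(Y|X) and the rescaled ratio H(Y|X)/H(Y) in one pass."""
    h_y = shannon_entropy(ct.col_totals, base=base)
    h_yx = conditional_entropy(ct, base=base)
    if h_y == 0:
        raise DegenerateDistributionError(
            f"response {ct.y_name!r} is constant: H(Y)=0, the rescaled ratio is undefined"
        )
    return EntropySummary(ct.y_name, ct.x_name, h_y, h_yx, h_yx / h_y, base)


def rescaled_conditional_entropy(ct: ContingencyTable) -> float:
    """H(Y|X)/H(Y): 0 = X predicts Y perfectly, 1 = X carries no information.

    Base-invariant; requires a non-constant response (H(Y) > 0).
    """
    return entropy_summary(ct).ratio


def mutual_conditional_entropy(ct: ContingencyTable) -> float:
    """Mutual conditional entropy: mean of H(Y|X)/H(Y) and H(X|Y)/H(X).

    Symmetric in the two items; in [0, 1] with lower values indicating a
    stronger association. Undefined (raises) when either margin is constant.
    """
    return 0.5 * (
        rescaled_conditional_entropy(ct) + rescaled_conditional_entropy(ct.transpose())
    )
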