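"""Synthetic Likert-type response tables with controllable latent structure.

The generator follows a graded-response-style mechanism: each subject carries
a latent trait θ ~ Normal(group mean, 1); a positive item with discrimination
``a`` and ordered thresholds t1 < t2 < t3 is answered

    response = 1 + #{ t : t < a·θ + ε },   ε ~ Logistic(0, 1),

and negative items substitute −θ for θ. Responses are then masked to the
missing code completely at random at ``missing_rate``. This produces the
monotone ordinal structure the entropy displays presuppose — it is a fixture
for testing the toolkit, not a psychometric claim.

The default item battery mirrors a 10-item self-esteem questionnaire: items
1, 2, 4, 6, 7 positively posed, items 3, 5, 8, 9, 10 negatively posed, all
on the four-point agreement scale. Default thresholds are asymmetric
(−2.5, −1.5, −0.5) so that high-trait subjects concentrate on "strongly
agree" while low-trait subjects spread across categories, matching the
agreement-heavy margins typical of such surveys.

``table1_fixture`` returns the worked 4×4 contingency table of two items
among 1977 US late-adolescent boys that anchors the deterministic tests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data_io import NEGATIVE, POSITIVE, OrdinalScale, ResponseTable, likert4
from .entropy import ContingencyTable
from .errors import ValidationError

__all__ = [
    "ItemSpec",
    "SyntheticConfig",
    "rosenberg_items",
    "generate_likert",
    "table1_fixture",
    "ROSENBERG_POSITIVE",
    "ROSENBERG_NEGATIVE",
]

ROSENBERG_POSITIVE = ("Q1", "Q2", "Q4", "Q6", "Q7")
ROSENBERG_NEGATIVE = ("Q3", "Q5", "Q8", "Q9", "Q10")

DEFAULT_THRESHOLDS = (-2.5, -1.5, -0.5)
DEFAULT_DISCRIMINATION = 1.5


@dataclass(frozen=True)
class ItemSpec:
    """One synthetic item: polarity, discrimination a ≥ 0, three increasing
    thresholds on the latent scale, and the index of the driving trait."""

    name: str
    polarity: str = POSITIVE
    a: float = DEFAULT_DISCRIMINATION
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    trait: int = 0

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValidationError(f"discrimination must be >= 0, got {self.a}")
        t = tuple(float(x) for x in self.thresholds)
        object.__setattr__(self, "thresholds", t)
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValidationError(f"thresholds must be strictly increasing: {t}")


def rosenberg_items(
    a: float = DEFAULT_DISCRIMINATION,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> tuple[ItemSpec, ...]:
    """The default 10-item battery with the standard polarity pattern."""
    items = []
    for i in range(1, 11):
        name = f"Q{i}"
        pol = POSITIVE if name in ROSENBERG_POSITIVE else NEGATIVE
        items.append(ItemSpec(name, pol, a, tuple(thresholds)))
    return tuple(items)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation settings: sample size, items, group mixture and missingness.

    ``groups`` maps the group covariate's labels to mixture proportions
    (summing to 1); ``trait_shift`` gives each group's latent mean offset.
    Default proportions 0.32 boys / 0.68 girls echo the US late-adolescent
    composition of the motivating survey sample.
    """

    n_subjects: int = 1000
    items: tuple[ItemSpec, ...] = field(default_factory=rosenberg_items)
    group_covariate: str = "gender"
    groups: Mapping[str, float] = field(default_factory=lambda: {"m": 0.32, "f": 0.68})
    trait_shift: Mapping[str, float] = field(default_factory=dict)
    age_range: tuple[int, int] = (15, 18)
    country: str = "US"
    missing_rate: float = 0.01
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        total = float(sum(self.groups.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"group proportions must sum to 1, got {total}")
        names = [it.name for it in self.items]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate item names: {names}")

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["items"] = [asdict(it) for it in self.items]
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def generate_likert(config: SyntheticConfig) -> ResponseTable:
    """Draw a synthetic response table; deterministic for a given seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    group_labels = list(config.groups)
    group_idx = rng.choice(len(group_labels), size=n, p=list(config.groups.values()))
    group = np.asarray(group_labels, dtype=object)[group_idx]
    shift = np.array([config.trait_shift.get(g, 0.0) for g in group_labels])[group_idx]

    n_traits = max(it.trait for it in config.items) + 1
    theta = rng.normal(0.0, 1.0, size=(n, n_traits)) + shift[:, None]

    data: dict[str, np.ndarray] = {}
    items: dict[str, OrdinalScale] = {}
    for it in config.items:
        sign = -1.0 if it.polarity == NEGATIVE else 1.0
        latent = it.a * sign * theta[:, it.trait] + rng.logistic(0.0, 1.0, size=n)
        resp = 1 + (latent[:, None] > np.asarray(it.thresholds)[None, :]).sum(axis=1)
        labels = resp.astype(str).astype(object)
        if config.missing_rate > 0:
            mask = rng.random(n) < config.missing_rate
            labels[mask] = "0"
        data[it.name] = labels
        items[it.name] = likert4(it.polarity)

    ages = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
    df = pd.DataFrame(data)
    df[config.group_covariate] = group
    df["age"] = ages.astype(str)
    df["country"] = config.country
    return ResponseTable(
        df, items, covariates=(config.group_covariate, "age", "country")
    )


TABLE1_COUNTS = (
    (11, 13, 110, 337),
    (2, 22, 220, 153),
    (20, 135, 328, 122),
    (117, 186, 157, 44),
)


def table1_fixture() -> ContingencyTable:
    """The worked 4×4 example: Qi (rows, negatively posed) vs Qj (columns,
    positively posed) among 1977 US late-adolescent boys; total count 1977."""
    return ContingencyTable(
        x_levels=("1", "2", "3", "4"),
        y_levels=("1", "2", "3", "4"),
        counts=np.array(TABLE1_COUNTS, dtype=np.int64),
        x_name="Qi",
        y_name="Qj",
    )
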