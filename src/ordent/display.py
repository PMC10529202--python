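"""Ordinal conditional-entropy displays: tidy profile tables and figures.

The tidy table produced by :func:`profile_grid` is the single source of
truth — one row per (response, covariate, covariate level, stratum) holding
the row-wise conditional entropy, the contributing subject count, optional
percentile CI bounds and an empty-level flag. :func:`render_profiles`
consumes only that table, so headless pipelines that skip figures produce
identical CSVs.

Ordinal levels are plotted equally spaced in their declared order: the
category codes are labels, not numbers, and metric spacing would impose
exactly the quantitative reading the entropy approach avoids.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data_io import NEGATIVE, POSITIVE, ResponseTable, crosstab
from .entropy import row_conditional_entropy
from .errors import SchemaError, ValidationError
from .resampling import ResampleConfig, ci_for_statistic

__all__ = ["DisplaySpec", "profile_grid", "render_profiles"]

TIDY_COLUMNS = [
    "response",
    "covariate",
    "stratum",
    "level",
    "h",
    "n",
    "ci_lo",
    "ci_hi",
    "empty",
]


@dataclass(frozen=True)
class DisplaySpec:
    """What to profile: a response item, covariate items (possibly fused
    pseudo-items), stratifying covariate columns, and CI settings."""

    response: str
    covariates: tuple[str, ...]
    strata: tuple[str, ...] = ()
    polarity_coloring: bool = True
    ci: Optional[ResampleConfig] = None
    base: Optional[float] = None  # None = nats

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "strata", tuple(self.strata))
        if self.response in self.covariates:
            raise ValidationError(f"response {self.response!r} cannot also be a covariate")


def _strata_cells(table: ResponseTable, strata: Sequence[str]):
    """Yield (stratum label, boolean subject mask) pairs in sorted value order."""
    if not strata:
        yield "all", pd.Series(True, index=table.data.index)
        return
    for col in strata:
        if col not in table.covariates:
            raise SchemaError(f"stratum column {col!r} is not a covariate")
    level_sets = [sorted(table.data[c].astype(str).unique()) for c in strata]
    for combo in itertools.product(*level_sets):
        mask = pd.Series(True, index=table.data.index)
        for col, val in zip(strata, combo):
            mask &= table.data[col].astype(str) == val
        label = "|".join(f"{c}={v}" for c, v in zip(strata, combo))
        yield label, mask


def _empty_cell_rows(spec: DisplaySpec, covariate: str, stratum: str, levels) -> list[dict]:
    return [
        {
            "response": spec.response,
            "covariate": covariate,
            "stratum": stratum,
            "level": lev,
            "h": 0.0,
            "n": 0,
            "ci_lo": np.nan,
            "ci_hi": np.nan,
            "empty": True,
        }
        for lev in levels
    ]


def profile_grid(table: ResponseTable, spec: DisplaySpec) -> pd.DataFrame:
    """One entropy profile per (covariate, stratum) cell, as a tidy table.

    Levels appear in declared scale order; empty levels are emitted with
    h = 0 and ``empty`` true, and a stratum with no contributing subjects is
    emitted all-empty rather than dropped. When ``spec.ci`` is set, per-level
    percentile intervals from fixed-row-total multinomial resampling fill
    ``ci_lo``/``ci_hi`` (cell seeds derived deterministically from the
    configured seed).
    """
    rows: list[dict] = []
    cell_idx = 0
    for covariate in spec.covariates:
        scale = table.items.get(covariate)
        if scale is None:
            raise SchemaError(f"unknown covariate item {covariate!r}")
        for stratum, mask in _strata_cells(table, spec.strata):
            sub = ResponseTable(
                table.data[mask].reset_index(drop=True),
                dict(table.items),
                table.covariates,
                table.fused,
            )
            try:
                ct = crosstab(sub, covariate, spec.response)
            except ValidationError:
                rows.extend(_empty_cell_rows(spec, covariate, stratum, scale.labels))
                cell_idx += 1
                continue
            profile = row_conditional_entropy(ct, base=spec.base)
            ci_lo = np.full(len(scale.labels), np.nan)
            ci_hi = np.full(len(scale.labels), np.nan)
            if spec.ci is not None:
                cell_cfg = ResampleConfig(
                    M=spec.ci.M,
                    level=spec.ci.level,
                    seed=None
                    if spec.ci.seed is None
                    else (spec.ci.seed + 1000003 * cell_idx) % (2**31),
                )
                res = ci_for_statistic(
                    ct,
                    lambda t: row_conditional_entropy(t, base=spec.base),
                    cell_cfg,
                    name="row_conditional_entropy",
                )
                ci_lo, ci_hi = np.asarray(res.lo), np.asarray(res.hi)
            for k, lev in enumerate(scale.labels):
                rows.append(
                    {
                        "response": spec.response,
                        "covariate": covariate,
                        "stratum": stratum,
                        "level": lev,
                        "h": float(profile.h_given_x[k]),
                        "n": int(profile.n_per_level[k]),
                        "ci_lo": float(ci_lo[k]),
                        "ci_hi": float(ci_hi[k]),
                        "empty": bool(profile.empty[k]),
                    }
                )
            cell_idx += 1
    return pd.DataFrame(rows, columns=TIDY_COLUMNS)


def _panel_color(polarity: Optional[str]) -> str:
    if polarity == NEGATIVE:
        return "firebrick"
    if polarity == POSITIVE:
        return "royalblue"
    return "dimgray"


def render_profiles(
    tidy: pd.DataFrame,
    out: str | Path,
    polarity: Optional[Mapping[str, str]] = None,
    base_label: str = "nats",
) -> list[Path]:
    """Render a profile grid to SVG and PNG, one panel per (covariate, stratum).

    The x axis holds the ordinal levels, equally spaced in declared order;
    CI whiskers are drawn when present; empty levels are drawn at 0 with a
    hollow marker; negatively posed covariates are coloured red, positively
    posed ones blue (driven by the ``polarity`` map).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    polarity = dict(polarity or {})
    covariates = list(dict.fromkeys(tidy["covariate"]))
    strata = list(dict.fromkeys(tidy["stratum"]))
    nrow, ncol = len(covariates), len(strata)
    fig, axes = plt.subplots(
        nrow,
        ncol,
        figsize=(max(3.2 * ncol, 4), max(2.6 * nrow, 3)),
        squeeze=False,
        sharey=True,
    )
    for i, cov in enumerate(covariates):
        for j, strat in enumerate(strata):
            ax = axes[i][j]
            cell = tidy[(tidy["covariate"] == cov) & (tidy["stratum"] == strat)]
            x = np.arange(len(cell))
            color = _panel_color(polarity.get(cov))
            filled = ~cell["empty"].to_numpy()
            if cell["ci_lo"].notna().any():
                yerr = np.vstack(
                    [
                        (cell["h"] - cell["ci_lo"]).clip(lower=0).fillna(0),
                        (cell["ci_hi"] - cell["h"]).clip(lower=0).fillna(0),
                    ]
                )
                ax.errorbar(x[filled], cell["h"].to_numpy()[filled],
                            yerr=yerr[:, filled], fmt="none", ecolor=color, capsize=3)
            ax.plot(x[filled], cell["h"].to_numpy()[filled], "o-", color=color)
            if (~filled).any():
                ax.plot(x[~filled], np.zeros((~filled).sum()), "o",
                        markerfacecolor="white", markeredgecolor=color)
            levels = cell["level"].tolist()
            ax.set_xticks(x, levels, rotation=90 if any("-" in l for l in levels) else 0)
            # separators between first-item groups of a fused covariate
            prefixes = [l.split("-")[0] for l in levels]
            for k in range(1, len(prefixes)):
                if prefixes[k] != prefixes[k - 1] and len(set(prefixes)) > 1 and "-" in levels[k]:
                    ax.axvline(k - 0.5, color="lightgray", lw=0.8, zorder=0)
            if i == 0:
                ax.set_title(strat, fontsize=9)
            if j == 0:
                ax.set_ylabel(f"H({cell['response'].iloc[0]} | {cov}=x) [{base_label}]", fontsize=8)
    fig.tight_layout()
    out = Path(out)
    paths = []
    for suffix in (".svg", ".png"):
        p = out.with_suffix(suffix)
        fig.savefig(p, bbox_inches="tight", dpi=150)
        paths.append(p)
    plt.close(fig)
    return paths
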