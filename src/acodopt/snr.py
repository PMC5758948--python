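"""Taguchi signal-to-noise analysis for the L9 codigestion experiment.

The quality statistic for every response here (biogas yield, biomethane
yield, soluble-COD removal) is the larger-the-better (LTB) S/N ratio

    S/N = -10 * log10( (1/n) * sum_i 1 / y_i**2 )        [dB]

computed per run over its replicates.  Because y enters squared, a negative
response (a COD-removal rate below zero in an inhibited digester) yields the
same S/N as its absolute value: the sign is silently discarded.  This module
reproduces that literal behavior by default while warning loudly, since an
inhibited run can thereby masquerade as a high-quality one; see
``negative_policy``.

Factor effects are the level means of the per-run S/N values: for a balanced
orthogonal array the mean S/N of the three runs holding factor F at level m
estimates the main effect of F at m.  Factors are ranked by the range
(max - min) of their three level means, and the per-response optimum is the
argmax level of each factor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .design import DesignTable, Formulation

__all__ = [
    "NegativeResponseWarning",
    "snr_ltb",
    "snr_ltb_from_moments",
    "snr_stb",
    "snr_ntb",
    "snr_table",
    "level_mean_snr",
    "FactorEffects",
    "effects_table",
    "optimal_formulation",
    "round_half_up",
]

NegativePolicy = Literal["literal", "exclude", "floor"]


class NegativeResponseWarning(UserWarning):
    """A negative response entered a larger-the-better S/N computation."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Report-facing rounding: decimal ties away from zero, as in the tables."""
    from decimal import ROUND_HALF_UP, Decimal
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _check_negatives(values: np.ndarray, policy: NegativePolicy,
                     floor_eps: float) -> np.ndarray:
    if np.any(values < 0):
        if policy == "literal":
            warnings.warn(
                "negative response value(s) in LTB S/N: squaring discards the "
                "sign, so inhibited runs can score as well as good ones",
                NegativeResponseWarning,
                stacklevel=3,
            )
            return values
        if policy == "exclude":
            kept = values[values >= 0]
            if kept.size == 0:
                raise ValueError("all values negative under policy 'exclude'")
            return kept
        if policy == "floor":
            return np.maximum(values, floor_eps)
        raise ValueError(f"unknown negative_policy {policy!r}")
    return values


def snr_ltb(
    values: Sequence[float],
    negative_policy: NegativePolicy = "literal",
    floor_eps: float = 1e-6,
) -> float:
    """Larger-the-better S/N ratio in dB over replicate measurements."""
    y = np.asarray(values, dtype=float)
    if y.size == 0:
        raise ValueError("snr_ltb requires at least one measurement")
    y = _check_negatives(y, negative_policy, floor_eps)
    if np.any(y == 0):
        raise ZeroDivisionError("snr_ltb undefined for a zero measurement")
    return float(-10.0 * np.log10(np.mean(1.0 / y**2)))


def snr_ltb_from_moments(mean: float, sd: float) -> float:
    """LTB S/N reconstructed from a replicate summary (mean, sd).

    Second-moment approximation

        S/N ~= 20*log10(m) - 10*log10(1 + 3*(s/m)**2)

    obtained by expanding E[1/y^2] around the mean; accurate to about
    +/-0.02 dB for coefficients of variation up to ~12 %.  This is the
    reconstruction path when only "mean +/- sd" summaries are published.
    """
    if mean <= 0:
        raise ValueError(f"moment approximation needs mean > 0, got {mean}")
    if sd < 0:
        raise ValueError(f"sd must be nonnegative, got {sd}")
    cv2 = (sd / mean) ** 2
    return float(20.0 * np.log10(mean) - 10.0 * np.log10(1.0 + 3.0 * cv2))


def snr_stb(values: Sequence[float]) -> float:
    """Smaller-the-better S/N: ``-10*log10(mean(y^2))`` in dB."""
    y = np.asarray(values, dtype=float)
    if y.size == 0:
        raise ValueError("snr_stb requires at least one measurement")
    return float(-10.0 * np.log10(np.mean(y**2)))


def snr_ntb(values: Sequence[float]) -> float:
    """Nominal-the-best S/N: ``10*log10(mean^2 / variance)`` in dB."""
    y = np.asarray(values, dtype=float)
    if y.size < 2:
        raise ValueError("snr_ntb requires at least two measurements")
    var = float(np.var(y, ddof=1))
    if var == 0:
        raise ZeroDivisionError("snr_ntb undefined for zero sample variance")
    return float(10.0 * np.log10(float(np.mean(y)) ** 2 / var))


def snr_table(
    run_table: pd.DataFrame,
    negative_policy: NegativePolicy = "literal",
) -> pd.DataFrame:
    """Per-run, per-response LTB S/N table (runs as index, responses columns).

    ``run_table`` is tidy with columns ``run_id``, ``response`` and either
    replicate columns ``rep1..repN`` or a ``mean``/``sd`` summary pair; rows
    with replicates use the exact formula, summary-only rows the moment
    approximation.
    """
    required = {"run_id", "response"}
    if not required.issubset(run_table.columns):
        raise ValueError(f"run table needs columns {sorted(required)}")
    rep_cols = [c for c in run_table.columns if c.startswith("rep")]
    out: dict[str, dict[int, float]] = {}
    for row in run_table.itertuples(index=False):
        reps = [getattr(row, c) for c in rep_cols]
        reps = [v for v in reps if pd.notna(v)]
        if reps:
            val = snr_ltb(reps, negative_policy=negative_policy)
        else:
            m, s = float(getattr(row, "mean")), float(getattr(row, "sd"))
            if m < 0:
                # moment path needs m > 0; mirror the literal squaring rule
                warnings.warn(
                    "negative mean in LTB S/N summary: using |mean|",
                    NegativeResponseWarning,
                    stacklevel=2,
                )
                m = abs(m)
            val = snr_ltb_from_moments(m, s)
        out.setdefault(row.response, {})[int(row.run_id)] = val
    df = pd.DataFrame(out).sort_index()
    df.index.name = "run_id"
    return df


def level_mean_snr(
    snr: pd.DataFrame,
    design: DesignTable,
    factor: str,
    level: int,
    response: str,
) -> float:
    """Mean S/N (dB) of the three runs holding ``factor`` at ``level``."""
    if response not in snr.columns:
        raise KeyError(f"unknown response {response!r}")
    runs = design.runs_at(factor, level)
    missing = [r for r in runs if r not in snr.index]
    if missing:
        raise ValueError(f"S/N table missing runs {missing} for {factor}{level}")
    return float(snr.loc[runs, response].mean())


@dataclass(frozen=True)
class FactorEffects:
    """Level means, ranges, ranks and best levels per factor and response.

    ``level_means``: tidy frame indexed by (response, factor) with columns
    ``level1..level3``, ``range``, ``rank``, ``best_level``.
    """

    table: pd.DataFrame

    def level_mean(self, response: str, factor: str, level: int) -> float:
        return float(self.table.loc[(response, factor), f"level{level}"])

    def rank(self, response: str, factor: str) -> int:
        return int(self.table.loc[(response, factor), "rank"])

    def ranks(self, response: str) -> dict[str, int]:
        sub = self.table.loc[response]
        return {f: int(sub.loc[f, "rank"]) for f in sub.index}

    def best_levels(self, response: str) -> tuple[int, ...]:
        sub = self.table.loc[response]
        return tuple(int(sub.loc[f, "best_level"]) for f in sub.index)

    @property
    def responses(self) -> list[str]:
        return list(self.table.index.get_level_values(0).unique())


def effects_table(snr: pd.DataFrame, design: DesignTable) -> FactorEffects:
    """Full factor-effects analysis of a 9-run S/N table.

    Ranks order factors by descending range of their level means; ties break
    by factor order (A before B ...).  ``best_level`` is the argmax level
    mean, ties resolved toward the lowest level index.
    """
    expected = set(design.run_ids)
    if set(snr.index) != expected:
        raise ValueError(
            f"S/N table must cover runs {sorted(expected)}, has {sorted(snr.index)}"
        )
    records = []
    for response in snr.columns:
        per_factor = []
        for f in design.factors:
            means = [level_mean_snr(snr, design, f.name, l, response)
                     for l in (1, 2, 3)]
            rng = max(means) - min(means)
            best = int(np.argmax(means)) + 1  # argmax takes the first maximum
            per_factor.append((f.name, means, rng, best))
        # rank by descending range; stable sort keeps factor order on ties
        order = sorted(range(len(per_factor)),
                       key=lambda i: -per_factor[i][2])
        ranks = {per_factor[i][0]: r + 1 for r, i in enumerate(order)}
        for name, means, rng, best in per_factor:
            records.append({
                "response": response,
                "factor": name,
                "level1": means[0],
                "level2": means[1],
                "level3": means[2],
                "range": rng,
                "rank": ranks[name],
                "best_level": best,
            })
    table = pd.DataFrame(records).set_index(["response", "factor"])
    return FactorEffects(table=table)


def optimal_formulation(effects: FactorEffects, response: str) -> Formulation:
    """Per-response Taguchi optimum: argmax level mean for every factor."""
    if response not in effects.responses:
        raise KeyError(f"no effects computed for response {response!r}")
    return Formulation(levels=effects.best_levels(response))
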