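"""Multiresponse optimization over the 81-point formulation grid.

A balanced orthogonal array supports an additive main-effects surrogate on
the raw response scale:

    y_hat(f) = y_bar + sum_F ( m_F(level_f) - y_bar )

where ``y_bar`` is the grand mean of the nine run means and ``m_F(l)`` the
mean response of the three runs holding factor F at level l.  The surrogate
is exact for purely additive effects and lets every one of the 3^4 = 81
candidate formulations be scored, not just the nine that were run.

Responses are combined Derringer–Suich style: each predicted response maps
to a desirability d in [0, 1] through a one-sided larger-is-better ramp,

    d(y) = clip((y - L) / (U - L), 0, 1) ** w

and candidates are ranked by the importance-weighted geometric mean D of
their per-response desirabilities (D = 0 as soon as any d = 0).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import DesignTable, Formulation, designation

__all__ = [
    "MainEffectsModel",
    "DesirabilitySpec",
    "fit_main_effects",
    "predict_response",
    "desirability",
    "overall_desirability",
    "optimize",
]


@dataclass(frozen=True)
class MainEffectsModel:
    """Additive main-effects surrogate for one response.

    ``level_means[factor]`` holds the three level means of the run means on
    the raw response scale; their average equals ``grand_mean`` for every
    factor (balance identity of the orthogonal array).
    """

    response: str
    grand_mean: float
    level_means: Mapping[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        for f, means in self.level_means.items():
            if len(means) != 3:
                raise ValueError(f"factor {f!r} needs 3 level means")


def fit_main_effects(
    run_means: Mapping[int, float] | Sequence[float] | pd.Series,
    design: DesignTable,
    response: str = "response",
) -> MainEffectsModel:
    """Fit the additive surrogate from the nine run means of one response."""
    if isinstance(run_means, pd.Series):
        means = {int(k): float(v) for k, v in run_means.items()}
    elif isinstance(run_means, Mapping):
        means = {int(k): float(v) for k, v in run_means.items()}
    else:
        vals = list(run_means)
        means = {i + 1: float(v) for i, v in enumerate(vals)}
    if set(means) != set(design.run_ids):
        raise ValueError(
            f"need run means for runs {sorted(design.run_ids)}, "
            f"got {sorted(means)}"
        )
    grand = float(np.mean([means[r] for r in design.run_ids]))
    level_means = {}
    for f in design.factors:
        level_means[f.name] = tuple(
            float(np.mean([means[r] for r in design.runs_at(f.name, l)]))
            for l in (1, 2, 3)
        )
    return MainEffectsModel(response=response, grand_mean=grand,
                            level_means=level_means)


def predict_response(model: MainEffectsModel, formulation: Formulation) -> float:
    """Additive prediction at an arbitrary formulation (raw response scale)."""
    total = model.grand_mean
    for (factor, means), level in zip(model.level_means.items(),
                                      formulation.levels):
        total += means[level - 1] - model.grand_mean
    return float(total)


@dataclass(frozen=True)
class DesirabilitySpec:
    """Larger-is-better desirability ramp for one response.

    ``lower``/``upper`` bound the ramp (d = 0 at or below lower, 1 at or
    above upper); ``weight`` is the ramp exponent; ``importance`` weights
    this response in the geometric mean.
    """

    response: str
    lower: float
    upper: float
    weight: float = 1.0
    importance: float = 1.0

    def __post_init__(self) -> None:
        if self.upper <= self.lower:
            raise ValueError(
                f"desirability bounds need upper > lower, got "
                f"[{self.lower}, {self.upper}]"
            )
        if self.weight <= 0 or self.importance <= 0:
            raise ValueError("weight and importance must be positive")

    @classmethod
    def from_observed(
        cls,
        response: str,
        run_means: Sequence[float],
        weight: float = 1.0,
        importance: float = 1.0,
    ) -> "DesirabilitySpec":
        """Bounds at the observed min/max of the run means (the default)."""
        vals = np.asarray(list(run_means), dtype=float)
        return cls(response=response, lower=float(vals.min()),
                   upper=float(vals.max()), weight=weight,
                   importance=importance)


def desirability(y: float, spec: DesirabilitySpec) -> float:
    """Per-response desirability in [0, 1] under the maximize ramp."""
    ramp = (y - spec.lower) / (spec.upper - spec.lower)
    return float(np.clip(ramp, 0.0, 1.0) ** spec.weight)


def overall_desirability(ds: Sequence[float],
                         importances: Sequence[float]) -> float:
    """Importance-weighted geometric mean; 0 if any component is 0.

    Invariant to a common rescaling of the importances.
    """
    d = np.asarray(ds, dtype=float)
    w = np.asarray(importances, dtype=float)
    if np.any(d == 0.0):
        return 0.0
    return float(np.exp(np.sum(w * np.log(d)) / np.sum(w)))


def optimize(
    models: Mapping[str, MainEffectsModel],
    specs: Mapping[str, DesirabilitySpec],
    top_k: int | None = None,
) -> pd.DataFrame:
    """Rank all 81 formulations by overall desirability.

    Returns a frame sorted by descending D (ties in designation-lexicographic
    order) with one row per formulation: the level indices, designation,
    predicted responses, per-response desirabilities and overall D.
    """
    missing = [r for r in specs if r not in models]
    if missing:
        raise ValueError(f"no fitted model for responses {missing}")
    responses = list(specs)
    rows = []
    for levels in itertools.product((1, 2, 3), repeat=4):
        f = Formulation(levels=levels)
        rec: dict[str, object] = {
            "designation": f.designation,
            **{f"{n}_level": l for n, l in zip("ABCD", levels)},
        }
        ds = []
        for r in responses:
            y = predict_response(models[r], f)
            d = desirability(y, specs[r])
            rec[f"pred_{r}"] = y
            rec[f"d_{r}"] = d
            ds.append(d)
        rec["overall_D"] = overall_desirability(
            ds, [specs[r].importance for r in responses]
        )
        rows.append(rec)
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["overall_D", "designation"], ascending=[False, True]
    ).reset_index(drop=True)
    if top_k is not None:
        df = df.head(top_k)
    return df
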