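"""Readers, writers and the top-level analysis pipeline.

The pipeline composes the package end to end: load (or receive) a nine-run
replicate table, compute per-run larger-the-better S/N ratios, derive the
factor-effects table and per-response Taguchi optima, fit the additive
main-effects surrogate, rank all 81 formulations by overall desirability,
and emit a self-contained JSON report.  Numeric fields carry full precision
plus 2-decimal display strings matching the conventional table layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from importlib.metadata import version, PackageNotFoundError
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import DesignTable, Formulation, build_l9, parse_designation
from .desirability import (DesirabilitySpec, fit_main_effects, optimize,
                           predict_response)
from .snr import (FactorEffects, effects_table, optimal_formulation,
                  round_half_up, snr_table)

__all__ = [
    "RunTableError",
    "load_run_table",
    "packaged_run_table",
    "packaged_design",
    "packaged_snr_table",
    "packaged_verification",
    "packaged_search_table",
    "write_run_table",
    "verification_summary",
    "AnalysisReport",
    "run_pipeline",
]

RUN_TABLE_REQUIRED = ("run_id", "response")


class RunTableError(ValueError):
    """Malformed run-table input; the message cites offending lines."""


def _package_version() -> str:
    try:
        return version("acodopt")
    except PackageNotFoundError:  # pragma: no cover - editable-install edge
        return "unknown"


def load_run_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a tidy run-table CSV.

    Columns: ``run_id``, ``response``, then either replicate columns
    ``rep1..repN`` or a ``mean``/``sd`` pair.  Duplicate (run, response)
    pairs, non-numeric cells and missing columns raise
    :class:`RunTableError` with the offending CSV line numbers.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise RunTableError(f"{path}: empty run-table file") from exc
    missing = [c for c in RUN_TABLE_REQUIRED if c not in df.columns]
    if missing:
        raise RunTableError(f"{path}: missing required columns {missing}")
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    if not rep_cols and not {"mean", "sd"}.issubset(df.columns):
        raise RunTableError(
            f"{path}: needs replicate columns rep1..repN or mean/sd columns"
        )
    value_cols = rep_cols + [c for c in ("mean", "sd") if c in df.columns]
    bad_lines = []
    for col in ["run_id"] + value_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        bad_lines.extend(int(i) + 2 for i in bad)  # +2: header + 1-based
        df[col] = coerced
    if bad_lines:
        raise RunTableError(
            f"{path}: non-numeric cells at CSV line(s) {sorted(set(bad_lines))}"
        )
    dup = df.duplicated(subset=["run_id", "response"], keep=False)
    if dup.any():
        lines = [int(i) + 2 for i in df.index[dup]]
        raise RunTableError(f"{path}: duplicate (run_id, response) at lines {lines}")
    df["run_id"] = df["run_id"].astype(int)
    return df


def write_run_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def packaged_run_table() -> pd.DataFrame:
    """The shipped nine-run screening summaries (mean ± sd per response)."""
    with resources.as_file(resources.files("acodopt.data") / "run_table.csv") as p:
        return load_run_table(p)


def packaged_design() -> pd.DataFrame:
    """The shipped L9 design layout with level indices and physical values."""
    return pd.read_csv(resources.files("acodopt.data") / "l9_design.csv")


def packaged_snr_table() -> pd.DataFrame:
    """The shipped per-run S/N values (dB) as published for the nine runs.

    These were computed from the study's unpublished triplicates; for the
    low-variance and single-replicate cells they match the reconstruction
    from the shipped mean/sd summaries, but for the high-variance negative
    COD-removal runs they cannot be rebuilt from summaries, so the factor
    effects of record are derived from this table.
    """
    df = pd.read_csv(resources.files("acodopt.data") / "snr_table.csv")
    return df.set_index("run_id")


def packaged_verification() -> pd.DataFrame:
    """Confirmation-run replicates at the selected optimum formulation."""
    return pd.read_csv(resources.files("acodopt.data") / "verification.csv")


def packaged_search_table() -> pd.DataFrame:
    """The shipped hidden-neuron candidate metrics table."""
    return pd.read_csv(
        resources.files("acodopt.data") / "hidden_neuron_search.csv"
    )


def verification_summary(replicates: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Replicate means of a confirmation experiment, with 2-dp display.

    ``replicates`` maps response name to its measured replicate values.
    """
    rows = []
    for response, values in replicates.items():
        vals = np.asarray(list(values), dtype=float)
        if vals.size == 0:
            raise ValueError(f"no replicates for response {response!r}")
        m = float(vals.mean())
        rows.append({
            "response": response,
            "n": int(vals.size),
            "mean": m,
            "mean_2dp": round_half_up(m, 2),
        })
    return pd.DataFrame(rows)


@dataclass
class AnalysisReport:
    """Self-contained result of one pipeline execution."""

    run_table: pd.DataFrame
    snr: pd.DataFrame
    effects: FactorEffects
    optima: dict[str, str]                    # response -> designation
    predictions_at: dict[str, dict[str, float]]
    ranking: pd.DataFrame
    verification: pd.DataFrame | None
    meta: dict

    def to_dict(self) -> dict:
        def disp(frame: pd.DataFrame) -> list[dict]:
            recs = frame.reset_index().to_dict(orient="records")
            for r in recs:
                for k, v in list(r.items()):
                    if isinstance(v, float):
                        r[f"{k}_2dp"] = f"{round_half_up(v, 2):.2f}"
            return recs

        return {
            "meta": self.meta,
            "inputs": self.run_table.to_dict(orient="records"),
            "snr_db": disp(self.snr),
            "effects": disp(self.effects.table),
            "optima": self.optima,
            "predictions_at_optimum": self.predictions_at,
            "ranking_top": disp(self.ranking.head(10)),
            "verification": (
                disp(self.verification) if self.verification is not None else None
            ),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True,
                          default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_pipeline(
    run_table: pd.DataFrame,
    design: DesignTable | None = None,
    specs: Mapping[str, DesirabilitySpec] | None = None,
    verification: pd.DataFrame | None = None,
    seed: int = 0,
) -> AnalysisReport:
    """Execute S/N -> effects -> optima -> desirability ranking -> report.

    Deterministic given inputs and seed; re-running on the report's echoed
    inputs reproduces it byte for byte.
    """
    design = design or build_l9()
    snr = snr_table(run_table)
    effects = effects_table(snr, design)
    optima = {
        r: optimal_formulation(effects, r).designation for r in snr.columns
    }

    # run means per response (from replicates when present, else summaries)
    rep_cols = [c for c in run_table.columns if c.startswith("rep")]
    def run_means(response: str) -> pd.Series:
        sub = run_table[run_table["response"] == response].set_index("run_id")
        if rep_cols and sub[rep_cols].notna().any(axis=None):
            return sub[rep_cols].mean(axis=1)
        return sub["mean"]

    models = {r: fit_main_effects(run_means(r), design, r) for r in snr.columns}
    if specs is None:
        specs = {
            r: DesirabilitySpec.from_observed(r, run_means(r).to_numpy())
            for r in snr.columns
        }
    ranking = optimize(models, specs)
    top = ranking.iloc[0]["designation"]
    f_top = Formulation(parse_designation(top))
    predictions_at = {
        "designation": top,
        **{r: predict_response(models[r], f_top) for r in snr.columns},
    }

    verif = None
    if verification is not None:
        verif = verification_summary({
            c: verification[c].to_numpy()
            for c in verification.columns if c != "replicate"
        })

    report = AnalysisReport(
        run_table=run_table,
        snr=snr,
        effects=effects,
        optima=optima,
        predictions_at=predictions_at,
        ranking=ranking,
        verification=verif,
        meta={
            "package": "acodopt",
            "version": _package_version(),
            "seed": seed,
            "responses": list(snr.columns),
        },
    )
    return report
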