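"""Process-chemistry metrics and digester-health diagnostics.

Covers the two derived quantities the study tracks alongside gas yields —
soluble-COD stabilization and free ammonia nitrogen (FAN) — plus rule-based
inhibition diagnostics over kinetic monitoring series (ammonia, volatile
fatty acids, pH).

FAN is the unionized, membrane-permeable ammonia fraction and the species
that actually inhibits methanogens; it is set by the NH4+/NH3 equilibrium,

    FAN = TAN * (1 + 10**(-pH) / 10**(-(0.09018 + 2729.92 / T)))**-1

with TAN the total ammonia nitrogen (mg/L) and T the temperature in Kelvin.
The exponent ``0.09018 + 2729.92/T`` is the temperature-dependent pKa of
ammonium, so FAN/TAN = 1 / (1 + 10**(pKa - pH)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KineticsRecord",
    "KINETICS_COLUMNS",
    "DiagnosticFlag",
    "DiagnosticsReport",
    "InhibitionThresholds",
    "UndefinedMetricError",
    "cods_stabilization",
    "clip_for_display",
    "free_ammonia",
    "celsius_to_kelvin",
    "diagnose",
]

#: Fixed CSV column order for kinetic monitoring series.
KINETICS_COLUMNS = (
    "time_d",
    "tan_mg_l",
    "fan_mg_l",
    "tvfa_mg_l",
    "acetic_mg_l",
    "propionic_mg_l",
    "butyric_mg_l",
    "valeric_mg_l",
    "temp_c",
    "ph",
)


class UndefinedMetricError(ValueError):
    """Raised when a metric is mathematically undefined for the input."""


@dataclass(frozen=True)
class KineticsRecord:
    """One observation of the nine monitored digestion variables.

    Concentrations in mg/L, temperature in °C, pH dimensionless.
    """

    tan: float
    fan: float
    tvfa: float
    acetic: float
    propionic: float
    butyric: float
    valeric: float
    temperature: float
    ph: float
    time_d: float = 0.0

    def __post_init__(self) -> None:
        conc = (self.tan, self.fan, self.tvfa, self.acetic,
                self.propionic, self.butyric, self.valeric)
        if any(c < 0 for c in conc):
            raise ValueError("concentrations must be nonnegative")
        if self.fan > self.tan:
            raise ValueError(f"FAN {self.fan} exceeds TAN {self.tan}")
        if not 0.0 <= self.ph <= 14.0:
            raise ValueError(f"pH {self.ph} outside [0, 14]")

    @property
    def tvfa_consistent(self) -> bool:
        # TVFA is measured independently of the acid profile, so a TVFA below
        # the largest single acid is suspicious but not impossible.
        return self.tvfa >= max(self.acetic, self.propionic,
                                self.butyric, self.valeric)


def cods_stabilization(cods_initial: float, cods_final: float) -> float:
    """Percent reduction of soluble COD over the digestion period.

    Returns ``100 * (CODsi - CODsf) / CODsi``.  Negative values are
    meaningful — they indicate net accumulation of hydrolyzed organics in an
    inhibited digester — and are *not* clipped here.
    """
    if cods_initial <= 0:
        raise UndefinedMetricError(
            f"initial soluble COD must be positive, got {cods_initial}"
        )
    if cods_final < 0:
        raise UndefinedMetricError(f"final soluble COD negative: {cods_final}")
    return (cods_initial - cods_final) / cods_initial * 100.0


def clip_for_display(cods_percent: float) -> float:
    """Floor negative stabilization values at zero for plots and summaries.

    Display convention only; the S/N analysis always works on the signed
    values.
    """
    return max(float(cods_percent), 0.0)


def celsius_to_kelvin(temp_c: float) -> float:
    return float(temp_c) + 273.15


def free_ammonia(tan: float, ph: float, temp_k: float) -> float:
    """Free (unionized) ammonia nitrogen, mg/L, from TAN, pH and T (Kelvin).

    Strictly increasing in pH and temperature, bounded by TAN.
    """
    if tan < 0:
        raise ValueError(f"TAN must be nonnegative, got {tan}")
    if temp_k <= 0:
        raise ValueError(f"temperature must be positive Kelvin, got {temp_k}")
    pka = 0.09018 + 2729.92 / temp_k
    # FAN/TAN = 1 / (1 + 10**(pKa - pH)); evaluated in log space for stability
    return tan / (1.0 + 10.0 ** (pka - ph))


@dataclass(frozen=True)
class InhibitionThresholds:
    """Rule thresholds for digester-stress diagnostics (all mg/L unless noted).

    Defaults follow values reported for chicken-manure codigestion systems:
    FAN above ~250 mg/L is toxic in mesophilic digesters at high solids
    (TS >= 10 %); thermophilic cultures tolerate more, with inhibition above
    ~700 mg/L; a propionate:acetate ratio over 1.4 together with acetate over
    800 mg/L signals imminent failure; TVFA above ~5000 mg/L marks rapid acid
    accumulation and above ~12000 mg/L enough acid to depress pH; TAN in
    roughly 1700–14000 mg/L has been reported as the undesirable band.
    """

    fan_mesophilic: float = 250.0
    fan_mesophilic_min_ts: float = 10.0  # % TS at which the rule applies
    fan_thermophilic: float = 700.0
    acetate_failure: float = 800.0
    propionate_acetate_ratio: float = 1.4
    tvfa_rapid: float = 5000.0
    tvfa_ph_suppression: float = 12000.0
    tan_low: float = 1700.0
    tan_high: float = 14000.0


@dataclass(frozen=True)
class DiagnosticFlag:
    name: str
    record_index: int
    value: float
    threshold: float
    detail: str = ""


@dataclass
class DiagnosticsReport:
    """Collection of raised stress flags, each citing record and threshold."""

    flags: list[DiagnosticFlag] = field(default_factory=list)

    @property
    def names(self) -> set[str]:
        return {f.name for f in self.flags}

    def __bool__(self) -> bool:
        return bool(self.flags)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "flag": f.name,
                    "record_index": f.record_index,
                    "value": f.value,
                    "threshold": f.threshold,
                    "detail": f.detail,
                }
                for f in self.flags
            ],
            columns=["flag", "record_index", "value", "threshold", "detail"],
        )


def diagnose(
    series: Sequence[KineticsRecord],
    ts_percent: float,
    regime: Literal["mesophilic", "thermophilic"],
    thresholds: InhibitionThresholds | None = None,
) -> DiagnosticsReport:
    """Scan a kinetic series for ammonia and VFA inhibition signatures.

    Each raised flag records the offending observation index, the value seen
    and the threshold it crossed.  A series strictly below every threshold
    yields an empty report.
    """
    if len(series) == 0:
        raise ValueError("diagnose requires a nonempty kinetics series")
    if regime not in ("mesophilic", "thermophilic"):
        raise ValueError(f"unknown regime {regime!r}")
    th = thresholds or InhibitionThresholds()
    rep = DiagnosticsReport()

    for i, rec in enumerate(series):
        if (
            regime == "mesophilic"
            and ts_percent >= th.fan_mesophilic_min_ts
            and rec.fan > th.fan_mesophilic
        ):
            rep.flags.append(DiagnosticFlag(
                "fan_mesophilic_toxic", i, rec.fan, th.fan_mesophilic,
                f"FAN toxic for mesophilic digestion at TS >= "
                f"{th.fan_mesophilic_min_ts}% (TS = {ts_percent}%)",
            ))
        if regime == "thermophilic" and rec.fan > th.fan_thermophilic:
            rep.flags.append(DiagnosticFlag(
                "fan_thermophilic_inhibition", i, rec.fan, th.fan_thermophilic,
                "FAN above thermophilic inhibition level",
            ))
        if rec.tan > 0 and not th.tan_low <= rec.tan <= th.tan_high:
            rep.flags.append(DiagnosticFlag(
                "tan_out_of_range", i, rec.tan, th.tan_low,
                f"TAN outside [{th.tan_low}, {th.tan_high}] mg/L band",
            ))
        if (
            rec.acetic > th.acetate_failure
            and rec.propionic > th.propionate_acetate_ratio * rec.acetic
        ):
            rep.flags.append(DiagnosticFlag(
                "acetate_propionate_failure", i,
                rec.propionic / rec.acetic, th.propionate_acetate_ratio,
                f"propionate:acetate ratio with acetate {rec.acetic} mg/L "
                f"> {th.acetate_failure} mg/L",
            ))
        if rec.tvfa > th.tvfa_rapid:
            rep.flags.append(DiagnosticFlag(
                "tvfa_rapid_increase", i, rec.tvfa, th.tvfa_rapid,
                "rapid VFA accumulation",
            ))
        if rec.tvfa > th.tvfa_ph_suppression:
            rep.flags.append(DiagnosticFlag(
                "tvfa_ph_suppression", i, rec.tvfa, th.tvfa_ph_suppression,
                "VFA level high enough to depress pH",
            ))
    return rep


def records_from_frame(df: pd.DataFrame) -> list[KineticsRecord]:
    """Build validated records from a kinetics table with the fixed header."""
    missing = [c for c in KINETICS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"kinetics table missing columns: {missing}")
    return [
        KineticsRecord(
            tan=row.tan_mg_l, fan=row.fan_mg_l, tvfa=row.tvfa_mg_l,
            acetic=row.acetic_mg_l, propionic=row.propionic_mg_l,
            butyric=row.butyric_mg_l, valeric=row.valeric_mg_l,
            temperature=row.temp_c, ph=row.ph, time_d=row.time_d,
        )
        for row in df.itertuples(index=False)
    ]
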