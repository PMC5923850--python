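"""Scenario library, case runner and reproduction reporting.

Each scenario describes one spill configuration: epidermis thickness,
porridge layer thickness and initial temperature, and the boundary schedule
(when the porridge is removed and when tempered-water cooling begins).  The
built-in library covers the systematic parameter study — porridge
temperature (65/70/75 °C), layer thickness (2/3/4 mm), epidermis thickness
(40/50/60 um), removal time (10/20/30 s), water cooling — plus two
near-processing-temperature spills (90 and 95 °C).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .config import NumericsConfig
from .damage import classify
from .materials import DamageKinetics, PerfusionModel
from .solver import TraceRecord, run_schedule

__all__ = [
    "Scenario",
    "CaseResult",
    "case_library",
    "run_case",
    "run_all",
    "REFERENCE_OMEGA",
]


@dataclass(frozen=True)
class Scenario:
    """One spill configuration and its boundary schedule.

    Times are seconds from the instant of the spill; ``t_off`` / ``t_cool``
    of ``None`` mean the porridge is never removed / water is never applied.
    """

    id: str
    epidermis_thickness: float = 60e-6  # m
    porridge_thickness: float = 3e-3  # m
    porridge_temperature: float = 70.0  # °C
    t_off: float | None = None  # s
    t_cool: float | None = None  # s
    t_end: float = 60.0  # s
    t_air: float = 20.0  # °C
    t_water: float = 15.0  # °C
    h_air: float = 10.0  # W/(m^2 K)
    h_water: float = 600.0  # W/(m^2 K)
    comment: str = ""

    def __post_init__(self) -> None:
        if self.t_off is not None and self.t_cool is not None:
            if not self.t_off < self.t_cool:
                raise ValueError("porridge removal must precede water cooling")
        for t_event in (self.t_off, self.t_cool):
            if t_event is not None and t_event > self.t_end:
                raise ValueError("event time beyond simulated duration")

    def extended(self, t_end: float) -> "Scenario":
        return replace(self, t_end=t_end)


@dataclass(frozen=True)
class CaseResult:
    """Outcome of one scenario run."""

    scenario: Scenario
    omega: float
    omega_60s: float
    peak_basal_temperature: float
    burn_class: str
    trace: TraceRecord

    def to_dict(self) -> dict:
        return {
            "case": self.scenario.id,
            "omega": self.omega,
            "omega_60s": self.omega_60s,
            "peak_basal_temperature_C": self.peak_basal_temperature,
            "burn_class": self.burn_class,
        }


def _s(id: str, comment: str, **kw) -> Scenario:
    return Scenario(id=id, comment=comment, **kw)


def case_library() -> dict[str, Scenario]:
    """The built-in scenario library (17 tabulated cases + 2 hot-spill sweeps)."""
    um = 1e-6
    mm = 1e-3
    lib = [
        _s("A", "Base case, 60 um epidermis, not removed"),
        _s("B", "5 °C warmer than the base case", porridge_temperature=75.0),
        _s("C", "5 °C colder than the base case", porridge_temperature=65.0),
        _s("D", "50 um epidermis", epidermis_thickness=50 * um),
        _s("E", "40 um epidermis", epidermis_thickness=40 * um),
        _s("F", "2.0 mm porridge layer", porridge_thickness=2 * mm),
        _s("G", "4.0 mm porridge layer", porridge_thickness=4 * mm),
        _s("H", "Porridge removal at 10 s", t_off=10.0),
        _s("I", "Removal 10 s, water cooling t > 20 s", t_off=10.0, t_cool=20.0),
        _s("J", "Removal 10 s, water cooling t > 11 s", t_off=10.0, t_cool=11.0),
        _s("K", "Porridge removal at 20 s", t_off=20.0),
        _s("L", "Porridge removal at 30 s", t_off=30.0),
        _s("M", "75 °C, porridge removal 10 s", porridge_temperature=75.0, t_off=10.0),
        _s("N", "75 °C, porridge removal at 20 s", porridge_temperature=75.0, t_off=20.0),
        _s("O", "75 °C, porridge removal at 30 s", porridge_temperature=75.0, t_off=30.0),
        _s(
            "P",
            "75 °C, removal at 30 s, water cooling t > 31 s",
            porridge_temperature=75.0,
            t_off=30.0,
            t_cool=31.0,
        ),
        _s(
            "Q",
            "75 °C, removal at 10 s, water cooling t > 11 s",
            porridge_temperature=75.0,
            t_off=10.0,
            t_cool=11.0,
        ),
        # near-processing-temperature spills, never removed
        _s("F9-90", "90 °C spill, not removed", porridge_temperature=90.0),
        _s("F9-95", "95 °C spill, not removed", porridge_temperature=95.0),
    ]
    return {s.id: s for s in lib}


#: Published basal-layer damage integrals at 60 s for the tabulated cases,
#: used by :func:`run_all` to report reproduction deviations.
REFERENCE_OMEGA: dict[str, float] = {
    "A": 0.444,
    "B": 2.591,
    "C": 0.075,
    "D": 0.491,
    "E": 0.549,
    "F": 0.206,
    "G": 0.642,
    "H": 0.103,
    "I": 0.103,
    "J": 0.101,
    "K": 0.239,
    "L": 0.338,
    "M": 0.599,
    "N": 1.421,
    "O": 2.009,
    "P": 1.985,
    "Q": 0.588,
}


def run_case(
    case_id: str | Scenario,
    numerics: NumericsConfig | None = None,
    perfusion: PerfusionModel | None = None,
    kinetics: DamageKinetics | None = None,
    out_dir: str | Path | None = None,
    snapshot_times: tuple[float, ...] = (),
) -> CaseResult:
    """Run one scenario (by library id or as a Scenario object).

    When ``out_dir`` is given, the time-series trace (CSV), any depth
    snapshots (CSV) and a JSON summary are written there.
    """
    if isinstance(case_id, Scenario):
        scenario = case_id
    else:
        library = case_library()
        if case_id not in library:
            raise KeyError(f"unknown case {case_id!r}; known: {sorted(library)}")
        scenario = library[case_id]
    trace = run_schedule(
        scenario,
        numerics=numerics,
        perfusion=perfusion,
        kinetics=kinetics,
        snapshot_times=snapshot_times,
    )
    result = CaseResult(
        scenario=scenario,
        omega=trace.omega,
        omega_60s=trace.omega_at(60.0),
        peak_basal_temperature=trace.peak_basal_temperature,
        burn_class=classify(trace.omega),
        trace=trace,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        trace.to_frame().to_csv(out / f"{scenario.id}_trace.csv", index=False)
        for t, profile in trace.snapshots.items():
            profile.to_csv(out / f"{scenario.id}_profile_{t:g}s.csv", index=False)
        (out / f"{scenario.id}_summary.json").write_text(
            json.dumps(result.to_dict(), indent=2)
        )
    return result


def run_all(
    numerics: NumericsConfig | None = None,
    perfusion: PerfusionModel | None = None,
    kinetics: DamageKinetics | None = None,
    case_ids: tuple[str, ...] | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Run the tabulated case library and report deviations from the
    published damage integrals.

    Returns a DataFrame with one row per case: simulated Omega at 60 s, the
    published value, the relative deviation and the burn class.
    """
    library = case_library()
    ids = case_ids if case_ids is not None else tuple(REFERENCE_OMEGA)
    rows = []
    for cid in ids:
        result = run_case(library[cid], numerics, perfusion, kinetics, out_dir=out_dir)
        ref = REFERENCE_OMEGA.get(cid)
        rows.append(
            {
                "case": cid,
                "comment": library[cid].comment,
                "omega_60s": result.omega_60s,
                "omega_published": ref,
                "relative_deviation": (
                    result.omega_60s / ref - 1.0 if ref else float("nan")
                ),
                "burn_class": result.burn_class,
                "peak_basal_temperature_C": result.peak_basal_temperature,
            }
        )
    df = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "reproduction.csv", index=False)
        (out / "reproduction.md").write_text(_markdown_report(df))
    return df


def _markdown_report(df: pd.DataFrame) -> str:
    lines = [
        "# Damage-integral reproduction",
        "",
        "| Case | Omega (sim, 60 s) | Omega (published) | Deviation | Class |",
        "|------|------------------:|------------------:|----------:|-------|",
    ]
    for _, r in df.iterrows():
        dev = (
            f"{100 * r.relative_deviation:+.1f}%"
            if pd.notna(r.relative_deviation)
            else "-"
        )
        lines.append(
            f"| {r['case']} | {r.omega_60s:.3f} | {r.omega_published if pd.notna(r.omega_published) else '-'} "
            f"| {dev} | {r.burn_class} |"
        )
    return "\n".join(lines) + "\n"
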