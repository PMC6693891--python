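"""Plausibility report: every mechanism's energy/force scale against the
thresholds that matter.

For each scenario the report evaluates seven candidate channel-activation
mechanisms and compares them to three literature comparator constants:
the thermal energy k_B·T at the scenario temperature, the ~1 pN
mechanosensitive-channel gating force, and the ~1 J/kg hyperthermia
loss-per-cycle benchmark. The comparators are carried as labelled
constants, never computed.

Outputs are deterministic: rows sorted, floats formatted to six
significant digits, so identical inputs give byte-identical files.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import mechanics, spin, thermo
from .constants import CHANNEL_GATING_FORCE, HYPERTHERMIA_LOSS_PER_CYCLE
from .params import Scenario
from .spin import DEFAULT_B_GRID

logger = logging.getLogger("magnetoferritin")

__all__ = ["MechanismResult", "Report", "run_report", "write_outputs"]

MECHANISMS = (
    "gradient_force",
    "interparticle_force",
    "torque",
    "diamagnetic_deformation",
    "magnetocaloric",
    "einstein_de_haas_energy",
    "einstein_de_haas_torque",
)


@dataclass(frozen=True)
class MechanismResult:
    """One mechanism evaluated on one scenario."""

    mechanism: str
    scenario: str
    value: float
    unit: str
    energy_equivalent: float = math.nan  # J, where an energy scale is defined
    ratio_to_kbt: float = math.nan
    exceeds_kbt: bool | None = None
    force_n: float = math.nan  # N, for force-type mechanisms
    exceeds_gating_force: bool | None = None


@dataclass
class Report:
    """All mechanism evaluations plus the supporting curve tables."""

    mechanisms: pd.DataFrame
    magnetization_curve: pd.DataFrame
    magnetocaloric_scan: pd.DataFrame
    thresholds: dict
    errors: list = dc_field(default_factory=list)


def _evaluate_scenario(s: Scenario) -> list[MechanismResult]:
    kbt = spin.thermal_energy(s.field.temperature)
    m_tot = spin.total_moment(s.particle, s.partition, s.field)
    m_sat = spin.saturation_moment(s.particle)
    ms = spin.saturation_magnetization(s.particle)
    results: list[MechanismResult] = []

    # External laboratory gradient pulling on the particle (negative control).
    f_ext = mechanics.gradient_pull_force(m_tot, s.field.external_gradient)
    results.append(
        MechanismResult(
            "gradient_force", s.label, f_ext, "N",
            force_n=f_ext,
            exceeds_gating_force=f_ext > CHANNEL_GATING_FORCE,
        )
    )

    # One particle's moment in the surface gradient of its saturated
    # neighbour (contact geometry).
    grad_surf = mechanics.surface_field_gradient(ms, s.particle.radius)
    f_pair = mechanics.gradient_pull_force(m_tot, grad_surf)
    results.append(
        MechanismResult(
            "interparticle_force", s.label, f_pair, "N",
            force_n=f_pair,
            exceeds_gating_force=f_pair > CHANNEL_GATING_FORCE,
        )
    )

    # Maximum torque on an anisotropic particle; its energy scale is m·B.
    torque = mechanics.max_torque(m_tot, s.field.b_field)
    results.append(
        MechanismResult(
            "torque", s.label, torque, "N·m",
            energy_equivalent=torque,  # N·m and J coincide for sin(θ)=1
            ratio_to_kbt=torque / kbt,
            exceeds_kbt=torque > kbt,
        )
    )

    if s.membrane is not None:
        b_particle = mechanics.pole_field(ms)
        b_total = mechanics.total_channel_field(s.field.b_field, b_particle)
        density = mechanics.diamagnetic_force_density(
            s.membrane.susceptibility, b_total, grad_surf
        )
        patch = mechanics.membrane_patch_force(density, s.membrane)
        d = mechanics.membrane_deformation(patch.pressure, s.membrane)
        results.append(
            MechanismResult(
                "diamagnetic_deformation", s.label, d, "m",
                force_n=patch.force,
                exceeds_gating_force=patch.force > CHANNEL_GATING_FORCE,
            )
        )

    mc = thermo.magnetocaloric_energy(s.particle, s.partition, s.field)
    results.append(
        MechanismResult(
            "magnetocaloric", s.label, mc.energy_transfer, "J",
            energy_equivalent=mc.energy_transfer,
            ratio_to_kbt=mc.ratio_to_kbt,
            exceeds_kbt=mc.energy_transfer > kbt,
        )
    )

    if s.edh is not None:
        de = thermo.edh_rotational_energy(s.particle, s.edh)
        results.append(
            MechanismResult(
                "einstein_de_haas_energy", s.label, de, "J",
                energy_equivalent=de,
                ratio_to_kbt=de / kbt,
                exceeds_kbt=de > kbt,
            )
        )
        gamma = thermo.edh_torque(m_sat, s.edh)
        results.append(
            MechanismResult(
                "einstein_de_haas_torque", s.label, gamma, "N·m",
                energy_equivalent=gamma,
                ratio_to_kbt=gamma / kbt,
                exceeds_kbt=gamma > kbt,
            )
        )
    return results


def run_report(scenarios: Sequence[Scenario]) -> Report:
    """Evaluate every mechanism over every scenario.

    Per-scenario failures are logged and collected in ``report.errors``,
    never fatal. An empty scenario set yields an empty (but well-formed)
    report.
    """
    rows: list[MechanismResult] = []
    errors: list[tuple[str, str]] = []
    for s in scenarios:
        t0 = time.perf_counter()
        try:
            rows.extend(_evaluate_scenario(s))
        except Exception as exc:  # noqa: BLE001 - report must survive bad scenarios
            logger.error("scenario %s failed: %s", s.label, exc)
            errors.append((s.label, str(exc)))
            continue
        logger.info(
            "scenario %s evaluated in %.1f ms",
            s.label,
            1e3 * (time.perf_counter() - t0),
        )

    columns = [
        "mechanism", "scenario", "value", "unit", "energy_equivalent",
        "ratio_to_kbt", "exceeds_kbt", "force_n", "exceeds_gating_force",
    ]
    mech_df = pd.DataFrame([r.__dict__ for r in rows], columns=columns)
    mech_df = mech_df.sort_values(["mechanism", "scenario"]).reset_index(drop=True)

    temps = sorted({s.field.temperature for s in scenarios})
    ns = sorted({s.partition.n_clusters for s in scenarios})
    if scenarios:
        particle = scenarios[0].particle
        temperature = temps[0]
        curve = spin.magnetization_curve(particle, ns, DEFAULT_B_GRID, temperature)
        scan = _magnetocaloric_scan(scenarios)
        kbt = spin.thermal_energy(temperature)
    else:
        curve = pd.DataFrame(
            columns=["n_clusters", "b_tesla", "moment_am2", "energy_joule",
                     "energy_over_kbt"]
        )
        scan = pd.DataFrame(
            columns=["n_clusters", "b_tesla", "x", "entropy_change_jk",
                     "energy_j", "ratio_kbt"]
        )
        kbt = math.nan

    thresholds = {
        "kbt_joule": kbt,
        "gating_force_newton": CHANNEL_GATING_FORCE,
        "hyperthermia_loss_j_per_kg": HYPERTHERMIA_LOSS_PER_CYCLE,
    }
    return Report(
        mechanisms=mech_df,
        magnetization_curve=curve,
        magnetocaloric_scan=scan,
        thresholds=thresholds,
        errors=errors,
    )


def _magnetocaloric_scan(scenarios: Sequence[Scenario]) -> pd.DataFrame:
    rows = []
    seen = set()
    for s in scenarios:
        key = (s.partition.n_clusters, s.field.b_field, s.field.temperature)
        if key in seen:
            continue
        seen.add(key)
        mc = thermo.magnetocaloric_energy(s.particle, s.partition, s.field)
        rows.append(
            {
                "n_clusters": mc.n_clusters,
                "b_tesla": s.field.b_field,
                "x": mc.reduced_field,
                "entropy_change_jk": mc.entropy_change,
                "energy_j": mc.energy_transfer,
                "ratio_kbt": mc.ratio_to_kbt,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["n_clusters", "b_tesla", "x", "entropy_change_jk",
                 "energy_j", "ratio_kbt"],
    )
    return df.sort_values(["n_clusters", "b_tesla"]).reset_index(drop=True)


def _round_sig(value, digits: int = 6):
    """Round to significant digits for stable JSON output."""
    if isinstance(value, float):
        if math.isnan(value):
            return None
        return float(f"{value:.{digits}g}")
    return value


def summary_dict(report: Report) -> dict:
    """JSON-ready summary: thresholds, mechanism rows, and a verdict list
    of which mechanisms exceed their comparator on any scenario."""
    records = []
    for rec in report.mechanisms.to_dict(orient="records"):
        records.append({k: _round_sig(v) for k, v in rec.items()})
    exceeding_kbt = sorted(
        report.mechanisms.loc[
            report.mechanisms["exceeds_kbt"] == True, "mechanism"  # noqa: E712
        ].unique()
    )
    exceeding_force = sorted(
        report.mechanisms.loc[
            report.mechanisms["exceeds_gating_force"] == True, "mechanism"  # noqa: E712
        ].unique()
    )
    return {
        "thresholds": {k: _round_sig(v) for k, v in report.thresholds.items()},
        "mechanisms": records,
        "mechanisms_exceeding_kbt": exceeding_kbt,
        "mechanisms_exceeding_gating_force": exceeding_force,
        "errors": report.errors,
    }


def write_outputs(report: Report, directory: str | Path, plots: bool = False) -> list[Path]:
    """Write the report artifacts into ``directory``.

    Always writes ``magnetization_curve.csv``, ``magnetocaloric_scan.csv``,
    ``mechanisms.csv`` and ``summary.json``; with ``plots=True`` adds PNG
    figures of the magnetization/energy curves and the magnetocaloric scan.
    Identical reports produce byte-identical CSV/JSON.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {directory}: {exc}") from exc

    written = []

    def _write_csv(df: pd.DataFrame, name: str) -> None:
        path = directory / name
        try:
            df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")
        except OSError as exc:
            raise OSError(f"cannot write {path}: {exc}") from exc
        written.append(path)

    _write_csv(report.magnetization_curve, "magnetization_curve.csv")
    _write_csv(report.magnetocaloric_scan, "magnetocaloric_scan.csv")
    _write_csv(report.mechanisms, "mechanisms.csv")

    summary_path = directory / "summary.json"
    try:
        summary_path.write_text(json.dumps(summary_dict(report), indent=2) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write {summary_path}: {exc}") from exc
    written.append(summary_path)

    if plots:
        from . import plotting

        written.append(
            plotting.plot_magnetization(
                report.magnetization_curve,
                report.thresholds["kbt_joule"],
                directory / "magnetization_curve.png",
            )
        )
        if not report.magnetocaloric_scan.empty:
            written.append(
                plotting.plot_magnetocaloric(
                    report.magnetocaloric_scan,
                    report.thresholds["kbt_joule"],
                    directory / "magnetocaloric_scan.png",
                )
            )
    return written
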