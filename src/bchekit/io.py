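"""CSV/JSON input-output and run configuration.

CSV dialect: comma-separated, UTF-8, '.' decimal, mandatory header row,
units encoded in column names.  Kinetics times are stored in seconds,
Caco-2 sample times in minutes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .adme import PermeabilityExperiment
from .dose_response import CensoredValue, DoseResponseTable, FourPLFit
from .exceptions import ParseError
from .fitting import FitResult
from .kinetics import AssayConditions, ProgressCurve, ProgressCurveSet

__all__ = [
    "RunConfig",
    "read_progress_csv",
    "write_progress_csv",
    "read_conditions_json",
    "write_conditions_json",
    "read_dose_response_csv",
    "write_dose_response_csv",
    "read_caco2_csv",
    "write_caco2_csv",
    "write_report",
]

PROGRESS_COLUMNS = ["time_s", "value", "value_kind", "inhibitor_nM", "replicate"]
DOSE_COLUMNS = ["conc_M", "ra_percent", "replicate"]
CACO2_COLUMNS = ["time_min", "acceptor_conc_uM", "direction", "replicate"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run; round-trips through JSON identically."""

    input_path: str = ""
    conditions_path: str = ""
    output_dir: str = "."
    scheme: str = "mixed"            # mixed | competitive | uncompetitive
    product_inhibition: bool = True
    multistart: int = 5
    seed: int | None = None
    noise_sigma: float = 0.0
    log_level: str = "INFO"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")


def write_conditions_json(conditions: AssayConditions, path: str | Path) -> None:
    Path(path).write_text(json.dumps(conditions.as_dict(), indent=2, sort_keys=True))


def read_conditions_json(path: str | Path) -> AssayConditions:
    return AssayConditions.from_dict(json.loads(Path(path).read_text()))


def write_progress_csv(curve_set: ProgressCurveSet, path: str | Path,
                       conditions_path: str | Path | None = None) -> None:
    rows = []
    for c in curve_set:
        kind = "absorbance" if c.absorbance is not None else "product_uM"
        values = c.signal
        for t, v in zip(c.times, values):
            rows.append((t, v, kind, c.inhibitor_conc, c.replicate_id))
    df = pd.DataFrame(rows, columns=PROGRESS_COLUMNS)
    df.to_csv(path, index=False)
    if conditions_path is not None:
        write_conditions_json(curve_set.conditions, conditions_path)


def read_progress_csv(path: str | Path, conditions_path: str | Path) -> ProgressCurveSet:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, PROGRESS_COLUMNS, path)
    conditions = read_conditions_json(conditions_path)
    curves = []
    for (inhibitor, replicate), grp in df.groupby(["inhibitor_nM", "replicate"], sort=True):
        kinds = grp["value_kind"].unique()
        if kinds.size != 1:
            raise ParseError(
                f"{path}: mixed value_kind within replicate {replicate!r} at I={inhibitor} nM"
            )
        kind = kinds[0]
        if kind not in ("absorbance", "product_uM"):
            raise ParseError(f"{path}: unknown value_kind {kind!r}")
        t = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            bad = int(grp.index[np.flatnonzero(np.diff(t) <= 0)[0] + 1]) + 2  # header + 1-based
            raise ParseError(f"{path}: non-monotone time at row {bad}")
        v = grp["value"].to_numpy(dtype=float)
        if kind == "absorbance":
            product = v / (conditions.epsilon * conditions.path_length * 1e-6)
            curve = ProgressCurve(times=t, product=product, absorbance=v,
                                  inhibitor_conc=float(inhibitor),
                                  replicate_id=str(replicate), is_noisy=True)
        else:
            curve = ProgressCurve(times=t, product=v, inhibitor_conc=float(inhibitor),
                                  replicate_id=str(replicate), is_noisy=True)
        curves.append(curve)
    curve_set = ProgressCurveSet(conditions=conditions, curves=curves)
    if not any(c.inhibitor_conc == 0 for c in curves):
        raise ParseError(f"{path}: no uninhibited (inhibitor_nM = 0) control curve present")
    return curve_set


def write_dose_response_csv(table: DoseResponseTable, path: str | Path) -> None:
    rep = table.replicate if table.replicate is not None else np.ones(table.concentrations.size, int)
    pd.DataFrame({
        "conc_M": table.concentrations,
        "ra_percent": table.ra_percent,
        "replicate": rep,
    }).to_csv(path, index=False)


def read_dose_response_csv(path: str | Path) -> DoseResponseTable:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, DOSE_COLUMNS, path)
    return DoseResponseTable(
        concentrations=df["conc_M"].to_numpy(float),
        ra_percent=df["ra_percent"].to_numpy(float),
        replicate=df["replicate"].to_numpy(),
    )


def write_caco2_csv(exp: PermeabilityExperiment, path: str | Path,
                    geometry_path: str | Path | None = None, replicate: int = 1) -> None:
    pd.DataFrame({
        "time_min": exp.sample_times,
        "acceptor_conc_uM": exp.acceptor_concs,
        "direction": exp.direction,
        "replicate": replicate,
    }).to_csv(path, index=False)
    if geometry_path is not None:
        Path(geometry_path).write_text(json.dumps({
            "donor_conc_C0_uM": exp.donor_conc_C0,
            "membrane_area_cm2": exp.membrane_area,
            "acceptor_volume_uL": exp.acceptor_volume,
            "donor_volume_uL": exp.donor_volume,
            "withdrawal_volume_uL": exp.withdrawal_volume,
            "replacement": exp.replacement,
        }, indent=2, sort_keys=True))


def read_caco2_csv(path: str | Path, geometry_path: str | Path) -> list[PermeabilityExperiment]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, CACO2_COLUMNS, path)
    geom = json.loads(Path(geometry_path).read_text())
    out = []
    for (direction, _rep), grp in df.groupby(["direction", "replicate"], sort=True):
        out.append(PermeabilityExperiment(
            direction=str(direction),
            donor_conc_C0=geom["donor_conc_C0_uM"],
            membrane_area=geom["membrane_area_cm2"],
            acceptor_volume=geom["acceptor_volume_uL"],
            donor_volume=geom["donor_volume_uL"],
            sample_times=grp["time_min"].to_numpy(float),
            acceptor_concs=grp["acceptor_conc_uM"].to_numpy(float),
            withdrawal_volume=geom.get("withdrawal_volume_uL", 0.0),
            replacement=geom.get("replacement", True),
        ))
    return out


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10
    return round(x, -int(floor(log10(abs(x)))) + sig - 1)


def write_report(
    path_prefix: str | Path,
    fit: FitResult | None = None,
    fourpl: FourPLFit | None = None,
    adme: dict | None = None,
    selectivity=None,
    config: RunConfig | None = None,
) -> dict:
    """Write a machine-readable JSON report plus a human-readable summary.

    IC50s are rounded to 2 significant figures and selectivity ratios to the
    nearest integer in the summary; the JSON keeps full precision.  Returns
    the report dictionary.
    """
    prefix = Path(path_prefix)
    report: dict = {"config": dataclasses.asdict(config) if config else None}
    lines: list[str] = ["# Analysis report", ""]
    if fit is not None:
        report["kinetics_fit"] = fit.as_dict()
        lines.append("## Global kinetics fit")
        lines.append("parameter  estimate  stderr  units")
        units = {"Km": "uM", "kcat": "1/s", "Kp": "uM", "Ki": "nM", "Kii": "nM"}
        for name, value in fit.estimates.as_dict().items():
            if value is None or name == "k_on":
                continue
            se = fit.standard_errors.get(name, float("nan"))
            lines.append(f"{name:<9} {value:>9.4g} {se:>7.2g}  {units.get(name, '')}")
        lines.append(f"RSS {fit.rss:.6g}   AICc {fit.aicc:.4g}   converged {fit.converged}")
        lines.append("")
    if fourpl is not None:
        report["dose_response"] = fourpl.as_dict()
        lines.append("## Dose-response (4PL)")
        lines.append(f"IC50 = {_round_sig(fourpl.ic50 * 1e9):g} nM  "
                     f"(hill {fourpl.hill:.2f}, top {fourpl.top:.1f}%, bottom {fourpl.bottom:.1f}%)")
        lines.append("")
    if selectivity is not None:
        if isinstance(selectivity, CensoredValue):
            report["selectivity_ratio"] = {"censor": selectivity.censor, "value": selectivity.value}
            lines.append(f"Selectivity ratio SR {selectivity.censor} {round(selectivity.value)}")
        else:
            report["selectivity_ratio"] = selectivity
            lines.append(f"Selectivity ratio SR = {round(selectivity)}")
        lines.append("")
    if adme is not None:
        report["adme"] = adme
        lines.append("## ADME")
        for k, v in adme.items():
            lines.append(f"{k}: {v:.4g}" if isinstance(v, float) else f"{k}: {v}")
        lines.append("")
    json_path = prefix.with_suffix(".json")
    txt_path = prefix.with_suffix(".txt")
    json_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    txt_path.write_text("\n".join(lines))
    return report
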