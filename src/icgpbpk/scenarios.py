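"""Cirrhosis, hepatectomy, clamping and dose scans.

A scan varies one scenario parameter over a grid, simulates the standard
0.5 mg/kg bolus for each value and collects the non-compartmental PK
parameters. Scans are the bridge between the mechanistic model and clinical
severity scales: the Child-Turcotte-Pugh classes map onto fixed composite
cirrhosis degrees, and a monotone scan can be inverted to recover the
scenario parameter that reproduces a clinically measured PK value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .nca import PKResults, pk_parameters
from .pbpk_core import ModelParameters
from .protocols import DosingProtocol, standard_bolus
from .simulator import default_grid, simulate

__all__ = [
    "CTP_FCIRRHOSIS",
    "ScanTable",
    "UnmappableError",
    "run_scan",
    "clamping_vs_resection",
    "invert_scan",
]

#: Child-Turcotte-Pugh class -> composite cirrhosis degree f_cirrhosis.
CTP_FCIRRHOSIS: dict[str, float] = {
    "control": 0.0,
    "mild": 0.41,      # CTP-A
    "moderate": 0.70,  # CTP-B
    "severe": 0.82,    # CTP-C
}

#: Scenario parameters admissible for scanning, with their ranges.
SCAN_RANGES: dict[str, tuple[float, float]] = {
    "f_cirrhosis": (0.0, 0.9),
    "f_shunts": (0.0, 0.9),
    "f_tissue_loss": (0.0, 0.9),
    "resection_rate": (0.0, 0.9),
    "f_bloodflow": (0.05, 2.0),
    "dose": (1.0, 500.0),  # mg
}

#: Default simulation horizon for scans [min]; covers the R20 sample and the
#: kel fit window with margin.
SCAN_T_END = 60.0
SCAN_DT = 0.1


class UnmappableError(ValueError):
    """A clinical value lies outside the attainable range of a scan."""


@dataclass
class ScanTable:
    """One scanned parameter, its grid, and per-value PK results."""

    parameter: str
    grid: np.ndarray
    results: list[PKResults]
    metadata: dict

    def values(self, pk_name: str) -> np.ndarray:
        """Column of one PK parameter (e.g. 'r15', 'cl', 'pdr', 't_half')."""
        return np.array([getattr(r, pk_name) for r in self.results])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for g, r in zip(self.grid, self.results):
            row = {self.parameter: g}
            row.update(
                {
                    k: getattr(r, k)
                    for k in ("kel", "pdr", "t_half", "auc_inf", "vd", "cl",
                              "r15", "r20", "c_max", "dose_mg")
                }
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _apply(scenario, parameter: str, value: float):
    if parameter == "f_cirrhosis":
        return scenario.with_cirrhosis(value)
    return replace(scenario, **{parameter: value})


def run_scan(
    parameter: str,
    grid,
    params: ModelParameters | None = None,
    protocol: DosingProtocol | None = None,
    t_end: float = SCAN_T_END,
    dt: float = SCAN_DT,
    **sim_kw,
) -> ScanTable:
    """Simulate the standard bolus across a parameter grid.

    ``f_cirrhosis`` sets shunts and tissue loss in lockstep; ``dose`` scans
    the bolus amount in mg instead of a scenario parameter.
    """
    if parameter not in SCAN_RANGES:
        raise ValueError(f"unknown scan parameter: {parameter!r}")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be one-dimensional and strictly increasing")
    lo, hi = SCAN_RANGES[parameter]
    if grid[0] < lo or grid[-1] > hi:
        raise ValueError(
            f"grid for {parameter} must lie within [{lo}, {hi}]"
        )
    if params is None:
        params = ModelParameters()
    if protocol is None:
        protocol = standard_bolus()
    tgrid = default_grid(t_end, dt)

    results = []
    for value in grid:
        if parameter == "dose":
            proto = DosingProtocol(
                [replace(protocol.events[0], amount=value, per_kg=False)]
            ).resolve(params.body)
            p = params
        else:
            proto = protocol
            p = replace(params, scenario=_apply(params.scenario, parameter, value))
        tc = simulate(p, proto, tgrid, **sim_kw)
        results.append(pk_parameters(tc))
    return ScanTable(
        parameter=parameter,
        grid=grid,
        results=results,
        metadata={"params": params, "protocol": protocol, "t_end": t_end, "dt": dt},
    )


def clamping_vs_resection(
    fractions,
    cirrhosis_degrees=(0.0, 0.41, 0.70, 0.82),
    params: ModelParameters | None = None,
    protocol: DosingProtocol | None = None,
    **sim_kw,
) -> dict[float, tuple[ScanTable, ScanTable]]:
    """Paired scans emulating intraoperative trial clamping vs hepatectomy.

    For each fraction x, one run reduces hepatic blood flow
    (f_bloodflow = 1 - x, the clamped inflow rerouted to the rest
    compartment) and one removes liver volume (resection_rate = x). Returns
    {cirrhosis degree: (clamping ScanTable, resection ScanTable)}; at x = 0
    the paired runs coincide.
    """
    fractions = np.asarray(fractions, dtype=float)
    if np.any((fractions < 0) | (fractions > 0.9)):
        raise ValueError("fractions must lie in [0, 0.9]")
    if params is None:
        params = ModelParameters()
    out = {}
    for fc in cirrhosis_degrees:
        base = replace(params, scenario=params.scenario.with_cirrhosis(fc))
        clamp_results, resect_results = [], []
        tgrid = default_grid(SCAN_T_END, SCAN_DT)
        proto = protocol if protocol is not None else standard_bolus()
        for x in fractions:
            s_clamp = replace(base.scenario, f_bloodflow=1.0 - x)
            s_res = replace(base.scenario, resection_rate=x)
            for s, acc in ((s_clamp, clamp_results), (s_res, resect_results)):
                tc = simulate(replace(base, scenario=s), proto, tgrid, **sim_kw)
                acc.append(pk_parameters(tc))
        meta = {"cirrhosis": fc}
        out[fc] = (
            ScanTable("clamped_fraction", fractions, clamp_results, meta),
            ScanTable("resection_rate", fractions, resect_results, meta),
        )
    return out


def invert_scan(scan: ScanTable, pk_name: str, clinical_value: float) -> float:
    """Map a clinically measured PK value back onto the scanned parameter.

    Uses piecewise-linear monotone interpolation of the scan curve; raises
    :class:`UnmappableError` when the value lies outside the attainable
    range.
    """
    y = scan.values(pk_name)
    x = scan.grid
    dy = np.diff(y)
    if np.all(dy >= 0):
        pass
    elif np.all(dy <= 0):
        x, y = x[::-1], y[::-1]
    else:
        raise UnmappableError(
            f"scan of {pk_name} vs {scan.parameter} is not monotone"
        )
    if not (y.min() <= clinical_value <= y.max()):
        raise UnmappableError(
            f"{pk_name} = {clinical_value} outside attainable range "
            f"[{y.min():.4g}, {y.max():.4g}]"
        )
    return float(np.interp(clinical_value, y, x))
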