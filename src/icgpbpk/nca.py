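"""Non-compartmental analysis of ICG plasma time courses.

The clinically reported ICG parameters all derive from the early,
monoexponential phase of plasma disappearance: the elimination rate constant
kel is the negative slope of a log-linear fit, PDR = 100·kel, half-life
t_1/2 = ln2/kel, AUC extrapolated to infinity by the trapezoidal rule plus a
c_last/kel tail, the apparent distribution volume Vd = D/(AUC_inf·kel),
clearance CL = Vd·kel, and the retention ratios R15 = c(15)/c_max and
R20 = c(20)/c_max.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

__all__ = ["PKResults", "NCAError", "fit_kel", "auc_infinity", "pk_parameters",
           "read_timecourse_csv"]

#: Default log-linear fit window [min] after dose start: the early
#: monoexponential phase over which clinical PDR is measured.
DEFAULT_WINDOW = (5.0, 15.0)


class NCAError(ValueError):
    """Time course unusable for non-compartmental analysis."""


@dataclass(frozen=True)
class PKResults:
    """Non-compartmental ICG pharmacokinetic parameters.

    Invariants: t_half·kel = ln 2 and CL = Vd·kel hold exactly by
    construction; R15 and R20 lie in [0, 1] for decaying curves.
    """

    kel: float        # elimination rate constant [1/min]
    pdr: float        # plasma disappearance rate [%/min]
    t_half: float     # half-life [min]
    auc_inf: float    # AUC extrapolated to infinity [mg*min/l]
    vd: float         # apparent volume of distribution [l]
    cl: float         # clearance [l/min]
    r15: float        # retention ratio at 15 min [-]
    r20: float        # retention ratio at 20 min [-]
    c_max: float      # maximum sampled concentration [mg/l]
    c0: float         # back-extrapolated intercept of the fit [mg/l]
    dose_mg: float    # administered dose [mg]
    window: tuple[float, float]  # kel fit window [min]
    r_squared: float  # quality of the log-linear fit [-]

    @property
    def cl_ml_min(self) -> float:
        return self.cl * 1000.0

    @property
    def r15_percent(self) -> float:
        return self.r15 * 100.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["window"] = list(self.window)
        d["cl_ml_min"] = self.cl_ml_min
        d["r15_percent"] = self.r15_percent
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _extract(tc) -> tuple[np.ndarray, np.ndarray]:
    """Accept a simulator TimeCourse or a (time, concentration) table in mg/l."""
    if hasattr(tc, "cve_mg_per_l"):
        return np.asarray(tc.time, float), np.asarray(tc.cve_mg_per_l, float)
    time, conc = tc
    return np.asarray(time, float), np.asarray(conc, float)


def fit_kel(
    tc, window: tuple[float, float] = DEFAULT_WINDOW
) -> tuple[float, float, float]:
    """Log-linear least-squares estimate of the elimination rate constant.

    Fits ln c = ln c0 - kel·t over the window; returns (kel [1/min],
    c0 [mg/l], R² of the fit). Requires at least three strictly positive
    samples inside the window.
    """
    time, conc = _extract(tc)
    lo, hi = window
    mask = (time >= lo) & (time <= hi)
    if mask.sum() < 3:
        raise NCAError(f"fewer than 3 samples in window [{lo}, {hi}] min")
    t, c = time[mask], conc[mask]
    if np.any(c <= 0):
        raise NCAError("non-positive concentrations inside the fit window")
    logc = np.log(c)
    slope, intercept = np.polyfit(t, logc, 1)
    resid = logc - (slope * t + intercept)
    ss_tot = np.sum((logc - logc.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return -slope, float(np.exp(intercept)), float(r2)


def auc_infinity(tc, kel: float) -> float:
    """Area under the curve [mg·min/l]: trapezoid over the observed span plus
    the monoexponential tail c_last/kel."""
    if kel <= 0:
        raise NCAError(f"kel must be positive for extrapolation, got {kel}")
    time, conc = _extract(tc)
    return float(np.trapezoid(conc, time) + conc[-1] / kel)


def _conc_at(time: np.ndarray, conc: np.ndarray, t: float) -> float:
    """Linear interpolation of the sampled curve at t (NaN outside range)."""
    if t < time[0] or t > time[-1]:
        return float("nan")
    return float(np.interp(t, time, conc))


def pk_parameters(
    tc,
    dose_mg: float | None = None,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> PKResults:
    """Full non-compartmental parameter set for one plasma time course.

    ``dose_mg`` may be omitted for simulator time courses, whose metadata
    carries the administered dose. c_max is the maximum of the sampled curve
    (not the back-extrapolated intercept).
    """
    if dose_mg is None:
        meta = getattr(tc, "metadata", None) or {}
        dose_mg = meta.get("dose_mg")
        if dose_mg is None:
            raise NCAError("dose_mg required for non-simulated time courses")
    if dose_mg <= 0:
        raise NCAError("dose must be positive")
    time, conc = _extract(tc)
    kel, c0, r2 = fit_kel((time, conc), window)
    auc = auc_infinity((time, conc), kel)
    vd = dose_mg / (auc * kel)
    cl = vd * kel
    c_max = float(conc.max())
    r15 = _conc_at(time, conc, 15.0) / c_max
    r20 = _conc_at(time, conc, 20.0) / c_max
    return PKResults(
        kel=float(kel),
        pdr=float(100.0 * kel),
        t_half=float(np.log(2) / kel),
        auc_inf=auc,
        vd=float(vd),
        cl=float(cl),
        r15=float(r15),
        r20=float(r20),
        c_max=c_max,
        c0=c0,
        dose_mg=float(dose_mg),
        window=(float(window[0]), float(window[1])),
        r_squared=r2,
    )


def read_timecourse_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read an observed time course from a two-column CSV
    (time_min, conc_mg_per_l)."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    if "time_min" in cols:
        t = df["time_min"].to_numpy(float)
        ccol = "conc_mg_per_l" if "conc_mg_per_l" in cols else cols[1]
        c = df[ccol].to_numpy(float)
    else:
        t = df.iloc[:, 0].to_numpy(float)
        c = df.iloc[:, 1].to_numpy(float)
    return t, c
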