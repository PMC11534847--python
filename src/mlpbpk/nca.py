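"""Non-compartmental analysis of a concentration-time profile.

Model-free PK parameters from a single-dose IV profile: the terminal
elimination rate constant kel (log-linear regression over the terminal
points), T1/2 = ln2/kel, AUC and AUMC by the linear-trapezoidal method with
the standard tail extrapolations, MRT = AUMC/AUC, CL = Dose/AUC(0-inf) and
Vdss = CL x MRT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["NCAResult", "NCAError", "fit_kel", "auc_aumc", "run_nca"]

TERMINAL_WINDOWS = range(3, 11)  # candidate terminal-fit sizes (last 3..10 points)


class NCAError(ValueError):
    pass


@dataclass
class NCAResult:
    kel: float          # 1/h
    t_half: float       # h
    auc_inf: float      # mg*h/L
    aumc_inf: float     # mg*h^2/L
    mrt: float          # h
    cl: float           # L/h
    vdss: float         # L
    auc_extrapolated_fraction: float
    cl_per_kg: float | None = None   # L/h/kg
    vdss_per_kg: float | None = None  # L/kg
    n_terminal: int | None = None


def _loglinear(times: np.ndarray, concs: np.ndarray) -> tuple[float, float]:
    """(slope, adjusted R^2) of ln(conc) vs time."""
    y = np.log(concs)
    slope, intercept = np.polyfit(times, y, 1)
    resid = y - (slope * times + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    n = times.size
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return slope, r2_adj


def fit_kel(times, concs, n_terminal: int | None = None) -> float:
    """Terminal elimination rate constant by log-linear regression.

    With ``n_terminal`` unset, the window with the best adjusted fit among
    the last 3..10 positive points is used.  Non-positive concentrations in
    the window shrink it (with a warning).
    """
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    pos = concs > 0
    first = int(np.argmax(pos)) if pos.any() else concs.size
    if (~pos[first:]).any():
        warnings.warn("non-positive concentrations excluded from terminal fit")
    t, c = times[pos], concs[pos]
    if t.size < 3:
        raise NCAError("need at least 3 positive terminal concentrations")
    if n_terminal is not None:
        k = min(n_terminal, t.size)
        if k < 3:
            raise NCAError("terminal window smaller than 3 usable points")
        slope, _ = _loglinear(t[-k:], c[-k:])
        return -slope
    best = None
    for k in TERMINAL_WINDOWS:
        if k > t.size:
            break
        slope, r2_adj = _loglinear(t[-k:], c[-k:])
        if best is None or r2_adj > best[1]:
            best = (slope, r2_adj, k)
    kel = -best[0]
    if kel <= 0:
        raise NCAError("terminal slope is non-negative; no elimination phase")
    return kel


def auc_aumc(times, concs, kel: float) -> tuple[float, float]:
    """AUC(0-inf) and AUMC(0-inf) by linear trapezoid plus tail.

    Tail: AUC += C_last/kel;  AUMC += C_last*t_last/kel + C_last/kel^2.
    """
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(concs < 0):
        raise ValueError("concentrations must be non-negative")
    auc_last = float(np.trapezoid(concs, times))
    aumc_last = float(np.trapezoid(concs * times, times))
    c_last, t_last = concs[-1], times[-1]
    auc_inf = auc_last + c_last / kel
    aumc_inf = aumc_last + c_last * t_last / kel + c_last / kel ** 2
    return auc_inf, aumc_inf


def run_nca(times, concs, dose: float, body_weight: float | None = None,
            n_terminal: int | None = None) -> NCAResult:
    """Full NCA of an IV concentration-time profile.

    ``dose`` in mg; concentrations in mg/L; times in h.  Per-kg clearance and
    distribution volume are reported when ``body_weight`` is given.
    """
    if dose <= 0:
        raise NCAError(f"dose must be positive, got {dose}")
    kel = fit_kel(times, concs, n_terminal=n_terminal)
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    auc_inf, aumc_inf = auc_aumc(times, concs, kel)
    tail = concs[-1] / kel
    mrt = aumc_inf / auc_inf
    cl = dose / auc_inf
    vdss = cl * mrt
    return NCAResult(
        kel=kel,
        t_half=float(np.log(2.0) / kel),
        auc_inf=auc_inf,
        aumc_inf=aumc_inf,
        mrt=mrt,
        cl=cl,
        vdss=vdss,
        auc_extrapolated_fraction=tail / auc_inf,
        cl_per_kg=cl / body_weight if body_weight else None,
        vdss_per_kg=vdss / body_weight if body_weight else None,
        n_terminal=n_terminal,
    )
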