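"""Effect-compartment inhibitory Emax pharmacodynamics.

A hypothetical effect compartment equilibrates with plasma at first-order
rate keo (dCe/dt = keo*(Cp - Ce)), introducing the observed hysteresis
between plasma concentration and analgesic response.  The response, as
percent of the pre-dose baseline (100%), follows an inhibitory Emax model
with full suppression achievable (Emax = 1):

    E(t) = 100 * (1 - Ce / (IC50 + Ce))

Metrics: Rmax (maximal percent reduction), TRmax (its time), AUCE (area
between baseline and response over 0-24 h) and T80_initial (first return to
80% of baseline after TRmax).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .drug import PDParams

__all__ = ["PDMetrics", "effect_compartment", "inhibitory_emax",
           "pd_metrics", "response_from_plasma"]


@dataclass
class PDMetrics:
    rmax: float          # max % reduction from baseline
    trmax: float         # h
    auce: float          # %*h over the evaluation window
    t80_initial: float   # h; 0 with flag if never below 80%
    below_80: bool = True

    def __post_init__(self):
        if not (0.0 <= self.rmax <= 100.0) or self.trmax < 0:
            raise ValueError("invalid PD metrics")


def effect_compartment(times, cp, keo: float) -> np.ndarray:
    """Effect-site concentration for a piecewise-linear plasma profile.

    Exact update over each interval (no additional discretization error
    beyond the linear interpolation of Cp); Ce(0) = 0.
    """
    if keo <= 0:
        raise ValueError("keo must be > 0")
    times = np.asarray(times, float)
    cp = np.asarray(cp, float)
    ce = np.zeros_like(cp)
    for i in range(1, len(times)):
        dt = times[i] - times[i - 1]
        e = np.exp(-keo * dt)
        slope = (cp[i] - cp[i - 1]) / dt
        # exact solution for Cp linear on the interval
        ce[i] = (ce[i - 1] * e + cp[i - 1] * (1 - e)
                 + slope * (dt - (1 - e) / keo))
    return ce


def inhibitory_emax(ce, params: PDParams) -> np.ndarray:
    """Response in % of baseline for effect-site concentration ``ce``."""
    ce = np.asarray(ce, float)
    if np.any(ce < 0):
        raise ValueError("Ce must be >= 0")
    out = params.baseline * (1.0 - ce / (params.ic50 + ce))
    return out if out.ndim else float(out)


def pd_metrics(times, response, window: float = 24.0,
               baseline: float = 100.0) -> PDMetrics:
    """Extract PD summary metrics from a response-time trajectory (% of
    baseline).  The trajectory must cover at least the evaluation window."""
    times = np.asarray(times, float)
    resp = np.asarray(response, float)
    if times[-1] < window - 1e-9:
        raise ValueError(f"trajectory must cover >= {window} h")
    m = times <= window + 1e-12
    t, e = times[m], resp[m]
    i_min = int(np.argmin(e))
    rmax = float(baseline - e[i_min])
    trmax = float(t[i_min])
    auce = float(np.trapezoid(baseline - e, t))
    after = (t > trmax) & (e >= 0.8 * baseline)
    below = bool(e.min() < 0.8 * baseline)
    if not below:
        t80 = 0.0
    else:
        idx = np.nonzero(after)[0]
        t80 = float(t[idx[0]]) if idx.size else float(t[-1])
    return PDMetrics(rmax=rmax, trmax=trmax, auce=auce, t80_initial=t80,
                     below_80=below)


def response_from_plasma(times, cp, params: PDParams) -> np.ndarray:
    """Convenience: plasma profile -> response profile."""
    return inhibitory_emax(effect_compartment(times, cp, params.keo), params)
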