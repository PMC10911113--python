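"""Melting curves, melting temperature, and heat capacity.

Two independent definitions of the melting temperature are provided:

* the temperature at which the melted fraction crosses 1/2 (monotone
  linear interpolation of the melting curve), and
* the maximum of the heat capacity C_v(T) = (<E^2> - <E>^2) / (k_B T^2)
  computed from potential-energy fluctuations (calorimetric
  definition), after Gaussian smoothing over the temperature ladder.

Uncertainties come from block averaging (>= 3 blocks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..units import KB


@dataclass
class MeltingCurve:
    temperatures: np.ndarray
    fraction_melted: np.ndarray
    tm: float
    tm_err: float


@dataclass
class HeatCapacityCurve:
    temperatures: np.ndarray
    cv: np.ndarray              # kcal/(mol K)
    tm: float
    tm_err: float


def _blocks(x: np.ndarray, n_blocks: int) -> list:
    n = len(x) // n_blocks
    return [x[i * n:(i + 1) * n] for i in range(n_blocks)] if n else [x]


def _tm_from_fraction(temps: np.ndarray, frac: np.ndarray) -> float:
    """Temperature of the 0.5 crossing, by monotone linear interpolation
    of the (isotonic-regressed) melting curve."""
    # enforce monotonicity: pool-adjacent-violators
    f = np.asarray(frac, float).copy()
    w = np.ones_like(f)
    i = 0
    vals = list(f)
    wts = list(w)
    pos = list(range(len(f)))
    out_v, out_w, out_n = [], [], []
    for v, wt in zip(vals, wts):
        out_v.append(v)
        out_w.append(wt)
        out_n.append(1)
        while len(out_v) > 1 and out_v[-2] > out_v[-1]:
            v2, w2, n2 = out_v.pop(), out_w.pop(), out_n.pop()
            v1, w1, n1 = out_v.pop(), out_w.pop(), out_n.pop()
            out_v.append((v1 * w1 + v2 * w2) / (w1 + w2))
            out_w.append(w1 + w2)
            out_n.append(n1 + n2)
    mono = np.repeat(out_v, out_n)
    if mono[0] >= 0.5:
        return float(temps[0])
    if mono[-1] <= 0.5:
        return float(temps[-1])
    i = int(np.searchsorted(mono, 0.5))
    t0, t1 = temps[i - 1], temps[i]
    f0, f1 = mono[i - 1], mono[i]
    if f1 == f0:
        return float(0.5 * (t0 + t1))
    return float(t0 + (0.5 - f0) * (t1 - t0) / (f1 - f0))


def melting_curve(temperatures, melted_samples: list,
                  n_blocks: int = 3) -> MeltingCurve:
    """Melted fraction against temperature and the Tm at half melting.

    ``melted_samples[t]`` is a boolean/0-1 array of per-sample melted
    states at ``temperatures[t]``.
    """
    temps = np.asarray(temperatures, float)
    if temps.size < 2:
        raise ValueError("need at least 2 temperatures")
    frac = np.array([np.mean(m) for m in melted_samples], float)
    tm = _tm_from_fraction(temps, frac)
    tms = []
    for b in range(n_blocks):
        fb = [np.mean(_blocks(np.asarray(m, float), n_blocks)[b])
              for m in melted_samples]
        tms.append(_tm_from_fraction(temps, np.array(fb)))
    return MeltingCurve(temps, frac, tm,
                        float(np.std(tms) / np.sqrt(max(1, n_blocks - 1))))


def heat_capacity(temperatures, energy_samples: list,
                  n_blocks: int = 3) -> HeatCapacityCurve:
    """C_v(T) from potential-energy fluctuations; Tm at the smoothed
    maximum (Gaussian kernel, bandwidth = ladder spacing)."""
    temps = np.asarray(temperatures, float)
    if temps.size < 2:
        raise ValueError("need at least 2 temperatures")

    def cv_of(samples_list):
        return np.array([np.var(np.asarray(e, float)) / (KB * t * t)
                         for e, t in zip(samples_list, temps)])

    def tm_of(cv):
        bw = float(np.mean(np.diff(temps))) or 1.0
        wm = np.exp(-0.5 * ((temps[:, None] - temps[None, :]) / bw) ** 2)
        smooth = (wm * cv[None, :]).sum(axis=1) / wm.sum(axis=1)
        i = int(np.argmax(smooth))
        # parabolic refinement on the smoothed curve
        if 0 < i < temps.size - 1:
            y0, y1, y2 = smooth[i - 1:i + 2]
            denom = (y0 - 2 * y1 + y2)
            if denom < 0:
                return float(temps[i] + 0.5 * (y0 - y2) / denom
                             * (temps[i + 1] - temps[i]))
        return float(temps[i])

    cv = cv_of(energy_samples)
    tms = []
    for b in range(n_blocks):
        cvb = cv_of([_blocks(np.asarray(e, float), n_blocks)[b]
                     for e in energy_samples])
        tms.append(tm_of(cvb))
    return HeatCapacityCurve(temps, cv, tm_of(cv),
                             float(np.std(tms) / np.sqrt(max(1, n_blocks - 1))))


def melting_analysis(temperatures, melted_samples: list,
                     energy_samples: list, n_blocks: int = 3):
    """Joint melting-curve + heat-capacity analysis of per-temperature
    ensembles (e.g. the output of replica exchange)."""
    return (melting_curve(temperatures, melted_samples, n_blocks),
            heat_capacity(temperatures, energy_samples, n_blocks))
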