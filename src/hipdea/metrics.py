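"""Osteoarthritis-predictive contact stress metrics over a gait sequence.

Eight scalars summarise the per-element acetabular contact stresses
p_{i,j} (element i, instance j) and element areas a_i across the t = 7
stance instances with time increment dt:

- absolute peak stress: max over cycle of the per-instance peak (MPa)
- average peak stress: mean over instances of the per-instance peak (MPa)
- peak stress-time dose: max over elements of sum_j p_{i,j} dt (MPa*s)
- average contact area: mean contacting area fraction, % of total area
- average stress: mean over instances of the area-weighted mean stress over
  contacting elements (MPa)
- average suprathreshold area: like contact area but counting elements with
  stress > 9.5 MPa (%)
- Maxian overdose: time-accumulated area-weighted mean of stresses > 6 MPa
  (MPa*s)
- suprathreshold elevated (STE) contact area: % of the ever-above-4-MPa area
  whose cumulative stress-time dose exceeds 5.5 MPa*s

All thresholds are strict (">") including the > 0 MPa contact criterion;
empty threshold sets contribute zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dea import GaitStressSequence


@dataclass
class MetricThresholds:
    suprathreshold_stress: float = 9.5  # MPa
    maxian_stress: float = 6.0  # MPa
    ste_dose: float = 5.5  # MPa*s
    ste_stress: float = 4.0  # MPa

    def __post_init__(self) -> None:
        if min(self.suprathreshold_stress, self.maxian_stress, self.ste_dose,
               self.ste_stress) <= 0:
            raise ValueError("thresholds must be positive")


METRIC_NAMES = [
    "absolute_peak_stress",
    "average_peak_stress",
    "peak_stress_time_dose",
    "average_contact_area",
    "average_stress",
    "average_suprathreshold_area",
    "maxian_overdose",
    "ste_contact_area",
]


@dataclass
class MetricSet:
    absolute_peak_stress: float  # MPa
    average_peak_stress: float  # MPa
    peak_stress_time_dose: float  # MPa*s
    average_contact_area: float  # %
    average_stress: float  # MPa
    average_suprathreshold_area: float  # %
    maxian_overdose: float  # MPa*s
    ste_contact_area: float  # %

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _check(seq: GaitStressSequence) -> tuple[np.ndarray, np.ndarray]:
    if seq.t == 0:
        raise ValueError("empty stress sequence")
    return seq.stresses, seq.areas


def absolute_peak_stress(seq: GaitStressSequence, thr: MetricThresholds | None = None) -> float:
    p, _ = _check(seq)
    return float(p.max(initial=0.0))


def average_peak_stress(seq: GaitStressSequence, thr: MetricThresholds | None = None) -> float:
    p, _ = _check(seq)
    return float(p.max(axis=1, initial=0.0).mean())


def peak_stress_time_dose(seq: GaitStressSequence, thr: MetricThresholds | None = None) -> float:
    p, _ = _check(seq)
    dose = p.sum(axis=0) * seq.dt
    return float(dose.max(initial=0.0))


def average_contact_area(seq: GaitStressSequence, thr: MetricThresholds | None = None) -> float:
    p, a = _check(seq)
    contacting = (p > 0.0) @ a
    return float(100.0 * contacting.sum() / (seq.total_area * seq.t))


def average_stress(seq: GaitStressSequence, thr: MetricThresholds | None = None) -> float:
    p, a = _check(seq)
    out = 0.0
    for j in range(seq.t):
        mask = p[j] > 0.0
        denom = a[mask].sum()
        if denom > 0:
            out += float((p[j][mask] * a[mask]).sum() / denom)
    return out / seq.t


def average_suprathreshold_area(seq: GaitStressSequence, thr: MetricThresholds | None = None) -> float:
    thr = thr or MetricThresholds()
    p, a = _check(seq)
    above = (p > thr.suprathreshold_stress) @ a
    return float(100.0 * above.sum() / (seq.total_area * seq.t))


def maxian_overdose(seq: GaitStressSequence, thr: MetricThresholds | None = None) -> float:
    thr = thr or MetricThresholds()
    p, a = _check(seq)
    out = 0.0
    for j in range(seq.t):
        mask = p[j] > thr.maxian_stress
        denom = a[mask].sum()
        if denom > 0:
            out += float((p[j][mask] * a[mask]).sum() / denom) * seq.dt
    return out


def ste_contact_area(seq: GaitStressSequence, thr: MetricThresholds | None = None) -> float:
    thr = thr or MetricThresholds()
    p, a = _check(seq)
    ever_loaded = (p > thr.ste_stress).any(axis=0)
    denom = a[ever_loaded].sum()
    if denom <= 0:
        return 0.0
    dose = p.sum(axis=0) * seq.dt
    # explicit intersection with the denominator set: at extreme dt an
    # element could exceed the dose threshold without ever topping the
    # instantaneous one, and the ratio must stay a fraction of that area
    num = a[(dose > thr.ste_dose) & ever_loaded].sum()
    return float(100.0 * num / denom)


_METRIC_FUNCS = {
    "absolute_peak_stress": absolute_peak_stress,
    "average_peak_stress": average_peak_stress,
    "peak_stress_time_dose": peak_stress_time_dose,
    "average_contact_area": average_contact_area,
    "average_stress": average_stress,
    "average_suprathreshold_area": average_suprathreshold_area,
    "maxian_overdose": maxian_overdose,
    "ste_contact_area": ste_contact_area,
}


def compute_all(seq: GaitStressSequence, thr: MetricThresholds | None = None) -> MetricSet:
    thr = thr or MetricThresholds()
    return MetricSet(**{name: f(seq, thr) for name, f in _METRIC_FUNCS.items()})
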