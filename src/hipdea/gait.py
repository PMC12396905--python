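"""Gait loading profiles and stance-phase discretization.

A gait loading profile (GLP) is a stance-phase time series of the hip joint
reaction force (JRF, % body weight, pelvis frame: +X anterior, +Y superior,
+Z lateral) and the three hip angles (flexion-extension, abduction-adduction,
internal-external rotation, degrees). Profiles are synchronised on their two
stance load peaks (heel strike, push off) and discretized into seven evenly
spaced quasistatic load instances with heel strike and push off as instances
2 and 6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

GRAVITY = 9.81  # m/s^2; converts kg body weight to N

GLP_COLUMNS = ["time", "fx", "fy", "fz", "flex", "abd", "rot"]


class GaitValidationError(ValueError):
    """Raised for malformed loading profiles."""


@dataclass
class GaitLoadingProfile:
    """JRF (%BW) and hip angles over the stance phase (time in [0, 1])."""

    name: str
    time: np.ndarray
    jrf: np.ndarray  # (n, 3) %BW
    angles: np.ndarray  # (n, 3) degrees

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.jrf = np.asarray(self.jrf, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.time.ndim != 1 or len(self.time) < 5:
            raise GaitValidationError("need at least 5 samples")
        if np.any(np.diff(self.time) <= 0):
            raise GaitValidationError("time must be strictly increasing")
        if abs(self.time[0]) > 1e-9 or abs(self.time[-1] - 1.0) > 1e-9:
            raise GaitValidationError("time must span [0, 1]")
        if self.jrf.shape != (len(self.time), 3) or self.angles.shape != self.jrf.shape:
            raise GaitValidationError("jrf and angles must be (n, 3)")
        # peak structure is required for synchronisation to be defined
        detect_peaks(self)

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.jrf, axis=1)

    def interpolate(self, t) -> tuple[np.ndarray, np.ndarray]:
        """Linear interpolation of (jrf, angles) at stance fraction(s) t."""
        t = np.asarray(t, dtype=float)
        if np.any(t < -1e-12) or np.any(t > 1.0 + 1e-12):
            raise GaitValidationError("query outside stance phase [0, 1]")
        t = np.clip(t, 0.0, 1.0)
        jrf = np.stack([np.interp(t, self.time, self.jrf[:, k]) for k in range(3)], axis=-1)
        ang = np.stack([np.interp(t, self.time, self.angles[:, k]) for k in range(3)], axis=-1)
        return jrf, ang


@dataclass
class LoadInstance:
    """One quasistatic load instance of a discretized stance phase."""

    index: int  # 1..7; 2 = heel strike, 6 = push off
    time: float  # stance fraction
    force: np.ndarray  # N, pelvis frame
    angles: np.ndarray  # degrees (flex, abd, rot)
    dt: float  # s, uniform inter-instance interval

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float).reshape(3)
        self.angles = np.asarray(self.angles, dtype=float).reshape(3)
        if not 1 <= self.index <= 7:
            raise GaitValidationError("instance index must be in 1..7")
        if self.dt <= 0:
            raise GaitValidationError("dt must be positive")


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------


def read_glp(path, name: str | None = None) -> GaitLoadingProfile:
    """Read a GLP CSV with columns time, fx, fy, fz, flex, abd, rot."""
    df = pd.read_csv(path)
    missing = [c for c in GLP_COLUMNS if c not in df.columns]
    if missing:
        raise GaitValidationError(f"GLP file missing columns: {missing}")
    return GaitLoadingProfile(
        name or str(path),
        df["time"].to_numpy(),
        df[["fx", "fy", "fz"]].to_numpy(),
        df[["flex", "abd", "rot"]].to_numpy(),
    )


def write_glp(glp: GaitLoadingProfile, path) -> None:
    pd.DataFrame(
        np.column_stack([glp.time, glp.jrf, glp.angles]), columns=GLP_COLUMNS
    ).to_csv(path, index=False)


# --------------------------------------------------------------------------
# synthetic profile families
# --------------------------------------------------------------------------

#: Family defaults. Peaks are %BW at heel strike / push off; ``medial_deg``
#: tilts the JRF from vertical toward medial (-Z), ``anterior_deg`` toward
#: anterior (+X); flexion runs from ``flex_hs`` at heel strike to ``flex_po``
#: (negative = extension) late in stance. The ordering encodes the
#: literature contrasts: the instrumented-implant-like family has the lowest
#: overall JRF; the dysplastic "harris"-like family the largest medial share;
#: the dysplastic "skalshoi"-like family the largest vertical share, highest
#: JRF and the least extension excursion.
GLP_FAMILIES: dict[str, dict] = {
    "bergmann_like": dict(
        peaks=(233.0, 205.0), valley=120.0, medial_deg=17.0, anterior_deg=4.0,
        flex_hs=25.0, flex_po=-15.0,
    ),
    "harris_like": dict(
        peaks=(285.0, 255.0), valley=150.0, medial_deg=28.0, anterior_deg=5.0,
        flex_hs=28.0, flex_po=-12.0,
    ),
    "skalshoi_like": dict(
        peaks=(320.0, 290.0), valley=165.0, medial_deg=12.0, anterior_deg=5.0,
        flex_hs=25.0, flex_po=-4.0,
    ),
}


def synth_glp(
    family: str,
    params: dict | None = None,
    seed: int | None = None,
    n_samples: int = 101,
    t_hs: float = 0.22,
    t_po: float = 0.78,
    jitter: float = 0.0,
) -> GaitLoadingProfile:
    """Generate a double-bump synthetic GLP for one of the three families.

    The magnitude is two smooth stance pulses over a mid-stance valley; the
    direction is the family's medial/anterior tilt from vertical (constant in
    stance up to a mild modulation). ``jitter`` adds seeded Gaussian noise
    (%BW) to the force components for robustness studies.
    """
    if family not in GLP_FAMILIES:
        raise GaitValidationError(f"unknown GLP family {family!r}")
    p = dict(GLP_FAMILIES[family])
    if params:
        p.update(params)

    t = np.linspace(0.0, 1.0, n_samples)
    width = 0.12
    base = p["valley"] * np.sin(np.pi * t)  # load shedding at stance edges
    bump1 = (p["peaks"][0] - p["valley"] * np.sin(np.pi * t_hs)) * np.exp(
        -0.5 * ((t - t_hs) / width) ** 2
    )
    bump2 = (p["peaks"][1] - p["valley"] * np.sin(np.pi * t_po)) * np.exp(
        -0.5 * ((t - t_po) / width) ** 2
    )
    mag = base + bump1 + bump2  # peak magnitudes land on the family %BW peaks

    med = np.deg2rad(p["medial_deg"])
    ant = np.deg2rad(p["anterior_deg"])
    direction = np.array(
        [np.sin(ant), np.cos(ant) * np.cos(med), -np.cos(ant) * np.sin(med)]
    )
    jrf = mag[:, None] * direction[None, :]
    if jitter > 0:
        rng = np.random.default_rng(seed)
        jrf = jrf + rng.normal(0.0, jitter, jrf.shape)

    flex = p["flex_hs"] + (p["flex_po"] - p["flex_hs"]) * t
    abd = 3.0 * np.sin(2.0 * np.pi * t)
    rot = np.zeros_like(t)
    return GaitLoadingProfile(family, t, jrf, np.column_stack([flex, abd, rot]))


# --------------------------------------------------------------------------
# peak detection and discretization
# --------------------------------------------------------------------------


def detect_peaks(glp_or_mag, time: np.ndarray | None = None) -> tuple[float, float]:
    """Locate the heel-strike and push-off peaks of |JRF|.

    Returns the stance fractions of the first and last prominent local
    maxima. Raises when fewer than two prominent maxima exist (the
    double-bump invariant).
    """
    if isinstance(glp_or_mag, GaitLoadingProfile):
        mag = glp_or_mag.magnitude
        time = glp_or_mag.time
    else:
        mag = np.asarray(glp_or_mag, dtype=float)
        if time is None:
            raise ValueError("time array required with raw magnitudes")
    prominence = 0.05 * (mag.max() - mag.min() + 1e-12)
    idx, _ = find_peaks(mag, prominence=prominence)
    if len(idx) < 2:
        raise GaitValidationError("fewer than two prominent load peaks")
    return float(time[idx[0]]), float(time[idx[-1]])


def discretize(
    glp: GaitLoadingProfile,
    body_weight_kg: float,
    stance_duration_s: float = 0.6,
) -> list[LoadInstance]:
    """Discretize a stance phase into 7 load instances anchored on its peaks.

    Spacing is (t_po - t_hs)/4; instance k sits at t_hs + (k-2)*spacing so
    heel strike and push off are instances 2 and 6. Forces are scaled to
    newtons from %BW; dt = spacing * stance_duration.
    """
    if body_weight_kg <= 0:
        raise GaitValidationError("body weight must be positive")
    if stance_duration_s <= 0:
        raise GaitValidationError("stance duration must be positive")
    t_hs, t_po = detect_peaks(glp)
    spacing = (t_po - t_hs) / 4.0
    grid_res = float(np.min(np.diff(glp.time)))
    if spacing < grid_res:
        raise GaitValidationError("load peaks too close to discretize")

    times = t_hs + (np.arange(1, 8) - 2) * spacing
    clipped = np.clip(times, 0.0, 1.0)
    if np.any(np.abs(clipped - times) > 1e-12):
        warnings.warn("instance times clipped to the stance phase", stacklevel=2)
    jrf, ang = glp.interpolate(clipped)
    force = jrf / 100.0 * body_weight_kg * GRAVITY
    dt = spacing * stance_duration_s
    return [
        LoadInstance(k + 1, float(clipped[k]), force[k], ang[k], dt) for k in range(7)
    ]
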