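"""Quantitative Western blot analysis.

Band signals from known masses of purified protein define a standard
curve (ordinary least squares, signal as response).  Lysate-lane signals
are inverse-interpolated through that curve to a mass, and dividing by
the µg of total protein loaded gives the abundance in ng/µg.  Only lanes
whose inverse-predicted mass falls inside the standards' mass range are
used ("linear range" rule); out-of-range lanes raise
:class:`~abpcensus.errors.OutOfLinearRangeError` and are excluded (and
logged) by the batch pipeline.

A GFP-intensity calibration line (intensity as a function of µM
concentration, fitted on proteins quantified by both methods) lets
fluorescence measurements stand in where no antibody exists.

The synthetic fixture generator emulates a blot with a hidden linear
signal-mass response plus Gaussian densitometry noise and known ng/µg
ground truth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import LinearModel
from .errors import (
    BelowCalibrationError,
    DegenerateDesignError,
    OutOfLinearRangeError,
    ValidationError,
)

__all__ = [
    "BlotLane",
    "CalibrationPair",
    "BlotGroundTruth",
    "aggregate_replicates",
    "fit_gfp_calibration",
    "fit_standard_curve",
    "generate_blot_fixture",
    "predict_concentration_from_gfp",
    "quantify_blot",
    "quantify_lysate",
    "read_lanes",
    "write_lanes",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BlotLane:
    """One gel lane: a purified-protein standard or a lysate sample.

    ``loaded_mass`` is ng of purified protein for standards and µg of
    total protein for lysates; ``signal`` is the densitometry band
    intensity in arbitrary units.
    """

    label: str
    kind: str  # "standard" | "lysate"
    loaded_mass: float
    signal: float

    def __post_init__(self) -> None:
        if self.kind not in ("standard", "lysate"):
            raise ValidationError(f"unknown lane kind {self.kind!r}")
        if not self.loaded_mass > 0:
            raise ValidationError("loaded_mass must be > 0")
        if self.signal < 0:
            raise ValidationError("signal must be >= 0")


@dataclass(frozen=True)
class CalibrationPair:
    """Per-cell GFP intensity paired with a Western-blot concentration."""

    gfp_intensity: float
    western_conc: float

    def __post_init__(self) -> None:
        if self.gfp_intensity < 0 or self.western_conc < 0:
            raise ValidationError("calibration values must be >= 0")


@dataclass(frozen=True)
class BlotGroundTruth:
    """Generator-side record of a synthetic blot fixture."""

    true_abundance: float
    slope: float
    intercept: float
    noise_sd: float
    seed: int


def _fit_line(x: np.ndarray, y: np.ndarray) -> LinearModel:
    if len(x) < 3:
        raise DegenerateDesignError("need at least 3 points")
    if len(np.unique(x)) < 2 or np.ptp(x) == 0:
        raise DegenerateDesignError("zero variance in x")
    res = stats.linregress(x, y)
    return LinearModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        x_range=(float(np.min(x)), float(np.max(x))),
    )


def fit_standard_curve(standards: Sequence[BlotLane]) -> LinearModel:
    """Least-squares line of band signal versus loaded mass (ng).

    Requires at least three standards spanning a non-degenerate mass
    range; ``x_range`` records the interpolation interval.
    """
    std = [s for s in standards if s.kind == "standard"]
    if len(std) < 3:
        raise DegenerateDesignError("need >= 3 standard lanes")
    masses = np.array([s.loaded_mass for s in std], dtype=float)
    if len(np.unique(masses)) < len(masses):
        raise DegenerateDesignError("duplicated standard masses")
    signals = np.array([s.signal for s in std], dtype=float)
    return _fit_line(masses, signals)


def quantify_lysate(lane: BlotLane, curve: LinearModel) -> float:
    """Abundance (ng ABP per µg total protein) of one lysate lane.

    The band signal is inverse-interpolated to a mass through the
    standard curve; masses outside the standards' range raise
    :class:`OutOfLinearRangeError`.
    """
    if lane.kind != "lysate":
        raise ValidationError("quantify_lysate expects a lysate lane")
    mass = curve.inverse(lane.signal)
    lo, hi = curve.x_range
    if not lo <= mass <= hi:
        raise OutOfLinearRangeError(
            f"lane {lane.label!r}: predicted mass {mass:.3g} ng outside "
            f"standard range [{lo:.3g}, {hi:.3g}] ng"
        )
    return mass / lane.loaded_mass


def aggregate_replicates(abundances: Sequence[float]) -> tuple[float, float | None, int]:
    """Mean, sample SD (n−1; ``None`` when n = 1), and n of replicates."""
    if len(abundances) == 0:
        raise ValidationError("no replicates to aggregate")
    arr = np.asarray(abundances, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else None
    return mean, sd, len(arr)


def quantify_blot(
    lanes: Sequence[BlotLane],
) -> dict:
    """Full single-blot pipeline: fit standards, quantify in-range lysates,
    aggregate replicates.

    Returns a dict with ``mean``, ``sd``, ``n``, the fitted ``curve``,
    per-lane ``abundances`` and the labels of ``excluded`` lanes.
    """
    curve = fit_standard_curve([l for l in lanes if l.kind == "standard"])
    abundances: dict[str, float] = {}
    excluded: list[str] = []
    for lane in lanes:
        if lane.kind != "lysate":
            continue
        try:
            abundances[lane.label] = quantify_lysate(lane, curve)
        except OutOfLinearRangeError as exc:
            logger.warning("excluding lane: %s", exc)
            excluded.append(lane.label)
    if not abundances:
        raise ValidationError("no lysate lanes inside the linear range")
    mean, sd, n = aggregate_replicates(list(abundances.values()))
    return {
        "mean": mean,
        "sd": sd,
        "n": n,
        "curve": curve,
        "abundances": abundances,
        "excluded": excluded,
    }


def fit_gfp_calibration(pairs: Sequence[CalibrationPair]) -> LinearModel:
    """Least-squares line of GFP intensity (y) versus µM concentration (x)."""
    if len(pairs) < 3:
        raise DegenerateDesignError("need >= 3 calibration pairs")
    x = np.array([p.western_conc for p in pairs], dtype=float)
    y = np.array([p.gfp_intensity for p in pairs], dtype=float)
    return _fit_line(x, y)


def predict_concentration_from_gfp(intensity: float, model: LinearModel) -> float:
    """Invert the calibration line: concentration = (intensity − b) / m."""
    conc = model.inverse(intensity)
    if conc < 0:
        raise BelowCalibrationError(
            f"intensity {intensity:.3g} below the calibration intercept "
            f"{model.intercept:.3g}"
        )
    return conc


def generate_blot_fixture(
    true_abundance: float = 7.99,
    standards: Sequence[float] = (5.0, 10.0, 20.0, 40.0, 80.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    slope: float = 100.0,
    intercept: float = 50.0,
    lysate_loads: Sequence[float] = (2.0, 4.0, 6.0),
) -> tuple[list[BlotLane], BlotGroundTruth]:
    """Synthetic blot: standards plus lysate lanes from a hidden linear
    response (signal = slope·mass + intercept) with Gaussian noise.

    ``standards`` are ng of purified protein; ``lysate_loads`` are µg of
    total protein, so each lysate band carries ``true_abundance × load``
    ng — the defaults place all bands comfortably inside the standards'
    mass range, as a well-designed blot would.  Deterministic under a
    fixed seed.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    lanes: list[BlotLane] = []
    for i, mass in enumerate(standards):
        signal = slope * mass + intercept + rng.normal(0.0, noise_sd)
        lanes.append(BlotLane(f"std-{i}", "standard", float(mass), max(signal, 0.0)))
    for i, load in enumerate(lysate_loads):
        band_mass = true_abundance * load
        signal = slope * band_mass + intercept + rng.normal(0.0, noise_sd)
        lanes.append(BlotLane(f"lys-{i}", "lysate", float(load), max(signal, 0.0)))
    truth = BlotGroundTruth(true_abundance, slope, intercept, noise_sd, seed)
    return lanes, truth


def read_lanes(path: str | Path) -> list[BlotLane]:
    """Read lanes from CSV (columns: label, kind, loaded_mass, signal)."""
    df = pd.read_csv(path)
    missing = {"label", "kind", "loaded_mass", "signal"} - set(df.columns)
    if missing:
        raise ValidationError(f"lane table missing columns: {sorted(missing)}")
    return [
        BlotLane(str(r.label), str(r.kind), float(r.loaded_mass), float(r.signal))
        for r in df.itertuples(index=False)
    ]


def write_lanes(lanes: Sequence[BlotLane], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"label": l.label, "kind": l.kind, "loaded_mass": l.loaded_mass, "signal": l.signal}
            for l in lanes
        ]
    ).to_csv(path, index=False, float_format="%.17g")
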