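"""Sweetness, sourness, and astringency targets from chemical profiles.

Sweetness is a perception-weighted sugar total,
``0.75*glucose + 1*sucrose + 1.5*fructose`` (mg/L inputs).  Sourness is
the summed molarity of the organic acids (mg/L divided by g/mol, i.e.
mmol/L).  Astringency is total tannin in tannic-acid equivalents (mg/L),
read off a Folin-Ciocalteu standard curve: transmittance at 410 nm is
converted to absorbance (A = -log10 T), inverted through a fitted
absorbance-vs-ppm line, and scaled by the sample dilution factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .chemicals import ACIDS, MOLAR_MASS_G_PER_MOL, SWEETNESS_WEIGHTS
from .synthetic import ChemProfile

__all__ = [
    "TasteScores",
    "TanninStandardCurve",
    "sweetness",
    "sourness",
    "fit_tannin_curve",
    "astringency",
    "default_calibration_points",
    "simulate_transmittance",
    "score_panel",
]

#: Tannic-acid standards (ppm) used for the calibration series.
CALIBRATION_PPM = (1.25, 2.5, 5.0, 10.0, 15.0, 20.0, 30.0)


@dataclass(frozen=True)
class TasteScores:
    sample_id: str
    sweetness: float  # weighted mg/L-equivalents
    sourness: float  # mmol/L
    astringency: float  # mg/L tannic-acid equivalents

    def __post_init__(self) -> None:
        for name in ("sweetness", "sourness", "astringency"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TanninStandardCurve:
    """Least-squares line of absorbance vs tannic-acid concentration."""

    slope: float  # absorbance per ppm
    intercept: float
    r_squared: float
    points: tuple[tuple[float, float], ...]  # (ppm, transmittance)


def _concentrations(profile) -> dict[str, float]:
    if isinstance(profile, ChemProfile):
        return profile.concentrations
    return dict(profile)


def sweetness(profile) -> float:
    """Weighted sugar total; accepts a ChemProfile or a plain mapping."""
    conc = _concentrations(profile)
    missing = [s for s in SWEETNESS_WEIGHTS if s not in conc]
    if missing:
        raise ValueError(f"profile missing sugar(s): {missing}")
    total = 0.0
    for sugar, weight in SWEETNESS_WEIGHTS.items():
        c = float(conc[sugar])
        if c < 0:
            raise ValueError(f"negative concentration for {sugar!r}")
        total += weight * c
    return total


def sourness(
    profile,
    molar_masses: dict[str, float] | None = None,
    include_formic: bool = True,
) -> float:
    """Summed acid molarity in mmol/L.

    Sugars and tannin are excluded.  Formic acid is counted by default
    (it appears in wine at mmol levels); pass ``include_formic=False`` to
    restrict to the six classic wine acids.
    """
    conc = _concentrations(profile)
    masses = MOLAR_MASS_G_PER_MOL if molar_masses is None else molar_masses
    acids = [a for a in ACIDS if include_formic or a != "formic"]
    total = 0.0
    for acid in acids:
        if acid not in conc:
            continue
        c = float(conc[acid])
        if c < 0:
            raise ValueError(f"negative concentration for {acid!r}")
        if c == 0:
            continue
        if acid not in masses:
            raise ValueError(f"no molar mass supplied for acid {acid!r}")
        if masses[acid] <= 0:
            raise ValueError(f"molar mass for {acid!r} must be positive")
        total += c / masses[acid]
    return total


def fit_tannin_curve(points) -> TanninStandardCurve:
    """Fit the standard curve from (ppm, transmittance) calibration pairs."""
    pts = [(float(p), float(t)) for p, t in points]
    if len({p for p, _ in pts}) < 2:
        raise ValueError("need >= 2 distinct calibration concentrations")
    for p, t in pts:
        if not (0.0 < t <= 1.0):
            raise ValueError(f"transmittance {t} at {p} ppm outside (0, 1]")
    ppm = np.array([p for p, _ in pts])
    absorbance = -np.log10(np.array([t for _, t in pts]))
    fit = stats.linregress(ppm, absorbance)
    return TanninStandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2) if len(pts) > 2 else 1.0,
        points=tuple(pts),
    )


def astringency(
    transmittance: float,
    curve: TanninStandardCurve,
    dilution_factor: float = 100.0,
) -> float:
    """Tannic-acid equivalents (mg/L) of the undiluted sample."""
    if not (0.0 < transmittance <= 1.0):
        raise ValueError(f"transmittance {transmittance} outside (0, 1]")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    if abs(curve.slope) < 1e-15:
        raise ValueError("zero-slope standard curve is not invertible")
    absorbance = -np.log10(transmittance)
    ppm = (absorbance - curve.intercept) / curve.slope
    if ppm < 0:
        if ppm < -1e-9:  # tolerate float round-off at the origin
            warnings.warn(
                f"curve inversion gave {ppm:.4g} ppm; clamping to 0", stacklevel=2
            )
        ppm = 0.0
    return float(ppm * dilution_factor)


# ---------------------------------------------------------------------------
# synthetic assay plumbing
# ---------------------------------------------------------------------------

def default_calibration_points(
    slope: float = 0.02, intercept: float = 0.0
) -> list[tuple[float, float]]:
    """Noiseless calibration series generated from a known line."""
    return [
        (p, float(10.0 ** -(slope * p + intercept))) for p in CALIBRATION_PPM
    ]


def simulate_transmittance(
    tannin_mg_per_l: float,
    curve: TanninStandardCurve,
    dilution_factor: float = 100.0,
) -> float:
    """Forward model of the assay: known tannin level -> 410 nm transmittance."""
    if tannin_mg_per_l < 0:
        raise ValueError("tannin concentration must be >= 0")
    ppm = tannin_mg_per_l / dilution_factor
    absorbance = curve.slope * ppm + curve.intercept
    return float(10.0**-absorbance)


def score_panel(
    profiles: list[ChemProfile],
    curve: TanninStandardCurve | None = None,
    dilution_factor: float = 100.0,
    include_formic: bool = True,
):
    """Score every profile; returns a DataFrame (sample_id + three scores).

    Astringency is computed through the full assay round trip — the known
    tannin level is pushed through the standard curve to a transmittance
    and read back — so the calibration path is exercised end to end.
    """
    import pandas as pd

    if curve is None:
        curve = fit_tannin_curve(default_calibration_points())
    rows = []
    for p in profiles:
        t = simulate_transmittance(p.concentrations["tannin"], curve, dilution_factor)
        rows.append(
            {
                "sample_id": p.sample_id,
                "sweetness": sweetness(p),
                "sourness": sourness(p, include_formic=include_formic),
                "astringency": astringency(t, curve, dilution_factor),
            }
        )
    return pd.DataFrame(rows)
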