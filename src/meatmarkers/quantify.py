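"""Calibration curves and adulterant-fraction quantification.

Binary meat mixtures (target species mixed into a background species at known
mass fractions, typically 0/20/40/60/80/100%) give a linear response of each
marker transition's intensity against the target fraction.  Fitting that line
by ordinary least squares yields a standard curve; an unknown sample's
fraction is read off by inverse prediction, multiple markers of one species
are combined by the median, and the detection limit follows the standard
calibration-based rule LOD = 3.3 x sigma_blank / slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MixtureDesign",
    "StandardCurve",
    "MixtureSample",
    "FractionEstimate",
    "fit_standard_curve",
    "estimate_fraction",
    "consensus_estimate",
    "lod_estimate",
    "detection_threshold",
    "detect_contaminant",
    "SpeciesCall",
    "DEFAULT_FRACTIONS",
]

DEFAULT_FRACTIONS = (0.0, 0.20, 0.40, 0.60, 0.80, 1.00)


@dataclass(frozen=True)
class MixtureDesign:
    """Binary-mixture calibration design: target species diluted in background."""

    target: str
    background: str
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS

    def __post_init__(self) -> None:
        f = self.fractions
        if len(f) < 3:
            raise ValueError("a calibration design needs at least 3 levels")
        if any(not 0.0 <= x <= 1.0 for x in f):
            raise ValueError("fractions must lie in [0, 1]")
        if any(b <= a for a, b in zip(f, f[1:])):
            raise ValueError("fractions must be strictly increasing")


@dataclass(frozen=True)
class StandardCurve:
    """OLS line of transition intensity on target mass fraction.

    ``x_mean``/``s_xx`` are retained for inverse-prediction intervals.
    """

    target: str
    background: str
    peptide: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    residual_sd: float
    x_mean: float
    s_xx: float
    slope_se: float = 0.0

    def slope_interval(self, confidence: float = 0.95) -> tuple[float, float]:
        """t-based confidence interval for the slope (n - 2 dof)."""
        dof = self.n_points - 2
        if dof <= 0 or self.slope_se == 0:
            return (self.slope, self.slope)
        t = float(stats.t.ppf(0.5 + confidence / 2.0, dof))
        return (self.slope - t * self.slope_se, self.slope + t * self.slope_se)


@dataclass(frozen=True)
class MixtureSample:
    """Measured transition intensities for one sample.

    ``intensities`` maps a transition id (any stable string, e.g. the peptide
    sequence) to a non-negative intensity; ``true_fractions`` is optional
    ground truth used by simulation fixtures.
    """

    sample_id: str
    intensities: Mapping[str, float]
    true_fractions: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        for key, value in self.intensities.items():
            if not math.isfinite(value) or value < 0:
                raise ValueError(
                    f"sample {self.sample_id}: intensity for {key!r} must be "
                    f"finite and non-negative, got {value}"
                )


@dataclass(frozen=True)
class FractionEstimate:
    estimate: float
    lower: float
    upper: float
    clipped: bool = False


def fit_standard_curve(
    design: MixtureDesign,
    intensities: Sequence[float] | Sequence[Sequence[float]],
    peptide: str,
    average_replicates: bool = True,
) -> StandardCurve:
    """Fit the calibration line for one marker peptide.

    ``intensities`` holds one value per design level, or one sequence of
    replicates per level.  Replicates are averaged before fitting by default;
    with ``average_replicates=False`` every replicate point enters the fit.
    """
    x = np.asarray(design.fractions, dtype=float)
    rows = list(intensities)
    if len(rows) != len(x):
        raise ValueError(
            f"need one intensity (or replicate set) per level: "
            f"{len(rows)} given for {len(x)} levels"
        )
    if rows and np.ndim(rows[0]) > 0:
        if average_replicates:
            y = np.array([float(np.mean(r)) for r in rows])
        else:
            y = np.concatenate([np.asarray(r, dtype=float) for r in rows])
            x = np.concatenate(
                [np.full(len(r), xi) for xi, r in zip(x, rows)]
            )
    else:
        y = np.asarray(rows, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: zero variance in fractions")
    n = len(x)
    slope, intercept = np.polyfit(x, y, 1)
    fitted = intercept + slope * x
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 0.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    residual_sd = math.sqrt(ss_res / (n - 2)) if n > 2 else 0.0
    s_xx = float(np.sum((x - x.mean()) ** 2))
    return StandardCurve(
        target=design.target,
        background=design.background,
        peptide=peptide,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r_squared,
        n_points=n,
        residual_sd=residual_sd,
        x_mean=float(x.mean()),
        s_xx=s_xx,
        slope_se=residual_sd / math.sqrt(s_xx) if s_xx > 0 else 0.0,
    )


#: Slopes below this (relative to residual noise) are unquantifiable.
_MIN_ABS_SLOPE = 1e-12


def estimate_fraction(
    curve: StandardCurve, intensity: float, confidence: float = 0.95
) -> FractionEstimate:
    """Inverse prediction of the target mass fraction from one intensity.

    The point estimate is (I - intercept)/slope, clipped to [0, 1] with the
    ``clipped`` flag set when it falls outside.  The interval propagates the
    curve's residual standard deviation through the approximate
    inverse-prediction standard error
    ``s/|b| * sqrt(1 + 1/n + (x_hat - x_mean)^2 / S_xx)`` with a t quantile on
    n - 2 degrees of freedom, and is clipped to [0, 1].
    """
    if abs(curve.slope) < _MIN_ABS_SLOPE:
        raise ValueError(
            f"curve for {curve.peptide} has slope ~ 0; fraction unquantifiable"
        )
    raw = (intensity - curve.intercept) / curve.slope
    clipped = not 0.0 <= raw <= 1.0
    estimate = min(1.0, max(0.0, raw))
    dof = curve.n_points - 2
    if dof > 0 and curve.residual_sd > 0 and curve.s_xx > 0:
        se = (curve.residual_sd / abs(curve.slope)) * math.sqrt(
            1.0 + 1.0 / curve.n_points + (raw - curve.x_mean) ** 2 / curve.s_xx
        )
        t = float(stats.t.ppf(0.5 + confidence / 2.0, dof))
        lower, upper = raw - t * se, raw + t * se
    else:
        lower = upper = raw
    return FractionEstimate(
        estimate=estimate,
        lower=min(1.0, max(0.0, lower)),
        upper=min(1.0, max(0.0, upper)),
        clipped=clipped,
    )


def consensus_estimate(estimates: Sequence[float]) -> tuple[float, float]:
    """Median and median-absolute-deviation across per-peptide estimates.

    The median tolerates a single corrupted marker (matrix interference,
    missed transition) better than the mean.
    """
    if len(estimates) == 0:
        raise ValueError("consensus needs at least one per-peptide estimate")
    arr = np.asarray(estimates, dtype=float)
    med = float(np.median(arr))
    mad = float(np.median(np.abs(arr - med)))
    return med, mad


def lod_estimate(curve: StandardCurve, blanks: Sequence[float]) -> float:
    """Calibration-based detection limit: 3.3 x sd(blanks) / slope, in [0, 1]."""
    if len(blanks) < 3:
        raise ValueError("LOD estimation needs >= 3 blank replicates")
    if curve.slope <= _MIN_ABS_SLOPE:
        raise ValueError("LOD undefined for non-positive slope")
    sd = float(np.std(np.asarray(blanks, dtype=float), ddof=1))
    return min(1.0, 3.3 * sd / curve.slope)


def detection_threshold(blanks: Sequence[float]) -> float:
    """Per-transition decision threshold: mean(blank) + 3 x sd(blank)."""
    arr = np.asarray(blanks, dtype=float)
    if arr.size == 0:
        raise ValueError("threshold needs blank measurements")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()) + 3.0 * sd


@dataclass(frozen=True)
class SpeciesCall:
    species: str
    detected: bool
    supporting_peptides: tuple[str, ...]
    fraction: float | None = None
    spread: float | None = None


def detect_contaminant(
    sample: MixtureSample,
    panel: Mapping[str, Sequence[str]],
    curves: Mapping[str, StandardCurve] | None = None,
    blank_thresholds: Mapping[str, float] | None = None,
) -> list[SpeciesCall]:
    """Screen one sample against a species -> transition-id panel.

    A species is called detected when any of its transitions exceeds its
    blank-derived threshold (default 0 when no threshold is supplied).  When a
    standard curve exists for a supporting transition, the detected species
    also gets a consensus fraction (median across its quantifiable markers)
    and spread (MAD).
    """
    calls = []
    for species in sorted(panel):
        supporting = []
        for tid in panel[species]:
            intensity = sample.intensities.get(tid, 0.0)
            threshold = (blank_thresholds or {}).get(tid, 0.0)
            if intensity > threshold:
                supporting.append(tid)
        fraction = spread = None
        if supporting and curves:
            per_peptide = [
                estimate_fraction(curves[tid], sample.intensities[tid]).estimate
                for tid in supporting
                if tid in curves
            ]
            if per_peptide:
                fraction, spread = consensus_estimate(per_peptide)
        calls.append(
            SpeciesCall(
                species=species,
                detected=bool(supporting),
                supporting_peptides=tuple(supporting),
                fraction=fraction,
                spread=spread,
            )
        )
    return calls
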