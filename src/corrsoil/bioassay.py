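"""Microbiological bioassay calibration and corrinoid quantification.

Growth (OD600) of a corrinoid-requiring indicator strain (an E. coli
methionine-synthase mutant) is a saturating, monotone function of corrinoid
concentration. Because the assay responds to structurally distinct
corrinoids with different sensitivities, all quantities are expressed as
**cobalamin equivalents** against a cyanocobalamin standard curve; no
corrinoid-specific correction is attempted.

The calibration model is deliberately non-parametric: a monotone
piecewise-linear interpolant of mean OD against log10 concentration.
Censoring is explicit at both ends:

* limit of detection: OD at or below blank mean + 3 x blank sd;
* saturation: OD at or above 95% of the plateau OD (the assay plateaus near
  1 nM cobalamin).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "StandardCurve",
    "QuantResult",
    "fit_standard_curve",
    "od_to_concentration",
    "CurveFitError",
]

#: tolerance (in OD units) for small non-monotonicities between replicate means
MONOTONE_TOL_OD = 1e-9
#: fraction of the plateau OD above which readings are treated as saturated
SATURATION_FRACTION = 0.95


class CurveFitError(ValueError):
    """Calibration data cannot support a monotone standard curve."""


@dataclass(frozen=True)
class StandardCurve:
    """Fitted monotone standard curve with censoring thresholds.

    ``points`` are (concentration nM, mean OD600, OD sd) in strictly
    increasing concentration order. ``quantitation_range`` is the
    concentration interval over which an OD can be inverted without hitting
    either censoring threshold, obtained by pushing the LOD OD and the
    saturation OD back through the interpolant and clipping to the
    calibration span.
    """

    points: tuple[tuple[float, float, float], ...]
    blank_od: float
    blank_sd: float
    lod_od: float
    plateau_od: float
    saturation_od: float
    saturation_conc: float
    quantitation_range: tuple[float, float]

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def ods(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    def forward(self, conc: float | np.ndarray) -> np.ndarray:
        """Interpolated OD at a concentration (clipped to calibration span)."""
        logc = np.log10(np.clip(conc, self.concentrations[0], self.concentrations[-1]))
        return np.interp(logc, np.log10(self.concentrations), self.ods)

    def inverse(self, od: float) -> float:
        """Concentration whose interpolated OD equals ``od`` (no censoring)."""
        logc = np.interp(od, self.ods, np.log10(self.concentrations))
        return float(10.0 ** logc)


@dataclass(frozen=True)
class QuantResult:
    """One sample's quantification: a value or exactly one censoring flag."""

    sample_id: str
    od_used: float
    concentration: float | None = None
    flag: str | None = None  # None | "below_LOD" | "above_saturation"

    def __post_init__(self) -> None:
        if (self.concentration is None) == (self.flag is None):
            raise ValueError("exactly one of concentration / flag must be set")
        if self.concentration is not None and self.concentration < 0:
            raise ValueError("negative concentration")


def fit_standard_curve(
    calibration_points: Iterable[tuple[float, float] | tuple[float, float, float]],
    blanks: Sequence[float],
    saturation_conc: float = 1.0,
    monotone_tol: float = MONOTONE_TOL_OD,
) -> StandardCurve:
    """Fit the monotone piecewise-linear standard curve.

    Parameters
    ----------
    calibration_points
        (concentration nM, mean OD[, OD sd]) tuples; >= 3 distinct
        concentrations required, strictly increasing after sorting.
    blanks
        Replicate ODs of zero-corrinoid wells; LOD OD = mean + 3 sd.
    saturation_conc
        Concentration (nM) at which the assay response is known to plateau;
        used as a sanity bound on the calibration span, default 1 nM.
    """
    pts = []
    for p in calibration_points:
        conc, od = float(p[0]), float(p[1])
        sd = float(p[2]) if len(p) > 2 else 0.0
        if conc <= 0:
            raise CurveFitError(f"non-positive calibration concentration {conc}")
        pts.append((conc, od, sd))
    pts.sort(key=lambda p: p[0])
    concs = np.array([p[0] for p in pts])
    ods = np.array([p[1] for p in pts])
    if len(pts) < 3:
        raise CurveFitError("need >= 3 calibration concentrations")
    if np.any(np.diff(concs) <= 0):
        raise CurveFitError("calibration concentrations must be strictly increasing")
    if np.any(np.diff(ods) < -monotone_tol):
        raise CurveFitError("mean OD must be non-decreasing with concentration")
    if np.ptp(ods) <= monotone_tol:
        raise CurveFitError("calibration ODs are constant; curve is degenerate")

    blanks = np.asarray(list(blanks), dtype=float)
    if blanks.size == 0:
        raise CurveFitError("blank wells required to set the limit of detection")
    blank_mean = float(blanks.mean())
    blank_sd = float(blanks.std(ddof=1)) if blanks.size > 1 else 0.0
    lod_od = blank_mean + 3.0 * blank_sd

    plateau_od = float(ods[-1])
    saturation_od = SATURATION_FRACTION * plateau_od
    if lod_od >= saturation_od:
        raise CurveFitError(
            f"LOD OD {lod_od:.3g} is not below the saturation OD {saturation_od:.3g}; "
            "no usable quantitation window"
        )

    # invert the censoring ODs through the interpolant, clipped to the span
    log_concs = np.log10(concs)
    lo = 10.0 ** float(np.interp(max(lod_od, ods[0]), ods, log_concs))
    hi = 10.0 ** float(np.interp(min(saturation_od, ods[-1]), ods, log_concs))
    lo = float(np.clip(lo, concs[0], concs[-1]))
    hi = float(np.clip(hi, concs[0], concs[-1]))
    if hi <= lo:
        raise CurveFitError("empty quantitation range after censoring bounds")

    return StandardCurve(
        points=tuple(pts),
        blank_od=blank_mean,
        blank_sd=blank_sd,
        lod_od=lod_od,
        plateau_od=plateau_od,
        saturation_od=saturation_od,
        saturation_conc=float(saturation_conc),
        quantitation_range=(lo, hi),
    )


def od_to_concentration(
    od: float | Sequence[float],
    curve: StandardCurve,
    sample_id: str = "sample",
    average_replicates: bool = True,
) -> QuantResult | list[QuantResult]:
    """Invert an OD reading to cobalamin-equivalent nM, with censoring.

    Replicate ODs are averaged before inversion by default; pass
    ``average_replicates=False`` to get one result per replicate.
    """
    if np.ndim(od) > 0:
        ods = [float(x) for x in od]
        if average_replicates:
            return od_to_concentration(float(np.mean(ods)), curve, sample_id)
        return [
            od_to_concentration(x, curve, f"{sample_id}.{i + 1}")
            for i, x in enumerate(ods)
        ]

    od = float(od)
    if od < 0:
        raise ValueError(f"negative OD600 {od} for sample {sample_id!r}")
    if od <= curve.lod_od:
        return QuantResult(sample_id, od, flag="below_LOD")
    if od >= curve.saturation_od:
        return QuantResult(sample_id, od, flag="above_saturation")
    return QuantResult(sample_id, od, concentration=curve.inverse(od))
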