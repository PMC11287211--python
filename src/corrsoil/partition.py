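"""Soil–water partition model for corrinoids from serial batch extractions.

A soil sample is extracted repeatedly with fresh aqueous buffer. At each
round the dissolved and adsorbed pools are assumed to reach the same
equilibrium, characterised by a single partition coefficient

    K_d = [B12_aq,n] / [B12_soil,n]

(aqueous over soil-phase concentration, dimensionless given both are molar).
Fresh buffer each round removes the aqueous fraction, so the soil pool
decays geometrically:

    [soil,n] = [soil,n-1] / (1 + K_d * vol_aq / vol_soil)

Two per-pair estimators for K_d from consecutive aqueous measurements are
provided. The default ``self_consistent`` form,

    K_d = vol_soil * (aq_n - aq_{n+1}) / (vol_aq * aq_{n+1}),

is the one implied by the equilibrium definition together with the
mass-balance relation, and is exactly inverted by the back-extrapolation
factor (1 + K_d * vol_aq / vol_soil). The ``printed`` variant replaces the
denominator with aq_n; it is retained for comparison because it circulates
in the literature, but it is not self-consistent with the forward model and
under-estimates K_d by a factor aq_{n+1}/aq_n.

Concentrations enter in nM (cobalamin equivalents, as delivered by the
bioassay); unit conversions to pmol per gram of soil are centralised in
:func:`aqueous_nM_to_pmol_per_g`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ExtractionGeometry",
    "ExtractionRound",
    "ExtractionSeries",
    "PartitionEstimate",
    "TotalPool",
    "estimate_kd",
    "back_extrapolate",
    "total_pool",
    "molecules_per_cell",
    "partition_upper_bound",
    "aqueous_nM_to_pmol_per_g",
    "NonIdentifiableError",
]

AVOGADRO = 6.02214076e23


class NonIdentifiableError(ValueError):
    """The series carries no information about K_d (non-decreasing pair etc.)."""


@dataclass(frozen=True)
class ExtractionGeometry:
    """Extraction geometry; defaults are 10 ml buffer over 1 g (1 ml) soil."""

    vol_aq: float = 0.01  # L
    vol_soil: float = 0.001  # L, soil density taken as 1 g/ml
    soil_mass: float = 1.0  # g

    def __post_init__(self) -> None:
        if min(self.vol_aq, self.vol_soil, self.soil_mass) <= 0:
            raise ValueError("geometry quantities must be strictly positive")

    @property
    def vol_ratio(self) -> float:
        """vol_aq / vol_soil — the depletion leverage per round."""
        return self.vol_aq / self.vol_soil


@dataclass(frozen=True)
class ExtractionRound:
    n: int
    aq_conc: float | None  # nM cobalamin equivalents; None when censored
    censored: bool = False
    lod: float | None = None  # nM; upper bound when censored below LOD


@dataclass(frozen=True)
class ExtractionSeries:
    """Ordered aqueous concentrations per extraction round.

    Censored rounds (below the bioassay LOD) carry ``censored=True`` and an
    ``lod`` bound; they are never zero-filled.
    """

    rounds: tuple[ExtractionRound, ...]
    geometry: ExtractionGeometry = field(default_factory=ExtractionGeometry)
    residual_soil_conc: float | None = None  # pmol/g measured after final round

    def __post_init__(self) -> None:
        indices = [r.n for r in self.rounds]
        if not indices:
            raise ValueError("empty extraction series")
        if indices != list(range(indices[0], indices[0] + len(indices))):
            raise ValueError(f"round indices not consecutive: {indices}")
        for r in self.rounds:
            if not r.censored and (r.aq_conc is None or r.aq_conc < 0):
                raise ValueError(f"round {r.n}: aqueous concentration must be >= 0")

    @classmethod
    def from_concentrations(
        cls,
        aq_conc_nM: Sequence[float],
        geometry: ExtractionGeometry | None = None,
        first_round: int = 1,
        residual_soil_conc: float | None = None,
    ) -> "ExtractionSeries":
        rounds = tuple(
            ExtractionRound(n=first_round + i, aq_conc=float(c))
            for i, c in enumerate(aq_conc_nM)
        )
        return cls(rounds, geometry or ExtractionGeometry(), residual_soil_conc)

    def concentrations(self) -> dict[int, float]:
        return {r.n: r.aq_conc for r in self.rounds if not r.censored}


@dataclass(frozen=True)
class PartitionEstimate:
    kd_pairs: tuple[tuple[int, float], ...]  # (round n of the pair's first member, kd)
    kd_mean: float
    kd_sd: float  # sd over pair estimates, ddof=1 (nan for a single pair)
    rounds_used: tuple[int, int]
    kd_form: str
    soil_conc_initial: float | None = None  # pmol/g, when back-extrapolated

    def __post_init__(self) -> None:
        for n, kd in self.kd_pairs:
            if not math.isfinite(kd) or kd < 0:
                raise NonIdentifiableError(f"pair at round {n}: invalid kd {kd}")


def estimate_kd(
    series: ExtractionSeries,
    rounds_used: tuple[int, int],
    kd_form: str = "self_consistent",
) -> PartitionEstimate:
    """Estimate K_d from consecutive-round pairs inside ``rounds_used``.

    ``rounds_used = (lo, hi)`` selects rounds lo..hi inclusive (the study
    convention is a late window, e.g. rounds 6-9, avoiding early-round
    desorption/lysis transients); the window is a required explicit choice.
    """
    if kd_form not in ("self_consistent", "printed"):
        raise ValueError(f"unknown kd_form {kd_form!r}")
    lo, hi = rounds_used
    conc = series.concentrations()
    used = [n for n in range(lo, hi + 1) if n in conc]
    if len(used) < 2:
        raise NonIdentifiableError(
            f"need >= 2 uncensored rounds in {lo}..{hi}, have {len(used)}"
        )
    g = series.geometry
    pairs: list[tuple[int, float]] = []
    for n in used[:-1]:
        if n + 1 not in conc:
            continue
        a_n, a_next = conc[n], conc[n + 1]
        if a_next <= 0:
            raise ZeroDivisionError(
                f"round {n + 1} aqueous concentration is zero; K_d undefined"
            )
        if a_next >= a_n:
            raise NonIdentifiableError(
                f"aqueous concentration does not decrease from round {n} "
                f"({a_n}) to {n + 1} ({a_next})"
            )
        denom = a_next if kd_form == "self_consistent" else a_n
        kd = g.vol_soil * (a_n - a_next) / (g.vol_aq * denom)
        pairs.append((n, kd))
    if not pairs:
        raise NonIdentifiableError("no usable consecutive pairs in window")
    kds = np.array([kd for _, kd in pairs])
    return PartitionEstimate(
        kd_pairs=tuple(pairs),
        kd_mean=float(kds.mean()),
        kd_sd=float(kds.std(ddof=1)) if len(kds) > 1 else float("nan"),
        rounds_used=(lo, hi),
        kd_form=kd_form,
    )


def back_extrapolate(
    soil_conc: float, kd: float, geometry: ExtractionGeometry, k_rounds: int
) -> float:
    """Undo ``k_rounds`` of extraction: soil pool at k rounds earlier.

    Each round multiplies the soil pool by 1/(1 + K_d * vol_aq / vol_soil),
    so the earlier pool is soil_conc * (1 + K_d * vol_aq / vol_soil)**k.
    Units are preserved (pmol/g in, pmol/g out).
    """
    if soil_conc < 0 or kd < 0 or k_rounds < 0:
        raise ValueError("soil_conc, kd and k_rounds must be non-negative")
    return soil_conc * (1.0 + kd * geometry.vol_ratio) ** k_rounds


def aqueous_nM_to_pmol_per_g(aq_conc_nM: float, geometry: ExtractionGeometry) -> float:
    """Amount removed by one extraction round, per gram of soil.

    nM * L = nmol * 1e3 = pmol; divided by soil mass in grams. This is the
    single audited unit conversion; everything downstream goes through it.
    """
    return aq_conc_nM * geometry.vol_aq * 1e3 / geometry.soil_mass


@dataclass(frozen=True)
class TotalPool:
    """Summed extracted corrinoid in pmol/g, as an interval when rounds are
    censored (each censored round contributes [0, LOD] of aqueous signal)."""

    low: float
    high: float
    n_censored: int

    @property
    def value(self) -> float:
        """Point value; only defined when nothing was censored."""
        if self.n_censored:
            raise ValueError("pool is an interval; censored rounds present")
        return self.low


def total_pool(series: ExtractionSeries, residual: float | None = None) -> TotalPool:
    """Total corrinoid recovered across all rounds plus any residual pool.

    ``residual`` (pmol/g; defaults to the series' measured residual, else 0)
    is the soil-phase pool remaining after the final round.
    """
    if all(r.censored for r in series.rounds):
        raise ValueError("all extraction rounds are censored; no pool estimate")
    if residual is None:
        residual = series.residual_soil_conc or 0.0
    low = high = float(residual)
    n_censored = 0
    for r in series.rounds:
        if r.censored:
            n_censored += 1
            if r.lod:
                high += aqueous_nM_to_pmol_per_g(r.lod, series.geometry)
        else:
            amt = aqueous_nM_to_pmol_per_g(r.aq_conc, series.geometry)
            low += amt
            high += amt
    return TotalPool(low=low, high=high, n_censored=n_censored)


def molecules_per_cell(
    soil_conc_pmol_per_g: float, cells_per_gram: float
) -> tuple[float, int]:
    """Corrinoid molecules per microbial cell and its order of magnitude.

    Soil microbial density is conventionally taken as ~1e9 cells per gram.
    Returns (molecules/cell, nearest power of ten).
    """
    if cells_per_gram <= 0:
        raise ValueError("cells_per_gram must be positive")
    if soil_conc_pmol_per_g < 0:
        raise ValueError("soil concentration must be >= 0")
    molecules = soil_conc_pmol_per_g * 1e-12 * AVOGADRO / cells_per_gram
    order = int(round(math.log10(molecules))) if molecules > 0 else 0
    return molecules, order


@dataclass(frozen=True)
class PartitionBound:
    kd_upper_bound: float
    assumptions: tuple[str, ...]


def partition_upper_bound(
    spike_conc_nM: float, detection_limit_nM: float, geometry: ExtractionGeometry
) -> PartitionBound:
    """Upper bound on K_d from a spike-recovery non-detection.

    A known amount of cobalamin (``spike_conc_nM`` in the aqueous volume) is
    added to soil; if nothing is detected in the extract, the aqueous phase
    is at most the detection limit while the soil phase holds (at least)
    the whole spike, so

        K_d <= detection_limit / (spike amount per soil volume).

    The full-adsorption assumption is echoed in the result record.
    """
    if spike_conc_nM <= 0:
        raise ValueError("spike concentration must be positive")
    if detection_limit_nM < 0:
        raise ValueError("detection limit must be >= 0")
    soil_phase_conc = spike_conc_nM * geometry.vol_aq / geometry.vol_soil
    return PartitionBound(
        kd_upper_bound=detection_limit_nM / soil_phase_conc,
        assumptions=(
            "entire spike assumed adsorbed to the soil phase",
            "aqueous phase at most the detection limit",
            "equilibrium reached before extraction",
        ),
    )
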