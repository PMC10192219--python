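"""Quantification arithmetic for pep-tRNA abundance measurements.

Covers the normalizations used when following pep-tRNA accumulation by
LC/MS: peak areas referenced to formyl-Met-adenosine (the initiator
species, insensitive to peptidyl-tRNA hydrolase inactivation), time-course
ratios, summed abundances, the ±tylosin drop-off frequency, the n-mer /
(n-mer + (n+1)-mer) drop-off rate, and log-log calibration-curve absolute
quantification.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceSeries",
    "CalibrationCurve",
    "rel_to_reference",
    "timecourse_relative",
    "summed_abundance",
    "dropoff_frequency",
    "dropoff_rate",
    "fit_calibration",
    "absolute_quantify",
]


@dataclass(frozen=True)
class AbundanceSeries:
    """Per-timepoint peak areas of one species plus its reference areas.

    ``areas`` and ``ref_areas`` are mappings from timepoint label to peak
    area; reference areas (f-Met-Ado) share the species' timepoints.
    """

    species: str
    areas: Mapping[str, float]
    ref_areas: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        for t, a in self.areas.items():
            if a < 0:
                raise ValueError(f"negative area at {t!r}: {a}")
        if self.ref_areas is not None:
            missing = set(self.areas) - set(self.ref_areas)
            if missing:
                raise ValueError(f"reference areas missing timepoints {missing}")
            for t, a in self.ref_areas.items():
                if a <= 0:
                    raise ValueError(f"nonpositive reference area at {t!r}: {a}")


def rel_to_reference(area, ref_area):
    """Area normalized to the reference (f-Met-Ado) area; vectorized."""
    ref = np.asarray(ref_area, dtype=float)
    if np.any(ref <= 0):
        raise ValueError("reference area must be > 0")
    out = np.asarray(area, dtype=float) / ref
    return float(out) if out.ndim == 0 else out


def timecourse_relative(
    series: AbundanceSeries,
    mode: str = "to_t0",
    t0: str = "0",
) -> dict[str, float]:
    """Per-timepoint relative values.

    ``to_t0`` (aminoacyl-adenosine convention): reference-normalize where a
    reference is present, then divide by the value at the t0 label; a zero
    t0 yields NaN at every timepoint with a warning.  ``to_reference``
    (dipeptide convention): each timepoint divided by its reference area.
    """
    if mode == "to_reference":
        if series.ref_areas is None:
            raise ValueError("to_reference mode requires reference areas")
        return {
            t: rel_to_reference(a, series.ref_areas[t])
            for t, a in series.areas.items()
        }
    if mode != "to_t0":
        raise ValueError(f"unknown mode {mode!r}")
    if t0 not in series.areas:
        raise ValueError(f"timepoint {t0!r} absent from series {series.species!r}")
    if series.ref_areas is not None:
        values = {
            t: rel_to_reference(a, series.ref_areas[t])
            for t, a in series.areas.items()
        }
    else:
        values = dict(series.areas)
    base = values[t0]
    if base == 0:
        logger.warning(
            "timecourse_relative: zero baseline at %r for %s; values undefined",
            t0, series.species,
        )
        return {t: math.nan for t in values}
    return {t: v / base for t, v in values.items()}


def summed_abundance(
    series_set: Sequence[Mapping[str, float]],
    percent_of: str | None = None,
) -> dict[str, float]:
    """Per-timepoint sum over a set of (already normalized) series.

    With ``percent_of`` set, the sums are rescaled so that the named
    baseline timepoint equals 100 (ratios between timepoints unchanged).
    """
    if not series_set:
        raise ValueError("need at least one series")
    timepoints = list(series_set[0])
    sums = {
        t: float(sum(s.get(t, 0.0) for s in series_set)) for t in timepoints
    }
    if percent_of is not None:
        base = sums[percent_of]
        if base == 0:
            raise ValueError(f"zero baseline at timepoint {percent_of!r}")
        sums = {t: v / base * 100.0 for t, v in sums.items()}
    return sums


def dropoff_frequency(no_drug_rel, tyl_rel, percent: bool = False):
    """Drop-off frequency: relative abundance without tylosin / with tylosin.

    Saturating tylosin dissociates (nearly) all elongating dipep-tRNAs, so
    the +tylosin level approximates the total flux; the ratio estimates the
    fraction dropping off spontaneously. Values above 1 (100%) can arise
    from noisy inputs and are flagged, not clipped.
    """
    tyl = np.asarray(tyl_rel, dtype=float)
    if np.any(tyl <= 0):
        raise ValueError("tylosin-treated relative abundance must be > 0")
    ratio = np.asarray(no_drug_rel, dtype=float) / tyl
    if np.any(ratio > 1):
        logger.warning("dropoff_frequency: value(s) exceed 100%%; check inputs")
    if percent:
        ratio = ratio * 100.0
    return float(ratio) if ratio.ndim == 0 else ratio


def dropoff_rate(n_k: float, n_k_plus_1: float) -> float:
    """Drop-off rate at codon k+?: n-mer / (n-mer + (n+1)-mer) amounts."""
    if n_k < 0 or n_k_plus_1 < 0:
        raise ValueError("amounts must be nonnegative")
    total = n_k + n_k_plus_1
    if total == 0:
        raise ValueError("both amounts zero: drop-off rate undefined")
    return n_k / total


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS fit of log10(area) vs log10(amount) for one peptide standard."""

    peptide: str
    slope: float
    intercept: float
    amount_range: tuple[float, float]

    def predict_area(self, amount: float) -> float:
        return 10 ** (self.intercept + self.slope * math.log10(amount))


def fit_calibration(
    peptide: str,
    amounts: Sequence[float],
    areas: Sequence[float],
) -> CalibrationCurve:
    """Fit a double-logarithmic calibration curve by least squares."""
    amounts = np.asarray(amounts, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if amounts.size < 2:
        raise ValueError("need at least 2 calibration points")
    if np.any(amounts <= 0) or np.any(areas <= 0):
        raise ValueError("calibration amounts and areas must be > 0")
    slope, intercept = np.polyfit(np.log10(amounts), np.log10(areas), 1)
    if not math.isfinite(slope) or slope == 0:
        raise ValueError("degenerate calibration fit")
    return CalibrationCurve(
        peptide=peptide,
        slope=float(slope),
        intercept=float(intercept),
        amount_range=(float(amounts.min()), float(amounts.max())),
    )


def absolute_quantify(area: float, curve: CalibrationCurve) -> float:
    """Invert the calibration curve: amount = 10^((log10(area) − b) / m).

    Extrapolation beyond the fitted amount range is flagged with a warning.
    """
    if area <= 0:
        raise ValueError(f"nonpositive area: {area}")
    amount = 10 ** ((math.log10(area) - curve.intercept) / curve.slope)
    lo, hi = curve.amount_range
    if not (lo <= amount <= hi):
        logger.warning(
            "absolute_quantify: amount %.4g outside calibration range "
            "[%.4g, %.4g] for %s", amount, lo, hi, curve.peptide,
        )
    return amount
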