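"""qPCR absolute-quantification arithmetic.

Copy numbers of a plasmid standard follow from its mass and length using a
molar mass of 660 g/mol per base pair (330 Da per nucleotide, two
nucleotides per pair) and Avogadro's number 6.022e23 — the conventional
back-of-envelope constants of qPCR standard preparation, kept exactly as
conventionally printed rather than refined to the crystallographic value.

A standard curve is the least-squares line of Ct on log10(copies) over a
dilution series; amplification efficiency is ``10**(-1/slope) - 1`` (a
perfectly doubling reaction gives slope -1/log10(2) = -3.3219 and
efficiency 1.0).  Unknowns are quantified by inverting the fitted line.

The abundance-ratio statistic expresses one group as a percentage of the
pooled total, ``100 * B / (A + B)`` — e.g. archaeal 16S copies as a
percentage of all prokaryotic (bacterial + archaeal) copies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AVOGADRO",
    "DALTONS_PER_BP",
    "PlasmidStandard",
    "StandardCurve",
    "plasmid_copies",
    "fit_standard_curve",
    "quantify",
    "abundance_ratio",
    "quantify_samples",
]

AVOGADRO = 6.022e23
DALTONS_PER_BP = 330.0 * 2  # 330 Da per nucleotide x 2 nucleotides per bp


def plasmid_copies(mass_grams: float, construct_length_bp: int) -> float:
    """Molecule count of a double-stranded construct from mass and length.

    copies = mass * N_A / (length * 660 g/mol/bp)
    """
    if construct_length_bp <= 0:
        raise ValueError("construct length must be positive")
    if mass_grams < 0:
        raise ValueError("mass must be non-negative")
    grams_per_molecule = construct_length_bp * DALTONS_PER_BP / AVOGADRO
    return mass_grams / grams_per_molecule


@dataclass(frozen=True)
class PlasmidStandard:
    """A quantified plasmid preparation (vector + insert)."""

    construct_length: int  # bp
    mass: float  # grams

    @property
    def copies(self) -> float:
        return plasmid_copies(self.mass, self.construct_length)

    def dilution_series(self, levels: list[float]) -> list[float]:
        """Copy numbers at the requested fractions of the stock (e.g. a
        10-fold series passes [1e-4, 1e-3, ...])."""
        return [self.copies * f for f in levels]


@dataclass(frozen=True)
class StandardCurve:
    """Ct = slope * log10(copies) + intercept."""

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        return 10 ** (-1 / self.slope) - 1

    @property
    def is_valid(self) -> bool:
        return self.slope < 0

    def predict_ct(self, copies: float) -> float:
        return self.slope * np.log10(copies) + self.intercept


def fit_standard_curve(points: list[tuple[float, float]]) -> StandardCurve:
    """Least-squares Ct-on-log10(copies) line over a dilution series.

    ``points`` are (copies, Ct) pairs; at least three distinct copy levels
    with positive copies are required.  Replicate Ct values at a level are
    allowed and enter the fit individually.
    """
    if any(c <= 0 for c, _ in points):
        raise ValueError("standard copies must be positive")
    levels = {c for c, _ in points}
    if len(levels) < 3:
        raise ValueError(
            f"need >= 3 distinct copy levels, got {len(levels)}"
        )
    x = np.log10([c for c, _ in points])
    y = np.array([ct for _, ct in points])
    fit = stats.linregress(x, y)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def quantify(
    ct: float, curve: StandardCurve, standard_range: tuple[float, float] | None = None
) -> float:
    """Invert the standard curve: copies = 10**((ct - intercept) / slope).

    With ``standard_range`` given as (min Ct, max Ct) of the standards,
    values outside it are extrapolated with a warning rather than
    rejected.
    """
    if not curve.is_valid:
        raise ValueError(f"invalid standard curve (slope={curve.slope})")
    if standard_range is not None:
        lo, hi = min(standard_range), max(standard_range)
        if not lo <= ct <= hi:
            warnings.warn(
                f"Ct {ct} outside standard range [{lo}, {hi}]; extrapolating",
                stacklevel=2,
            )
    return float(10 ** ((ct - curve.intercept) / curve.slope))


def abundance_ratio(a_copies: float, b_copies: float) -> float | None:
    """Group B as a percentage of the pooled total: 100 * B / (A + B).

    Used with A = bacterial and B = archaeal copies this is the archaeal
    fraction of all prokaryotes; the same statistic serves any pair of
    groups.  Returns None (undefined) when both totals are zero.
    """
    if a_copies < 0 or b_copies < 0:
        raise ValueError("copy numbers must be non-negative")
    total = a_copies + b_copies
    if total == 0:
        return None
    return 100.0 * b_copies / total


def quantify_samples(
    standards: pd.DataFrame,
    samples: pd.DataFrame,
    ratio_pairs: list[tuple[str, str]] | None = None,
) -> tuple[StandardCurve, pd.DataFrame, pd.DataFrame]:
    """Fit the curve and quantify a sample table.

    ``standards`` needs columns (copies, ct); ``samples`` needs
    (sample, group, ct).  Returns the fitted curve, the sample table with
    an added ``copies`` column, and a per-sample ratio table for each
    requested (group_a, group_b) pair (copies summed within sample and
    group before the ratio).
    """
    curve = fit_standard_curve(list(zip(standards["copies"], standards["ct"])))
    ct_range = (float(standards["ct"].min()), float(standards["ct"].max()))
    out = samples.copy()
    out["copies"] = [quantify(ct, curve, ct_range) for ct in out["ct"]]
    rows = []
    for a, b in ratio_pairs or []:
        totals = out.groupby(["sample", "group"])["copies"].sum()
        for sample in out["sample"].unique():
            a_c = float(totals.get((sample, a), 0.0))
            b_c = float(totals.get((sample, b), 0.0))
            rows.append(
                {
                    "sample": sample,
                    "group_a": a,
                    "group_b": b,
                    "a_copies": a_c,
                    "b_copies": b_c,
                    "ratio_percent": abundance_ratio(a_c, b_c),
                }
            )
    return curve, out, pd.DataFrame(rows)
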