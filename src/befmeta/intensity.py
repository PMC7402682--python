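"""Standardization of heterogeneous stressor/nutrient levels into a common intensity.

Concentrations of different compounds (metals, pesticides, N and P forms) are not
comparable across studies. Each compound is therefore expressed relative to an
environmental quality criterion issued by a regulator (ECHA, USEPA, WFD, ...):

    intensity = log(conc_treatment / conc_criteria)

so that 0 means "exactly at the criterion", negative values are below the level
considered safe and positive values above it. When a study reports several
compounds, the compound with the highest standardized intensity defines the
observation's intensity.

The log base defaults to 10 (one unit = one order of magnitude relative to the
criterion) and is configurable; it rescales intensity slopes, so every table the
pipeline emits records the base used.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

__all__ = ["CompoundLevel", "ecd_intensity", "max_intensity"]

logger = logging.getLogger(__name__)

_CRITERIA_SOURCES = ("ECHA", "USEPA", "WFD", "other")


@dataclass(frozen=True)
class CompoundLevel:
    """One compound's treatment concentration and its quality criterion.

    Both concentrations must be positive and expressed in the same units;
    ``units`` is free text used only to detect accidental mismatches.
    """

    compound: str
    conc_treatment: float
    conc_criteria: float
    criteria_source: str = "other"
    units: str | None = None

    def __post_init__(self) -> None:
        if not self.conc_treatment > 0:
            raise ValueError(
                f"{self.compound}: treatment concentration must be > 0, "
                f"got {self.conc_treatment}"
            )
        if not self.conc_criteria > 0:
            raise ValueError(
                f"{self.compound}: criterion concentration must be > 0, "
                f"got {self.conc_criteria}"
            )
        if self.criteria_source not in _CRITERIA_SOURCES:
            raise ValueError(
                f"criteria_source must be one of {_CRITERIA_SOURCES}, "
                f"got {self.criteria_source!r}"
            )


def ecd_intensity(level: CompoundLevel, base: float = 10.0) -> float:
    """Standardized environmental-change-driver intensity of one compound.

    Returns ``log_base(conc_treatment / conc_criteria)``: 0 at the criterion,
    negative below it, positive above it.
    """
    if base <= 0 or base == 1.0:
        raise ValueError(f"log base must be positive and != 1, got {base}")
    return math.log(level.conc_treatment / level.conc_criteria, base)


def max_intensity(
    levels: list[CompoundLevel], base: float = 10.0
) -> tuple[float, str]:
    """Intensity of the compound with the highest standardized intensity.

    When an observation reports several compounds, the one exceeding its
    criterion by the largest factor defines the observation's intensity.
    Ties are broken by input order (first compound wins) and logged.
    Standardized intensities are unitless, so compounds reported in different
    units are comparable (units must only agree within a compound, which
    :class:`CompoundLevel` assumes by construction).
    """
    if not levels:
        raise ValueError("max_intensity requires at least one compound level")
    intensities = [ecd_intensity(lv, base=base) for lv in levels]
    best = max(intensities)
    idx = intensities.index(best)  # first occurrence = documented tie-break
    if intensities.count(best) > 1:
        logger.info(
            "intensity tie at %.6g; keeping first compound %r by input order",
            best,
            levels[idx].compound,
        )
    return best, levels[idx].compound
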