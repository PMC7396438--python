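"""Adduct-mass arithmetic and internal-control-normalised band quantification.

These desk calculations back the stoichiometry arguments of cross-linking
immunoblots: the predicted molecular mass of a covalent adduct is the sum of
its monomer masses (e.g. a ~95 kDa receptor subunit plus a ~47 kDa chaperone
gives a ~142 kDa product, plus a second chaperone copy ~189 kDa), and band
intensities are made comparable across lanes by dividing each band by a
nonspecific internal-control band and normalising to a reference lane.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import InputError, MeasurementError


@dataclass(frozen=True)
class Species:
    name: str
    monomer_mass: float  # kDa

    def __post_init__(self) -> None:
        if self.monomer_mass <= 0:
            raise InputError(f"species {self.name!r}: mass must be positive")


@dataclass
class BandMeasurement:
    lane: str
    band: float               # arbitrary units
    internal_control: float   # arbitrary units

    def __post_init__(self) -> None:
        if self.band < 0:
            raise MeasurementError(f"lane {self.lane!r}: negative band intensity")
        if self.internal_control <= 0:
            raise MeasurementError(f"lane {self.lane!r}: internal control must be > 0")

    @property
    def ratio(self) -> float:
        return self.band / self.internal_control


def predicted_mass(stoichiometry: Mapping[Species, int]) -> float:
    """Sum of count x monomer mass (kDa) over the adduct's stoichiometry."""
    if not stoichiometry:
        raise InputError("empty stoichiometry")
    if any(c < 0 for c in stoichiometry.values()):
        raise InputError("stoichiometry counts must be >= 0")
    if all(c == 0 for c in stoichiometry.values()):
        raise InputError("stoichiometry counts must not all be zero")
    return float(sum(count * sp.monomer_mass for sp, count in stoichiometry.items()))


def normalize_bands(measurements: Sequence[BandMeasurement],
                    reference: str) -> dict[str, float]:
    """Control-normalised relative amounts; the reference lane maps to 1.00.

    Each band/control ratio is divided by the reference lane's ratio, making
    the result invariant to global intensity rescaling and unit choice.
    """
    by_lane = {m.lane: m for m in measurements}
    if reference not in by_lane:
        raise InputError(f"reference lane {reference!r} not among measurements")
    ref_ratio = by_lane[reference].ratio
    if ref_ratio == 0:
        raise MeasurementError(f"reference lane {reference!r} has zero band intensity")
    return {m.lane: m.ratio / ref_ratio for m in measurements}


def sum_amounts(amounts: Sequence[float]) -> float:
    """Arithmetic sum of relative amounts (e.g. the two products of a dual
    cross-linking lane)."""
    return float(sum(amounts))


def average_replicates(values: Sequence[float]) -> tuple[float, float]:
    """Mean and standard deviation over biological replicates.

    With a single replicate the standard deviation is reported as 0.0.
    """
    if not values:
        raise InputError("no replicate values")
    mean = statistics.fmean(values)
    sd = statistics.stdev(values) if len(values) > 1 else 0.0
    return mean, sd
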