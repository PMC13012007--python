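"""Plate designs for tumoroid drug screens.

A screen exposes each patient-derived tumoroid (PDT) sample to one or more
drugs in a five-step, ten-fold dilution series, four technical replicates per
condition, plus drug-free vehicle wells (0.5% DMSO).  Wells are imaged
repeatedly over the cultivation period; the drug-sensitivity readout is taken
on a single readout day (day 7 by default), with day 1 serving as the
per-well baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "DrugSeries",
    "PlateDesign",
    "OXALIPLATIN",
    "SN38",
    "DEFAULT_DESIGN",
    "VEHICLE_LABEL",
]

VEHICLE_LABEL = "DMSO"


@dataclass(frozen=True)
class DrugSeries:
    """One drug and its tested dilution series, in the drug's native units."""

    name: str
    unit: str
    concentrations: tuple[float, ...]

    def __post_init__(self) -> None:
        c = self.concentrations
        if len(c) < 2:
            raise ValueError(f"{self.name}: need at least 2 concentrations")
        if any(x <= 0 for x in c):
            raise ValueError(f"{self.name}: concentrations must be positive")
        for lo, hi in zip(c, c[1:]):
            if hi <= lo:
                raise ValueError(f"{self.name}: concentrations must be strictly increasing")
            if not math.isclose(hi / lo, 10.0, rel_tol=1e-9):
                raise ValueError(
                    f"{self.name}: dilution series must be 10-fold per step "
                    f"(got {hi}/{lo})"
                )

    @property
    def c_min(self) -> float:
        return self.concentrations[0]

    @property
    def c_max(self) -> float:
        return self.concentrations[-1]


#: Oxaliplatin, the variable agent of FOLFOX: 0.012–120 µmol/L.
OXALIPLATIN = DrugSeries("oxaliplatin", "umol/L", (0.012, 0.12, 1.2, 12.0, 120.0))

#: SN-38 (active metabolite of irinotecan, variable agent of FOLFIRI):
#: 0.032–320 nmol/L.
SN38 = DrugSeries("SN-38", "nmol/L", (0.032, 0.32, 3.2, 32.0, 320.0))


@dataclass(frozen=True)
class PlateDesign:
    """Layout of one sample's screen: drugs, replication and imaging schedule."""

    drugs: tuple[DrugSeries, ...] = (OXALIPLATIN, SN38)
    n_replicates: int = 4
    vehicle_label: str = VEHICLE_LABEL
    imaging_days: tuple[int, ...] = (1, 3, 5, 7)
    readout_day: int = 7

    def __post_init__(self) -> None:
        if not self.drugs:
            raise ValueError("design needs at least one drug")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be a positive integer")
        days = self.imaging_days
        if list(days) != sorted(set(days)) or any(d < 1 for d in days):
            raise ValueError("imaging_days must be strictly increasing positive integers")
        if 1 not in days:
            raise ValueError("day 1 (baseline) must be an imaging day")
        if self.readout_day not in days:
            raise ValueError(f"readout_day {self.readout_day} not in imaging_days {days}")

    def drug(self, name: str) -> DrugSeries:
        for d in self.drugs:
            if d.name == name:
                return d
        raise KeyError(name)

    @property
    def wells_per_sample(self) -> int:
        """Treated conditions plus one vehicle condition, all replicated."""
        n_conditions = sum(len(d.concentrations) for d in self.drugs) + 1
        return n_conditions * self.n_replicates


DEFAULT_DESIGN = PlateDesign()
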