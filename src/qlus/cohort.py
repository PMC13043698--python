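"""Oxygenation indices and per-infant aggregation of zone-level features.

Two noninvasive oxygenation indices are used. The oxygen saturation index

    OSI = MAP * FiO2(%) / SpO2(%)

with MAP the mean airway pressure in cmH2O; FiO2 and SpO2 are placed on a
common percentage scale so that OSI equals MAP when FiO2 = 1.0 and
SpO2 = 100% (the standard clinical convention; a raw-fraction variant is
available via ``percent_scale=False``). Higher OSI is worse oxygenation.
The SpO2/FiO2 (S/F) ratio — SpO2 in %, FiO2 as a fraction — is higher with
better oxygenation and is available for every infant; OSI additionally needs
a MAP, so it exists only under pressure-delivering support (for CPAP the set
pressure is taken as the MAP).

The eight zone-level feature sets of one infant are averaged into a single
representative Q-LUS value per feature. Undefined (NaN) correlation values
are excluded from that feature's mean rather than imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import IncompleteSubjectError, ValidationError
from .image_io import ZONES
from .texture import TextureFeatures

SUPPORT_MODES = ("none", "high_flow", "cpap", "cmv", "hfov")
#: Modes that deliver a measurable/set mean airway pressure.
PRESSURE_MODES = ("cpap", "cmv", "hfov")


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-infant oxygenation inputs recorded at the time of imaging."""

    subject_id: str
    support_mode: str
    fio2: float
    spo2: float
    map_cmH2O: float | None = None
    machine_id: str = ""

    def __post_init__(self) -> None:
        if self.support_mode not in SUPPORT_MODES:
            raise ValidationError(
                f"support_mode {self.support_mode!r} not in {SUPPORT_MODES}"
            )
        if not 0.21 <= self.fio2 <= 1.0:
            raise ValidationError(f"fio2 {self.fio2} outside [0.21, 1.0]")
        if not 0 < self.spo2 <= 100:
            raise ValidationError(f"spo2 {self.spo2} outside (0, 100]")
        if self.map_cmH2O is not None:
            if self.map_cmH2O <= 0:
                raise ValidationError("map_cmH2O must be positive when present")
            if self.support_mode not in PRESSURE_MODES:
                raise ValidationError(
                    f"MAP recorded under support_mode {self.support_mode!r}"
                )
        elif self.support_mode in PRESSURE_MODES:
            raise ValidationError(
                f"support_mode {self.support_mode!r} requires a MAP "
                "(for CPAP, the set pressure)"
            )


@dataclass(frozen=True)
class OxygenationIndices:
    """OSI (when MAP is available) and S/F ratio for one infant."""

    sf_ratio: float
    osi: float | None = None

    def __post_init__(self) -> None:
        if self.sf_ratio is None and self.osi is None:
            raise ValidationError("at least one oxygenation index must be present")


@dataclass(frozen=True)
class SubjectQlus:
    """Zone-averaged Q-LUS feature values for one infant."""

    subject_id: str
    features: Mapping[str, float]
    n_zones_used: int
    machine_id: str = ""


def oxygen_saturation_index(
    map_cmH2O: float, fio2: float, spo2: float, percent_scale: bool = True
) -> float:
    """OSI = MAP * FiO2 / SpO2 with FiO2 and SpO2 on the same % scale.

    Strictly increasing in MAP and FiO2, strictly decreasing in SpO2.
    """
    if map_cmH2O <= 0:
        raise ValidationError("map_cmH2O must be positive")
    if not 0.21 <= fio2 <= 1.0:
        raise ValidationError(f"fio2 {fio2} outside [0.21, 1.0]")
    if spo2 == 0:
        raise ZeroDivisionError("spo2 must be nonzero")
    if not 0 < spo2 <= 100:
        raise ValidationError(f"spo2 {spo2} outside (0, 100]")
    fio2_scaled = fio2 * 100.0 if percent_scale else fio2
    return map_cmH2O * fio2_scaled / spo2


def sf_ratio(spo2: float, fio2: float) -> float:
    """S/F ratio = SpO2(%) / FiO2(fraction); higher is better oxygenation."""
    if not 0.21 <= fio2 <= 1.0:
        raise ValidationError(f"fio2 {fio2} outside [0.21, 1.0]")
    if not 0 < spo2 <= 100:
        raise ValidationError(f"spo2 {spo2} outside (0, 100]")
    return spo2 / fio2


def compute_indices(
    rec: ClinicalRecord, percent_scale: bool = True
) -> OxygenationIndices:
    """Indices for one record: S/F always; OSI iff a MAP is available."""
    sf = sf_ratio(rec.spo2, rec.fio2)
    osi = None
    if rec.map_cmH2O is not None:
        osi = oxygen_saturation_index(
            rec.map_cmH2O, rec.fio2, rec.spo2, percent_scale=percent_scale
        )
    return OxygenationIndices(sf_ratio=sf, osi=osi)


def aggregate_subject(
    features_by_zone: Mapping[str, TextureFeatures],
    subject_id: str = "",
    machine_id: str = "",
    policy: str = "strict",
    min_zones_lenient: int = 6,
) -> SubjectQlus:
    """Average zone-level features into one representative Q-LUS value.

    Under the default ``strict`` policy all 8 zones must be present;
    ``lenient`` accepts ``min_zones_lenient`` or more. Each feature's subject
    value is the arithmetic mean over the zones where that feature is defined
    (NaN correlation values are excluded, never imputed).
    """
    if policy not in ("strict", "lenient"):
        raise ValueError(f"unknown aggregation policy {policy!r}")
    unknown = set(features_by_zone) - set(ZONES)
    if unknown:
        raise ValidationError(f"unknown zone labels: {sorted(unknown)}")
    n_zones = len(features_by_zone)
    min_zones = len(ZONES) if policy == "strict" else min_zones_lenient
    if n_zones < min_zones:
        raise IncompleteSubjectError(
            f"subject {subject_id!r}: {n_zones} zones present, "
            f"{min_zones} required under {policy} policy"
        )
    means: dict[str, float] = {}
    for name in TextureFeatures.FEATURE_NAMES:
        vals = [
            getattr(features_by_zone[zone], name)
            for zone in sorted(features_by_zone)  # fixed order: exact invariance
            if not math.isnan(getattr(features_by_zone[zone], name))
        ]
        means[name] = float(np.mean(vals)) if vals else float("nan")
    return SubjectQlus(
        subject_id=subject_id,
        features=means,
        n_zones_used=n_zones,
        machine_id=machine_id,
    )
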