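"""Ellipsoid model for right-ventricular volume and ejection fraction.

The right ventricle is approximated by an ellipsoid whose three diameters
are distances measurable in standard 2D transthoracic echocardiography
(TTE) views: the right ventricular inflow tract (RVIT3) and the right
ventricular long axis (RVLAX), both from the apical four-chamber view,
and the left ventricular maximum outer basal diameter (LVD) from the
apical two-chamber view.  The volume of an ellipsoid with diameters
``d1, d2, d3`` is ``(pi/6) * d1 * d2 * d3``, so with the distances in cm
the right-ventricular volume (RVV) in mL is::

    RVV = (pi/6) * RVIT3 * RVLAX * LVD

Applying the formula at end-diastole and end-systole gives the
end-diastolic and end-systolic volumes (EDV, ESV) from which the
ejection fraction follows as ``EF% = 100 * (EDV - ESV) / EDV``.

Systematic under-measurement of the distances cancels in the EF quota,
which is why EF (not absolute volume) is the quantity this model is used
for clinically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

from .exceptions import DomainError, UsageError

__all__ = [
    "Phase",
    "DistanceTriplet",
    "VolumePair",
    "EFResult",
    "ellipsoid_volume",
    "ejection_fraction",
    "ef_from_distances",
]


class Phase(str, Enum):
    """Cardiac phase at which a measurement was taken."""

    END_DIASTOLE = "end_diastole"
    END_SYSTOLE = "end_systole"


def _check_positive_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise DomainError(f"{name} must be finite, got {value!r}")
    if value <= 0.0:
        raise DomainError(f"{name} must be strictly positive, got {value!r}")
    return value


@dataclass(frozen=True)
class DistanceTriplet:
    """The three TTE distances (cm) defining the ellipsoid at one phase.

    No ordering between the distances is required; the volume formula is
    symmetric under any permutation of the three.
    """

    rvit3: float
    rvlax: float
    lvd: float
    phase: Phase | None = None

    def __post_init__(self) -> None:
        for name in ("rvit3", "rvlax", "lvd"):
            object.__setattr__(
                self, name, _check_positive_finite(name, getattr(self, name))
            )
        if self.phase is not None:
            object.__setattr__(self, "phase", Phase(self.phase))

    def scaled(self, factor: float) -> "DistanceTriplet":
        """Return a copy with every distance multiplied by ``factor``."""
        return DistanceTriplet(
            self.rvit3 * factor, self.rvlax * factor, self.lvd * factor, self.phase
        )


@dataclass(frozen=True)
class VolumePair:
    """End-diastolic and end-systolic volume (mL) for one ventricle.

    ``esv > edv`` is physiologically inverted but tolerated: noisy
    measurements can produce it and downstream statistics must still run.
    The condition is exposed via :attr:`inverted`.
    """

    edv: float
    esv: float

    def __post_init__(self) -> None:
        edv = float(self.edv)
        esv = float(self.esv)
        if not (math.isfinite(edv) and math.isfinite(esv)):
            raise DomainError(f"volumes must be finite, got edv={edv!r}, esv={esv!r}")
        if edv <= 0.0:
            raise DomainError(f"edv must be strictly positive, got {edv!r}")
        if esv < 0.0:
            raise DomainError(f"esv must be non-negative, got {esv!r}")
        object.__setattr__(self, "edv", edv)
        object.__setattr__(self, "esv", esv)

    @property
    def inverted(self) -> bool:
        return self.esv > self.edv


@dataclass(frozen=True)
class EFResult:
    """Ejection fraction on the 0-100 percent scale with its volumes.

    ``ef_percent`` is kept at full floating precision; rounding to the
    integer percent used in reports happens only at serialization time
    (:meth:`to_dict` with ``round_ef=True``).
    """

    ef_percent: float
    edv: float
    esv: float
    inverted_flag: bool = field(default=False)

    def to_dict(self, round_ef: bool = False) -> dict:
        ef = round(self.ef_percent) if round_ef else self.ef_percent
        return {
            "ef_percent": ef,
            "edv_ml": self.edv,
            "esv_ml": self.esv,
            "inverted": self.inverted_flag,
        }


def ellipsoid_volume(d: DistanceTriplet) -> float:
    """Ellipsoid RV volume in mL from a cm distance triplet.

    ``(pi/6) * rvit3 * rvlax * lvd`` — with cm inputs the result is in
    cm^3, i.e. mL.  Symmetric in the three distances.
    """
    return (math.pi / 6.0) * d.rvit3 * d.rvlax * d.lvd


def ejection_fraction(v: VolumePair) -> EFResult:
    """Ejection fraction ``100 * (edv - esv) / edv`` from a volume pair.

    If ``esv > edv`` the EF is negative and ``inverted_flag`` is set;
    the value is retained rather than rejected so that agreement
    statistics over noisy cohorts keep every subject.
    """
    ef = 100.0 * (v.edv - v.esv) / v.edv
    return EFResult(ef_percent=ef, edv=v.edv, esv=v.esv, inverted_flag=v.inverted)


def ef_from_distances(
    diastolic: DistanceTriplet, systolic: DistanceTriplet
) -> EFResult:
    """EF from a diastolic and a systolic distance triplet.

    Composition of :func:`ellipsoid_volume` (both phases) and
    :func:`ejection_fraction`.  Because the volume is a product of the
    three distances, the EF depends only on the per-distance
    systolic/diastolic ratios.  Phases, when annotated on the triplets,
    must match their argument positions.
    """
    if diastolic.phase is not None and diastolic.phase is not Phase.END_DIASTOLE:
        raise UsageError(
            f"diastolic triplet is annotated with phase {diastolic.phase.value!r}"
        )
    if systolic.phase is not None and systolic.phase is not Phase.END_SYSTOLE:
        raise UsageError(
            f"systolic triplet is annotated with phase {systolic.phase.value!r}"
        )
    return ejection_fraction(
        VolumePair(edv=ellipsoid_volume(diastolic), esv=ellipsoid_volume(systolic))
    )
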