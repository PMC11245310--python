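"""Equilibrium holdup mathematics.

The holdup assay measures, at equilibrium, the fraction of a prey protein
depleted from solution by bait-saturated resin (the *binding intensity*, BI).
Under bait excess this fraction equals the fraction bound of a single-site
bimolecular equilibrium, so BI and the dissociation constant Kd are linked by
the hyperbola

    BI = [bait] / ([bait] + Kd)        Kd = [bait] * (1 - BI) / BI

Affinities are carried as pK = -log10(Kd in molar), so that differences in
pK are proportional to binding free-energy differences. Measurements below
the panel's detection limit are *censored*: their pK holds the detection
threshold and must be read as an upper bound on affinity.

All concentrations are in molar internally; use the unit helpers on
:class:`BaitConcentration` at the I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "AffinityValue",
    "BindingIntensity",
    "BaitConcentration",
    "kd_to_pk",
    "pk_to_kd",
    "bi_to_kd",
    "kd_to_bi",
    "censor_affinity",
    "detection_pk",
]


@dataclass(frozen=True)
class AffinityValue:
    """A binding strength as pK = -log10(Kd / M).

    When ``censored`` is true the measurement was below the detection limit
    of its panel; ``pk`` then holds the detection-threshold pK and is an
    upper bound on the true affinity.
    """

    pk: float
    censored: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.pk):
            raise ValueError(f"pk must be finite, got {self.pk!r}")

    @property
    def kd(self) -> float:
        """Implied dissociation constant in molar."""
        return 10.0 ** (-self.pk)


@dataclass(frozen=True)
class BindingIntensity:
    """Fraction of prey depleted by the bait resin, in [0, 1).

    ``clamped`` records that a raw out-of-range measurement was clipped.
    Negative raw depletion is expected measurement noise and is clamped to
    zero; a raw value >= 1 is physically impossible and rejected.
    """

    bi: float
    clamped: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.bi < 1.0):
            raise ValueError(f"bi must lie in [0, 1), got {self.bi!r}")

    @classmethod
    def from_raw(cls, raw: float) -> "BindingIntensity":
        """Build from a raw depletion measurement, clamping noise below 0."""
        if not math.isfinite(raw):
            raise ValueError(f"raw binding intensity must be finite, got {raw!r}")
        if raw >= 1.0:
            raise ValueError(
                f"raw binding intensity {raw!r} >= 1 is impossible (full depletion "
                "of an equilibrium cannot be exceeded)"
            )
        if raw < 0.0:
            return cls(0.0, clamped=True)
        return cls(raw)


@dataclass(frozen=True)
class BaitConcentration:
    """Estimated immobilized-bait concentration in the holdup slurry (molar)."""

    conc: float

    def __post_init__(self) -> None:
        if not (self.conc > 0.0 and math.isfinite(self.conc)):
            raise ValueError(f"bait concentration must be positive, got {self.conc!r}")

    @classmethod
    def from_micromolar(cls, um: float) -> "BaitConcentration":
        return cls(um * 1e-6)

    @classmethod
    def from_nanomolar(cls, nm: float) -> "BaitConcentration":
        return cls(nm * 1e-9)


def kd_to_pk(kd: float) -> float:
    """pK = -log10(Kd), Kd in molar. 100 uM -> 4.0, 100 nM -> 7.0."""
    if not (kd > 0.0):
        raise ValueError(f"Kd must be positive, got {kd!r}")
    return -math.log10(kd)


def pk_to_kd(pk: float) -> float:
    """Inverse of :func:`kd_to_pk`."""
    return 10.0 ** (-pk)


def _as_bi(bi: "BindingIntensity | float") -> float:
    return bi.bi if isinstance(bi, BindingIntensity) else float(bi)


def bi_to_kd(bi: "BindingIntensity | float", bait: BaitConcentration) -> float:
    """Invert the hyperbola: Kd = [bait] * (1 - BI) / BI.

    BI == 0 signals no detectable depletion; infinity is returned (no finite
    Kd exists) and callers should censor via :func:`censor_affinity`.
    """
    b = _as_bi(bi)
    if b >= 1.0:
        raise ValueError(f"binding intensity {b!r} >= 1 has no finite-bait solution")
    if b <= 0.0:
        return math.inf
    return bait.conc * (1.0 - b) / b


def kd_to_bi(kd: float, bait: BaitConcentration) -> float:
    """Forward hyperbola: BI = [bait] / ([bait] + Kd). Kd=0 gives 1.0."""
    if kd < 0.0:
        raise ValueError(f"Kd must be nonnegative, got {kd!r}")
    return bait.conc / (bait.conc + kd)


def detection_pk(bi_threshold: float, bait: BaitConcentration) -> float:
    """Panel detection-threshold pK implied by a BI detection threshold."""
    if not (0.0 < bi_threshold < 1.0):
        raise ValueError(f"bi_threshold must lie in (0, 1), got {bi_threshold!r}")
    return kd_to_pk(bait.conc * (1.0 - bi_threshold) / bi_threshold)


def censor_affinity(
    bi: "BindingIntensity | float",
    bi_threshold: float,
    bait: BaitConcentration,
) -> AffinityValue:
    """Convert a BI to an :class:`AffinityValue`, censoring below threshold.

    A BI exactly at the threshold counts as censored (deterministic
    tie-break). Censored values carry the detection-threshold pK.
    """
    thr_pk = detection_pk(bi_threshold, bait)
    b = _as_bi(bi)
    if b <= bi_threshold:
        return AffinityValue(pk=thr_pk, censored=True)
    return AffinityValue(pk=kd_to_pk(bi_to_kd(b, bait)), censored=False)
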