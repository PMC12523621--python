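"""Parametric baseline hazards and piecewise effective-age hazard profiles.

The time-to-adverse-outcome model is a proportional-hazards intensity
``lambda(t | h) = h * lambda0(t)`` where ``lambda0`` is a parametric
baseline hazard (Weibull, Gamma or Log-Normal) and ``h > 0`` is a patient
heterogeneity multiplier.  Periodic checkups rejuvenate the patient: between
checkups the intensity is evaluated at an *effective age* rather than at
calendar time.  A :class:`HazardProfile` represents that piecewise-linear
effective-age map together with the baseline, and integrates the intensity
segment by segment using the closed-form cumulative hazard of the family.

Time is measured in months throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger("followup_pricing")

__all__ = [
    "BaselineHazard",
    "EffectiveAgeSegment",
    "HazardProfile",
    "hazard_at",
    "cumulative_hazard",
    "ConfigurationError",
    "DomainError",
]


class ConfigurationError(ValueError):
    """Invalid model configuration (unknown family, bad parameters...)."""


class DomainError(ValueError):
    """Argument outside the mathematical domain of an operation."""


_FAMILIES = ("weibull", "gamma", "lognormal")

#: grid used to probe monotonicity of the hazard (months)
_PROBE_GRID = np.linspace(1e-6, 120.0, 4001)


@dataclass(frozen=True)
class BaselineHazard:
    """Parametric baseline hazard ``lambda0(t)``, time in months.

    Parameters
    ----------
    family:
        One of ``weibull``, ``gamma``, ``lognormal``.
    params:
        Family parameters.  Weibull: ``{"shape": k, "scale": s}`` with
        ``lambda0(t) = (k/s) (t/s)^(k-1)``.  Gamma: ``{"shape", "scale"}``
        of the gamma event-time distribution.  Lognormal: ``{"sigma",
        "scale"}`` as in :data:`scipy.stats.lognorm` (``scale = exp(mu)``).

    Notes
    -----
    The pricing model assumes an increasing hazard that vanishes at
    discharge (``lambda0(0) = 0``).  Parameter sets violating this are
    accepted — some published fits do — but flagged via :attr:`increasing`
    and a logged warning, since dominance and price-bound sign guarantees
    then no longer hold.
    """

    family: str
    params: dict
    time_unit: str = "months"
    increasing: bool = field(init=False, compare=False)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigurationError(
                f"unknown baseline family {self.family!r}; expected one of {_FAMILIES}"
            )
        for name, value in self.params.items():
            if not (value > 0):
                raise ConfigurationError(
                    f"baseline parameter {name!r} must be positive, got {value!r}"
                )
        with np.errstate(all="ignore"):
            rates = np.asarray(self.rate(_PROBE_GRID))
            finite = np.isfinite(rates)
            increasing = bool(finite.all() and np.all(np.diff(rates) >= -1e-12))
        object.__setattr__(self, "increasing", increasing)
        if not increasing:
            logger.warning(
                "baseline hazard %s%s is not nondecreasing on the probe grid; "
                "the model's monotone-risk assumption is violated",
                self.family,
                self.params,
            )

    # -- distribution plumbing ------------------------------------------------

    def _frozen(self):
        if self.family == "gamma":
            return stats.gamma(self.params["shape"], scale=self.params["scale"])
        if self.family == "lognormal":
            return stats.lognorm(self.params["sigma"], scale=self.params["scale"])
        raise AssertionError(self.family)

    def rate(self, t):
        """Hazard rate ``lambda0(t)`` (vectorised)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise DomainError("hazard is defined for t >= 0 only")
        if self.family == "weibull":
            k = self.params["shape"]
            s = self.params["scale"]
            with np.errstate(divide="ignore", over="ignore"):
                out = (k / s) * np.power(t / s, k - 1.0)
            # k<1 diverges at 0; k=1 constant; k>1 vanishes at 0
            if k >= 1.0:
                out = np.where(t == 0.0, 0.0 if k > 1.0 else 1.0 / s, out)
            return out if out.shape else float(out)
        dist = self._frozen()
        sf = dist.sf(t)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(sf > 0, dist.pdf(t) / np.where(sf > 0, sf, 1.0), np.inf)
        return out if out.shape else float(out)

    def cumulative(self, t):
        """Cumulative hazard ``Lambda0(t) = -log S(t)``, closed form."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise DomainError("cumulative hazard is defined for t >= 0 only")
        if self.family == "weibull":
            with np.errstate(over="ignore"):
                out = np.power(t / self.params["scale"], self.params["shape"])
            return out if out.shape else float(out)
        dist = self._frozen()
        out = -dist.logsf(t)
        out = np.asarray(out)
        return out if out.shape else float(out)


@dataclass(frozen=True)
class EffectiveAgeSegment:
    """Half-open interval ``[start, end)`` with effective age
    ``age_offset + (t - start)``."""

    start: float
    end: float
    age_offset: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ConfigurationError(
                f"segment needs start < end, got [{self.start}, {self.end})"
            )
        if self.age_offset < 0:
            raise ConfigurationError("age_offset must be >= 0")

    def effective_age(self, t: float) -> float:
        return self.age_offset + (t - self.start)


@dataclass(frozen=True)
class HazardProfile:
    """A baseline hazard evaluated along a piecewise effective-age map.

    The segments are contiguous, ordered, and cover ``[t0, horizon)``.
    Evaluating at ``t`` yields ``h * lambda0(effective_age(t))``.
    """

    baseline: BaselineHazard
    segments: tuple[EffectiveAgeSegment, ...]

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        if not segs:
            raise ConfigurationError("profile needs at least one segment")
        for a, b in zip(segs, segs[1:]):
            if not math.isclose(a.end, b.start, rel_tol=0.0, abs_tol=1e-9):
                raise ConfigurationError(
                    f"segments must be contiguous: [{a.start},{a.end}) then "
                    f"[{b.start},{b.end})"
                )
        object.__setattr__(self, "segments", segs)

    @property
    def t0(self) -> float:
        return self.segments[0].start

    @property
    def horizon(self) -> float:
        return self.segments[-1].end

    def segment_at(self, t: float) -> EffectiveAgeSegment:
        if not (self.t0 <= t < self.horizon):
            raise DomainError(
                f"t={t} outside profile domain [{self.t0}, {self.horizon})"
            )
        for seg in self.segments:
            if seg.start <= t < seg.end:
                return seg
        return self.segments[-1]

    def effective_age(self, t: float) -> float:
        return self.segment_at(t).effective_age(t)

    def restrict(self, a: float, b: float) -> "HazardProfile":
        """Sub-profile on ``[a, b)``; effective-age map unchanged."""
        if not (self.t0 <= a < b <= self.horizon + 1e-9):
            raise DomainError(f"[{a}, {b}) not within [{self.t0}, {self.horizon})")
        parts = []
        for seg in self.segments:
            lo = max(seg.start, a)
            hi = min(seg.end, b)
            if hi - lo > 1e-12:
                parts.append(
                    EffectiveAgeSegment(lo, hi, seg.age_offset + (lo - seg.start))
                )
        return HazardProfile(self.baseline, tuple(parts))


def identity_profile(baseline: BaselineHazard, horizon: float) -> HazardProfile:
    """Profile with effective age equal to calendar time on ``[0, horizon)``."""
    return HazardProfile(baseline, (EffectiveAgeSegment(0.0, horizon, 0.0),))


def hazard_at(profile: HazardProfile, t: float, h: float) -> float:
    """Conditional intensity ``h * lambda0(effective age at t)``.

    Raises :class:`DomainError` for ``t`` outside the profile domain.
    """
    if h <= 0:
        raise DomainError("heterogeneity weight h must be > 0")
    return h * float(profile.baseline.rate(profile.effective_age(t)))


def cumulative_hazard(profile: HazardProfile, a: float, b: float, h: float = 1.0) -> float:
    """Expected event count ``h * int_a^b lambda0(effective age) dt``.

    Computed segment by segment from the family's closed-form cumulative
    hazard, so boundaries of the (non-smooth) effective-age map are never
    integrated across.
    """
    if a > b:
        raise DomainError(f"need a <= b, got a={a} > b={b}")
    if not (profile.t0 - 1e-9 <= a and b <= profile.horizon + 1e-9):
        raise DomainError(
            f"[{a}, {b}] not within profile domain [{profile.t0}, {profile.horizon})"
        )
    if a == b:
        return 0.0
    base = profile.baseline
    total = 0.0
    for seg in profile.segments:
        lo = max(seg.start, a)
        hi = min(seg.end, b)
        if hi - lo <= 1e-15:
            continue
        u0 = seg.age_offset + (lo - seg.start)
        u1 = seg.age_offset + (hi - seg.start)
        total += float(base.cumulative(u1)) - float(base.cumulative(u0))
    return h * total
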