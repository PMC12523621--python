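"""Periodic follow-up policies, checkup schedules and virtual ages.

A follow-up policy ``(n, tau)`` schedules checkups every ``tau`` months in
one of three windows: policy I within the warranty period ``[0, W]``,
policy II within the post-warranty period ``(W, L]``, policy III over the
whole planning horizon ``[0, L]``.  Each checkup rejuvenates the patient:
the age accrued since the previous checkup is discounted by the
age-reduction factor ``theta`` in [0, 1] (smaller means a more effective
checkup), giving the virtual age ``v_i = theta * t_i`` — equal to
``i * tau * theta`` when checkups start at time zero.  Between checkups the
hazard is read off the baseline at ``v_{i-1} + (t - t_{i-1})``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .hazard import (
    BaselineHazard,
    ConfigurationError,
    EffectiveAgeSegment,
    HazardProfile,
    identity_profile,
)

__all__ = ["Policy", "PolicySpec", "CheckupSchedule", "checkup_schedule", "build_profile"]

#: tolerance for comparing checkup times against window boundaries
_TIME_TOL = 1e-9


class Policy(str, enum.Enum):
    NONE = "NONE"
    I = "I"
    II = "II"
    III = "III"


@dataclass(frozen=True)
class PolicySpec:
    """A priced follow-up offer: policy window, interval, efficacy, costs."""

    policy: Policy
    tau: float
    theta: float
    W: float
    L: float
    cf: float

    def __post_init__(self) -> None:
        problems = []
        if self.tau <= 0:
            problems.append(f"tau must be > 0, got {self.tau}")
        if not 0.0 <= self.theta <= 1.0:
            problems.append(f"theta must be in [0, 1], got {self.theta}")
        if not 0.0 < self.W < self.L:
            problems.append(f"need 0 < W < L, got W={self.W}, L={self.L}")
        if self.cf < 0:
            problems.append(f"cf must be >= 0, got {self.cf}")
        if problems:
            raise ConfigurationError("; ".join(problems))

    # Table-3 checkup counts.  The floor is taken with a small tolerance so
    # that fractional tau (e.g. 6.5) hitting a boundary exactly still counts.
    @property
    def n1(self) -> int:
        return int(math.floor(self.W / self.tau + _TIME_TOL))

    @property
    def n2(self) -> int:
        return int(math.floor((self.L - self.W) / self.tau + _TIME_TOL))

    @property
    def n3(self) -> int:
        return int(math.floor(self.L / self.tau + _TIME_TOL))

    @property
    def n4(self) -> int:
        return int(math.floor(self.W / self.tau + _TIME_TOL))

    @property
    def n_checkups(self) -> int:
        """Number of checkups the policy actually delivers."""
        return {
            Policy.NONE: 0,
            Policy.I: self.n1,
            Policy.II: self.n2,
            Policy.III: self.n3,
        }[self.policy]


@dataclass(frozen=True)
class CheckupSchedule:
    """Checkup times ``t_i`` and post-checkup virtual ages ``v_i = i tau theta``."""

    times: tuple[float, ...]
    virtual_ages: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.times)


def checkup_schedule(spec: PolicySpec) -> CheckupSchedule:
    """Checkup times for the policy window; empty when tau exceeds it.

    Policy I: ``i*tau`` for ``i = 1..n1`` (a checkup landing exactly at W is
    included; its virtual age governs the post-warranty hazard).
    Policy II: ``W + i*tau`` for ``i = 1..n2``.
    Policy III: ``i*tau`` for ``i = 1..n3``.
    """
    p = spec.policy
    if p is Policy.NONE:
        return CheckupSchedule((), ())
    if p is Policy.I:
        count, offset = spec.n1, 0.0
    elif p is Policy.II:
        count, offset = spec.n2, spec.W
    else:
        count, offset = spec.n3, 0.0
    times = tuple(offset + i * spec.tau for i in range(1, count + 1))
    # Kijima-type-I virtual age: each inter-checkup age increment is
    # discounted by theta, so v_i = theta * t_i.  For policies I and III
    # (checkups from time 0) this telescopes to the arithmetic form
    # v_i = i*tau*theta; for policy II it keeps the first checkup's
    # rejuvenation proportional to the age actually accrued, so theta = 1
    # leaves the hazard untouched under every policy.
    vages = tuple(spec.theta * t for t in times)
    return CheckupSchedule(times, vages)


def build_profile(spec: PolicySpec, baseline: BaselineHazard) -> HazardProfile:
    """Piecewise effective-age hazard profile on ``[0, L)``.

    Before the first checkup the effective age is calendar time; between
    checkups ``t_{i-1}`` and ``t_i`` it is ``v_{i-1} + (t - t_{i-1})``; after
    the final checkup of the window the last virtual age carries through to
    ``L``.  Use :meth:`HazardProfile.restrict` for the warranty-window
    ``[0, W)`` and post-warranty ``[W, L)`` pieces.
    """
    sched = checkup_schedule(spec)
    if not sched.times:
        return identity_profile(baseline, spec.L)
    segments = []
    prev_t, prev_v = 0.0, 0.0
    for t_i, v_i in zip(sched.times, sched.virtual_ages):
        t_i = min(t_i, spec.L)  # guard float spill past the horizon
        if t_i - prev_t > _TIME_TOL:
            segments.append(EffectiveAgeSegment(prev_t, t_i, prev_v))
        prev_t, prev_v = t_i, v_i
    if spec.L - prev_t > _TIME_TOL:
        segments.append(EffectiveAgeSegment(prev_t, spec.L, prev_v))
    return HazardProfile(baseline, tuple(segments))
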