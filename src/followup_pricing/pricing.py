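"""Expected costs and win-win price intervals for follow-up policies.

Adverse outcomes arrive as a non-homogeneous Poisson process, so the
expected AO count over a window is the integral of the effective-age
intensity.  For risk group ``k`` with weight
``phi_k = int_{h_{k-1}}^{h_k} h g(h) dh`` and per-AO treatment cost
``c_k^r``:

* patient, no purchase:      ``c_k^r phi_k H_none(W, L)``
* patient, purchase at P:    ``P + c_k^r phi_k H_pol(W, L)``
* hospital, no provision:    ``c_k^r phi_k H_none(0, W)``
* hospital, provision at P:  ``c_k^r phi_k H_pol(0, W) + n_j c_f - P``

where ``H_pol(a, b)`` is the baseline-time integral of the policy's
effective-age hazard over ``[a, b]`` and ``n_j`` the checkup count.
Equating purchase with no-purchase (and provision with no-provision)
gives the closed-form price bounds

* ``P_p = c_k^r phi_k [H_none(W,L) - H_pol(W,L)]``  (patient maximum)
* ``P_h = c_k^r phi_k [H_pol(0,W) - H_none(0,W)] + n_j c_f``  (hospital
  minimum; floored at zero, the raw value is kept for diagnostics)

The win-win interval ``[P_h, P_p]`` exists iff ``P_p > P_h``.  For policy
II the warranty-window hazard is untouched, so ``P_h = n_2 c_f`` exactly.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .frailty import RiskStratum
from .hazard import BaselineHazard, ConfigurationError, cumulative_hazard, identity_profile
from .policy import Policy, PolicySpec, build_profile

__all__ = [
    "Party",
    "CostSummary",
    "PriceInterval",
    "expected_costs",
    "price_bounds",
    "sweep",
    "SWEEPABLE",
]


class Party(str, enum.Enum):
    HOSPITAL = "hospital"
    PATIENT = "patient"


@dataclass(frozen=True)
class CostSummary:
    """Expected cost of one party under one purchase decision."""

    party: Party
    policy: Policy
    stratum: int
    purchase: bool
    treatment: float
    checkup: float
    price_transfer: float

    @property
    def expected_cost(self) -> float:
        return self.treatment + self.checkup + self.price_transfer


@dataclass(frozen=True)
class PriceInterval:
    """Win-win price interval for one policy and risk group."""

    policy: Policy
    stratum: int
    P_h: float
    P_p: float
    P_h_raw: float  # before flooring at zero
    exists: bool
    width: float


def _window_integrals(spec: PolicySpec, baseline: BaselineHazard):
    """Baseline-time integrals (h = 1) of the policy and no-policy hazards."""
    profile = build_profile(spec, baseline)
    none = identity_profile(baseline, spec.L)
    return {
        "pol_w": cumulative_hazard(profile, 0.0, spec.W),
        "pol_pw": cumulative_hazard(profile, spec.W, spec.L),
        "none_w": cumulative_hazard(none, 0.0, spec.W),
        "none_pw": cumulative_hazard(none, spec.W, spec.L),
    }


def expected_costs(
    spec: PolicySpec,
    stratum: RiskStratum,
    baseline: BaselineHazard,
    P_k: float,
) -> dict[tuple[str, bool], CostSummary]:
    """The four expected-cost summaries (party x purchase decision).

    Keyed by ``(party value, purchase)``, e.g. ``("patient", True)``.
    """
    H = _window_integrals(spec, baseline)
    c, phi = stratum.treatment_cost, stratum.phi
    n_j = spec.n_checkups
    k = stratum.index
    out = {
        ("patient", False): CostSummary(
            Party.PATIENT, spec.policy, k, False, c * phi * H["none_pw"], 0.0, 0.0
        ),
        ("patient", True): CostSummary(
            Party.PATIENT, spec.policy, k, True, c * phi * H["pol_pw"], 0.0, P_k
        ),
        ("hospital", False): CostSummary(
            Party.HOSPITAL, spec.policy, k, False, c * phi * H["none_w"], 0.0, 0.0
        ),
        ("hospital", True): CostSummary(
            Party.HOSPITAL, spec.policy, k, True, c * phi * H["pol_w"], n_j * spec.cf, -P_k
        ),
    }
    return out


def price_bounds(
    spec: PolicySpec, stratum: RiskStratum, baseline: BaselineHazard
) -> PriceInterval:
    """Win-win price interval via the closed-form bounds.

    Computed directly from segment-wise closed-form cumulative hazards (not
    by differencing the full cost functions) so the bounds are exact up to
    the family's cumulative-hazard evaluation.
    """
    if spec.policy is Policy.NONE:
        return PriceInterval(spec.policy, stratum.index, 0.0, 0.0, 0.0, False, 0.0)
    H = _window_integrals(spec, baseline)
    c, phi = stratum.treatment_cost, stratum.phi
    P_p = c * phi * (H["none_pw"] - H["pol_pw"])
    P_h_raw = c * phi * (H["pol_w"] - H["none_w"]) + spec.n_checkups * spec.cf
    P_h = max(0.0, P_h_raw)
    exists = P_p > P_h
    return PriceInterval(
        spec.policy,
        stratum.index,
        P_h,
        P_p,
        P_h_raw,
        exists,
        max(0.0, P_p - P_h),
    )


SWEEPABLE = ("tau", "theta", "cf", "ckr", "L")


def sweep(
    spec: PolicySpec,
    strata: Sequence[RiskStratum],
    baseline: BaselineHazard,
    parameter: str,
    grid: Iterable[float],
    policies: Sequence[Policy] = (Policy.I, Policy.II, Policy.III),
) -> pd.DataFrame:
    """Price intervals over a one-parameter grid.

    ``parameter`` is one of ``tau``, ``theta``, ``cf``, ``L`` (absolute
    values) or ``ckr`` (multiplicative factors applied to every stratum's
    treatment cost; 1.0 is the baseline).  Rows are emitted in grid order,
    one per (value, policy, stratum); a grid value that violates the policy
    invariants yields rows with an ``error`` message instead of aborting
    the sweep.
    """
    if parameter not in SWEEPABLE:
        raise ConfigurationError(
            f"cannot sweep {parameter!r}; choose one of {SWEEPABLE}"
        )
    rows = []
    for value in grid:
        for policy in policies:
            try:
                if parameter == "ckr":
                    cur = replace(spec, policy=policy)
                    cur_strata = [
                        replace(s, treatment_cost=s.treatment_cost * value)
                        for s in strata
                    ]
                else:
                    cur = replace(spec, policy=policy, **{parameter: value})
                    cur_strata = list(strata)
            except (ConfigurationError, ValueError) as err:
                for s in strata:
                    rows.append(
                        {
                            "value": value,
                            "policy": policy.value,
                            "stratum": s.index,
                            "error": str(err),
                        }
                    )
                continue
            for s in cur_strata:
                iv = price_bounds(cur, s, baseline)
                rows.append(
                    {
                        "value": value,
                        "policy": policy.value,
                        "stratum": s.index,
                        "P_h": iv.P_h,
                        "P_p": iv.P_p,
                        "exists": iv.exists,
                        "width": iv.width,
                        "error": "",
                    }
                )
    df = pd.DataFrame(rows)
    df.insert(0, "parameter", parameter)
    return df
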