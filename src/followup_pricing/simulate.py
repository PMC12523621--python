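"""Synthetic cohorts and Monte-Carlo oracles for the pricing model.

Generates heterogeneous patients — covariates ``X``, Gamma frailty ``Z``
(mean 1, variance ``sigma``), combined multiplier ``h = Z exp(X B)`` — and
simulates their recurrent adverse-outcome times as a non-homogeneous
Poisson process with intensity ``h * lambda0(effective age)`` under any
follow-up policy.  Event times come from Lewis-Shedler thinning with a
piecewise-constant majorant per effective-age segment, so the simulation
touches only the *pointwise* hazard and stays an independent check on the
closed-form cumulative-hazard integrals used by the pricing module.

Default study conditions (see :class:`SimConfig`) emulate a paediatric
chronic-disease cohort: a 36-month observation window, an increasing
Weibull baseline, and two covariates — a glycaemic-control deviation score
(continuous, sd 1.8) and centred age in years (sd 4).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .frailty import HeterogeneityModel, PatientRecord, RiskStratum
from .hazard import BaselineHazard, DomainError, HazardProfile, identity_profile
from .policy import Policy, PolicySpec, build_profile, checkup_schedule

logger = logging.getLogger("followup_pricing")

__all__ = ["SimConfig", "simulate_cohort", "simulate_nhpp", "simulate_expected_cost"]


class MajorantError(RuntimeError):
    """The thinning majorant was violated or could not be constructed."""


def _default_covariates(rng: np.random.Generator, n: int) -> np.ndarray:
    """Glycaemic-control deviation (sd 1.8) and centred age in years (sd 4)."""
    control = rng.normal(0.0, 1.8, size=n)
    age = rng.normal(0.0, 4.0, size=n)
    return np.column_stack([control, age])


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic cohort.

    ``covariate_sampler(rng, n) -> (n, p) array`` draws the observed
    heterogeneity; ``B`` are the log-hazard-ratio coefficients; ``sigma``
    the frailty variance.  ``window`` is the per-patient observation span
    in months.  A fixed ``seed`` makes the cohort bit-reproducible.
    """

    n_patients: int = 500
    B: tuple[float, ...] = (0.3, -0.05)
    sigma: float = 0.6
    baseline: BaselineHazard = field(
        default_factory=lambda: BaselineHazard("weibull", {"shape": 2.0, "scale": 15.0})
    )
    policy: PolicySpec = field(
        default_factory=lambda: PolicySpec(Policy.NONE, 3.0, 0.1, 12.0, 36.0, 428.0)
    )
    window: float = 36.0
    seed: int = 0
    covariate_sampler: Callable[[np.random.Generator, int], np.ndarray] = field(
        default=_default_covariates, compare=False
    )

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise DomainError("sigma must be >= 0")
        if self.n_patients < 1:
            raise DomainError("n_patients must be >= 1")


def _segment_majorant(profile: HazardProfile, seg_idx: int, hi: float) -> float:
    """Supremum of lambda0(effective age) on a segment (h excluded)."""
    seg = profile.segments[seg_idx]
    end = min(seg.end, hi)
    age_lo = seg.age_offset
    age_hi = seg.age_offset + (end - seg.start)
    base = profile.baseline
    if base.increasing:
        return float(base.rate(age_hi))
    # bracket the supremum numerically on a fine grid with headroom
    ages = np.linspace(max(age_lo, 1e-9), age_hi, 257)
    sup = float(np.max(base.rate(ages))) * 1.05
    if not math.isfinite(sup):
        raise MajorantError(
            f"unbounded hazard on segment [{seg.start}, {seg.end})"
        )
    return sup


def simulate_nhpp(
    profile: HazardProfile,
    h: float,
    rng: np.random.Generator,
    t_max: float | None = None,
) -> list[float]:
    """Event times of the NHPP with intensity ``h*lambda0(eff age)`` on
    ``[profile.t0, t_max)`` by Lewis-Shedler thinning.

    Accepted points are re-checked against the majorant; a violation is a
    hard error (it would mean the simulation is biased).
    """
    if t_max is None:
        t_max = profile.horizon
    events: list[float] = []
    proposals = 0
    accepted = 0
    for idx, seg in enumerate(profile.segments):
        if seg.start >= t_max:
            break
        end = min(seg.end, t_max)
        lam_bar = h * _segment_majorant(profile, idx, t_max)
        if lam_bar <= 0:
            continue
        t = seg.start
        while True:
            t += rng.exponential(1.0 / lam_bar)
            if t >= end:
                break
            proposals += 1
            lam = h * float(profile.baseline.rate(seg.effective_age(t)))
            if lam > lam_bar * (1.0 + 1e-9):
                raise MajorantError(
                    f"intensity {lam:.6g} exceeds majorant {lam_bar:.6g} "
                    f"at t={t:.6g} on segment [{seg.start}, {seg.end})"
                )
            if rng.uniform() * lam_bar <= lam:
                events.append(t)
                accepted += 1
    if proposals:
        logger.debug(
            "thinning acceptance rate %.3f (%d/%d)",
            accepted / proposals,
            accepted,
            proposals,
        )
    return events


def simulate_cohort(cfg: SimConfig) -> list[PatientRecord]:
    """Draw a synthetic cohort under the configured study conditions.

    Per patient: covariates, frailty ``Z ~ Gamma(mean 1, var sigma)``
    (degenerate at 1 when ``sigma = 0``), ``h = Z exp(X B)``, then AO times
    on ``[0, window)`` from the policy's effective-age NHPP.  Randomness
    flows from a single seeded generator; each patient consumes an
    independent spawned substream so cohorts are reproducible.
    """
    root = np.random.SeedSequence(cfg.seed)
    cov_rng = np.random.default_rng(root.spawn(1)[0])
    X = cfg.covariate_sampler(cov_rng, cfg.n_patients)
    B = np.asarray(cfg.B, dtype=float)
    if X.shape[1] != B.size:
        raise DomainError(
            f"covariate dimension {X.shape[1]} does not match len(B)={B.size}"
        )
    profile = build_profile(cfg.policy, cfg.baseline)
    if profile.horizon < cfg.window - 1e-9:
        raise DomainError("policy horizon L must cover the observation window")
    sched = checkup_schedule(cfg.policy)
    followups = tuple(t for t in sched.times if t <= cfg.window + 1e-9)

    streams = root.spawn(1 + cfg.n_patients)[1:]
    records = []
    for i in range(cfg.n_patients):
        rng = np.random.default_rng(streams[i])
        if cfg.sigma > 0:
            a = 1.0 / cfg.sigma
            z = rng.gamma(shape=a, scale=1.0 / a)
        else:
            z = 1.0
        h = z * math.exp(float(X[i] @ B))
        times = simulate_nhpp(profile, h, rng, t_max=cfg.window)
        records.append(
            PatientRecord(
                id=f"P{i:05d}",
                covariates=tuple(X[i]),
                event_times=tuple(times),
                window_end=cfg.window,
                followup_times=followups,
                frailty=z,
            )
        )
    return records


def _truncated_h_sampler(
    model: HeterogeneityModel, bounds: tuple[float, float]
) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Inverse-CDF sampler of h restricted to a stratum's bounds."""
    lo, hi = bounds
    F_lo, F_hi = float(model.cdf(lo)), float(model.cdf(hi))
    if F_hi - F_lo <= 0:
        raise DomainError(f"stratum ({lo}, {hi}) carries no probability mass")

    def draw(rng: np.random.Generator, size: int) -> np.ndarray:
        q = F_lo + (F_hi - F_lo) * rng.uniform(size=size)
        return np.asarray(model.ppf(q), dtype=float)

    return draw


def simulate_expected_cost(
    spec: PolicySpec,
    stratum: RiskStratum,
    h_model: HeterogeneityModel,
    baseline: BaselineHazard,
    P_k: float,
    replicates: int,
    seed: int,
    party: str = "patient",
    purchase: bool = True,
) -> dict:
    """Monte-Carlo estimate of an expected-cost summary with standard error.

    Draws ``h`` from the stratum-truncated heterogeneity distribution,
    simulates AO event times by thinning in the party's cost window
    (``[W, L]`` for the patient, ``[0, W]`` for the hospital), and averages
    ``c_k^r * count`` plus the deterministic checkup/price terms.

    Note the treatment term estimates ``c_k^r E[h] H`` *conditional on the
    stratum normalised to probability one*; the closed-form counterpart is
    ``c_k^r phi_k H`` with ``phi_k = mass * E[h | stratum]``, so comparisons
    multiply by the stratum mass (see tests) or compare per-membership costs.
    """
    if replicates < 100:
        raise DomainError("need at least 100 replicates")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    draw_h = _truncated_h_sampler(h_model, stratum.bounds)
    if purchase and spec.policy is not Policy.NONE:
        profile = build_profile(spec, baseline)
    else:
        profile = identity_profile(baseline, spec.L)
    if party == "patient":
        window = (spec.W, spec.L)
        checkup = 0.0
        price = P_k if purchase else 0.0
    else:
        window = (0.0, spec.W)
        checkup = spec.n_checkups * spec.cf if purchase else 0.0
        price = -P_k if purchase else 0.0

    hs = draw_h(rng, replicates)
    counts = np.empty(replicates)
    sub = profile.restrict(*window)
    for r in range(replicates):
        counts[r] = len(simulate_nhpp(sub, float(hs[r]), rng))
    treat = stratum.treatment_cost * counts
    mean_treat = float(np.mean(treat))
    se_treat = float(np.std(treat, ddof=1) / math.sqrt(replicates))
    return {
        "party": party,
        "policy": spec.policy.value,
        "stratum": stratum.index,
        "purchase": purchase,
        "treatment": mean_treat,
        "treatment_se": se_treat,
        "checkup": checkup,
        "price_transfer": price,
        "expected_cost": mean_treat + checkup + price,
        "replicates": replicates,
        "mean_count": float(np.mean(counts)),
    }
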