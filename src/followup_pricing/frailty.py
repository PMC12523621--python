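"""Patient heterogeneity: frailty model, risk stratification, fitting.

The conditional adverse-outcome (AO) intensity is
``lambda(t | X, Z) = Z * exp(X B) * lambda0(t)`` with a Gamma frailty
``Z`` of mean 1 and variance ``sigma``.  The combined multiplier
``h = Z * exp(X B)`` summarises both observed and unobserved heterogeneity;
its distribution ``g(h)``, truncated to the observed range
``[h_min, h_max]``, drives the stratification of patients into ``N``
equal-probability risk groups and the group weights
``phi_k = int_{h_{k-1}}^{h_k} h g(h) dh`` that enter the pricing formulas.

Fitting integrates the frailty out of the recurrent-event likelihood
analytically: for a patient with ``m`` events at times ``t_j`` observed on
``[0, T]``, conditional on ``Z = z`` the NHPP likelihood is
``prod_j z e^{XB} lambda0(t_j) * exp(-z e^{XB} Lambda0(T))`` and the Gamma
mixture gives the closed-form marginal used by :func:`fit_frailty_model`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .hazard import BaselineHazard, ConfigurationError, DomainError

logger = logging.getLogger("followup_pricing")

__all__ = [
    "HeterogeneityModel",
    "RiskStratum",
    "PatientRecord",
    "FitResult",
    "stratify",
    "phi_weight",
    "fit_frailty_model",
    "FitError",
]


class FitError(RuntimeError):
    """Optimizer failed to converge; carries the best iterate found."""

    def __init__(self, message: str, best: "FitResult | None" = None) -> None:
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class HeterogeneityModel:
    """Distribution of the combined heterogeneity multiplier ``h``.

    ``gamma`` is parameterised by ``(mean, variance)``; ``uniform`` by
    ``(low, high)``; ``empirical`` carries the fitted per-patient ``h``
    values.  ``observed_range`` truncates all stratification integrals.
    """

    family: str
    params: dict
    observed_range: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.observed_range
        if not 0.0 < lo < hi:
            raise ConfigurationError(
                f"observed_range must satisfy 0 < h_min < h_max, got ({lo}, {hi})"
            )
        if self.family == "gamma":
            m, v = self.params["mean"], self.params["variance"]
            if m <= 0 or v <= 0:
                raise ConfigurationError("gamma h-model needs positive mean and variance")
        elif self.family == "uniform":
            a, b = self.params["low"], self.params["high"]
            if not a < b:
                raise ConfigurationError("uniform h-model needs low < high")
        elif self.family == "empirical":
            vals = np.asarray(self.params["values"], dtype=float)
            if vals.size == 0 or np.any(vals <= 0):
                raise ConfigurationError("empirical h-model needs positive values")
        else:
            raise ConfigurationError(f"unknown heterogeneity family {self.family!r}")

    def _frozen(self):
        if self.family == "gamma":
            m, v = self.params["mean"], self.params["variance"]
            return stats.gamma(m * m / v, scale=v / m)
        if self.family == "uniform":
            a, b = self.params["low"], self.params["high"]
            return stats.uniform(a, b - a)
        raise AssertionError(self.family)

    def cdf(self, h):
        if self.family == "empirical":
            vals = np.sort(np.asarray(self.params["values"], dtype=float))
            return np.searchsorted(vals, h, side="right") / vals.size
        return self._frozen().cdf(h)

    def ppf(self, q):
        if self.family == "empirical":
            return np.quantile(np.asarray(self.params["values"], dtype=float), q)
        return self._frozen().ppf(q)

    def pdf(self, h):
        if self.family == "empirical":
            raise ConfigurationError("empirical h-model has no density")
        return self._frozen().pdf(h)

    def truncated_mass(self) -> float:
        lo, hi = self.observed_range
        return float(self.cdf(hi) - self.cdf(lo))


@dataclass(frozen=True)
class RiskStratum:
    """Risk group ``k`` on ``(h_{k-1}, h_k]`` with weight phi and AO cost."""

    index: int
    bounds: tuple[float, float]
    mass: float
    phi: float
    treatment_cost: float

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not lo < hi:
            raise ConfigurationError(f"stratum bounds need lo < hi, got ({lo}, {hi})")
        if self.phi <= 0:
            raise ConfigurationError("stratum weight phi must be > 0")
        if self.treatment_cost < 0:
            raise ConfigurationError("treatment cost must be >= 0")


@dataclass(frozen=True)
class PatientRecord:
    """One patient's covariates and recurrent AO history on ``[0, window_end]``."""

    id: str
    covariates: tuple[float, ...]
    event_times: tuple[float, ...]
    window_end: float
    followup_times: tuple[float, ...] = ()
    frailty: float | None = None  # known only for synthetic cohorts

    def __post_init__(self) -> None:
        ev = tuple(float(t) for t in self.event_times)
        if any(b <= a for a, b in zip(ev, ev[1:])):
            raise ConfigurationError(f"patient {self.id}: event times must be strictly increasing")
        if ev and (ev[0] <= 0 or ev[-1] >= self.window_end):
            raise ConfigurationError(
                f"patient {self.id}: events must lie strictly inside (0, window_end)"
            )


@dataclass(frozen=True)
class FitResult:
    """Fitted Gamma-frailty proportional-hazards model."""

    sigma_hat: float
    B_hat: tuple[float, ...]
    baseline: BaselineHazard
    log_marginal_likelihood: float
    h_model: HeterogeneityModel
    aic: float
    per_family: dict = field(default_factory=dict, compare=False)
    patient_h: tuple[float, ...] = ()


# -- stratification -----------------------------------------------------------


def stratify(model: HeterogeneityModel, N: int) -> list[tuple[float, float]]:
    """Equal-probability cutoffs of ``g(h)`` truncated to the observed range.

    Returns ``N`` intervals ``(h_{k-1}, h_k]`` with
    ``h_0 = h_min < ... < h_N = h_max`` such that each carries mass
    ``(1/N) * int_{h_min}^{h_max} g(h) dh``.
    """
    if N < 1:
        raise DomainError(f"N must be >= 1, got {N}")
    lo, hi = model.observed_range
    F_lo = float(model.cdf(lo))
    F_hi = float(model.cdf(hi))
    total = F_hi - F_lo
    if total <= 0:
        raise ConfigurationError(
            f"heterogeneity model carries no mass on observed_range ({lo}, {hi})"
        )
    cuts = [lo]
    for k in range(1, N):
        target = F_lo + total * k / N
        guess = float(model.ppf(target))
        if model.family == "empirical":
            cuts.append(guess)
            continue
        # polish the quantile by root-finding on the CDF
        root = optimize.brentq(
            lambda h: float(model.cdf(h)) - target, lo, hi, xtol=1e-10
        )
        cuts.append(root)
    cuts.append(hi)
    return [(cuts[k], cuts[k + 1]) for k in range(N)]


def phi_weight(model: HeterogeneityModel, lo: float, hi: float) -> float:
    """First-moment weight ``phi = int_lo^hi h g(h) dh``.

    For the gamma family this uses the incomplete-gamma identity
    ``int h g(h) dh = mean * [F_(shape+1)(hi) - F_(shape+1)(lo)]``; other
    families fall back to adaptive quadrature.
    """
    if lo >= hi:
        raise DomainError(f"need lo < hi, got lo={lo}, hi={hi}")
    rng = model.observed_range
    if lo < rng[0] - 1e-12 or hi > rng[1] + 1e-12:
        raise DomainError(f"({lo}, {hi}) outside observed_range {rng}")
    if model.family == "gamma":
        m, v = model.params["mean"], model.params["variance"]
        shape, scale = m * m / v, v / m
        shifted = stats.gamma(shape + 1.0, scale=scale)
        return float(m * (shifted.cdf(hi) - shifted.cdf(lo)))
    if model.family == "uniform":
        a, b = model.params["low"], model.params["high"]
        lo_c, hi_c = max(lo, a), min(hi, b)
        if hi_c <= lo_c:
            return 0.0
        return (hi_c**2 - lo_c**2) / (2.0 * (b - a))
    if model.family == "empirical":
        vals = np.asarray(model.params["values"], dtype=float)
        sel = vals[(vals > lo) & (vals <= hi)]
        return float(sel.sum() / vals.size)
    from scipy.integrate import quad

    val, _ = quad(lambda h: h * model.pdf(h), lo, hi, epsabs=1e-12, epsrel=1e-10)
    return float(val)


def build_strata(
    model: HeterogeneityModel, N: int, treatment_costs: Sequence[float]
) -> list[RiskStratum]:
    """Stratify and attach per-group AO treatment costs."""
    if len(treatment_costs) != N:
        raise ConfigurationError(
            f"expected {N} treatment costs, got {len(treatment_costs)}"
        )
    bounds = stratify(model, N)
    total = model.truncated_mass()
    return [
        RiskStratum(
            index=k + 1,
            bounds=bnd,
            mass=total / N,
            phi=phi_weight(model, *bnd),
            treatment_cost=float(c),
        )
        for k, (bnd, c) in enumerate(zip(bounds, treatment_costs))
    ]


# -- maximum marginal likelihood fitting --------------------------------------

_BASELINE_NPARAMS = {"weibull": 2, "gamma": 2, "lognormal": 2}


def _baseline_from_vector(family: str, vec: np.ndarray) -> BaselineHazard:
    a, b = np.exp(vec)
    if family == "weibull":
        return BaselineHazard("weibull", {"shape": a, "scale": b})
    if family == "gamma":
        return BaselineHazard("gamma", {"shape": a, "scale": b})
    return BaselineHazard("lognormal", {"sigma": a, "scale": b})


def _neg_log_marginal(
    theta: np.ndarray,
    family: str,
    X: np.ndarray,
    m: np.ndarray,
    log_rate_terms_fn,
    Lambda_T_fn,
) -> float:
    """Negative marginal log-likelihood; theta = (B, log sigma, log base params)."""
    p = X.shape[1]
    B = theta[:p]
    sigma = math.exp(theta[p])
    bvec = theta[p + 1 :]
    try:
        log_lam_sum, Lambda_T = log_rate_terms_fn(bvec), Lambda_T_fn(bvec)
    except (FloatingPointError, ValueError):
        return 1e12
    if not (np.all(np.isfinite(log_lam_sum)) and np.all(np.isfinite(Lambda_T))):
        return 1e12
    a = 1.0 / sigma
    # log integral of z^m e^{-z mu} against Gamma(a, scale 1/a); wild
    # exploration steps may overflow — they are rejected by the finite check
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        eta = X @ B
        mu = np.exp(eta) * Lambda_T
        ll = (
            m * eta
            + log_lam_sum
            + special.gammaln(a + m)
            - special.gammaln(a)
            - a * np.log1p(mu / a)
            - m * np.log(a + mu)
        )
        out = -float(np.sum(ll))
    return out if math.isfinite(out) else 1e12


def _fit_one_family(
    family: str, X: np.ndarray, records: Sequence[PatientRecord]
) -> tuple[float, np.ndarray, BaselineHazard, float]:
    """Maximise the marginal likelihood for one baseline family."""
    m = np.array([len(r.event_times) for r in records], dtype=float)
    T = np.array([r.window_end for r in records], dtype=float)
    all_events = np.concatenate(
        [np.asarray(r.event_times, dtype=float) for r in records]
    ) if m.sum() else np.empty(0)
    counts_idx = np.repeat(np.arange(len(records)), m.astype(int))

    def log_rate_terms(bvec: np.ndarray) -> np.ndarray:
        base = _baseline_from_vector(family, bvec)
        if all_events.size == 0:
            return np.zeros(len(records))
        with np.errstate(divide="ignore"):
            lr = np.log(base.rate(all_events))
        out = np.zeros(len(records))
        np.add.at(out, counts_idx, lr)
        return out

    def Lambda_T(bvec: np.ndarray) -> np.ndarray:
        base = _baseline_from_vector(family, bvec)
        return np.asarray(base.cumulative(T), dtype=float)

    p = X.shape[1]
    # moment-style inits: unit-ish scale from the median window, shape 1
    t_scale = max(float(np.median(T)), 1.0)
    base_init = np.log([1.0, t_scale / 2.0])
    x0 = np.concatenate([np.zeros(p), [math.log(0.5)], base_init])
    bounds = (
        [(-10.0, 10.0)] * p
        + [(math.log(1e-6), math.log(50.0))]
        + [(math.log(1e-4), math.log(1e4))] * 2
    )
    # candidate baselines probed during optimisation should not spam the
    # monotonicity warning; the selected model is re-validated afterwards
    prev_disabled = logger.disabled
    logger.disabled = True
    try:
        res = optimize.minimize(
            _neg_log_marginal,
            x0,
            args=(family, X, m, log_rate_terms, Lambda_T),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500},
        )
    finally:
        logger.disabled = prev_disabled
    if not res.success and not math.isfinite(res.fun):
        raise FitError(f"{family} fit failed: {res.message}")
    B_hat = res.x[:p]
    sigma_hat = math.exp(res.x[p])
    baseline = _baseline_from_vector(family, res.x[p + 1 :])
    return -res.fun, B_hat, baseline, sigma_hat


def fit_frailty_model(
    records: Sequence[PatientRecord],
    candidate_families: Sequence[str] = ("weibull", "gamma", "lognormal"),
) -> FitResult:
    """Maximum-marginal-likelihood fit of the Gamma-frailty NHPP model.

    For each candidate baseline family the frailty is integrated out
    analytically per patient and ``(sigma, B, baseline params)`` maximised
    jointly; the family with the highest log marginal likelihood wins.  The
    fitted heterogeneity distribution is summarised by moment-matching
    ``h = Z exp(X B)`` to a Gamma, and the observed range is the min/max of
    the per-patient posterior ``h`` values.
    """
    if len(records) < 2:
        raise DomainError("need at least two patients to fit the frailty model")
    X = np.array([r.covariates for r in records], dtype=float)
    if X.ndim != 2:
        raise DomainError("all patients must share a common covariate dimension")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DomainError("covariate matrix is rank deficient")

    per_family: dict[str, dict] = {}
    best = None
    for family in candidate_families:
        try:
            ll, B_hat, baseline, sigma_hat = _fit_one_family(family, X, records)
        except FitError as err:
            logger.warning("family %s failed to fit: %s", family, err)
            continue
        n_par = X.shape[1] + 1 + _BASELINE_NPARAMS[family]
        per_family[family] = {
            "log_likelihood": ll,
            "aic": 2 * n_par - 2 * ll,
            "sigma": sigma_hat,
            "B": tuple(B_hat),
            "baseline_params": dict(baseline.params),
        }
        if best is None or ll > best[0]:
            best = (ll, family, B_hat, baseline, sigma_hat)
    if best is None:
        raise FitError("no candidate family converged")
    ll, family, B_hat, baseline, sigma_hat = best

    eta = X @ B_hat
    m = np.array([len(r.event_times) for r in records], dtype=float)
    mu = np.exp(eta) * np.asarray(baseline.cumulative(
        np.array([r.window_end for r in records], dtype=float)
    ))
    a = 1.0 / sigma_hat
    z_post = (a + m) / (a + mu)  # posterior mean frailty per patient
    h_patient = z_post * np.exp(eta)

    # moment-match h = Z e^{XB} over the cohort to a Gamma distribution
    mean_h = float(np.mean(np.exp(eta)))  # E[Z] = 1
    var_h = float(
        (1.0 + sigma_hat) * np.mean(np.exp(2.0 * eta)) - mean_h**2
    )
    var_h = max(var_h, 1e-12)
    h_model = HeterogeneityModel(
        "gamma",
        {"mean": mean_h, "variance": var_h},
        observed_range=(float(h_patient.min()), float(h_patient.max())),
    )
    n_par = X.shape[1] + 1 + _BASELINE_NPARAMS[family]
    return FitResult(
        sigma_hat=sigma_hat,
        B_hat=tuple(B_hat),
        baseline=baseline,
        log_marginal_likelihood=ll,
        h_model=h_model,
        aic=2 * n_par - 2 * ll,
        per_family=per_family,
        patient_h=tuple(h_patient),
    )


def marginal_log_likelihood(
    records: Sequence[PatientRecord],
    B: Sequence[float],
    sigma: float,
    baseline: BaselineHazard,
) -> float:
    """Marginal log-likelihood at given parameters (frailty integrated out)."""
    X = np.array([r.covariates for r in records], dtype=float)
    m = np.array([len(r.event_times) for r in records], dtype=float)
    T = np.array([r.window_end for r in records], dtype=float)
    eta = X @ np.asarray(B, dtype=float)
    mu = np.exp(eta) * np.asarray(baseline.cumulative(T), dtype=float)
    log_lam_sum = np.array(
        [
            float(np.sum(np.log(baseline.rate(np.asarray(r.event_times)))))
            if r.event_times
            else 0.0
            for r in records
        ]
    )
    a = 1.0 / max(sigma, 1e-12)
    ll = (
        m * eta
        + log_lam_sum
        + special.gammaln(a + m)
        - special.gammaln(a)
        - a * np.log1p(mu / a)
        - m * np.log(a + mu)
    )
    return float(np.sum(ll))


# -- delimited-text event histories -------------------------------------------
#
# Layout: one row per AO event with columns
#   id, covariate_1..covariate_p, event_time, window_end
# and a single row with empty event_time for patients without events.
# Follow-up times travel in an optional companion table (id, followup_time).


def write_patient_records(records: Sequence[PatientRecord], path) -> None:
    import pandas as pd

    p = len(records[0].covariates) if records else 0
    rows = []
    for r in records:
        base = {"id": r.id, "window_end": r.window_end}
        base.update({f"covariate_{j + 1}": r.covariates[j] for j in range(p)})
        if r.event_times:
            for t in r.event_times:
                rows.append({**base, "event_time": t})
        else:
            rows.append({**base, "event_time": np.nan})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_patient_records(path, followup_path=None) -> list[PatientRecord]:
    import pandas as pd

    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as err:
        raise ConfigurationError(f"{path}: empty or unparseable event-history file") from err
    required = {"id", "event_time", "window_end"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"{path}: missing columns {sorted(missing)}")
    cov_cols = sorted(
        (c for c in df.columns if c.startswith("covariate_")),
        key=lambda c: int(c.split("_")[1]),
    )
    followups: dict[str, list[float]] = {}
    if followup_path is not None:
        fdf = pd.read_csv(followup_path, sep="\t")
        for pid, grp in fdf.groupby("id"):
            followups[str(pid)] = sorted(float(t) for t in grp["followup_time"])
    records = []
    for pid, grp in df.groupby("id", sort=False):
        events = tuple(
            sorted(float(t) for t in grp["event_time"].dropna())
        )
        records.append(
            PatientRecord(
                id=str(pid),
                covariates=tuple(float(grp.iloc[0][c]) for c in cov_cols),
                event_times=events,
                window_end=float(grp.iloc[0]["window_end"]),
                followup_times=tuple(followups.get(str(pid), ())),
            )
        )
    return records
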