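"""Run configuration: schema, validation, YAML I/O, case-study defaults.

A run configuration bundles the baseline hazard, the heterogeneity
distribution with its observed range, the risk strata (explicit bounds and
per-group AO treatment costs), and the follow-up policy parameters
(tau, theta, W, L, cf).  All defaults reproduce the paediatric
type-1-diabetes case study: three risk groups with h-cutoffs
(0.0449, 0.1331, 0.2300, 0.7182) and treatment costs (6520, 10200, 15580),
cf = 428, theta = 0.1, W = 12 months, L = 36 months, tau = 3 months.

Validation aggregates every problem into a single error so a bad file is
reported once, completely.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Sequence

import yaml

from .frailty import HeterogeneityModel, RiskStratum, phi_weight
from .hazard import BaselineHazard, ConfigurationError
from .policy import Policy, PolicySpec

__all__ = ["RunConfig", "load_config", "default_config", "ConfigValidationError"]


class ConfigValidationError(ConfigurationError):
    """All configuration problems, reported together."""

    def __init__(self, problems: Sequence[str]) -> None:
        self.problems = list(problems)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(problems))


#: case-study defaults (months, currency units as configured)
DEFAULTS: dict[str, Any] = {
    "baseline": {"family": "weibull", "params": {"shape": 0.12, "scale": 1.657}},
    "heterogeneity": {
        "family": "gamma",
        "mean": 2.4006,
        "variance": 0.0813,
        "range": [0.0449, 0.7182],
    },
    "strata": [
        {"bounds": [0.0449, 0.1331], "cost": 6520.0},
        {"bounds": [0.1331, 0.2300], "cost": 10200.0},
        {"bounds": [0.2300, 0.7182], "cost": 15580.0},
    ],
    "policy": {"tau": 3.0, "theta": 0.1, "W": 12.0, "L": 36.0, "cf": 428.0},
    "currency": "CNY",
    "seed": 0,
}


@dataclass(frozen=True)
class RunConfig:
    """Validated model + policy configuration for a pricing run."""

    baseline: BaselineHazard
    h_model: HeterogeneityModel
    strata: tuple[RiskStratum, ...]
    tau: float
    theta: float
    W: float
    L: float
    cf: float
    currency: str = "CNY"
    seed: int = 0
    raw: dict = field(default_factory=dict, compare=False, repr=False)

    def policy_spec(self, policy: Policy | str, **overrides) -> PolicySpec:
        kw = {"tau": self.tau, "theta": self.theta, "W": self.W, "L": self.L, "cf": self.cf}
        kw.update(overrides)
        return PolicySpec(Policy(policy), **kw)

    @property
    def config_hash(self) -> str:
        """Stable short hash of the raw mapping, embedded in every output."""
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _require(mapping: dict, key: str, problems: list[str], context: str):
    if key not in mapping:
        problems.append(f"{context}: missing required field {key!r}")
        return None
    return mapping[key]


def build_config(data: dict) -> RunConfig:
    """Validate a raw mapping and build a :class:`RunConfig`.

    Every problem is collected; nothing is computed until the whole
    mapping validates.
    """
    problems: list[str] = []

    base_map = _require(data, "baseline", problems, "config") or {}
    family = _require(base_map, "family", problems, "baseline")
    params = _require(base_map, "params", problems, "baseline")

    het_map = _require(data, "heterogeneity", problems, "config") or {}
    strata_list = _require(data, "strata", problems, "config") or []
    pol_map = _require(data, "policy", problems, "config") or {}
    pol_vals = {}
    for key in ("tau", "theta", "W", "L", "cf"):
        val = _require(pol_map, key, problems, "policy")
        if val is not None:
            try:
                pol_vals[key] = float(val)
            except (TypeError, ValueError):
                problems.append(f"policy: {key} must be a number, got {val!r}")

    baseline = h_model = None
    if family is not None and params is not None:
        try:
            baseline = BaselineHazard(str(family), dict(params))
        except ConfigurationError as err:
            problems.append(f"baseline: {err}")

    if het_map:
        fam = het_map.get("family", "gamma")
        rng = het_map.get("range")
        if rng is None:
            problems.append("heterogeneity: missing required field 'range'")
        else:
            try:
                if fam == "gamma":
                    h_params = {
                        "mean": float(het_map["mean"]),
                        "variance": float(het_map["variance"]),
                    }
                elif fam == "uniform":
                    h_params = {
                        "low": float(het_map["low"]),
                        "high": float(het_map["high"]),
                    }
                elif fam == "empirical":
                    h_params = {"values": [float(v) for v in het_map["values"]]}
                else:
                    raise ConfigurationError(f"unknown heterogeneity family {fam!r}")
                h_model = HeterogeneityModel(fam, h_params, (float(rng[0]), float(rng[1])))
            except KeyError as err:
                problems.append(f"heterogeneity: missing field {err}")
            except (ConfigurationError, TypeError, ValueError) as err:
                problems.append(f"heterogeneity: {err}")

    strata: list[RiskStratum] = []
    if h_model is not None and strata_list:
        total = h_model.truncated_mass()
        n = len(strata_list)
        for k, entry in enumerate(strata_list, start=1):
            try:
                lo, hi = (float(v) for v in entry["bounds"])
                cost = float(entry["cost"])
                strata.append(
                    RiskStratum(
                        index=k,
                        bounds=(lo, hi),
                        mass=total / n,
                        phi=phi_weight(h_model, lo, hi),
                        treatment_cost=cost,
                    )
                )
            except (KeyError, ConfigurationError, TypeError, ValueError) as err:
                problems.append(f"strata[{k}]: {err}")

    if pol_vals.keys() == {"tau", "theta", "W", "L", "cf"}:
        try:
            PolicySpec(Policy.NONE, **pol_vals)
        except ConfigurationError as err:
            problems.append(f"policy: {err}")

    if problems:
        raise ConfigValidationError(problems)
    assert baseline is not None and h_model is not None
    return RunConfig(
        baseline=baseline,
        h_model=h_model,
        strata=tuple(strata),
        currency=str(data.get("currency", "CNY")),
        seed=int(data.get("seed", 0)),
        raw=data,
        **pol_vals,
    )


def default_config(**overrides) -> RunConfig:
    """The case-study configuration, optionally with top-level overrides."""
    data = json.loads(json.dumps(DEFAULTS))  # deep copy
    for key, val in overrides.items():
        if isinstance(val, dict) and isinstance(data.get(key), dict):
            data[key].update(val)
        else:
            data[key] = val
    return build_config(data)


def load_config(path) -> RunConfig:
    """Read and validate a YAML configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigValidationError([f"{path}: top level must be a mapping"])
    return build_config(data)
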