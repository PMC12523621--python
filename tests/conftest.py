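import numpy as np
import pytest

from followup_pricing import (
    BaselineHazard,
    HazardProfile,
    HeterogeneityModel,
    Policy,
    PolicySpec,
    RiskStratum,
    default_config,
    phi_weight,
)


@pytest.fixture(scope="session")
def weibull2():
    """Increasing Weibull baseline: lambda0(t) = 2t (shape 2, scale 1)."""
    return BaselineHazard("weibull", {"shape": 2.0, "scale": 1.0})


@pytest.fixture(scope="session")
def weibull_months():
    """Increasing Weibull on a monthly scale used by simulation tests."""
    return BaselineHazard("weibull", {"shape": 2.0, "scale": 15.0})


@pytest.fixture(scope="session")
def case_config():
    """The case-study default configuration (Table-style inputs)."""
    return default_config()


@pytest.fixture(scope="session")
def gamma_h():
    """A gamma heterogeneity model with non-trivial truncation."""
    return HeterogeneityModel(
        "gamma", {"mean": 2.4006, "variance": 0.0813}, observed_range=(0.5, 4.5)
    )


@pytest.fixture(scope="session")
def gamma_stratum(gamma_h):
    """Middle equal-mass stratum of the gamma model with a realistic AO cost."""
    from followup_pricing import stratify

    bounds = stratify(gamma_h, 3)[1]
    return RiskStratum(
        index=2,
        bounds=bounds,
        mass=gamma_h.truncated_mass() / 3,
        phi=phi_weight(gamma_h, *bounds),
        treatment_cost=10200.0,
    )


def make_spec(policy=Policy.I, tau=3.0, theta=0.1, W=12.0, L=36.0, cf=428.0):
    return PolicySpec(Policy(policy), tau=tau, theta=theta, W=W, L=L, cf=cf)


@pytest.fixture
def spec_factory():
    return make_spec


def riemann_cumulative(profile: HazardProfile, a: float, b: float, h: float, step=1e-4):
    """Brute-force fixed-step quadrature of the effective-age intensity."""
    total = 0.0
    for seg in profile.segments:
        lo, hi = max(seg.start, a), min(seg.end, b)
        if hi - lo <= 0:
            continue
        n = max(int(np.ceil((hi - lo) / step)), 2)
        t = np.linspace(lo, hi, n + 1)
        ages = seg.age_offset + (t - seg.start)
        rates = profile.baseline.rate(np.maximum(ages, 1e-12))
        total += np.trapezoid(rates, t)
    return h * total
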