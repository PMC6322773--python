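"""Synthetic cohorts of 6–59-month-old children for offline validation.

The generator emulates the marginal structure of large pooled nutritional
surveys from low- and middle-income countries: per child it draws sex and
age, a height-for-age z-score (HAZ) and a weight-for-height z-score (WHZ),
inverts the growth reference to obtain length and weight, and draws a
mid-arm circumference (MAC) from a linear model on age and WHZ.  Default
parameters target the pooled-survey marginals: HAZ ~ N(-1.5, 1.5),
WHZ ~ N(-0.6, 1.2), MAC mean 14.2 cm with SD 1.3 cm and a MAC-WHZ
correlation of about 0.7; P(male) = 0.506; age uniform over completed
months 6-59.

HAZ and WHZ are drawn independently given age — a modelling choice, since
pooled surveys publish only marginal summaries — and the joint structure is
fully configurable.  Latent (pre-rounding) values are retained so recovery
tests can separate estimator error from measurement rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .growth import GrowthReference
from .fixtures import fixture_reference

__all__ = ["SimulationConfig", "SyntheticCohort", "simulate_cohort", "inject_error_structure"]

#: default region mix (proportions) and a representative country per region
DEFAULT_REGIONS = {
    "Africa": 0.50,
    "South-East Asia": 0.20,
    "Middle East": 0.10,
    "Americas": 0.08,
    "Eastern Europe": 0.06,
    "Western Pacific": 0.06,
}

_REGION_COUNTRIES = {
    "Africa": ("Ethiopia", "Niger", "Kenya", "Malawi"),
    "South-East Asia": ("Bangladesh", "Nepal", "Myanmar"),
    "Middle East": ("Yemen", "Afghanistan"),
    "Americas": ("Haiti", "Guatemala"),
    "Eastern Europe": ("Albania", "Tajikistan"),
    "Western Pacific": ("Cambodia", "Laos"),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the cohort generator; defaults target pooled-survey marginals."""

    n: int = 10_000
    seed: int = 0
    sex_ratio: float = 0.506          # P(male)
    age_low: int = 6                  # completed months, inclusive
    age_high: int = 59                # inclusive
    haz_mean: float = -1.5
    haz_sd: float = 1.5
    whz_mean: float = -0.6
    whz_sd: float = 1.2
    mac_intercept: float = 14.655     # cm, at WHZ 0 and the age midpoint
    mac_age_slope: float = 0.02       # cm per month, centred on the age midpoint
    mac_whz_slope: float = 0.758      # cm per WHZ unit -> corr(MAC, WHZ) ~ 0.7
    mac_resid_sd: float = 0.876       # cm; total MAC SD ~ 1.3
    round_length_cm: float = 0.1
    round_weight_kg: float = 0.1
    round_mac_cm: float = 0.1
    year_low: int = 1992
    year_high: int = 2017
    region_mix: dict = field(default_factory=lambda: dict(DEFAULT_REGIONS))
    max_redraws: int = 100

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        for name in ("haz_sd", "whz_sd", "mac_resid_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.age_low <= self.age_high:
            raise ValueError("age_low must be <= age_high")
        total = sum(self.region_mix.values())
        if self.region_mix and abs(total - 1.0) > 1e-9:
            raise ValueError(f"region proportions must sum to 1, got {total}")


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated records plus the latent truth and generation provenance."""

    records: pd.DataFrame
    latent: pd.DataFrame
    config: SimulationConfig
    redraws: int = 0

    @property
    def provenance(self) -> dict:
        d = asdict(self.config)
        d["redraws"] = self.redraws
        return d


def _round_to(x, precision):
    if precision <= 0:
        return x
    return np.round(x / precision) * precision


def _age_midpoint(config):
    return 0.5 * (config.age_low + config.age_high)


def simulate_cohort(config: SimulationConfig,
                    reference: GrowthReference | None = None) -> SyntheticCohort:
    """Draw a cohort under ``config``; byte-identical for a given (config, seed).

    Children whose drawn HAZ implies a length outside the weight-for-height
    reference range have HAZ/WHZ redrawn (capped at ``config.max_redraws``
    passes; exceeding the cap raises).
    """
    ref = reference or fixture_reference()
    rng = np.random.default_rng(config.seed)
    n = config.n

    sex = np.where(rng.random(n) < config.sex_ratio, "male", "female")
    age = rng.integers(config.age_low, config.age_high + 1, size=n)
    haz = rng.normal(config.haz_mean, config.haz_sd, size=n)
    whz = rng.normal(config.whz_mean, config.whz_sd, size=n)

    height = np.empty(n)
    for s in ("male", "female"):
        m = sex == s
        if np.any(m):
            height[m] = ref.value("height-for-age", s, age[m], haz[m])

    # redraw children whose implied length leaves the weight-for-height grid
    wfh_lo = max(ref.table("weight-for-height", s).axis_range[0] for s in ("male", "female"))
    wfh_hi = min(ref.table("weight-for-height", s).axis_range[1] for s in ("male", "female"))
    redraws = 0
    bad = (height < wfh_lo) | (height > wfh_hi)
    passes = 0
    while np.any(bad):
        passes += 1
        if passes > config.max_redraws:
            raise RuntimeError(
                f"{int(bad.sum())} children still outside the reference range "
                f"after {config.max_redraws} redraw passes"
            )
        redraws += int(bad.sum())
        haz[bad] = rng.normal(config.haz_mean, config.haz_sd, size=int(bad.sum()))
        whz[bad] = rng.normal(config.whz_mean, config.whz_sd, size=int(bad.sum()))
        for s in ("male", "female"):
            m = bad & (sex == s)
            if np.any(m):
                height[m] = ref.value("height-for-age", s, age[m], haz[m])
        bad = (height < wfh_lo) | (height > wfh_hi)

    weight = np.empty(n)
    for s in ("male", "female"):
        m = sex == s
        if np.any(m):
            weight[m] = ref.value("weight-for-height", s, height[m], whz[m])

    mac = (
        config.mac_intercept
        + config.mac_age_slope * (age - _age_midpoint(config))
        + config.mac_whz_slope * whz
        + rng.normal(0.0, config.mac_resid_sd, size=n)
    )

    regions = list(config.region_mix) or ["unassigned"]
    probs = list(config.region_mix.values()) or [1.0]
    region = rng.choice(regions, size=n, p=probs) if n else np.array([], dtype=object)
    country = np.array([
        _REGION_COUNTRIES.get(r, ("unknown",))[i % len(_REGION_COUNTRIES.get(r, ("unknown",)))]
        for i, r in enumerate(region)
    ], dtype=object)
    year = rng.integers(config.year_low, config.year_high + 1, size=n)

    records = pd.DataFrame(
        {
            "id": np.arange(n),
            "country": country,
            "year": year,
            "region": region,
            "sex": sex,
            "age_months": age,
            "weight_kg": np.maximum(_round_to(weight, config.round_weight_kg), 0.1),
            "height_cm": _round_to(height, config.round_length_cm),
            "mac_cm": np.maximum(_round_to(mac, config.round_mac_cm), 0.1),
        }
    )
    latent = pd.DataFrame(
        {
            "id": np.arange(n),
            "haz_true": haz,
            "whz_true": whz,
            "height_true_cm": height,
            "weight_true_kg": weight,
            "mac_true_cm": mac,
        }
    )
    return SyntheticCohort(records=records, latent=latent, config=config, redraws=redraws)


def inject_error_structure(records: pd.DataFrame, method_error_spec: dict,
                           seed: int = 0) -> pd.DataFrame:
    """Attach pseudo-method estimates with known percentage-error structure.

    ``method_error_spec`` maps a pseudo-method name to (mu, sigma) of the
    percentage-error distribution; each estimate is
    actual x (1 + e/100), e ~ N(mu, sigma).  Lets the accuracy layer be
    exercised and calibrated without any tape calibration.
    """
    rng = np.random.default_rng(seed)
    out = records.copy()
    actual = out["weight_kg"].to_numpy(dtype=float)
    for name, (mu, sigma) in method_error_spec.items():
        if sigma < 0:
            raise ValueError(f"{name}: sigma must be non-negative")
        e = rng.normal(mu, sigma, size=len(out)) if sigma > 0 else np.full(len(out), float(mu))
        out[f"est_{name}"] = actual * (1.0 + e / 100.0)
        out[f"inrange_{name}"] = True
    return out
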