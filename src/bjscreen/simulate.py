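"""Seeded generator of paired serum/urine cohorts.

The generative model follows the physiology the screen exploits.  Each
sample is a patient visit with a latent plasma-cell clone class (kappa
clone, lambda clone, or none).  Both chains get a polyclonal background
drawn log-normally with a shared per-sample factor (so the healthy ratio
stays near 1 while absolute levels vary); a clonal sample adds heavy-tailed
monoclonal production to the involved chain.  Free light chains spill into
urine as Bence Jones protein (BJP) when the involved serum concentration
exceeds the proximal tubular reabsorption capacity — about 133 mg/L for
kappa and 278 mg/L for lambda at normal renal function — with the capacity
optionally scaled linearly by eGFR and the threshold softened by a logistic
width to mimic inter-patient variability in renal handling.  uIFE truth is
positive exactly when BJP appears; positive samples then draw a 24-h urinary
M-protein mass which also feeds urine total protein.

All randomness comes from one integer seed; identical parameters and seed
reproduce the cohort bit-for-bit, and the random draws are laid out so that
runs differing only in a physiological parameter share their random numbers
(common random numbers), which makes monotonicity testable.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit
from scipy.stats import truncnorm

from .cohort import Cohort, SampleRecord, UIFE_KAPPA, UIFE_LAMBDA, UIFE_NEGATIVE
from .errors import ConfigError


@dataclass(frozen=True)
class LogNormal:
    """Log-normal distribution parameterized by its median and log-sd."""

    median: float
    sigma: float

    def transform(self, z: np.ndarray) -> np.ndarray:
        return self.median * np.exp(self.sigma * z)


@dataclass(frozen=True)
class TruncNormal:
    """Normal distribution truncated to [low, high]."""

    mean: float
    sd: float
    low: float
    high: float

    def ppf(self, u: np.ndarray) -> np.ndarray:
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return truncnorm.ppf(u, a, b, loc=self.mean, scale=self.sd)


@dataclass(frozen=True)
class SimulatorParams:
    """Configuration of the cohort generator.

    Defaults emulate a myeloma follow-up population: 31% kappa clones and
    20.5% lambda clones per sample, monoclonal production far above the
    renal reabsorption capacities so nearly every clone spills into urine,
    and eGFR centred near 82 mL/min/1.73 m^2 truncated to [15, 113].
    """

    n: int = 268
    p_kappa_clone: float = 0.31
    p_lambda_clone: float = 0.205
    # polyclonal background, mg/L; shared log-factor keeps the ratio tight
    polyclonal_kappa: LogNormal = LogNormal(12.5, 0.15)
    polyclonal_lambda: LogNormal = LogNormal(12.0, 0.15)
    polyclonal_common_sigma: float = 0.3
    # monoclonal production added to the involved chain, mg/L
    monoclonal_kappa: LogNormal = LogNormal(2000.0, 0.9)
    monoclonal_lambda: LogNormal = LogNormal(3200.0, 0.9)
    # renal physiology
    egfr_distribution: TruncNormal = TruncNormal(84.0, 24.0, 15.0, 113.0)
    reabsorption_capacity_kappa: float = 133.0
    reabsorption_capacity_lambda: float = 278.0
    egfr_scaling: bool = True
    reference_egfr: float = 90.0
    appearance_noise_width: float = 25.0  # logistic scale, mg/L; 0 = hard step
    # urine side
    urine_mprotein_kappa: LogNormal = LogNormal(3340.0, 1.2)
    urine_mprotein_lambda: LogNormal = LogNormal(4460.0, 1.2)
    urine_protein_baseline: LogNormal = LogNormal(0.08, 0.8)
    urine_volume_l: float = 1.5  # daily urine volume used for mg/24h -> g/L
    measurement_cv: float = 0.05  # multiplicative assay noise fraction
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n < 1:
            problems.append("n must be >= 1")
        for name in ("p_kappa_clone", "p_lambda_clone"):
            p = getattr(self, name)
            if not (0 <= p <= 1):
                problems.append(f"{name} must be in [0, 1]")
        if self.p_kappa_clone + self.p_lambda_clone > 1:
            problems.append("p_kappa_clone + p_lambda_clone must be <= 1")
        for name in ("polyclonal_kappa", "polyclonal_lambda",
                     "monoclonal_kappa", "monoclonal_lambda",
                     "urine_mprotein_kappa", "urine_mprotein_lambda",
                     "urine_protein_baseline"):
            dist = getattr(self, name)
            if dist.median <= 0 or dist.sigma < 0:
                problems.append(f"{name}: median must be > 0 and sigma >= 0")
        for name in ("reabsorption_capacity_kappa",
                     "reabsorption_capacity_lambda"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if self.appearance_noise_width < 0:
            problems.append("appearance_noise_width must be >= 0")
        if self.reference_egfr <= 0:
            problems.append("reference_egfr must be > 0")
        if self.urine_volume_l <= 0:
            problems.append("urine_volume_l must be > 0")
        if self.measurement_cv < 0:
            problems.append("measurement_cv must be >= 0")
        if problems:
            raise ConfigError("invalid simulator params: " + "; ".join(problems))


def preset_params(name: str, seed: int = 0) -> SimulatorParams:
    """Named cohort presets.

    ``derivation_like``: n=268 myeloma follow-up samples, clone mixture
    (0.31, 0.205), about half the samples uIFE-positive.
    ``validation_like``: n=716 routine mixed-request samples with the same
    physiology but lower clone prevalence (about 27.5% uIFE-positive).
    """
    if name == "derivation_like":
        return SimulatorParams(seed=seed)
    if name == "validation_like":
        return SimulatorParams(
            n=716, p_kappa_clone=0.166, p_lambda_clone=0.110, seed=seed
        )
    raise ConfigError(
        f"unknown preset {name!r}; known presets: "
        "['derivation_like', 'validation_like']"
    )


def generate_cohort(params: SimulatorParams) -> Cohort:
    """Generate a fully reproducible synthetic paired serum/urine cohort."""
    params.validate()
    n = params.n
    rng = np.random.default_rng(params.seed)

    # fixed draw layout: parameter changes never shift the random stream
    u_class = rng.random(n)
    z_common = rng.standard_normal(n)
    z_kappa = rng.standard_normal(n)
    z_lambda = rng.standard_normal(n)
    z_production = rng.standard_normal(n)
    u_egfr = rng.random(n)
    u_appear = rng.random(n)
    z_mprotein = rng.standard_normal(n)
    z_uprotein = rng.standard_normal(n)
    z_noise = rng.standard_normal((3, n))

    is_kappa = u_class < params.p_kappa_clone
    is_lambda = (~is_kappa) & (
        u_class < params.p_kappa_clone + params.p_lambda_clone
    )
    common = np.exp(params.polyclonal_common_sigma * z_common)
    poly_k = params.polyclonal_kappa.transform(z_kappa) * common
    poly_l = params.polyclonal_lambda.transform(z_lambda) * common

    production = np.where(
        is_kappa,
        params.monoclonal_kappa.transform(z_production),
        np.where(is_lambda,
                 params.monoclonal_lambda.transform(z_production), 0.0),
    )
    kappa = poly_k + np.where(is_kappa, production, 0.0)
    lam = poly_l + np.where(is_lambda, production, 0.0)

    egfr = params.egfr_distribution.ppf(u_egfr)
    capacity = np.where(is_kappa, params.reabsorption_capacity_kappa,
                        params.reabsorption_capacity_lambda)
    if params.egfr_scaling:
        capacity = capacity * np.maximum(egfr, 0.0) / params.reference_egfr
    involved = np.where(is_kappa, kappa, lam)
    if params.appearance_noise_width > 0:
        p_appear = expit((involved - capacity) / params.appearance_noise_width)
    else:
        p_appear = (involved > capacity).astype(float)
    clonal = is_kappa | is_lambda
    bjp_present = clonal & (u_appear < p_appear)

    mprotein = np.where(
        is_kappa,
        params.urine_mprotein_kappa.transform(z_mprotein),
        params.urine_mprotein_lambda.transform(z_mprotein),
    )
    uprotein = params.urine_protein_baseline.transform(z_uprotein)
    # BJP adds its daily mass, diluted into the daily urine volume
    uprotein = uprotein + np.where(
        bjp_present, mprotein / 1000.0 / params.urine_volume_l, 0.0
    )

    cv = params.measurement_cv
    if cv > 0:
        kappa = kappa * np.exp(cv * z_noise[0])
        lam = lam * np.exp(cv * z_noise[1])
        uprotein = uprotein * np.exp(cv * z_noise[2])

    records = []
    for i in range(n):
        if bjp_present[i]:
            uife = UIFE_KAPPA if is_kappa[i] else UIFE_LAMBDA
            mp: Optional[float] = float(mprotein[i])
        else:
            uife = UIFE_NEGATIVE
            mp = None
        records.append(SampleRecord(
            sample_id=f"s{i + 1:05d}",
            patient_id=f"p{i + 1:05d}",
            kappa_sflc=float(kappa[i]),
            lambda_sflc=float(lam[i]),
            urine_total_protein=float(uprotein[i]),
            uife_result=uife,
            urine_mprotein=mp,
            egfr=float(egfr[i]),
        ))
    return Cohort(records=records, name=f"synthetic-n{n}",
                  source="synthetic", seed=params.seed)


# ---------------------------------------------------------------------------
# Config (de)serialization
# ---------------------------------------------------------------------------


def params_to_config(params: SimulatorParams) -> dict:
    """Params as a plain dict suitable for JSON or YAML."""
    def encode(value):
        if isinstance(value, (LogNormal, TruncNormal)):
            return dataclasses.asdict(value)
        return value
    return {f.name: encode(getattr(params, f.name))
            for f in dataclasses.fields(params)}


def params_from_config(config: dict) -> SimulatorParams:
    """Inverse of :func:`params_to_config`; unknown keys are an error."""
    fields = {f.name: f for f in dataclasses.fields(SimulatorParams)}
    unknown = set(config) - set(fields)
    if unknown:
        raise ConfigError(f"unknown simulator params: {sorted(unknown)}")
    kwargs = {}
    for key, value in config.items():
        default = fields[key].default
        if isinstance(default, LogNormal):
            kwargs[key] = LogNormal(**value) if isinstance(value, dict) \
                else value
        elif isinstance(default, TruncNormal):
            kwargs[key] = TruncNormal(**value) if isinstance(value, dict) \
                else value
        else:
            kwargs[key] = value
    params = SimulatorParams(**kwargs)
    params.validate()
    return params
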