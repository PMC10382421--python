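"""Synthetic inputs with known ground truth.

Two generators cover everything the pipeline consumes:

* CCD response tables from a specified "true" coded-unit quadratic plus
  additive Gaussian noise (run means of replicate instrument reads are
  close to normal), and
* oral concentration–time profiles from the one-compartment first-order
  absorption model

      C(t) = D * ka / (V/F * (ka - ke)) * (exp(-ke t) - exp(-ka t)),

  with mean-preserving lognormal between-subject variability (acting on
  the concentration scale, i.e. on apparent volume) and lognormal residual
  noise per sample, which keeps concentrations positive. The analytic
  truths AUC_inf = D / (V/F * ke), MRT = 1/ka + 1/ke and
  Tmax = ln(ka/ke) / (ka - ke) are returned alongside for testing.

Randomness: one `numpy` Generator per call, seeded from the caller's seed;
the pipeline splits a single top-level seed into per-stage streams with
`numpy.random.SeedSequence.spawn`.

Default PK parameter sets emulate the two study groups (10 mg/kg oral
vanillic acid, sampled 10–2880 min): the standard-drug preset reproduces
the group's reported Tmax ~10 min, MRT ~572 min and AUC_inf ~72500
µg·min/mL, the pharmacosome preset Tmax ~30 min, MRT ~1748 min and AUC_inf
~278600 µg·min/mL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import CCDDesign, ResponseTable
from .nca import ConcentrationProfile
from .rsm import model_matrix, n_params, term_names
from .fixtures import fixtures, PaperFixtures  # re-export  # noqa: F401

__all__ = [
    "TrueResponseModel",
    "OralPKParams",
    "PKTruth",
    "PAPER_SCHEDULE_MIN",
    "simulate_ccd_responses",
    "simulate_oral_pk",
    "one_compartment_conc",
    "standard_va_params",
    "pharmacosome_params",
    "fixtures",
]

PAPER_SCHEDULE_MIN = (10.0, 20.0, 30.0, 60.0, 90.0, 120.0, 360.0, 1440.0, 2880.0)


@dataclass(frozen=True)
class TrueResponseModel:
    """Ground-truth coded-unit quadratic (b0, b1, b2, b12, b11, b22) + noise."""

    name: str
    coefficients: tuple[float, ...]
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def coef_array(self, k: int) -> np.ndarray:
        coef = np.asarray(self.coefficients, dtype=float)
        expected = n_params(k)
        if coef.shape != (expected,):
            raise ValueError(
                f"{self.name}: expected {expected} coefficients "
                f"({', '.join(term_names(k))}), got {coef.shape}"
            )
        return coef


def simulate_ccd_responses(
    design: CCDDesign, models: list[TrueResponseModel], seed: int
) -> ResponseTable:
    """Responses y_r = quadratic(coded_r) + N(0, noise_sd), reproducible by seed."""
    rng = np.random.default_rng(seed)
    X = model_matrix(design.coded_matrix)
    means = {}
    sds = {}
    for m in models:
        y = X @ m.coef_array(design.k)
        if m.noise_sd > 0:
            y = y + rng.normal(0.0, m.noise_sd, size=design.n_runs)
        means[m.name] = y
        sds[m.name] = np.zeros(design.n_runs)
    return ResponseTable(design=design, means=means, sds=sds)


@dataclass(frozen=True)
class OralPKParams:
    """One-compartment oral absorption parameters.

    ka, ke in 1/min; v_over_f (apparent volume over bioavailability) in
    L/kg; dose in mg/kg, so concentrations come out in mg/L == µg/mL.
    """

    ka: float
    ke: float
    v_over_f: float
    dose: float
    between_subject_cv: float = 0.0
    residual_cv: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ka", "ke", "v_over_f", "dose"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if abs(self.ka - self.ke) < 1e-12:
            raise ValueError("ka == ke is degenerate for this model")
        if self.between_subject_cv < 0 or self.residual_cv < 0:
            raise ValueError("CVs must be >= 0")


@dataclass(frozen=True)
class PKTruth:
    """Analytic population values of the generating model."""

    auc_inf: float
    mrt: float
    tmax: float
    cmax: float


def one_compartment_conc(params: OralPKParams, times: np.ndarray) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    a = params.dose * params.ka / (params.v_over_f * (params.ka - params.ke))
    return a * (np.exp(-params.ke * t) - np.exp(-params.ka * t))


def _truth(params: OralPKParams) -> PKTruth:
    tmax = float(np.log(params.ka / params.ke) / (params.ka - params.ke))
    cmax = float(one_compartment_conc(params, np.array([tmax]))[0])
    return PKTruth(
        auc_inf=params.dose / (params.v_over_f * params.ke),
        mrt=1.0 / params.ka + 1.0 / params.ke,
        tmax=tmax,
        cmax=cmax,
    )


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 lognormal multipliers with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return np.exp(rng.normal(-sigma2 / 2, np.sqrt(sigma2), size=size))


def simulate_oral_pk(
    params: OralPKParams,
    times=PAPER_SCHEDULE_MIN,
    n_subjects: int = 6,
    seed: int = 0,
    group: str = "group",
) -> tuple[list[ConcentrationProfile], PKTruth]:
    """Simulate subject profiles at the given schedule; returns (profiles, truth)."""
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    base = one_compartment_conc(params, t)
    profiles = []
    bsv = _lognormal_factors(rng, params.between_subject_cv, n_subjects)
    for s in range(n_subjects):
        eps = _lognormal_factors(rng, params.residual_cv, len(t))
        conc = base * bsv[s] * eps
        profiles.append(
            ConcentrationProfile(
                group=group,
                subject_id=f"{group}_{s + 1:02d}",
                times=t.copy(),
                concentrations=conc,
                dose=params.dose,
            )
        )
    return profiles, _truth(params)


def standard_va_params(
    between_subject_cv: float = 0.15, residual_cv: float = 0.10
) -> OralPKParams:
    """Preset emulating the standard-drug group (fast absorption, MRT ~572 min)."""
    return OralPKParams(
        ka=0.59,
        ke=0.00175,
        v_over_f=0.0788,
        dose=10.0,
        between_subject_cv=between_subject_cv,
        residual_cv=residual_cv,
    )


def pharmacosome_params(
    between_subject_cv: float = 0.15, residual_cv: float = 0.10
) -> OralPKParams:
    """Preset emulating the nanoparticle-formulation group (MRT ~1748 min)."""
    return OralPKParams(
        ka=0.20,
        ke=5.734e-4,
        v_over_f=0.0626,
        dose=10.0,
        between_subject_cv=between_subject_cv,
        residual_cv=residual_cv,
    )
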