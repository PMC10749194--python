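"""Synthetic cohort generator with prescribed group distributions and
covariate correlation structure.

Each subject carries a ground-truth ALPS index plus clinical covariates
(age; for patients also disease duration and daily seizure frequency). The
generator draws them from a Gaussian copula: correlated standard-normal
scores with the target correlation matrix are pushed through the inverse
CDF of each configured (truncated-)normal marginal. This gives exactly the
configured marginals and, for the mild truncation used here, empirical
Pearson correlations that converge to the targets as n grows.

Defaults reproduce the study conditions of a childhood-absence-epilepsy
(CAE) case-control comparison: 42 patients vs 50 healthy controls (HC),
group ALPS distributions N(1.45, 0.36) and N(1.66, 0.30), pediatric ages,
and ALPS correlated with age (both groups) and disease duration (patients).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats

from .errors import ConfigError

#: ALPS truth values are truncated to this range so every subject is
#: realisable as a phantom (the perivascular diffusivity must stay below
#: the tracts' parallel diffusivity); with the default group distributions
#: the truncation probability is < 1e-6.
ALPS_BOUNDS = (0.05, 3.4)


@dataclass(frozen=True)
class Marginal:
    """Truncated-normal marginal: mean/sd of the parent normal plus bounds."""

    mean: float
    sd: float
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ConfigError(f"marginal sd must be > 0, got {self.sd}")
        if not self.lower < self.upper:
            raise ConfigError(f"empty truncation interval [{self.lower}, {self.upper}]")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return stats.truncnorm.ppf(u, a, b, loc=self.mean, scale=self.sd)


@dataclass(frozen=True)
class GroupConfig:
    """Sampling configuration for one cohort group.

    ``r_alps_*`` are the target Pearson correlations between the true ALPS
    index and each covariate; covariates are mutually uncorrelated. Leave a
    covariate marginal ``None`` to omit it (healthy controls have no
    disease duration or seizure frequency).
    """

    n: int
    alps: Marginal
    age: Marginal
    duration: Optional[Marginal] = None
    frequency: Optional[Marginal] = None
    r_alps_age: float = 0.0
    r_alps_duration: float = 0.0
    r_alps_frequency: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ConfigError(f"need n >= 3 subjects per group, got {self.n}")


@dataclass(frozen=True)
class CohortConfig:
    """Two-group cohort: patients (CAE) and healthy controls (HC)."""

    cae: GroupConfig
    hc: GroupConfig
    seed: int = 0


@dataclass
class Subject:
    """One simulated participant; ``alps_measured`` is filled by the
    imaging pipeline."""

    id: str
    group: str                      # "CAE" | "HC"
    age: float                      # years
    duration: Optional[float]       # months; None for HC
    frequency: Optional[float]      # events/day; None for HC
    alps_true: float
    alps_measured: Optional[float] = None


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """Study-condition defaults: group sizes, ALPS and covariate
    distributions, and correlation targets of the emulated cohort."""
    cae = GroupConfig(
        n=42,
        alps=Marginal(1.45, 0.36, *ALPS_BOUNDS),
        age=Marginal(8.31, 2.12, 4.0, 12.0),
        duration=Marginal(10.71, 4.97, 0.0, np.inf),
        frequency=Marginal(7.71, 2.00, 0.0, np.inf),
        r_alps_age=0.766,
        r_alps_duration=-0.48,
        r_alps_frequency=0.0,
    )
    hc = GroupConfig(
        n=50,
        alps=Marginal(1.66, 0.30, *ALPS_BOUNDS),
        age=Marginal(8.44, 1.94, 4.0, 12.0),
        r_alps_age=0.651,
    )
    return CohortConfig(cae=cae, hc=hc, seed=seed)


def _correlation_matrix(cfg: GroupConfig, names: list[str]) -> np.ndarray:
    """Star-shaped correlation matrix: ALPS correlated with each covariate,
    covariates mutually independent. Validated pairwise and for joint
    positive semi-definiteness."""
    targets = {
        "age": cfg.r_alps_age,
        "duration": cfg.r_alps_duration,
        "frequency": cfg.r_alps_frequency,
    }
    k = len(names)
    r = np.eye(k)
    for j, name in enumerate(names[1:], start=1):
        rho = targets[name]
        if not -1.0 <= rho <= 1.0:
            raise ConfigError(f"correlation target (alps, {name}) = {rho} outside [-1, 1]")
        r[0, j] = r[j, 0] = rho
    min_eig = float(np.linalg.eigvalsh(r).min())
    if min_eig < -1e-12:
        ssq = float(sum(r[0, 1:] ** 2))
        raise ConfigError(
            "correlation targets are jointly infeasible (matrix not positive "
            f"semi-definite; sum of squared ALPS correlations {ssq:.3f} > 1): "
            + ", ".join(f"(alps, {n}) = {r[0, j]:.3f}" for j, n in enumerate(names[1:], 1))
        )
    return r


def _sample_group(
    cfg: GroupConfig, group: str, rng: np.random.Generator
) -> list[Subject]:
    names = ["alps", "age"]
    marginals = [cfg.alps, cfg.age]
    if cfg.duration is not None:
        names.append("duration")
        marginals.append(cfg.duration)
    if cfg.frequency is not None:
        names.append("frequency")
        marginals.append(cfg.frequency)
    r = _correlation_matrix(cfg, names)
    # Gaussian copula: correlated normal scores -> uniforms -> marginals
    chol = np.linalg.cholesky(r + 1e-14 * np.eye(len(names)))
    z = rng.standard_normal((cfg.n, len(names))) @ chol.T
    u = stats.norm.cdf(z)
    cols = {name: m.ppf(u[:, j]) for j, (name, m) in enumerate(zip(names, marginals))}
    subjects = []
    for i in range(cfg.n):
        subjects.append(Subject(
            id=f"{group}{i + 1:03d}",
            group=group,
            age=float(cols["age"][i]),
            duration=float(cols["duration"][i]) if "duration" in cols else None,
            frequency=float(cols["frequency"][i]) if "frequency" in cols else None,
            alps_true=float(cols["alps"][i]),
        ))
    return subjects


def sample_cohort(config: CohortConfig, seed: int | None = None) -> list[Subject]:
    """Draw the full two-group cohort; fully determined by the seed.

    ``seed`` overrides ``config.seed`` when given. Patients are sampled
    first, controls second, each from an independent child stream of the
    seed so group draws do not interact.
    """
    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    child_cae, child_hc = ss.spawn(2)
    out = _sample_group(config.cae, "CAE", np.random.default_rng(child_cae))
    out += _sample_group(config.hc, "HC", np.random.default_rng(child_hc))
    return out
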