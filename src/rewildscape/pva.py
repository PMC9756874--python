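"""Stochastic individual-based population viability analysis (PVA).

A small two-sex projector for reintroduced ungulate populations.  Each
iteration follows individuals (sex, age) through an annual birth-pulse
cycle:

    breeding -> survival -> aging -> ceiling truncation at K

Breeding happens only while at least one adult male is alive (polygynous
mating: male numbers otherwise do not limit reproduction).  An iteration
is extinct from the first year in which either sex has no living
individuals — the two-sex extinction threshold — and stays at N = 0
thereafter.  Summaries (per-year mean N, SE over iterations, extinction
probability) come from ``iterations`` independent replicates.

``deterministic_lambda`` builds the female-based Leslie matrix under the
same census convention (newborns are age 0, survive the age-0 class rate,
and are first counted at age 1) and returns its dominant eigenvalue — the
analytic growth-rate oracle for the stochastic projector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AgeClass",
    "PVAConfig",
    "TrajectorySummary",
    "project",
    "deterministic_lambda",
    "load_config",
]

FEMALE, MALE = 0, 1


class ConfigError(ValueError):
    pass


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class AgeClass:
    """Annual survival for one age range, per sex.

    ``max_age`` is inclusive; the last class is open-ended (individuals
    reaching it stay in it with its survival rate).
    """

    min_age: int
    max_age: int
    survival_female: float
    survival_male: float


@dataclass
class PVAConfig:
    """Demographic rates and simulation settings for one population.

    Probabilities are annual.  ``litter_distribution`` maps offspring count
    to probability and must sum to 1; ``sex_ratio_at_birth`` is the
    probability a newborn is male.  ``carrying_capacity`` is a ceiling:
    individuals beyond K are removed at random each year.
    """

    initial_individuals: list[tuple[int, int]]  # (sex, age)
    age_classes: list[AgeClass]
    breeding_proportion: float
    litter_distribution: dict[int, float]
    sex_ratio_at_birth: float = 0.5
    first_breeding_age: int = 2
    carrying_capacity: float = math.inf
    years: int = 19
    iterations: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.years < 1 or self.iterations < 1:
            raise ConfigError("years and iterations must be >= 1")
        if not (0.0 <= self.breeding_proportion <= 1.0):
            raise ConfigError("breeding proportion must be in [0, 1]")
        if not (0.0 <= self.sex_ratio_at_birth <= 1.0):
            raise ConfigError("sex ratio must be in [0, 1]")
        if not self.litter_distribution:
            raise ConfigError("litter distribution is empty")
        if any(p < 0 for p in self.litter_distribution.values()):
            raise ConfigError("litter probabilities must be >= 0")
        if abs(sum(self.litter_distribution.values()) - 1.0) > 1e-9:
            raise ConfigError("litter distribution must sum to 1")
        if not self.age_classes:
            raise ConfigError("no age classes")
        for ac in self.age_classes:
            for s in (ac.survival_female, ac.survival_male):
                if not (0.0 <= s <= 1.0):
                    raise ConfigError("survival probabilities must be in [0, 1]")
        if self.max_age < self.first_breeding_age:
            raise ConfigError("no breeding ages inside the age-class table")

    @property
    def max_age(self) -> int:
        return max(ac.max_age for ac in self.age_classes)

    def survival(self, sex: int, age: int) -> float:
        for ac in self.age_classes:
            if ac.min_age <= age <= ac.max_age:
                return ac.survival_female if sex == FEMALE else ac.survival_male
        return 0.0  # outside the table: dies

    @property
    def mean_litter(self) -> float:
        return sum(k * p for k, p in self.litter_distribution.items())


@dataclass
class TrajectorySummary:
    """Across-iteration summary of the projected population."""

    years: np.ndarray            # 0..years (year 0 = initial census)
    mean_n: np.ndarray
    se_n: np.ndarray
    extinction_probability: float
    final_mean_n: float
    final_se_n: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "mean_n": self.mean_n, "se_n": self.se_n})


def _simulate_once(config: PVAConfig, rng: np.random.Generator) -> np.ndarray:
    """One replicate; returns N at census years 0..years (0 after extinction)."""
    sexes = np.array([s for s, _ in config.initial_individuals], dtype=int)
    ages = np.array([a for _, a in config.initial_individuals], dtype=int)
    litter_sizes = np.array(sorted(config.litter_distribution), dtype=int)
    litter_probs = np.array([config.litter_distribution[k] for k in litter_sizes])
    # survival lookup table [sex, age] so the annual cycle stays vectorised
    surv_table = np.array(
        [
            [config.survival(sex, age) for age in range(config.max_age + 1)]
            for sex in (FEMALE, MALE)
        ]
    )
    n_by_year = np.zeros(config.years + 1, dtype=float)
    extinct = (sexes == FEMALE).sum() == 0 or (sexes == MALE).sum() == 0
    n_by_year[0] = 0 if extinct else sexes.size

    for year in range(1, config.years + 1):
        if extinct:
            break
        # breeding: binomial number of breeders among adult females,
        # conditional on >= 1 adult male being alive
        adult_f = (sexes == FEMALE) & (ages >= config.first_breeding_age)
        adult_m = (sexes == MALE) & (ages >= config.first_breeding_age)
        newborn_sexes = np.empty(0, dtype=int)
        if adult_m.any() and adult_f.any() and config.breeding_proportion > 0:
            breeders = rng.binomial(int(adult_f.sum()), config.breeding_proportion)
            if breeders > 0:
                litters = rng.choice(litter_sizes, size=breeders, p=litter_probs)
                n_off = int(litters.sum())
                newborn_sexes = (
                    rng.uniform(size=n_off) < config.sex_ratio_at_birth
                ).astype(int)
        sexes = np.concatenate([sexes, newborn_sexes])
        ages = np.concatenate([ages, np.zeros(newborn_sexes.size, dtype=int)])

        # survival: per-individual Bernoulli by sex and age class
        p_surv = surv_table[sexes, np.minimum(ages, config.max_age)]
        alive = rng.uniform(size=sexes.size) < p_surv
        sexes, ages = sexes[alive], ages[alive]

        # aging; the oldest class is open-ended (individuals stay in it)
        ages = np.minimum(ages + 1, config.max_age)

        # ceiling density dependence: random removal down to K
        if sexes.size > config.carrying_capacity:
            keep_idx = rng.choice(
                sexes.size, size=int(config.carrying_capacity), replace=False
            )
            sexes, ages = sexes[keep_idx], ages[keep_idx]

        if (sexes == FEMALE).sum() == 0 or (sexes == MALE).sum() == 0:
            extinct = True  # absorbing: leaves n_by_year at 0 from here on
            break
        n_by_year[year] = sexes.size
    return n_by_year


def project(config: PVAConfig) -> TrajectorySummary:
    """Run the stochastic projection and summarise across iterations."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(config.iterations)
    traj = np.stack(
        [_simulate_once(config, np.random.default_rng(s)) for s in streams]
    )
    mean_n = traj.mean(axis=0)
    se_n = traj.std(axis=0, ddof=1) / math.sqrt(config.iterations) if config.iterations > 1 else np.zeros_like(mean_n)
    extinct = (traj[:, -1] == 0).mean()
    return TrajectorySummary(
        years=np.arange(config.years + 1),
        mean_n=mean_n,
        se_n=se_n,
        extinction_probability=float(extinct),
        final_mean_n=float(mean_n[-1]),
        final_se_n=float(se_n[-1]),
    )


def leslie_matrix(config: PVAConfig) -> np.ndarray:
    """Female-based Leslie matrix consistent with the simulation cycle.

    State = females at ages 1..max_age at the census.  A female of age
    a >= first_breeding_age contributes ``breeding_proportion * mean_litter
    * (1 - sex_ratio_at_birth) * s0`` age-1 daughters to the next census
    (newborns survive the age-0 female class before first being counted);
    survival moves age a to a+1 with the age-a female rate; the terminal
    age class is open-ended (a self-loop with its own survival), matching
    the simulator, so immortal non-breeding populations have lambda = 1.
    """
    config.validate()
    A = config.max_age
    if A < 1:
        raise StructureError("age-class table must reach at least age 1")
    s0 = config.survival(FEMALE, 0)
    L = np.zeros((A, A))
    for a in range(1, A + 1):
        if a >= config.first_breeding_age:
            L[0, a - 1] = (
                config.breeding_proportion
                * config.mean_litter
                * (1.0 - config.sex_ratio_at_birth)
                * s0
            )
        if a < A:
            L[a, a - 1] = config.survival(FEMALE, a)
    L[A - 1, A - 1] += config.survival(FEMALE, A)  # open-ended terminal class
    return L


def deterministic_lambda(config: PVAConfig) -> float:
    """Dominant eigenvalue of the female Leslie matrix (annual growth rate)."""
    L = leslie_matrix(config)
    eig = np.linalg.eigvals(L)
    lam = float(np.max(eig.real[np.abs(eig.imag) < 1e-9])) if np.any(np.abs(eig.imag) < 1e-9) else float(np.max(np.abs(eig)))
    if not np.isfinite(lam) or lam <= 0:
        raise StructureError("Leslie matrix has no positive dominant eigenvalue")
    return lam


def stable_age_distribution(config: PVAConfig) -> np.ndarray:
    """Right eigenvector (ages 1..max_age, normalised) of the Leslie matrix."""
    L = leslie_matrix(config)
    vals, vecs = np.linalg.eig(L)
    idx = int(np.argmax(vals.real))
    v = np.abs(vecs[:, idx].real)
    return v / v.sum()


def load_config(path: str | Path) -> PVAConfig:
    """Load a PVAConfig from YAML.

    Expected layout::

        initial_individuals: [{sex: F, age: 2, n: 10}, {sex: M, age: 2, n: 8}]
        age_classes: [{min_age: 0, max_age: 0, survival_female: 0.6, survival_male: 0.6}, ...]
        breeding_proportion: 0.85
        litter_distribution: {1: 0.4, 2: 0.55, 3: 0.05}
        sex_ratio_at_birth: 0.5
        first_breeding_age: 2
        carrying_capacity: 400
        years: 19
        iterations: 100
        seed: 0
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    individuals: list[tuple[int, int]] = []
    for entry in raw["initial_individuals"]:
        sex = FEMALE if str(entry["sex"]).upper().startswith("F") else MALE
        individuals.extend([(sex, int(entry["age"]))] * int(entry.get("n", 1)))
    classes = [
        AgeClass(
            min_age=int(c["min_age"]),
            max_age=int(c["max_age"]),
            survival_female=float(c["survival_female"]),
            survival_male=float(c["survival_male"]),
        )
        for c in raw["age_classes"]
    ]
    k = raw.get("carrying_capacity")
    return PVAConfig(
        initial_individuals=individuals,
        age_classes=classes,
        breeding_proportion=float(raw["breeding_proportion"]),
        litter_distribution={int(k_): float(v) for k_, v in raw["litter_distribution"].items()},
        sex_ratio_at_birth=float(raw.get("sex_ratio_at_birth", 0.5)),
        first_breeding_age=int(raw.get("first_breeding_age", 2)),
        carrying_capacity=float(k) if k is not None else math.inf,
        years=int(raw.get("years", 19)),
        iterations=int(raw.get("iterations", 100)),
        seed=int(raw.get("seed", 0)),
    )
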