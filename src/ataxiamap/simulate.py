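"""Synthetic longitudinal cohort generator.

Emulates the statistical structure of the pooled natural-history SCA
cohorts the analysis is designed for: a mixture of SCA1/2/3/6 genotypes
with genotype-specific mean onset ages (32.7, 33.0, 37.2, 51.0 years),
item-level ordinal SARA scores drawn from the generative course model,
1-6 roughly annual visits per subject, per-item missingness, expanded CAG
repeat lengths negatively correlated with onset age within genotype
(target Pearson r of tau vs log CAG = -0.7), and an optional pre-ataxic
fraction observed before their start of progression (RISCA-like).

Scores are simulated from the ordinal course model itself, so generated
cohorts are self-consistent with the likelihood used for inference and
the ground truth is retained for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort
from .model import PopulationParams, level_distribution
from .scales import SARA, ScaleDefinition

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_population_params",
    "generate_cohort",
    "generate_trial_changes",
    "generate_univariate_cohort",
]

#: Default per-item mean-delta bands (years per one-point increase): gait and
#: stance fast (2.5-5), sitting and speech intermediate (5-7.5), the four
#: limb/speech-motor items slow (9-12.5).
DEFAULT_DELTA_BANDS: tuple[tuple[float, float], ...] = (
    (2.5, 5.0),
    (2.5, 5.0),
    (5.0, 7.5),
    (5.0, 7.5),
    (9.0, 12.5),
    (9.0, 12.5),
    (9.0, 12.5),
    (9.0, 12.5),
)

DEFAULT_TAU_POP = {"SCA1": 32.7, "SCA2": 33.0, "SCA3": 37.2, "SCA6": 51.0}
DEFAULT_CAG_MEDIAN = {"SCA1": 46.5, "SCA2": 39.0, "SCA3": 70.0, "SCA6": 22.0}


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort generator."""

    n_subjects: int = 300
    genotype_props: dict = field(
        default_factory=lambda: {"SCA1": 0.22, "SCA2": 0.23, "SCA3": 0.36, "SCA6": 0.19}
    )
    tau_pop: dict = field(default_factory=lambda: dict(DEFAULT_TAU_POP))
    sigma_tau: float = 8.0
    sigma_xi: float = 0.4
    delta_bands: tuple = DEFAULT_DELTA_BANDS
    offset_range: tuple[float, float] = (0.0, 3.0)
    steepness_factor: float = 0.3
    visit_count_range: tuple[int, int] = (1, 6)
    visit_interval_years: float = 1.0
    visit_interval_jitter: float = 0.15
    missing_rate: float = 0.03
    duration_at_entry_range: tuple[float, float] = (0.0, 15.0)
    preataxic_fraction: float = 0.10
    preataxic_lead_years: float = 10.0
    cag_median: dict = field(default_factory=lambda: dict(DEFAULT_CAG_MEDIAN))
    cag_log_sd: float = 0.08
    cag_tau_correlation: float = -0.7
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.genotype_props.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"genotype proportions must sum to 1, got {total}")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must lie in [0, 1]")
        if not 0 <= self.preataxic_fraction < 1:
            raise ValueError("preataxic_fraction must lie in [0, 1)")

    # -- serialization (YAML/JSON round-trip via plain dicts) ---------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["delta_bands"] = [list(b) for b in self.delta_bands]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("offset_range", "visit_count_range", "duration_at_entry_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "delta_bands" in d:
            d["delta_bands"] = tuple(tuple(b) for b in d["delta_bands"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class GroundTruth:
    """Generating parameters retained for recovery tests."""

    population: PopulationParams
    individuals: pd.DataFrame  # subject_id, sca_type, xi, tau, cag, preataxic

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "population": self.population.to_dict(),
            "individuals": self.individuals.to_dict(orient="list"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            population=PopulationParams.from_dict(payload["population"]),
            individuals=pd.DataFrame(payload["individuals"]),
        )


def generate_population_params(
    scale: ScaleDefinition,
    config: GeneratorConfig | None = None,
    seed: int | None = None,
) -> PopulationParams:
    """Draw population parameters with per-item mean deltas in the configured
    bands.

    Each level duration is drawn uniformly from its item's band, so the item
    mean delta necessarily falls inside the band; a degenerate band [d, d]
    gives exactly equal deltas.  Deterministic given the seed.
    """
    if config is None:
        config = GeneratorConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    bands = config.delta_bands
    if len(bands) != scale.n_items:
        raise ValueError(
            f"need {scale.n_items} delta bands for scale {scale.name}, got {len(bands)}"
        )
    deltas = []
    for (low, high), maximum in zip(bands, scale.maxima):
        if low <= 0 or high < low:
            raise ValueError(f"invalid delta band ({low}, {high})")
        deltas.append(rng.uniform(low, high, size=maximum - 1))
    offsets = np.concatenate(
        ([0.0], rng.uniform(*config.offset_range, size=scale.n_items - 1))
    ) if scale.n_items > 1 else np.zeros(1)
    steepness = np.array([config.steepness_factor * d.min() for d in deltas])
    tau_values = np.array(list(config.tau_pop.values()))
    props = np.array([config.genotype_props.get(g, 0.0) for g in config.tau_pop])
    props = props / props.sum()
    overall_tau = float(np.sum(props * tau_values))
    between_var = float(np.sum(props * (tau_values - overall_tau) ** 2))
    return PopulationParams(
        item_names=scale.item_names,
        maxima=scale.maxima,
        deltas=deltas,
        offsets=offsets,
        steepness=steepness,
        tau_pop=overall_tau,
        sigma_tau=float(np.sqrt(config.sigma_tau**2 + between_var)),
        sigma_xi=config.sigma_xi,
    )


def _draw_cag(
    rng: np.random.Generator, genotype: str, tau: float, config: GeneratorConfig
) -> int:
    """CAG repeat from the inverse linear model on tau: within genotype,
    log CAG = mu_g + rho * sd * z_tau + sqrt(1 - rho^2) * sd * noise with
    rho = the configured tau-log(CAG) correlation (negative)."""
    rho = config.cag_tau_correlation
    sd = config.cag_log_sd
    mu = np.log(config.cag_median[genotype])
    z_tau = (tau - config.tau_pop[genotype]) / config.sigma_tau
    log_cag = mu + rho * sd * z_tau + np.sqrt(1.0 - rho**2) * sd * rng.standard_normal()
    return max(1, int(round(np.exp(log_cag))))


_COHORT_BY_CONTINENT = {
    "EUROSCA": "Europe",
    "RISCA": "Europe",
    "SPATAX": "Europe",
    "CRC-SCA": "America",
}


def generate_cohort(
    pop: PopulationParams | None = None,
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    scale: ScaleDefinition = SARA,
) -> tuple[Cohort, GroundTruth]:
    """Simulate a long-format cohort from the ordinal course model.

    Per subject: genotype from the mixture; tau ~ Normal(genotype onset mean,
    sigma_tau); xi ~ Normal(0, sigma_xi); CAG from the inverse linear model
    on tau; baseline age = tau + Uniform(duration-at-entry) years — or below
    tau for the pre-ataxic fraction; 1-6 visits at roughly annual intervals;
    item levels sampled from the model's level distribution at the subject's
    reparameterized time; independent per-item missingness (never leaving a
    visit with every item missing).  Deterministic given the seed.
    """
    if config is None:
        config = GeneratorConfig()
    if config.n_subjects < 1:
        raise ValueError("n_subjects must be positive")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    if pop is None:
        pop = generate_population_params(scale, config, seed=seed)
    genotypes = list(config.genotype_props)
    props = np.array([config.genotype_props[g] for g in genotypes])

    rows = []
    truth_rows = []
    K = len(pop.item_names)
    for i in range(config.n_subjects):
        subject_id = f"S{i + 1:04d}"
        genotype = genotypes[rng.choice(len(genotypes), p=props)]
        tau = rng.normal(config.tau_pop[genotype], config.sigma_tau)
        xi = rng.normal(0.0, config.sigma_xi)
        cag = _draw_cag(rng, genotype, tau, config)
        preataxic = bool(rng.uniform() < config.preataxic_fraction)
        if preataxic:
            baseline = tau - rng.uniform(0.0, config.preataxic_lead_years)
            study = "RISCA"
        else:
            baseline = tau + rng.uniform(*config.duration_at_entry_range)
            study = ["EUROSCA", "CRC-SCA", "SPATAX"][rng.choice(3, p=[0.5, 0.3, 0.2])]
        baseline = max(baseline, 18.0)
        sex = "F" if rng.uniform() < 0.5 else "M"
        n_visits = int(rng.integers(config.visit_count_range[0],
                                    config.visit_count_range[1] + 1))
        gaps = np.maximum(
            rng.normal(config.visit_interval_years, config.visit_interval_jitter,
                       size=n_visits - 1),
            0.25,
        )
        ages = baseline + np.concatenate(([0.0], np.cumsum(gaps)))
        truth_rows.append(
            {
                "subject_id": subject_id,
                "sca_type": genotype,
                "xi": xi,
                "tau": tau,
                "cag": cag,
                "preataxic": preataxic,
            }
        )
        psi = np.exp(xi) * (ages - tau)
        for age, p in zip(ages, psi):
            scores: list[float] = []
            for k in range(K):
                probs = level_distribution(float(p), k, pop)
                scores.append(float(rng.choice(len(probs), p=probs)))
            missing = rng.uniform(size=K) < config.missing_rate
            if missing.all():
                missing[rng.integers(K)] = False
            row = {
                "subject_id": subject_id,
                "age": round(float(age), 3),
                "sca_type": genotype,
                "sex": sex,
                "cag": cag,
                "cohort": study,
                "continent": _COHORT_BY_CONTINENT[study],
            }
            for column, score, miss in zip(scale.columns, scores, missing):
                row[column] = np.nan if miss else score
            rows.append(row)

    df = pd.DataFrame(rows)
    cohort = Cohort(df=df, scale=scale)
    truth = GroundTruth(population=pop, individuals=pd.DataFrame(truth_rows))
    return cohort, truth


def generate_trial_changes(
    pop: PopulationParams,
    config: GeneratorConfig | None = None,
    months: float = 12.0,
    seed: int | None = None,
    scale: ScaleDefinition = SARA,
    exclude_preataxic: bool = True,
) -> tuple[np.ndarray, float, float]:
    """Simulate per-subject total-score changes over a trial of ``months``.

    Each subject gets two complete visits ``months/12`` years apart; the
    change is the difference in total score.  Pre-ataxic subjects are
    excluded from the returned summary statistics by default (they do not
    progress over a short window and would dilute the change).  Returns
    (changes, mean, sd).
    """
    if config is None:
        config = GeneratorConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    dt = months / 12.0
    genotypes = list(config.genotype_props)
    props = np.array([config.genotype_props[g] for g in genotypes])
    K = len(pop.item_names)
    changes = []
    for _ in range(config.n_subjects):
        genotype = genotypes[rng.choice(len(genotypes), p=props)]
        tau = rng.normal(config.tau_pop[genotype], config.sigma_tau)
        xi = rng.normal(0.0, config.sigma_xi)
        preataxic = rng.uniform() < config.preataxic_fraction
        if preataxic and exclude_preataxic:
            continue
        if preataxic:
            baseline = tau - rng.uniform(0.0, config.preataxic_lead_years)
        else:
            baseline = tau + rng.uniform(*config.duration_at_entry_range)
        totals = []
        for age in (baseline, baseline + dt):
            psi = np.exp(xi) * (age - tau)
            total = 0
            for k in range(K):
                probs = level_distribution(float(psi), k, pop)
                total += int(rng.choice(len(probs), p=probs))
            totals.append(total)
        changes.append(totals[1] - totals[0])
    changes_arr = np.asarray(changes, dtype=float)
    return changes_arr, float(np.mean(changes_arr)), float(np.std(changes_arr, ddof=1))


def generate_univariate_cohort(
    n_subjects: int = 300,
    n_levels: int = 10,
    delta: float = 1.0,
    n_visits: int = 4,
    sigma_tau: float = 5.0,
    sigma_xi: float = 0.3,
    tau_pop: float = 40.0,
    steepness: float = 0.3,
    seed: int = 0,
) -> tuple[Cohort, PopulationParams, pd.DataFrame]:
    """Single pseudo-item cohort with equal level durations, for recovery tests.

    Levels run 0 .. n_levels - 1 with ``n_levels - 2`` equal true deltas.
    Baseline ages are drawn from a fixed age window *independent of the
    subject's onset age*: a latent-dependent entry process (enrolment at a
    given disease duration) makes the visit schedule informative about tau
    and biases population-parameter estimates that condition on ages as
    fixed covariates, so a clean recovery oracle requires non-informative
    entry.  Returns (cohort, true population params, true individuals).
    """
    rng = np.random.default_rng(seed)
    pseudo = ScaleDefinition(
        name="pseudo-total", items=(("total", n_levels - 1),), column_prefix="total"
    )
    pop = PopulationParams(
        item_names=("total",),
        maxima=(n_levels - 1,),
        deltas=[np.full(n_levels - 2, float(delta))],
        offsets=np.zeros(1),
        steepness=np.array([steepness]),
        tau_pop=tau_pop,
        sigma_tau=sigma_tau,
        sigma_xi=sigma_xi,
    )
    span = delta * (n_levels - 2)
    rows = []
    truth_rows = []
    for i in range(n_subjects):
        subject_id = f"U{i + 1:04d}"
        tau = rng.normal(tau_pop, sigma_tau)
        xi = rng.normal(0.0, sigma_xi)
        baseline = rng.uniform(tau_pop - 4.0, tau_pop + span + 1.0)
        ages = baseline + np.arange(n_visits) * 1.0
        psi = np.exp(xi) * (ages - tau)
        truth_rows.append({"subject_id": subject_id, "xi": xi, "tau": tau})
        for age, p in zip(ages, psi):
            probs = level_distribution(float(p), 0, pop)
            rows.append(
                {
                    "subject_id": subject_id,
                    "age": round(float(age), 3),
                    "total_1": float(rng.choice(len(probs), p=probs)),
                }
            )
    cohort = Cohort(df=pd.DataFrame(rows), scale=pseudo)
    return cohort, pop, pd.DataFrame(truth_rows)
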