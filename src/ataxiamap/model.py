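"""Generative ordinal disease-course model.

The model places every subject on a common population disease clock.  A
subject with individual parameters (xi, tau) observed at age t sits at the
reparameterized time

    psi = exp(xi) * (t - tau)

where tau is the start-of-progression age (the age at which the reference
item first leaves 0) and exp(xi) is the subject's acceleration factor
relative to the population (population mean of xi is 0).

On the population clock each item k progresses through its levels as an
ordered-logistic process: level l is entered at threshold c_{k,l} and the
exceedance probability is

    P(Y_k >= l | psi) = logistic((psi - c_{k,l}) / s_k)

with per-item steepness s_k (years).  Thresholds are cumulative level
durations: c_{k,1} = theta_k (onset offset, 0 for the reference item) and
c_{k,l+1} = c_{k,l} + delta_{k,l}, so delta_{k,l} is the average time in
years spent at level l before moving to l+1.  A subject with xi = ln 2
spends half the calendar time at each level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.special import expit, log_expit

from .cohort import Cohort
from .scales import ScaleDefinition

__all__ = [
    "PopulationParams",
    "IndividualParams",
    "reparameterize",
    "exceedance",
    "level_distribution",
    "most_likely_level",
    "population_trajectory",
    "log_likelihood",
]


@dataclass
class PopulationParams:
    """Population (fixed-effect) parameters of the ordinal course model.

    Attributes
    ----------
    item_names, maxima : per-item identity and number of levels.
    deltas : list of arrays; ``deltas[k][l-1]`` is the years spent at level l
        of item k (length ``maxima[k] - 1``; an item with maximum 1 has none).
    offsets : array of theta_k >= 0, years from the individual start of
        progression to the first threshold of item k; offsets[0] is 0 so that
        tau is anchored to the reference (first) item.
    steepness : array of s_k > 0 (years), transition sharpness.
    tau_pop, sigma_tau : mean and SD of the start-of-progression age (years).
    sigma_xi : SD of the log acceleration factor.
    """

    item_names: tuple[str, ...]
    maxima: tuple[int, ...]
    deltas: list[np.ndarray]
    offsets: np.ndarray
    steepness: np.ndarray
    tau_pop: float
    sigma_tau: float
    sigma_xi: float
    _thresholds: list[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.deltas = [np.asarray(d, dtype=float) for d in self.deltas]
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.steepness = np.asarray(self.steepness, dtype=float)
        if len(self.deltas) != len(self.item_names):
            raise ValueError("one delta vector per item required")
        for name, maximum, d in zip(self.item_names, self.maxima, self.deltas):
            if len(d) != maximum - 1:
                raise ValueError(
                    f"item {name!r} with maximum {maximum} needs {maximum - 1} deltas"
                )
            if np.any(d <= 0):
                raise ValueError(f"non-positive delta for item {name!r}")
        if np.any(self.steepness <= 0):
            raise ValueError("steepness must be strictly positive")
        if np.any(self.offsets < 0):
            raise ValueError("onset offsets must be non-negative")
        if self.sigma_tau <= 0 or self.sigma_xi <= 0:
            raise ValueError("sigma_tau and sigma_xi must be positive")
        self._thresholds = [
            o + np.concatenate(([0.0], np.cumsum(d)))
            for o, d in zip(self.offsets, self.deltas)
        ]

    @classmethod
    def for_scale(
        cls,
        scale: ScaleDefinition,
        deltas: list[np.ndarray],
        offsets: np.ndarray | None = None,
        steepness: np.ndarray | None = None,
        tau_pop: float = 38.0,
        sigma_tau: float = 8.0,
        sigma_xi: float = 0.4,
    ) -> "PopulationParams":
        n = scale.n_items
        if offsets is None:
            offsets = np.zeros(n)
        if steepness is None:
            # sharp but finite transitions by default
            steepness = np.array([0.3 * np.min(d) if len(d) else 0.3 for d in deltas])
        return cls(
            item_names=scale.item_names,
            maxima=scale.maxima,
            deltas=deltas,
            offsets=offsets,
            steepness=steepness,
            tau_pop=tau_pop,
            sigma_tau=sigma_tau,
            sigma_xi=sigma_xi,
        )

    def thresholds(self, item: int) -> np.ndarray:
        """Thresholds c_{k,1} .. c_{k,L_k} (years on the population clock)."""
        return self._thresholds[item]

    def mean_delta(self, item: int) -> float:
        """Average years per one-point increase of the item."""
        return float(np.mean(self.deltas[item]))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "item_names": list(self.item_names),
            "maxima": list(self.maxima),
            "deltas_years": [d.tolist() for d in self.deltas],
            "onset_offsets_years": self.offsets.tolist(),
            "steepness_years": self.steepness.tolist(),
            "tau_pop_years": self.tau_pop,
            "sigma_tau_years": self.sigma_tau,
            "sigma_xi_log": self.sigma_xi,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationParams":
        return cls(
            item_names=tuple(d["item_names"]),
            maxima=tuple(d["maxima"]),
            deltas=[np.asarray(x) for x in d["deltas_years"]],
            offsets=np.asarray(d["onset_offsets_years"]),
            steepness=np.asarray(d["steepness_years"]),
            tau_pop=d["tau_pop_years"],
            sigma_tau=d["sigma_tau_years"],
            sigma_xi=d["sigma_xi_log"],
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "PopulationParams":
        p = Path(text_or_path) if not str(text_or_path).lstrip().startswith("{") else None
        text = p.read_text() if p is not None and p.exists() else str(text_or_path)
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class IndividualParams:
    """Individual random effects: log acceleration xi and onset age tau (years)."""

    xi: float
    tau: float

    @property
    def acceleration(self) -> float:
        return float(np.exp(self.xi))

    def to_dict(self) -> dict:
        return {"xi_log_acceleration": self.xi, "tau_onset_years": self.tau}


def reparameterize(age: float | np.ndarray, ind: IndividualParams) -> float | np.ndarray:
    """Individual age -> position psi on the population disease clock."""
    return np.exp(ind.xi) * (np.asarray(age, dtype=float) - ind.tau)


def exceedance(
    psi: float | np.ndarray, item: int, level: int, pop: PopulationParams
) -> float | np.ndarray:
    """P(Y_item >= level | psi), the ordered-logistic exceedance curve."""
    if not 1 <= level <= pop.maxima[item]:
        raise ValueError(f"level {level} out of range 1..{pop.maxima[item]}")
    c = pop.thresholds(item)[level - 1]
    return expit((np.asarray(psi, dtype=float) - c) / pop.steepness[item])


def level_distribution(
    psi: float | np.ndarray, item: int, pop: PopulationParams
) -> np.ndarray:
    """Probability vector over levels 0..L of one item at clock position psi.

    P(Y = l) = P(Y >= l) - P(Y >= l+1) with P(Y >= 0) = 1 and
    P(Y >= L+1) = 0.  For strictly increasing thresholds all entries are
    non-negative and each row sums to 1.  Vectorized: an array psi of shape
    (...,) yields probabilities of shape (..., L + 1).
    """
    psi_arr = np.asarray(psi, dtype=float)
    c = pop.thresholds(item)
    z = (psi_arr[..., None] - c) / pop.steepness[item]
    exc = expit(z)  # shape (..., L)
    ones = np.ones(psi_arr.shape + (1,))
    zeros = np.zeros(psi_arr.shape + (1,))
    upper = np.concatenate([ones, exc], axis=-1)
    lower = np.concatenate([exc, zeros], axis=-1)
    probs = upper - lower
    if np.ndim(psi) == 0:
        return probs[0] if probs.ndim == 2 else probs
    return probs


def most_likely_level(
    psi: float | np.ndarray, item: int, pop: PopulationParams
) -> int | np.ndarray:
    """Most probable level at psi; ties break toward the lower level.

    A non-decreasing step function of psi.
    """
    probs = level_distribution(psi, item, pop)
    idx = np.argmax(probs, axis=-1)  # argmax returns the first (lowest) maximum
    if np.ndim(psi) == 0:
        return int(idx)
    return idx


def population_trajectory(
    ages: np.ndarray, pop: PopulationParams
) -> "np.ndarray | object":
    """Average trajectory: per-item most-likely level at each age for the
    typical subject (xi = 0, tau = tau_pop).

    Returns a pandas DataFrame with one column per item plus ``total``.
    """
    import pandas as pd

    ages = np.asarray(ages, dtype=float)
    if np.any(np.diff(ages) < 0):
        raise ValueError("age grid must be sorted")
    psi = ages - pop.tau_pop
    data = {"age": ages}
    total = np.zeros(len(ages), dtype=int)
    for k, name in enumerate(pop.item_names):
        levels = most_likely_level(psi, k, pop)
        data[name] = levels
        total += levels
    data["total"] = total
    return pd.DataFrame(data)


def _obs_log_prob(
    psi: np.ndarray, levels: np.ndarray, thresholds: np.ndarray, s: float
) -> np.ndarray:
    """log P(Y = level | psi) for arrays of observations of one item.

    Computed on the log scale via log_expit to stay finite far from the
    thresholds; interior levels use log(sig(a) - sig(b)) =
    log_sig(a) + log(1 - exp(log_sig(b) - log_sig(a))).
    """
    psi = np.asarray(psi, dtype=float)
    levels = np.asarray(levels, dtype=int)
    L = len(thresholds)
    out = np.empty(psi.shape, dtype=float)

    at_floor = levels == 0
    at_ceiling = levels == L
    interior = ~(at_floor | at_ceiling)

    if at_floor.any():
        # P(Y=0) = 1 - sig((psi - c_1)/s) = sig(-(psi - c_1)/s)
        out[at_floor] = log_expit(-(psi[at_floor] - thresholds[0]) / s)
    if at_ceiling.any():
        out[at_ceiling] = log_expit((psi[at_ceiling] - thresholds[L - 1]) / s)
    if interior.any():
        li = levels[interior]
        a = (psi[interior] - thresholds[li - 1]) / s
        b = (psi[interior] - thresholds[li]) / s
        log_hi = log_expit(a)
        log_lo = log_expit(b)
        # diff <= 0 since b < a; clamp so the result stays finite even when
        # psi sits far beyond both thresholds (keeps MCMC able to recover)
        diff = np.minimum(log_lo - log_hi, -1e-12)
        out[interior] = log_hi + np.log1p(-np.exp(diff))
    return np.maximum(out, -700.0)


def log_likelihood(
    cohort: Cohort,
    pop: PopulationParams,
    inds: Mapping[str, IndividualParams],
) -> float:
    """Observation log-likelihood of a cohort under the ordinal model.

    Sums log P(Y = observed level) over every non-missing (visit, item)
    pair; missing entries contribute zero.  ``inds`` must cover every
    subject in the cohort.
    """
    total = 0.0
    df = cohort.df
    columns = cohort.scale.columns
    for subject, group in df.groupby("subject_id", sort=False):
        if subject not in inds:
            raise KeyError(f"no individual parameters for subject {subject!r}")
        psi = reparameterize(group["age"].to_numpy(dtype=float), inds[subject])
        for k, column in enumerate(columns):
            y = group[column].to_numpy(dtype=float)
            mask = ~np.isnan(y)
            if not mask.any():
                continue
            obs = y[mask].astype(int)
            if np.any(obs > pop.maxima[k]):
                raise ValueError(
                    f"observation exceeds maximum {pop.maxima[k]} "
                    f"for item {pop.item_names[k]!r}"
                )
            total += float(
                _obs_log_prob(
                    psi[mask], obs, pop.thresholds(k), float(pop.steepness[k])
                ).sum()
            )
    return total
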