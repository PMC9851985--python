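"""MCMC-SAEM estimation of the ordinal disease-course model.

Estimation alternates Metropolis-within-Gibbs sampling of the per-subject
random effects (xi_i, tau_i) with updates of the population parameters.
During burn-in the hyperparameters (tau_pop, sigma_tau, sigma_xi) follow
closed-form stochastic-approximation (SAEM) updates from the current
individual draws with a decreasing step schedule, the structural parameters
(level durations, onset offsets, steepness) move by adaptive random-walk
Metropolis, and proposal scales adapt toward a target acceptance rate.
After burn-in all adaptation stops: structural parameters are sampled by
fixed-scale Metropolis under near-flat Normal(0, 1e6) priors on their
unconstrained transforms, and the hyperparameters by conjugate Gibbs steps
(flat prior on tau_pop, Jeffreys on the variances).

Identifiability: the population mean of xi is 0 by construction — after
every individual update the xi vector is recentred and the time-scale
parameters (deltas, offsets, steepness) are rescaled by exp(-mean xi),
which leaves the likelihood exactly invariant.

The sampler is exposed both as a scikit-learn style estimator
(:class:`OrdinalProgressionModel`) and as the module function :func:`fit`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import Cohort
from .model import IndividualParams, PopulationParams, _obs_log_prob
from .scales import ScaleDefinition

logger = logging.getLogger(__name__)

__all__ = [
    "McmcConfig",
    "PosteriorSamples",
    "PersonalizationResult",
    "OrdinalProgressionModel",
    "NonIdentifiableError",
    "fit",
    "personalize",
    "geweke",
    "FULL_PROFILE",
    "TEST_PROFILE",
]


class NonIdentifiableError(ValueError):
    """Raised when the cohort carries no information about progression."""


@dataclass(frozen=True)
class McmcConfig:
    """Sampler configuration.

    ``n_burnin`` warm-up iterations are discarded; ``n_samples`` draws per
    chain are retained.  ``saem_exponent`` controls the decreasing SAEM step
    schedule: steps are 1 for the first half of burn-in, then k**(-exponent).
    """

    n_burnin: int = 5500
    n_samples: int = 3500
    n_chains: int = 2
    seed: int = 0
    proposal_scales: dict = field(
        default_factory=lambda: {
            "xi": 0.1,
            "tau": 1.0,
            "delta": 0.15,       # log scale
            "offset": 0.5,       # years
            "steepness": 0.25,   # log scale
        }
    )
    saem_exponent: float = 0.65
    adapt_target: float = 0.3
    adapt_window: int = 40

    def __post_init__(self) -> None:
        if self.n_burnin < 1 or self.n_samples < 1 or self.n_chains < 1:
            raise ValueError("iteration and chain counts must be positive")
        if not 0 < self.saem_exponent <= 1:
            raise ValueError("saem_exponent must lie in (0, 1]")


#: Full-length profile used for final analyses.
FULL_PROFILE = McmcConfig(n_burnin=5500, n_samples=3500)
#: Reduced desk-scale profile for tests and smoke runs.
TEST_PROFILE = McmcConfig(n_burnin=1000, n_samples=500)


# ---------------------------------------------------------------------------
# flattened data layout


class _FlatData:
    """Cohort flattened to per-item observation arrays for fast likelihoods."""

    def __init__(self, cohort: Cohort):
        df = cohort.df
        self.scale = cohort.scale
        self.subject_ids = cohort.subject_ids
        self.index = {s: i for i, s in enumerate(self.subject_ids)}
        self.n_subjects = len(self.subject_ids)
        subj = df["subject_id"].map(self.index).to_numpy(dtype=np.intp)
        age = df["age"].to_numpy(dtype=float)
        self.obs_subj: list[np.ndarray] = []
        self.obs_age: list[np.ndarray] = []
        self.obs_level: list[np.ndarray] = []
        for column in cohort.scale.columns:
            y = df[column].to_numpy(dtype=float)
            mask = ~np.isnan(y)
            self.obs_subj.append(subj[mask])
            self.obs_age.append(age[mask])
            self.obs_level.append(y[mask].astype(np.intp))
        self.n_obs = int(sum(len(a) for a in self.obs_age))

    def first_ages(self) -> np.ndarray:
        out = np.full(self.n_subjects, np.inf)
        for s, a in zip(self.obs_subj, self.obs_age):
            np.minimum.at(out, s, a)
        return out


def _thresholds(log_deltas: list[np.ndarray], offsets: np.ndarray) -> list[np.ndarray]:
    return [
        o + np.concatenate(([0.0], np.cumsum(np.exp(ld))))
        for o, ld in zip(offsets, log_deltas)
    ]


def _item_loglik(
    data: _FlatData, k: int, thr: np.ndarray, s: float, xi: np.ndarray, tau: np.ndarray
) -> float:
    subj = data.obs_subj[k]
    psi = np.exp(xi[subj]) * (data.obs_age[k] - tau[subj])
    return float(_obs_log_prob(psi, data.obs_level[k], thr, s).sum())


def _per_subject_loglik(
    data: _FlatData,
    thresholds: list[np.ndarray],
    steepness: np.ndarray,
    xi: np.ndarray,
    tau: np.ndarray,
) -> np.ndarray:
    ll = np.zeros(data.n_subjects)
    for k in range(len(thresholds)):
        subj = data.obs_subj[k]
        if len(subj) == 0:
            continue
        psi = np.exp(xi[subj]) * (data.obs_age[k] - tau[subj])
        lp = _obs_log_prob(psi, data.obs_level[k], thresholds[k], float(steepness[k]))
        ll += np.bincount(subj, weights=lp, minlength=data.n_subjects)
    return ll


# ---------------------------------------------------------------------------
# posterior container


@dataclass
class PosteriorSamples:
    """Retained posterior draws of population and individual parameters.

    Arrays are stacked over chains: ``n_draws = n_samples * n_chains`` rows.
    ``deltas[k]`` has shape (n_draws, L_k - 1); ``xi`` and ``tau`` have shape
    (n_draws, n_subjects).
    """

    item_names: tuple[str, ...]
    maxima: tuple[int, ...]
    subject_ids: list[str]
    deltas: list[np.ndarray]
    offsets: np.ndarray
    steepness: np.ndarray
    tau_pop: np.ndarray
    sigma_tau: np.ndarray
    sigma_xi: np.ndarray
    xi: np.ndarray
    tau: np.ndarray
    chain: np.ndarray
    acceptance_rates: dict
    config: dict
    seed: int

    @property
    def n_draws(self) -> int:
        return len(self.tau_pop)

    def median_population_params(self) -> PopulationParams:
        """Posterior-median plug-in population parameters."""
        return PopulationParams(
            item_names=self.item_names,
            maxima=self.maxima,
            deltas=[np.median(d, axis=0) for d in self.deltas],
            offsets=np.median(self.offsets, axis=0),
            steepness=np.median(self.steepness, axis=0),
            tau_pop=float(np.median(self.tau_pop)),
            sigma_tau=float(np.median(self.sigma_tau)),
            sigma_xi=float(np.median(self.sigma_xi)),
        )

    def individual_medians(self) -> pd.DataFrame:
        """Posterior medians of (xi, tau) per subject."""
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "xi": np.median(self.xi, axis=0),
                "tau": np.median(self.tau, axis=0),
            }
        )

    # -- persistence --------------------------------------------------------

    def _population_frame(self) -> pd.DataFrame:
        data = {"chain": self.chain}
        for k, name in enumerate(self.item_names):
            for l in range(self.deltas[k].shape[1]):
                data[f"delta__{name}__{l + 1}"] = self.deltas[k][:, l]
            data[f"offset__{name}"] = self.offsets[:, k]
            data[f"steepness__{name}"] = self.steepness[:, k]
        data["tau_pop"] = self.tau_pop
        data["sigma_tau"] = self.sigma_tau
        data["sigma_xi"] = self.sigma_xi
        return pd.DataFrame(data)

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self._population_frame().to_csv(d / "population.csv", index=False)
        pd.DataFrame(self.xi, columns=self.subject_ids).to_csv(
            d / "individual_xi.csv", index=False
        )
        pd.DataFrame(self.tau, columns=self.subject_ids).to_csv(
            d / "individual_tau.csv", index=False
        )
        meta = {
            "item_names": list(self.item_names),
            "maxima": list(self.maxima),
            "seed": self.seed,
            "config": self.config,
        }
        (d / "meta.json").write_text(json.dumps(meta, indent=2))
        (d / "diagnostics.json").write_text(
            json.dumps({"acceptance_rates": self.acceptance_rates}, indent=2)
        )

    @classmethod
    def load(cls, directory: str | Path) -> "PosteriorSamples":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        diag = json.loads((d / "diagnostics.json").read_text())
        popdf = pd.read_csv(d / "population.csv")
        xi = pd.read_csv(d / "individual_xi.csv")
        tau = pd.read_csv(d / "individual_tau.csv")
        item_names = tuple(meta["item_names"])
        maxima = tuple(meta["maxima"])
        deltas = []
        offsets, steepness = [], []
        for name, maximum in zip(item_names, maxima):
            cols = [f"delta__{name}__{l + 1}" for l in range(maximum - 1)]
            deltas.append(popdf[cols].to_numpy())
            offsets.append(popdf[f"offset__{name}"].to_numpy())
            steepness.append(popdf[f"steepness__{name}"].to_numpy())
        return cls(
            item_names=item_names,
            maxima=maxima,
            subject_ids=list(xi.columns),
            deltas=deltas,
            offsets=np.column_stack(offsets),
            steepness=np.column_stack(steepness),
            tau_pop=popdf["tau_pop"].to_numpy(),
            sigma_tau=popdf["sigma_tau"].to_numpy(),
            sigma_xi=popdf["sigma_xi"].to_numpy(),
            xi=xi.to_numpy(),
            tau=tau.to_numpy(),
            chain=popdf["chain"].to_numpy(dtype=int),
            acceptance_rates=diag["acceptance_rates"],
            config=meta["config"],
            seed=meta["seed"],
        )


# ---------------------------------------------------------------------------
# the sampler


class _AdaptiveScale:
    """One proposal scale with windowed Robbins-Monro adaptation."""

    def __init__(self, value: float, target: float, window: int):
        self.value = value
        self.target = target
        self.window = window
        self._acc = 0
        self._tries = 0
        self.sampling_acc = 0
        self.sampling_tries = 0

    def record(self, accepted: int, tries: int, adapting: bool) -> None:
        if adapting:
            self._acc += accepted
            self._tries += tries
            if self._tries >= self.window:
                rate = self._acc / self._tries
                self.value *= float(np.exp(rate - self.target))
                self.value = float(np.clip(self.value, 1e-4, 1e4))
                self._acc = self._tries = 0
        else:
            self.sampling_acc += accepted
            self.sampling_tries += tries

    @property
    def sampling_rate(self) -> float:
        if self.sampling_tries == 0:
            return float("nan")
        return self.sampling_acc / self.sampling_tries


def _init_state(data: _FlatData, rng: np.random.Generator) -> dict:
    """Crude but serviceable starting values from observed score trajectories."""
    n = data.n_subjects
    K = len(data.obs_age)
    maxima = np.array(list(data.scale.maxima))
    # accumulate totals at each subject's first and last observed age
    first_total = np.zeros(n)
    first_age = data.first_ages()
    last_total = np.zeros(n)
    last_age = np.full(n, -np.inf)
    tol = 1e-9
    for k in range(K):
        s, a, y = data.obs_subj[k], data.obs_age[k], data.obs_level[k]
        np.maximum.at(last_age, s, a)
    for k in range(K):
        s, a, y = data.obs_subj[k], data.obs_age[k], data.obs_level[k]
        at_first = np.abs(a - first_age[s]) < tol
        np.add.at(first_total, s[at_first], y[at_first])
        at_last = np.abs(a - last_age[s]) < tol
        np.add.at(last_total, s[at_last], y[at_last])
    span = last_age - first_age
    d_tot = last_total - first_total
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = d_tot[span > 0.5] / span[span > 0.5]
    rates = rates[rates > 0]
    if len(rates) >= 5:
        d0 = float(np.clip(1.0 / np.median(rates), 0.2, 15.0))
    else:
        d0 = 2.0
    tau0 = np.where(
        first_total > 0, first_age - d0 * first_total, last_age + d0
    )
    xi0 = np.zeros(n)
    # spread each item's course over the total-score course: with course
    # length d0 * T (T = scale maximum) per item, the total accrues at the
    # observed 1/d0 points per year
    T = float(maxima.sum())
    log_deltas = [np.full(m - 1, np.log(d0 * T / (m - 1))) for m in maxima]
    offsets = np.zeros(K)
    log_s = np.array([float(ld[0]) + np.log(0.3) for ld in log_deltas])
    return {
        "xi": xi0,
        "tau": tau0,
        "log_deltas": log_deltas,
        "offsets": offsets,
        "log_s": log_s,
        "tau_pop": float(np.mean(tau0)),
        "sigma_tau": float(max(np.std(tau0), 1.0)),
        "sigma_xi": 0.5,
        "d0": d0,
    }


def _check_identifiable(data: _FlatData) -> None:
    interior = np.zeros(data.n_subjects, dtype=bool)
    for k, maximum in enumerate(data.scale.maxima):
        y = data.obs_level[k]
        mask = (y > 0) & (y < maximum)
        interior[np.unique(data.obs_subj[k][mask])] = True
    if interior.sum() < 2:
        raise NonIdentifiableError(
            "cohort is non-identifiable: fewer than 2 subjects with an "
            "observation strictly between 0 and the item maximum"
        )


def _run_chain(
    data: _FlatData, config: McmcConfig, chain_id: int, seed: int
) -> dict:
    rng = np.random.default_rng(seed)
    n = data.n_subjects
    K = len(data.obs_age)
    n_total = config.n_burnin + config.n_samples
    half_burn = config.n_burnin // 2

    st = _init_state(data, rng)
    xi, tau = st["xi"], st["tau"]
    log_deltas, offsets, log_s = st["log_deltas"], st["offsets"], st["log_s"]
    tau_pop, sigma_tau, sigma_xi = st["tau_pop"], st["sigma_tau"], st["sigma_xi"]

    scales = {
        name: _AdaptiveScale(config.proposal_scales[name], config.adapt_target,
                             config.adapt_window * (n if name in ("xi", "tau") else 1))
        for name in ("xi", "tau", "delta", "offset", "steepness")
    }

    prior_sd = 1e6  # near-flat Normal prior on unconstrained transforms

    thr = _thresholds(log_deltas, offsets)
    steep = np.exp(log_s)
    ll_sub = _per_subject_loglik(data, thr, steep, xi, tau)
    if not np.all(np.isfinite(ll_sub)):
        raise FloatingPointError("non-finite log-likelihood at initialization")

    # SAEM sufficient statistics
    S_tau, S_tau2 = float(np.mean(tau)), float(np.mean(tau**2))
    S_xi2 = float(np.mean(xi**2) + sigma_xi**2)

    out = {
        "deltas": [np.empty((config.n_samples, m - 1)) for m in data.scale.maxima],
        "offsets": np.empty((config.n_samples, K)),
        "steepness": np.empty((config.n_samples, K)),
        "tau_pop": np.empty(config.n_samples),
        "sigma_tau": np.empty(config.n_samples),
        "sigma_xi": np.empty(config.n_samples),
        "xi": np.empty((config.n_samples, n)),
        "tau": np.empty((config.n_samples, n)),
    }

    for it in range(n_total):
        adapting = it < config.n_burnin

        # ---- individual blocks -------------------------------------------
        for name, vec, prior_mu, prior_sigma in (
            ("xi", xi, 0.0, sigma_xi),
            ("tau", tau, tau_pop, sigma_tau),
        ):
            prop = vec + scales[name].value * rng.standard_normal(n)
            if name == "xi":
                ll_prop = _per_subject_loglik(data, thr, steep, prop, tau)
            else:
                ll_prop = _per_subject_loglik(data, thr, steep, xi, prop)
            logr = (
                ll_prop
                - ll_sub
                - 0.5 * ((prop - prior_mu) / prior_sigma) ** 2
                + 0.5 * ((vec - prior_mu) / prior_sigma) ** 2
            )
            accept = np.log(rng.uniform(size=n)) < logr
            vec[accept] = prop[accept]
            ll_sub[accept] = ll_prop[accept]
            scales[name].record(int(accept.sum()), n, adapting)

        # ---- recentre xi (identifiability), compensate the time scale ----
        m = float(np.mean(xi))
        if m != 0.0:
            xi -= m
            for ld in log_deltas:
                ld -= m
            offsets *= np.exp(-m)
            log_s -= m
            thr = _thresholds(log_deltas, offsets)
            steep = np.exp(log_s)

        # ---- structural population parameters ----------------------------
        # Thresholds are updated one site at a time in threshold space (the
        # cumulative-delta parameterization mixes poorly: a single delta move
        # shifts every higher threshold).  The first threshold of the
        # reference item is anchored at 0 (tau identifiability); the first
        # threshold of the other items is their non-negative onset offset.
        for k in range(K):
            ll_k = _item_loglik(data, k, thr[k], float(steep[k]), xi, tau)
            thr_k = thr[k]
            L = len(thr_k)
            for l in range(L):
                if k == 0 and l == 0:
                    continue  # anchored
                scale_name = "offset" if l == 0 else "delta"
                old_c = thr_k[l]
                new_c = old_c + scales[scale_name].value * rng.standard_normal()
                lower = thr_k[l - 1] if l > 0 else 0.0
                upper = thr_k[l + 1] if l < L - 1 else np.inf
                if not (lower <= new_c < upper) or (l == 0 and new_c < 0):
                    scales[scale_name].record(0, 1, adapting)
                    continue
                if l > 0 and new_c == lower:
                    scales[scale_name].record(0, 1, adapting)
                    continue
                thr_new = thr_k.copy()
                thr_new[l] = new_c
                ll_new = _item_loglik(data, k, thr_new, float(steep[k]), xi, tau)
                # near-flat prior on the log of each affected level duration
                logp = 0.0
                for a, b in ((l - 1, l), (l, l + 1)):
                    if 0 <= a and b <= L - 1:
                        old_gap = np.log(thr_k[b] - thr_k[a])
                        new_gap = np.log(thr_new[b] - thr_new[a])
                        logp += (old_gap**2 - new_gap**2) / (2 * prior_sd**2)
                        logp += old_gap - new_gap  # Jacobian of log-delta prior
                logr = ll_new - ll_k + logp
                if np.log(rng.uniform()) < logr:
                    thr_k = thr_new
                    thr[k] = thr_new
                    ll_k = ll_new
                    scales[scale_name].record(1, 1, adapting)
                else:
                    scales[scale_name].record(0, 1, adapting)
            offsets[k] = thr_k[0]
            log_deltas[k] = np.log(np.diff(thr_k)) if L > 1 else log_deltas[k]
            # steepness
            old = log_s[k]
            new = old + scales["steepness"].value * rng.standard_normal()
            ll_new = _item_loglik(data, k, thr[k], float(np.exp(new)), xi, tau)
            logr = ll_new - ll_k - (new**2 - old**2) / (2 * prior_sd**2)
            if np.log(rng.uniform()) < logr:
                log_s[k] = new
                steep[k] = np.exp(new)
                ll_k = ll_new
                scales["steepness"].record(1, 1, adapting)
            else:
                scales["steepness"].record(0, 1, adapting)

        ll_sub = _per_subject_loglik(data, thr, steep, xi, tau)
        if not np.all(np.isfinite(ll_sub)):
            raise FloatingPointError(f"non-finite log-likelihood at iteration {it}")

        # ---- hyperparameters ---------------------------------------------
        if adapting:
            # SAEM: step 1 for the first half of burn-in, then k^(-exponent)
            step = 1.0 if it < half_burn else (it - half_burn + 1) ** (-config.saem_exponent)
            S_tau += step * (float(np.mean(tau)) - S_tau)
            S_tau2 += step * (float(np.mean(tau**2)) - S_tau2)
            S_xi2 += step * (float(np.mean(xi**2)) - S_xi2)
            tau_pop = S_tau
            sigma_tau = float(np.sqrt(max(S_tau2 - S_tau**2, 1e-4)))
            sigma_xi = float(np.sqrt(max(S_xi2, 1e-6)))
        else:
            # conjugate Gibbs: flat prior on tau_pop, Jeffreys on variances
            tau_pop = float(rng.normal(np.mean(tau), sigma_tau / np.sqrt(n)))
            ss_tau = float(np.sum((tau - tau_pop) ** 2))
            sigma_tau = float(
                np.sqrt(ss_tau / (2.0 * rng.gamma(n / 2.0, 1.0)))
            )
            ss_xi = float(np.sum(xi**2))
            sigma_xi = float(
                np.sqrt(max(ss_xi / (2.0 * rng.gamma(n / 2.0, 1.0)), 1e-8))
            )
            sigma_tau = max(sigma_tau, 1e-2)
            sigma_xi = max(sigma_xi, 1e-3)

        # ---- record -------------------------------------------------------
        if it >= config.n_burnin:
            j = it - config.n_burnin
            for k in range(K):
                out["deltas"][k][j] = np.exp(log_deltas[k])
            out["offsets"][j] = offsets
            out["steepness"][j] = steep
            out["tau_pop"][j] = tau_pop
            out["sigma_tau"][j] = sigma_tau
            out["sigma_xi"][j] = sigma_xi
            out["xi"][j] = xi
            out["tau"][j] = tau

    out["acceptance"] = {name: s.sampling_rate for name, s in scales.items()}
    out["chain"] = np.full(config.n_samples, chain_id, dtype=int)
    return out


def fit(
    cohort: Cohort,
    config: McmcConfig | None = None,
    mode: str = "multivariate",
) -> PosteriorSamples:
    """Fit the ordinal course model to a cohort by MCMC-SAEM.

    ``mode="multivariate"`` models the scale's items jointly; ``"univariate"``
    collapses each visit to its total score and fits a single pseudo-item
    whose levels are the total-score values (one delta per total-score
    level).  Deterministic given ``config.seed``.
    """
    if config is None:
        config = McmcConfig()
    if mode not in ("univariate", "multivariate"):
        raise ValueError("mode must be 'univariate' or 'multivariate'")
    work = _collapse_to_total(cohort) if mode == "univariate" else cohort
    data = _FlatData(work)
    if data.n_subjects < 2:
        raise NonIdentifiableError("need at least 2 subjects")
    _check_identifiable(data)

    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_chains)
    chains = [
        _run_chain(data, config, chain_id=c, seed=int(seeds[c] % (2**31)))
        for c in range(config.n_chains)
    ]

    def cat(key):
        return np.concatenate([ch[key] for ch in chains], axis=0)

    acceptance = {
        name: float(np.mean([ch["acceptance"][name] for ch in chains
                             if np.isfinite(ch["acceptance"][name])]))
        for name in chains[0]["acceptance"]
        if any(np.isfinite(ch["acceptance"][name]) for ch in chains)
    }
    return PosteriorSamples(
        item_names=work.scale.item_names,
        maxima=work.scale.maxima,
        subject_ids=data.subject_ids,
        deltas=[
            np.concatenate([ch["deltas"][k] for ch in chains], axis=0)
            for k in range(work.scale.n_items)
        ],
        offsets=cat("offsets"),
        steepness=cat("steepness"),
        tau_pop=cat("tau_pop"),
        sigma_tau=cat("sigma_tau"),
        sigma_xi=cat("sigma_xi"),
        xi=cat("xi"),
        tau=cat("tau"),
        chain=cat("chain"),
        acceptance_rates=acceptance,
        config={
            "n_burnin": config.n_burnin,
            "n_samples": config.n_samples,
            "n_chains": config.n_chains,
            "mode": mode,
        },
        seed=config.seed,
    )


def _collapse_to_total(cohort: Cohort) -> Cohort:
    """Rewrite the cohort as a single pseudo-item holding the total score."""
    totals = cohort.total_scores()
    df = cohort.df[["subject_id", "age"]].copy()
    df["total_1"] = totals
    df = df[~df["total_1"].isna()]
    pseudo = ScaleDefinition(
        name=f"{cohort.scale.name}-total",
        items=(("total", cohort.scale.total_maximum),),
        column_prefix="total",
    )
    return Cohort(df=df.reset_index(drop=True), scale=pseudo)


# ---------------------------------------------------------------------------
# personalization of a single subject


@dataclass
class PersonalizationResult:
    """Posterior mode and draws of one subject's (xi, tau)."""

    xi_mode: float
    tau_mode: float
    xi_draws: np.ndarray
    tau_draws: np.ndarray

    @property
    def params(self) -> IndividualParams:
        return IndividualParams(xi=self.xi_mode, tau=self.tau_mode)


def personalize(
    visits: pd.DataFrame,
    pop: PopulationParams,
    scale: ScaleDefinition,
    config: McmcConfig | None = None,
) -> PersonalizationResult:
    """Estimate (xi, tau) for one subject given fixed population parameters.

    Maximizes the observation log-likelihood plus the Gaussian priors
    N(0, sigma_xi) and N(tau_pop, sigma_tau) for the mode, then draws from
    the conditional posterior by random-walk Metropolis.
    """
    from scipy.optimize import minimize

    if config is None:
        config = McmcConfig(n_burnin=500, n_samples=500, n_chains=1)
    ages = visits["age"].to_numpy(dtype=float)
    obs = []
    for k, column in enumerate(scale.columns):
        y = visits[column].to_numpy(dtype=float)
        mask = ~np.isnan(y)
        if mask.any():
            obs.append((k, ages[mask], y[mask].astype(int)))
    if not obs:
        raise ValueError("subject has no non-missing observations")

    def neg_log_post(theta):
        xi, tau = theta
        ll = 0.0
        for k, a, y in obs:
            psi = np.exp(xi) * (a - tau)
            ll += _obs_log_prob(
                psi, y, pop.thresholds(k), float(pop.steepness[k])
            ).sum()
        ll -= 0.5 * (xi / pop.sigma_xi) ** 2
        ll -= 0.5 * ((tau - pop.tau_pop) / pop.sigma_tau) ** 2
        return -ll

    best = None
    for tau_start in (pop.tau_pop, float(ages.min()), float(ages.min()) - 5.0):
        res = minimize(neg_log_post, x0=[0.0, tau_start], method="Nelder-Mead")
        if best is None or res.fun < best.fun:
            best = res
    xi_mode, tau_mode = map(float, best.x)

    rng = np.random.default_rng(config.seed)
    xi_c, tau_c = xi_mode, tau_mode
    lp_c = -neg_log_post([xi_c, tau_c])
    n_total = config.n_burnin + config.n_samples
    draws = np.empty((config.n_samples, 2))
    step = np.array([0.5 * pop.sigma_xi, 0.5 * pop.sigma_tau])
    for it in range(n_total):
        prop = np.array([xi_c, tau_c]) + step * rng.standard_normal(2)
        lp_p = -neg_log_post(prop)
        if np.log(rng.uniform()) < lp_p - lp_c:
            xi_c, tau_c = map(float, prop)
            lp_c = lp_p
        if it >= config.n_burnin:
            draws[it - config.n_burnin] = (xi_c, tau_c)
    return PersonalizationResult(
        xi_mode=xi_mode,
        tau_mode=tau_mode,
        xi_draws=draws[:, 0],
        tau_draws=draws[:, 1],
    )


# ---------------------------------------------------------------------------
# convergence diagnostics


def _long_run_variance(x: np.ndarray) -> float:
    """Spectral density at zero via a Bartlett-window (Newey-West) estimator."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    gamma0 = float(np.dot(xc, xc)) / n
    lag_max = int(np.floor(4.0 * (n / 100.0) ** (2.0 / 9.0)))
    lrv = gamma0
    for lag in range(1, min(lag_max, n - 1) + 1):
        gamma = float(np.dot(xc[:-lag], xc[lag:])) / n
        lrv += 2.0 * (1.0 - lag / (lag_max + 1.0)) * gamma
    return max(lrv, 0.0)


def geweke(chain: Sequence[float], first_frac: float = 0.1, last_frac: float = 0.5) -> float:
    """Geweke convergence z-score of a scalar chain.

    Compares the mean of the first ``first_frac`` of the chain with the mean
    of the last ``last_frac``; the variance of each segment mean uses a
    spectral-density-at-zero (long-run variance) estimate.  |z| < 2 is
    conventionally read as consistent with convergence.
    """
    x = np.asarray(chain, dtype=float)
    if len(x) < 100:
        raise ValueError("chain must have at least 100 draws")
    if not 0 < first_frac < 1 or not 0 < last_frac < 1 or first_frac + last_frac > 1:
        raise ValueError("segment fractions must be in (0,1) and sum to at most 1")
    a = x[: int(np.floor(first_frac * len(x)))]
    b = x[len(x) - int(np.floor(last_frac * len(x))):]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant chain segment: Geweke variance undefined")
    var = _long_run_variance(a) / len(a) + _long_run_variance(b) / len(b)
    return float((a.mean() - b.mean()) / np.sqrt(var))


# ---------------------------------------------------------------------------
# scikit-learn style estimator


class OrdinalProgressionModel(BaseEstimator):
    """Ordinal Bayesian disease-course model with MCMC-SAEM estimation.

    Parameters
    ----------
    mode : {"multivariate", "univariate"}
        Model items jointly, or the total score as one pseudo-item.
    n_burnin, n_samples, n_chains, seed
        Sampler budget; the full-length default matches 5500 discarded
        warm-up iterations plus 3500 retained draws per chain.
    profile : {"full", "test", None}
        Shorthand overriding the iteration counts: ``"full"`` = 5500+3500,
        ``"test"`` = 1000+500 (desk-scale).

    Attributes
    ----------
    samples_ : PosteriorSamples
        Retained posterior draws.
    population_params_ : PopulationParams
        Posterior-median plug-in estimates.
    individual_params_ : pandas.DataFrame
        Posterior medians of (xi, tau) per subject.
    acceptance_rates_ : dict
        Sampling-phase Metropolis acceptance rate per block.
    """

    def __init__(
        self,
        mode: str = "multivariate",
        n_burnin: int = 5500,
        n_samples: int = 3500,
        n_chains: int = 2,
        seed: int = 0,
        profile: str | None = None,
    ):
        self.mode = mode
        self.n_burnin = n_burnin
        self.n_samples = n_samples
        self.n_chains = n_chains
        self.seed = seed
        self.profile = profile

    def _config(self) -> McmcConfig:
        if self.profile == "full":
            base = FULL_PROFILE
        elif self.profile == "test":
            base = TEST_PROFILE
        elif self.profile is None:
            base = McmcConfig(n_burnin=self.n_burnin, n_samples=self.n_samples)
        else:
            raise ValueError(f"unknown profile {self.profile!r}")
        return replace(base, n_chains=self.n_chains, seed=self.seed)

    def fit(self, X: Cohort, y=None) -> "OrdinalProgressionModel":
        if not isinstance(X, Cohort):
            raise TypeError("X must be a Cohort (long-format visits bound to a scale)")
        self.scale_ = _collapse_to_total(X).scale if self.mode == "univariate" else X.scale
        self.samples_ = fit(X, config=self._config(), mode=self.mode)
        self.population_params_ = self.samples_.median_population_params()
        self.individual_params_ = self.samples_.individual_medians()
        self.acceptance_rates_ = self.samples_.acceptance_rates
        self.n_subjects_ = len(self.samples_.subject_ids)
        return self

    def personalize(self, visits: pd.DataFrame) -> PersonalizationResult:
        """Posterior mode and draws of (xi, tau) for one (new) subject."""
        self._check_fitted()
        scale = self._fitted_scale()
        return personalize(visits, self.population_params_, scale)

    def predict(self, X: Cohort | pd.DataFrame) -> pd.DataFrame:
        """Most-likely item levels per visit after personalizing each subject."""
        from .model import most_likely_level, reparameterize

        self._check_fitted()
        df = X.df if isinstance(X, Cohort) else X
        scale = self._fitted_scale()
        rows = []
        for subject, group in df.groupby("subject_id", sort=False):
            pers = personalize(group, self.population_params_, scale)
            psi = reparameterize(group["age"].to_numpy(dtype=float), pers.params)
            for visit_i, age in enumerate(group["age"]):
                rec = {"subject_id": subject, "age": float(age)}
                for k, column in enumerate(scale.columns):
                    rec[column] = int(
                        most_likely_level(float(psi[visit_i]), k, self.population_params_)
                    )
                rows.append(rec)
        return pd.DataFrame(rows)

    def score(self, X: Cohort, y=None) -> float:
        """Mean per-observation log-likelihood at personalized modes."""
        from .model import log_likelihood

        self._check_fitted()
        scale = self._fitted_scale()
        work = _collapse_to_total(X) if self.mode == "univariate" else X
        inds = {
            subject: personalize(group, self.population_params_, scale).params
            for subject, group in work.df.groupby("subject_id", sort=False)
        }
        n_obs = _FlatData(work).n_obs
        return log_likelihood(work, self.population_params_, inds) / max(n_obs, 1)

    def _fitted_scale(self) -> ScaleDefinition:
        return self.scale_

    def _check_fitted(self) -> None:
        if not hasattr(self, "samples_"):
            raise RuntimeError("estimator is not fitted; call fit() first")
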