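"""Known-truth synthetic Likert data with the structure the analysis assumes.

The default configuration emulates a questionnaire study of ~455
respondents on five-category Likert items: person trait Normal(0, 1),
item difficulties spread evenly over [-2, 2] logits, symmetric shared
thresholds (-1.5, -0.5, 0.5, 1.5).  Missingness (MCAR) and misfit
(random responders) can be injected to exercise the preprocessing and
fit-diagnostic stages.  Every generator is a pure function of its
configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .data import ResponseMatrix, ScaleDefinition
from .errors import ConfigurationError
from .model import category_probabilities

__all__ = [
    "SimulationConfig",
    "simulate_responses",
    "make_two_version_study",
    "make_upps_like_study",
    "inject_random_responders",
    "inject_missing",
]

DEFAULT_TAUS = (-1.5, -0.5, 0.5, 1.5)


def evenly_spaced_betas(n_items: int, spread: float = 2.0) -> np.ndarray:
    """Item difficulties evenly spaced on [-spread, spread], mean 0."""
    if n_items == 1:
        return np.zeros(1)
    return np.linspace(-spread, spread, n_items)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated response matrix."""

    n_persons: int = 455
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    item_betas: tuple[float, ...] = tuple(evenly_spaced_betas(12))
    taus: tuple[float, ...] = DEFAULT_TAUS
    n_categories: int = 5
    seed: int = 0
    missing_rate: float = 0.0
    random_responder_fraction: float = 0.0
    item_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        betas = np.asarray(self.item_betas, dtype=float)
        taus = np.asarray(self.taus, dtype=float)
        if self.n_persons < 2 or betas.size < 2:
            raise ConfigurationError("need at least 2 persons and 2 items")
        if self.theta_sd < 0:
            raise ConfigurationError("theta_sd must be nonnegative")
        if taus.size != self.n_categories - 1:
            raise ConfigurationError(
                f"need {self.n_categories - 1} thresholds for "
                f"{self.n_categories} categories"
            )
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if not 0 <= self.random_responder_fraction < 1:
            raise ConfigurationError("random_responder_fraction must be in [0, 1)")
        if abs(betas.mean()) > 1e-9:
            import warnings

            warnings.warn("item_betas re-centered to mean 0")
            object.__setattr__(self, "item_betas", tuple(betas - betas.mean()))
        if abs(taus.sum()) > 1e-9:
            import warnings

            warnings.warn("taus re-centered to sum 0")
            object.__setattr__(self, "taus", tuple(taus - taus.mean()))
        if self.item_ids is not None and len(self.item_ids) != betas.size:
            raise ConfigurationError("item_ids length must match item_betas")


@dataclass(frozen=True)
class SimulationTruth:
    """Generating parameters behind a simulated matrix."""

    theta: np.ndarray
    beta: np.ndarray
    tau: np.ndarray


def _draw_categories(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Vectorized categorical draw along the last axis of ``probs``."""
    cum = probs.cumsum(axis=-1)
    u = rng.random(probs.shape[:-1])[..., None]
    return (u > cum).sum(axis=-1)


def simulate_responses(config: SimulationConfig) -> tuple[ResponseMatrix, SimulationTruth]:
    """Draw an RSM-consistent response matrix; fully determined by the seed."""
    rng = np.random.default_rng(config.seed)
    beta = np.asarray(config.item_betas, dtype=float)
    tau = np.asarray(config.taus, dtype=float)
    theta = rng.normal(config.theta_mean, config.theta_sd, config.n_persons)
    probs = category_probabilities(theta[:, None], beta[None, :], tau)
    scores = _draw_categories(rng, probs).astype(float)

    n_random = int(round(config.random_responder_fraction * config.n_persons))
    if n_random:
        idx = rng.choice(config.n_persons, size=n_random, replace=False)
        scores[idx] = rng.integers(0, config.n_categories, (n_random, beta.size))

    if config.missing_rate > 0:
        mask = rng.random(scores.shape) < config.missing_rate
        scores[mask] = np.nan

    item_ids = config.item_ids or tuple(f"i{j + 1}" for j in range(beta.size))
    rm = ResponseMatrix(
        person_ids=tuple(f"p{n + 1}" for n in range(config.n_persons)),
        item_ids=tuple(item_ids),
        responses=scores,
        n_categories=config.n_categories,
    )
    return rm, SimulationTruth(theta=theta, beta=beta, tau=tau)


def make_two_version_study(
    config: SimulationConfig,
    short_subset: Sequence[int],
    independent_traits: bool = False,
) -> tuple[ResponseMatrix, ResponseMatrix, SimulationTruth]:
    """A full-form matrix and its short-form column subset sharing one trait.

    ``short_subset`` indexes the full-form items.  The short form is a view
    of the same simulated responses, guaranteeing the common-trait
    structure the concordance analysis assumes.  With
    ``independent_traits=True`` the short form is re-simulated from an
    independent trait draw — a negative control for which downstream
    concordance collapses to ~0.
    """
    short_subset = list(short_subset)
    n_items = len(config.item_betas)
    if not short_subset or any(not 0 <= j < n_items for j in short_subset):
        raise ConfigurationError("short_subset must index the full-form items")
    full, truth = simulate_responses(config)
    if independent_traits:
        alt = replace(config, seed=config.seed + 1)
        alt_full, _ = simulate_responses(alt)
        short = alt_full.subset_items([full.item_ids[j] for j in short_subset])
    else:
        short = full.subset_items([full.item_ids[j] for j in short_subset])
    return full, short, truth


def make_upps_like_study(
    scale: ScaleDefinition,
    n_persons: int = 455,
    seed: int = 0,
    theta_sd: float = 1.0,
    beta_spread: float = 2.0,
    missing_rate: float = 0.0,
) -> tuple[ResponseMatrix, dict[str, SimulationTruth]]:
    """Simulate a whole multi-dimension questionnaire matching a scale layout.

    Each dimension gets an independent trait draw (unidimensional within
    dimension, as the analysis assumes) and difficulties evenly spread over
    [-beta_spread, beta_spread]; the returned matrix spans all dimensions'
    items so the preprocessing stage sees the full administered instrument.
    """
    rng = np.random.default_rng(seed)
    blocks: list[np.ndarray] = []
    item_ids: list[str] = []
    truths: dict[str, SimulationTruth] = {}
    n_cat = scale.n_categories
    tau = np.asarray(DEFAULT_TAUS, dtype=float)
    if tau.size != n_cat - 1:
        tau = np.linspace(-1.5, 1.5, n_cat - 1)
    for dim, items in scale.dimensions.items():
        beta = evenly_spaced_betas(len(items), beta_spread)
        theta = rng.normal(0.0, theta_sd, n_persons)
        probs = category_probabilities(theta[:, None], beta[None, :], tau)
        scores = _draw_categories(rng, probs).astype(float)
        blocks.append(scores)
        item_ids.extend(items)
        truths[dim] = SimulationTruth(theta=theta, beta=beta, tau=tau)
    responses = np.concatenate(blocks, axis=1)
    if missing_rate > 0:
        mask = rng.random(responses.shape) < missing_rate
        responses[mask] = np.nan
    rm = ResponseMatrix(
        person_ids=tuple(f"p{n + 1}" for n in range(n_persons)),
        item_ids=tuple(item_ids),
        responses=responses,
        n_categories=n_cat,
    )
    return rm, truths


def inject_random_responders(
    rm: ResponseMatrix, fraction: float, seed: int = 0
) -> tuple[ResponseMatrix, list[str]]:
    """Replace a random subset of persons' responses with uniform category draws.

    Returns the modified matrix and the affected person ids (a misfit
    fixture: such persons show inflated OUTFIT on a well-targeted test).
    """
    if not 0 <= fraction <= 1:
        raise ConfigurationError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_sel = int(round(fraction * rm.n_persons))
    if n_sel == 0:
        return rm, []
    idx = np.sort(rng.choice(rm.n_persons, size=n_sel, replace=False))
    scores = rm.responses.copy()
    draws = rng.integers(0, rm.n_categories, (n_sel, rm.n_items)).astype(float)
    keep_nan = np.isnan(scores[idx])
    scores[idx] = np.where(keep_nan, np.nan, draws)
    out = ResponseMatrix(
        person_ids=rm.person_ids,
        item_ids=rm.item_ids,
        responses=scores,
        n_categories=rm.n_categories,
    )
    return out, [rm.person_ids[i] for i in idx]


def inject_missing(rm: ResponseMatrix, rate: float, seed: int = 0) -> ResponseMatrix:
    """Set entries missing completely at random at the given rate."""
    if not 0 <= rate < 1:
        raise ConfigurationError("rate must be in [0, 1)")
    if rate == 0:
        return rm
    rng = np.random.default_rng(seed)
    scores = rm.responses.copy()
    mask = rng.random(scores.shape) < rate
    scores[mask] = np.nan
    return ResponseMatrix(
        person_ids=rm.person_ids,
        item_ids=rm.item_ids,
        responses=scores,
        n_categories=rm.n_categories,
    )
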