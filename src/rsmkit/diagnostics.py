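"""Model-fit diagnostics: residual fit statistics, separation, information.

INFIT and OUTFIT mean-squares have expectation 1 under the model; the
interpretation bands follow the conventional Rasch reading (values above 2
degrade measurement, 1.5-2 are unproductive, 0.5-1.5 productive, below 0.5
deterministic/overfitting).  Separation indices gauge how many statistically
distinct strata the instrument resolves on each margin, and the test
information function is the pointwise sum of item score variances, whose
inverse square root is the standard error of measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ResponseMatrix
from .model import RatingScaleModel, score_variance

__all__ = [
    "FitStatistics",
    "SeparationSummary",
    "InformationCurve",
    "standardized_residuals",
    "infit_outfit",
    "classify_mnsq",
    "item_total_correlations",
    "separation",
    "information_function",
    "item_map",
    "item_map_from_values",
]

BAND_DEGRADING = "degrading"
BAND_UNPRODUCTIVE = "unproductive"
BAND_PRODUCTIVE = "productive"
BAND_OVERFIT = "overfit-deterministic"


@dataclass(frozen=True)
class FitStatistics:
    """Per-unit mean-square fit statistics along one margin."""

    margin: str  # "items" or "persons"
    ids: tuple[str, ...]
    infit_mnsq: np.ndarray
    outfit_mnsq: np.ndarray
    classification: tuple[str, ...]
    item_total_correlation: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "infit_mnsq": self.infit_mnsq,
                "outfit_mnsq": self.outfit_mnsq,
                "classification": list(self.classification),
            },
            index=list(self.ids),
        )
        if self.item_total_correlation is not None:
            df["item_total_correlation"] = self.item_total_correlation
        return df


@dataclass(frozen=True)
class SeparationSummary:
    """Separation/reliability summary for one margin.

    ``adjusted_sd`` is the measurement-error-adjusted true spread:
    ``adjusted_sd^2 = max(observed_sd^2 - rmse^2, 0)``; reliability is its
    share of the observed variance, the separation index is
    ``adjusted_sd / rmse`` and strata = (4G + 1) / 3.
    """

    margin: str
    observed_sd: float
    rmse: float
    adjusted_sd: float
    reliability: float
    separation_index: float
    strata: float
    verdict: str  # "adequate" | "inadequate"


@dataclass(frozen=True)
class InformationCurve:
    theta_grid: np.ndarray
    information: np.ndarray
    se: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"theta": self.theta_grid, "information": self.information, "se": self.se}
        )


def _aligned_responses(rm: ResponseMatrix, fit: RatingScaleModel) -> np.ndarray:
    """Responses restricted to the units retained by the fit, fit order."""
    sub = rm
    if rm.person_ids != fit.person_ids_ or rm.item_ids != fit.item_ids_:
        sub = rm.subset_persons(fit.person_ids_).subset_items(fit.item_ids_)
    return sub.responses


def standardized_residuals(rm: ResponseMatrix, fit: RatingScaleModel) -> np.ndarray:
    """z = (x - E) / sqrt(W) at the fitted parameters; missing propagates."""
    x = _aligned_responses(rm, fit)
    e, w = fit.expected_matrix()
    return (x - e) / np.sqrt(w)


def classify_mnsq(value: float) -> str:
    """Map a mean-square to its interpretation band.

    > 2.0 degrading; (1.5, 2.0] unproductive; [0.5, 1.5] productive;
    < 0.5 overfit-deterministic.  The bands partition [0, inf).
    """
    if value < 0:
        raise ValueError("mean-squares are nonnegative")
    if value > 2.0:
        return BAND_DEGRADING
    if value > 1.5:
        return BAND_UNPRODUCTIVE
    if value >= 0.5:
        return BAND_PRODUCTIVE
    return BAND_OVERFIT


def item_total_correlations(rm: ResponseMatrix, fit: RatingScaleModel) -> np.ndarray:
    """Pearson r between each item's score and the rest-of-scale total.

    The rest-score (total minus the item itself) avoids the self-inflation
    a raw total would introduce.  Persons with a missing value on the item
    are dropped pairwise; the rest-score averages the person's other
    observed items.
    """
    x = _aligned_responses(rm, fit)
    n_items = x.shape[1]
    out = np.full(n_items, np.nan)
    for j in range(n_items):
        rest = np.delete(x, j, axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rest_mean = np.nanmean(rest, axis=1)
        ok = ~np.isnan(x[:, j]) & ~np.isnan(rest_mean)
        if ok.sum() > 2 and np.std(x[ok, j]) > 0 and np.std(rest_mean[ok]) > 0:
            out[j] = stats.pearsonr(x[ok, j], rest_mean[ok]).statistic
    return out


def infit_outfit(
    rm: ResponseMatrix, fit: RatingScaleModel, margin: str = "items"
) -> FitStatistics:
    """Information-weighted (INFIT) and unweighted (OUTFIT) mean-squares.

    OUTFIT is the plain mean of squared standardized residuals over the
    observed cells of each unit; INFIT weights by the model variance,
    ``sum((x - E)^2) / sum(W)``, damping the influence of off-target cells.
    """
    if margin not in {"items", "persons"}:
        raise ValueError("margin must be 'items' or 'persons'")
    x = _aligned_responses(rm, fit)
    e, w = fit.expected_matrix()
    obs = ~np.isnan(x)
    sq = np.where(obs, (x - e) ** 2, 0.0)
    z2 = sq / w
    axis = 0 if margin == "items" else 1
    n_obs = obs.sum(axis=axis)
    if (n_obs == 0).any():
        warnings.warn(f"{margin} with no observed responses get NaN fit statistics")
    with np.errstate(invalid="ignore", divide="ignore"):
        outfit = np.where(n_obs > 0, z2.sum(axis=axis) / np.maximum(n_obs, 1), np.nan)
        infit = np.where(
            n_obs > 0,
            sq.sum(axis=axis) / np.where(obs, w, 0.0).sum(axis=axis),
            np.nan,
        )
    ids = fit.item_ids_ if margin == "items" else fit.person_ids_
    classification = tuple(
        classify_mnsq(v) if np.isfinite(v) else "unavailable" for v in outfit
    )
    itc = item_total_correlations(rm, fit) if margin == "items" else None
    return FitStatistics(
        margin=margin,
        ids=tuple(ids),
        infit_mnsq=infit,
        outfit_mnsq=outfit,
        classification=classification,
        item_total_correlation=itc,
    )


def separation(fit: RatingScaleModel, margin: str = "persons") -> SeparationSummary:
    """Separation index, reliability and strata for one margin.

    Computed over non-extreme units only: extreme measures rest on the
    fractional-score adjustment and would distort the spread.  Verdicts use
    the conventional floors (persons: separation >= 2 adequate; items: >= 3).
    """
    if margin == "persons":
        keep = ~fit.extreme_persons_
        measures = fit.theta_[keep]
        ses = fit.se_theta_[keep]
        floor = 2.0
    elif margin == "items":
        keep = ~fit.extreme_items_
        measures = fit.beta_[keep]
        ses = fit.se_beta_[keep]
        floor = 3.0
    else:
        raise ValueError("margin must be 'persons' or 'items'")
    if measures.size < 2:
        raise ValueError("need at least 2 non-extreme units for separation")
    observed_sd = float(np.std(measures, ddof=1))
    rmse = float(np.sqrt(np.mean(ses**2)))
    adj_var = max(observed_sd**2 - rmse**2, 0.0)
    adjusted_sd = float(np.sqrt(adj_var))
    reliability = adj_var / observed_sd**2 if observed_sd > 0 else 0.0
    sep = adjusted_sd / rmse if rmse > 0 else np.inf
    strata = (4 * sep + 1) / 3
    return SeparationSummary(
        margin=margin,
        observed_sd=observed_sd,
        rmse=rmse,
        adjusted_sd=adjusted_sd,
        reliability=float(reliability),
        separation_index=float(sep),
        strata=float(strata),
        verdict="adequate" if sep >= floor else "inadequate",
    )


def information_function(
    fit: RatingScaleModel, theta_grid: np.ndarray | None = None
) -> InformationCurve:
    """Test information I(theta) = sum of item score variances, and its SE.

    Default grid: -6..6 logits in 0.1 steps.
    """
    if theta_grid is None:
        theta_grid = np.arange(-6.0, 6.0 + 1e-9, 0.1)
    theta_grid = np.asarray(theta_grid, dtype=float)
    info = score_variance(theta_grid[:, None], fit.beta_[None, :], fit.tau_).sum(axis=1)
    return InformationCurve(
        theta_grid=theta_grid, information=info, se=1.0 / np.sqrt(info)
    )


def item_map_from_values(item_ids, betas) -> pd.DataFrame:
    """Item map from explicit difficulty values (see :func:`item_map`)."""
    df = pd.DataFrame({"item": list(item_ids), "beta": np.asarray(betas, dtype=float)})
    df = df.sort_values(["beta", "item"], kind="mergesort").reset_index(drop=True)
    df["gap_to_previous"] = df["beta"].diff()
    return df


def item_map(fit: RatingScaleModel) -> pd.DataFrame:
    """Items sorted by difficulty with the logit gap to the previous item.

    Ties are broken by item id; the first row's gap is NaN.
    """
    df = pd.DataFrame({"item": list(fit.item_ids_), "beta": fit.beta_})
    df = df.sort_values(["beta", "item"], kind="mergesort").reset_index(drop=True)
    df["gap_to_previous"] = df["beta"].diff()
    return df
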