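"""Full-form vs short-form concordance of person measures.

Each version of a dimension is calibrated independently; the two sets of
person measures are z-scored and regressed (ideal concordance: slope 1,
intercept 0).  The Reduction-in-Uncertainty index

    RiU = 1 - sqrt(1 - r^2)

is the fraction of statistical uncertainty about one score removed by
knowing the other; RiU >= 0.5 supports using the short form as a surrogate.
The efficiency index relates the item-count saving to the score agreement:
(n_short / n_full) / r, with values at or below 0.80 counting as efficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import ResponseMatrix, ScaleDefinition, subset_dimension
from .model import RatingScaleModel, fit_rsm

__all__ = [
    "ConcordanceReport",
    "standardize",
    "concordance_regression",
    "reduction_in_uncertainty",
    "efficiency_index",
    "order_preservation",
    "adjacent_gap_analysis",
    "compare_versions",
]

RIU_THRESHOLD = 0.5
EFFICIENCY_CRITERION = 0.80
SUBSTANTIAL_GAP = 0.5
CENTRAL_GAP = 0.3
CENTRAL_REGION = (-1.0, 1.0)


@dataclass(frozen=True)
class GapFlag:
    item_low: str
    item_high: str
    gap: float
    kind: str  # "substantial" | "central-region"


@dataclass(frozen=True)
class ConcordanceReport:
    dimension: str
    slope: float
    intercept: float
    r: float
    r_squared: float
    riu: float
    riu_verdict: str  # "concordant" | "not-concordant"
    efficiency: float
    efficiency_verdict: str  # "efficient" | "not-efficient"
    n_persons: int
    n_dropped_pairs: int
    order_tau: float | None = None
    gap_flags: tuple[GapFlag, ...] = ()
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "dimension": self.dimension,
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.r,
            "r_squared": self.r_squared,
            "riu": self.riu,
            "riu_verdict": self.riu_verdict,
            "efficiency": self.efficiency,
            "efficiency_verdict": self.efficiency_verdict,
            "n_persons": self.n_persons,
            "n_dropped_pairs": self.n_dropped_pairs,
            "order_tau": self.order_tau,
            "gap_flags": [
                {"item_low": g.item_low, "item_high": g.item_high,
                 "gap": g.gap, "kind": g.kind}
                for g in self.gap_flags
            ],
        }


def standardize(measures, ddof: int = 1) -> np.ndarray:
    """z-score a measure vector (sample SD by default); idempotent."""
    x = np.asarray(measures, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to standardize")
    sd = np.std(x, ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


def concordance_regression(z_short, z_full) -> tuple[float, float, float, float]:
    """OLS of full-version on short-version measures: (slope, intercept, r, R^2).

    With z-scored inputs the slope equals the Pearson correlation and the
    intercept is 0.
    """
    z_short = np.asarray(z_short, dtype=float)
    z_full = np.asarray(z_full, dtype=float)
    if z_short.shape != z_full.shape:
        raise ValueError("paired measure vectors must have equal length")
    res = stats.linregress(z_short, z_full)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue),
        float(res.rvalue**2),
    )


def reduction_in_uncertainty(r: float) -> float:
    """RiU = 1 - sqrt(1 - r^2); 0 at r = 0, 1 at |r| = 1."""
    if abs(r) > 1:
        raise ValueError("correlation must lie in [-1, 1]")
    return 1.0 - float(np.sqrt(1.0 - r**2))


def riu_verdict(riu: float, threshold: float = RIU_THRESHOLD) -> str:
    return "concordant" if riu >= threshold else "not-concordant"


def efficiency_index(
    n_short: int,
    n_full: int,
    r: float,
    criterion: float = EFFICIENCY_CRITERION,
    form: str = "ratio-over-r",
) -> tuple[float, str]:
    """Short-form efficiency: item-count ratio scaled by the score correlation.

    The default reading divides the ratio by the diagonal correlation,
    (n_short / n_full) / r, so that fewer items and higher agreement both
    lower the index; values <= ``criterion`` are "efficient".  The
    multiplicative reading is available as ``form="ratio-times-r"``.
    """
    if not 0 < n_short <= n_full:
        raise ValueError("need 0 < n_short <= n_full")
    if not 0 < r <= 1:
        raise ValueError("efficiency is undefined for r <= 0")
    ratio = n_short / n_full
    if form == "ratio-over-r":
        eff = ratio / r
    elif form == "ratio-times-r":
        eff = ratio * r
    else:
        raise ValueError(f"unknown efficiency form {form!r}")
    return float(eff), ("efficient" if eff <= criterion else "not-efficient")


def order_preservation(beta_full, beta_short) -> float:
    """Kendall tau between shared-item difficulties from the two calibrations."""
    beta_full = np.asarray(beta_full, dtype=float)
    beta_short = np.asarray(beta_short, dtype=float)
    if beta_full.size != beta_short.size or beta_full.size < 3:
        raise ValueError("need >= 3 paired item difficulties")
    return float(stats.kendalltau(beta_full, beta_short).statistic)


def adjacent_gap_analysis(
    item_map_df,
    substantial: float = SUBSTANTIAL_GAP,
    central_limit: float = CENTRAL_GAP,
    central_region: tuple[float, float] = CENTRAL_REGION,
) -> tuple[GapFlag, ...]:
    """Flag large gaps between adjacent items on the difficulty continuum.

    A gap above ``substantial`` logits is flagged outright; a gap above
    ``central_limit`` is additionally flagged when both items sit inside the
    central region, where finer measurement resolution is wanted.
    """
    flags: list[GapFlag] = []
    items = list(item_map_df["item"])
    betas = np.asarray(item_map_df["beta"], dtype=float)
    lo, hi = central_region
    for prev, cur in zip(range(len(items) - 1), range(1, len(items))):
        gap = betas[cur] - betas[prev]
        if gap > substantial:
            flags.append(GapFlag(items[prev], items[cur], float(gap), "substantial"))
        elif gap > central_limit and lo <= betas[prev] and betas[cur] <= hi:
            flags.append(GapFlag(items[prev], items[cur], float(gap), "central-region"))
    return tuple(flags)


def compare_versions(
    rm: ResponseMatrix,
    scale: ScaleDefinition,
    dimension: str,
    anchored: bool = False,
    efficiency_form: str = "ratio-over-r",
    **fit_config,
) -> tuple[ConcordanceReport, RatingScaleModel, RatingScaleModel]:
    """Run the full-vs-short concordance pipeline for one dimension.

    Both versions are calibrated independently (``anchored=True`` instead
    scores the short form at the full-form item anchors).  Persons flagged
    extreme or dropped in either fit are excluded pairwise.

    Returns the report and the two fitted models (full, short).
    """
    rm_full = subset_dimension(rm, scale, dimension, "full")
    rm_short = subset_dimension(rm, scale, dimension, "short")
    fit_full = fit_rsm(rm_full, **fit_config)
    fit_short = fit_rsm(rm_short, **fit_config)

    theta_full = dict(zip(fit_full.person_ids_, fit_full.theta_))
    ext_full = dict(zip(fit_full.person_ids_, fit_full.extreme_persons_))
    if anchored:
        theta_anchor, _ = fit_full.score_persons(rm_short)
        theta_short = dict(zip(rm_short.person_ids, theta_anchor))
        ext_short = {p: False for p in rm_short.person_ids}
    else:
        theta_short = dict(zip(fit_short.person_ids_, fit_short.theta_))
        ext_short = dict(zip(fit_short.person_ids_, fit_short.extreme_persons_))

    pairs = [
        p
        for p in rm.person_ids
        if p in theta_full and p in theta_short
        and not ext_full.get(p, True) and not ext_short.get(p, True)
        and np.isfinite(theta_full[p]) and np.isfinite(theta_short[p])
    ]
    n_dropped = rm.n_persons - len(pairs)
    tf = np.array([theta_full[p] for p in pairs])
    ts = np.array([theta_short[p] for p in pairs])
    z_full = standardize(tf)
    z_short = standardize(ts)
    slope, intercept, r, r2 = concordance_regression(z_short, z_full)
    riu = reduction_in_uncertainty(r)
    n_full_items = len(scale.items_for(dimension, "full"))
    n_short_items = len(scale.items_for(dimension, "short"))
    eff, eff_verdict = efficiency_index(
        n_short_items, n_full_items, abs(r), form=efficiency_form
    )

    shared = [i for i in scale.items_for(dimension, "short")]
    pos_full = {i: j for j, i in enumerate(fit_full.item_ids_)}
    pos_short = {i: j for j, i in enumerate(fit_short.item_ids_)}
    tau_order = None
    if len(shared) >= 3 and all(i in pos_full and i in pos_short for i in shared):
        tau_order = order_preservation(
            fit_full.beta_[[pos_full[i] for i in shared]],
            fit_short.beta_[[pos_short[i] for i in shared]],
        )

    from .diagnostics import item_map  # local import avoids a cycle

    gaps = adjacent_gap_analysis(item_map(fit_short))
    report = ConcordanceReport(
        dimension=dimension,
        slope=slope,
        intercept=intercept,
        r=r,
        r_squared=r2,
        riu=riu,
        riu_verdict=riu_verdict(riu),
        efficiency=eff,
        efficiency_verdict=eff_verdict,
        n_persons=len(pairs),
        n_dropped_pairs=n_dropped,
        order_tau=tau_order,
        gap_flags=gaps,
    )
    return report, fit_full, fit_short
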