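"""Stress scoring of survey sites and the grazing regression.

The trained mesocosm ensembles are applied to survey sites whose responses
have been standardized against the <1 %-grazing field control sites. The
ensemble mean output is read as a linearly interpolated stress score on the
1 (low) to 2 (high) scale and clipped into [1, 2]; raw means are retained
for transparency. Scores are then regressed on the catchment grazing
proportion by ordinary least squares, with the slope tested through the
F = (R^2/1) / ((1-R^2)/(n-2)) identity. A significant positive sediment
regression alongside a non-significant nutrient regression is the
"sediment-mediated" verdict: community composition at heavily grazed sites
resembles the high-sediment, not the high-nutrient, mesocosm communities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import Ensemble, predict
from .errors import DataError
from .stats import f_sf

__all__ = ["SiteScore", "RegressionResult", "score_sites", "regress_scores", "diagnose_report"]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    F: float
    df1: int
    df2: int
    p: float
    n: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "F": self.F,
            "df1": self.df1,
            "df2": self.df2,
            "p": self.p,
            "n": self.n,
        }


@dataclass(frozen=True)
class SiteScore:
    site_id: str
    target_name: str
    score: float
    score_sd: float
    grazing_proportion: float


def score_sites(
    ens: Ensemble,
    site_features: pd.DataFrame,
    grazing: pd.Series,
    threshold: float = 1.5,
) -> pd.DataFrame:
    """Per-site stress scores from one ensemble.

    ``site_features`` must carry ``site_id`` and the ensemble's input
    variables (already standardized against field controls). Returns a
    table with raw ensemble mean, the clipped score in [1, 2], the
    (unclipped) member SD, and the grazing proportion.
    """
    preds = predict(ens, site_features, id_col="site_id", threshold=threshold)
    g = grazing.set_axis(site_features["site_id"]).loc[preds["site_id"]].to_numpy(float)
    return pd.DataFrame(
        {
            "site_id": preds["site_id"],
            "target": ens.target_name,
            "raw_mean": preds["mean"],
            "score": np.clip(preds["mean"], 1.0, 2.0),
            "score_sd": preds["sd"],
            "vote_fraction_high": preds["vote_fraction_high"],
            "grazing_proportion": g,
        }
    )


def regress_scores(scores: pd.DataFrame, value_col: str = "score") -> RegressionResult:
    """OLS of the site score on the grazing proportion, F-test on the slope."""
    x = scores["grazing_proportion"].to_numpy(float)
    y = scores[value_col].to_numpy(float)
    n = len(x)
    if n < 3:
        raise DataError(f"regression needs at least 3 sites, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise DataError("grazing proportions are all equal; slope undefined")
    syy = float(np.sum((y - y.mean()) ** 2))
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    r_squared = 0.0 if syy == 0.0 else (sxy * sxy) / (sxx * syy)
    df1, df2 = 1, n - 2
    if r_squared >= 1.0:
        F, p = math.inf, 0.0
    else:
        F = (r_squared / df1) / ((1.0 - r_squared) / df2)
        p = f_sf(F, df1, df2)
    return RegressionResult(slope, intercept, r_squared, float(F), df1, df2, p, n)


def diagnose_report(
    nutrient_result: RegressionResult,
    sediment_result: RegressionResult,
    alpha: float = 0.05,
) -> dict:
    """Composite verdict: which stressor pathway tracks the grazing gradient.

    Purely presentational — no new statistics beyond the two regressions.
    """
    nut_sig = nutrient_result.p < alpha
    sed_sig = sediment_result.p < alpha
    if nut_sig and sed_sig:
        verdict = "both"
    elif sed_sig:
        verdict = "sediment-mediated"
    elif nut_sig:
        verdict = "nutrient-mediated"
    else:
        verdict = "neither"
    return {
        "alpha": alpha,
        "verdict": verdict,
        "nutrient": {
            **nutrient_result.to_dict(),
            "significant": bool(nut_sig),
            "slope_sign": int(np.sign(nutrient_result.slope)),
        },
        "sediment": {
            **sediment_result.to_dict(),
            "significant": bool(sed_sig),
            "slope_sign": int(np.sign(sediment_result.slope)),
        },
    }


def plot_scores(scores: pd.DataFrame, result: RegressionResult, path) -> None:
    """Scatter of site scores vs grazing with the fitted line (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(
        scores["grazing_proportion"], scores["score"], yerr=scores["score_sd"],
        fmt="o", mfc="white", mec="k", ecolor="grey", capsize=2,
    )
    xs = np.linspace(scores["grazing_proportion"].min(), scores["grazing_proportion"].max(), 50)
    ax.plot(xs, result.intercept + result.slope * xs, "k-")
    target = scores["target"].iloc[0] if len(scores) else ""
    ax.set_xlabel("proportion of catchment under grazing")
    ax.set_ylabel(f"predicted {target} level (1 = low, 2 = high)")
    ax.set_title(f"R$^2$ = {result.r_squared:.2f}, p = {result.p:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
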