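"""Evaluation statistics for network-scale biotic-index predictions.

Three checks, mirroring how space-filling eDNA-based assessments are
judged against point observations:

* per-taxon confusion counts (TP/FP/TN/FN) of model-predicted presence
  against kick-net presence at matched sites, and their unweighted mean
  accuracy across taxa;
* an ordinary least-squares regression of the *measured* (kick-net)
  index on the *predicted* (eDNA-based) index at matched sites, with
  95% confidence intervals, the regression F-test, and the two
  hypothesis checks of interest (slope CI covering 1, intercept CI
  covering 0);
* the association between the predicted index and an ordinal river
  habitat-status class over all classified reaches: a column-normalised
  two-dimensional histogram plus an OLS fit with a 95% mean-response
  confidence band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ConfusionRecord",
    "RegressionSummary",
    "HabitatAssociation",
    "confusion_per_taxon",
    "mean_accuracy",
    "regress_measured_on_predicted",
    "habitat_association",
]


@dataclass(frozen=True)
class ConfusionRecord:
    taxon: str
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def n_sites(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @property
    def accuracy(self) -> float:
        return (self.TP + self.TN) / self.n_sites


@dataclass(frozen=True)
class RegressionSummary:
    slope: float
    intercept: float
    slope_ci95: float  # half-width
    intercept_ci95: float  # half-width
    r2: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    slope_ci_covers_one: bool
    intercept_ci_covers_zero: bool

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("slope", "intercept", "slope_ci95", "intercept_ci95",
              "r2", "f_stat", "p_value")}
        d["df"] = list(self.df)
        d["slope_ci_covers_one"] = bool(self.slope_ci_covers_one)
        d["intercept_ci_covers_zero"] = bool(self.intercept_ci_covers_zero)
        return d


@dataclass
class HabitatAssociation:
    histogram: pd.DataFrame  # rows = index value 0..20, cols = habitat class
    r2: float
    slope: float
    intercept: float
    band: pd.DataFrame  # columns: habitat, mean, lower, upper (95% mean response)
    n: int


def confusion_per_taxon(pred: pd.DataFrame, obs: pd.DataFrame
                        ) -> list[ConfusionRecord]:
    """Per-taxon confusion counts at matched units.

    ``pred`` and ``obs`` are unit × taxon boolean frames over identical
    unit and taxon sets (matching of eDNA-predicted reaches to kick-net
    sites happens upstream via the site map).
    """
    unmatched = set(pred.index) ^ set(obs.index)
    if unmatched:
        raise ValueError(f"unmatched unit(s): {sorted(map(str, unmatched))[:10]}")
    if set(pred.columns) != set(obs.columns):
        raise ValueError("taxon sets differ between predictions and observations")
    obs = obs.loc[pred.index, pred.columns]
    records = []
    for taxon in pred.columns:
        p = pred[taxon].to_numpy(dtype=bool)
        o = obs[taxon].to_numpy(dtype=bool)
        records.append(ConfusionRecord(
            taxon=str(taxon),
            TP=int((p & o).sum()), FP=int((p & ~o).sum()),
            TN=int((~p & ~o).sum()), FN=int((~p & o).sum())))
    return records


def confusion_frame(records: list[ConfusionRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "taxon": r.taxon, "TP": r.TP, "FP": r.FP, "TN": r.TN, "FN": r.FN,
        "accuracy": r.accuracy} for r in records])


def mean_accuracy(records: list[ConfusionRecord]) -> float:
    """Unweighted mean per-taxon accuracy, in percent."""
    if not records:
        raise ValueError("no confusion records")
    return 100.0 * float(np.mean([r.accuracy for r in records]))


def regress_measured_on_predicted(predicted: np.ndarray, measured: np.ndarray,
                                  direction: str = "measured_on_predicted"
                                  ) -> RegressionSummary:
    """OLS of measured index on predicted index (or the reverse).

    95% CIs use the t distribution with n−2 df; the F statistic tests
    the regression against the intercept-only model.
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(measured, dtype=float)
    if direction == "predicted_on_measured":
        x, y = y, x
    elif direction != "measured_on_predicted":
        raise ValueError(f"unknown direction {direction!r}")
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 matched pairs")
    if np.var(x) == 0:
        raise ValueError("degenerate regression: predictor has zero variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=0.05)
    intercept, slope = res.params
    r2 = float(res.rsquared)
    if np.var(y) == 0:  # no explainable variance
        r2 = 0.0
    int_hw = (ci[0, 1] - ci[0, 0]) / 2
    slope_hw = (ci[1, 1] - ci[1, 0]) / 2
    return RegressionSummary(
        slope=float(slope), intercept=float(intercept),
        slope_ci95=float(slope_hw), intercept_ci95=float(int_hw),
        r2=r2, f_stat=float(res.fvalue),
        df=(int(res.df_model), int(res.df_resid)),
        p_value=float(res.f_pvalue),
        slope_ci_covers_one=bool(abs(slope - 1.0) <= slope_hw),
        intercept_ci_covers_zero=bool(abs(intercept) <= int_hw))


def habitat_association(scores: pd.Series, habitat: pd.Series,
                        max_score: int = 20) -> HabitatAssociation:
    """Predicted-index vs habitat-class association over classified reaches.

    ``scores`` and ``habitat`` are indexed by reach id; only reaches
    present in both enter.  Habitat classes must carry an ordinal coding
    (1..K, worst → best).  The histogram is normalised within each
    habitat class; the confidence band is the 95% mean-response band of
    the OLS fit of score on class code.
    """
    common = scores.index.intersection(habitat.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 reaches with both score and habitat class")
    s = scores.loc[common].to_numpy(dtype=float)
    h = habitat.loc[common].to_numpy(dtype=float)

    classes = np.unique(h)
    hist = pd.DataFrame(0.0, index=pd.RangeIndex(0, max_score + 1, name="ibch"),
                        columns=pd.Index(classes.astype(int), name="habitat_class"))
    for c in classes:
        vals = s[h == c].astype(int)
        counts = np.bincount(vals, minlength=max_score + 1)[:max_score + 1]
        hist[int(c)] = counts / counts.sum()

    if len(classes) == 1:  # degenerate: no gradient to regress on
        mean = float(s.mean())
        band = pd.DataFrame({"habitat": classes.astype(float), "mean": [mean],
                             "lower": [mean], "upper": [mean]})
        return HabitatAssociation(histogram=hist, r2=0.0, slope=0.0,
                                  intercept=mean, band=band,
                                  n=int(len(common)))
    res = sm.OLS(s, sm.add_constant(h)).fit()
    grid = np.linspace(classes.min(), classes.max(), 50)
    pred = res.get_prediction(sm.add_constant(grid)).summary_frame(alpha=0.05)
    band = pd.DataFrame({
        "habitat": grid, "mean": pred["mean"].to_numpy(),
        "lower": pred["mean_ci_lower"].to_numpy(),
        "upper": pred["mean_ci_upper"].to_numpy()})
    return HabitatAssociation(
        histogram=hist, r2=float(res.rsquared),
        slope=float(res.params[1]), intercept=float(res.params[0]),
        band=band, n=int(len(common)))
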