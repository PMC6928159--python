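"""Group-level statistics: cohort t-tests with FDR control and the
correlation analyses validating the recovery model.

The experimental unit for the t-tests is the animal: slice means are first
averaged per animal so repeated slices from one nerve do not
pseudo-replicate.  All raw p-values of a test family are adjusted together
by the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "pairwise_ttests",
    "bh_adjust",
    "pearson",
    "correlate_probability_behavior",
    "correlate_scalars_histology",
]


@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"|r| > 1: {self.r}")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sort ascending; adjusted_(i) = min_{j >= i} p_(j) * m / j, capped at 1,
    mapped back to the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def pearson(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Sample Pearson correlation with the two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("need at least 3 pairs for a defined p-value")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero variance input")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(x_name, y_name, float(r), float(p), int(x.size))


def _animal_means(records: pd.DataFrame, parameter: str) -> pd.DataFrame:
    return (
        records.groupby(["animal_id", "cohort", "week"], as_index=False)[parameter]
        .mean()
    )


def pairwise_ttests(
    records: pd.DataFrame,
    parameters: list[str],
    region: str | None = "distal",
    equal_var: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-timepoint pairwise cohort comparisons for each scalar index.

    Welch's unpaired two-sample t-test by default (``equal_var=True`` for
    the pooled-variance variant).  Slice records are reduced to one mean
    per animal before testing; pairs where a cohort has fewer than two
    animals are skipped.  The whole family (parameters x timepoints x
    cohort pairs) is BH-adjusted together.
    """
    subset = records if region is None else records[records["region"] == region]
    rows = []
    for parameter in parameters:
        means = _animal_means(subset, parameter)
        for week in sorted(means["week"].unique()):
            at_week = means[means["week"] == week]
            cohorts = sorted(at_week["cohort"].unique())
            for a, b in combinations(cohorts, 2):
                xa = at_week.loc[at_week["cohort"] == a, parameter].to_numpy()
                xb = at_week.loc[at_week["cohort"] == b, parameter].to_numpy()
                if xa.size < 2 or xb.size < 2:
                    continue  # logged by caller context; nothing to test
                if np.var(xa) == 0 and np.var(xb) == 0:
                    # degenerate: no within-group variance
                    equal_means = np.mean(xa) == np.mean(xb)
                    t = 0.0 if equal_means else np.inf * np.sign(
                        np.mean(xa) - np.mean(xb)
                    )
                    p = 1.0 if equal_means else 0.0
                else:
                    t, p = sps.ttest_ind(xa, xb, equal_var=equal_var)
                rows.append({
                    "parameter": parameter, "week": week,
                    "cohort_a": a, "cohort_b": b,
                    "n_a": xa.size, "n_b": xb.size,
                    "t": float(t), "p_raw": float(p),
                })
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adjusted"] = bh_adjust(table["p_raw"].to_numpy())
        table["significant"] = table["p_adjusted"] < alpha
    return table


def correlate_probability_behavior(
    nerve_summary: pd.DataFrame,
    behavior: pd.DataFrame,
    week: int = 12,
) -> dict[str, CorrelationResult]:
    """Correlate per-nerve mean distal recovery probabilities with endpoint
    behavioral recovery at the given week (crush and cut/repair nerves).

    Both behavioral axes are put on a "larger = better recovered" scale:
    SFI is already oriented that way (0 normal, strongly negative after
    injury); the foot-fault asymmetry score is flipped to 1 - FF so that
    positive correlations mean the model tracks recovery on both axes.
    """
    nerves = nerve_summary[
        (nerve_summary["week"] == week)
        & nerve_summary["cohort"].isin(["crush", "cut_repair"])
        & nerve_summary["assessable"]
    ]
    endpoint = behavior[behavior["week"] == behavior["endpoint_week"]]
    merged = nerves.merge(
        endpoint[["animal_id", "sfi", "ff"]], on="animal_id", how="inner"
    )
    if len(merged) == 0:
        raise ValueError(f"no nerves with both probabilities and week-{week} behavior")
    prob = merged["mean_probability"].to_numpy(float)
    return {
        "sfi": pearson(prob, merged["sfi"].to_numpy(float),
                       "mean_probability", "sfi"),
        "ff": pearson(prob, 1.0 - merged["ff"].to_numpy(float),
                      "mean_probability", "ff_recovery"),
    }


SCALARS_VS_HISTOLOGY = ("rd", "ad", "rk", "ak", "rd_ad", "fa")


def correlate_scalars_histology(
    records: pd.DataFrame,
    histology: pd.DataFrame,
    apply_outlier_filter: bool = True,
) -> dict[str, CorrelationResult]:
    """Correlate distal per-animal scalar means with axon density.

    Indices: RD, AD, RK, AK, the RD/AD ratio and FA.  The slice outlier
    rules are applied first (the published analysis excludes RD > 1,
    RK outside (0, 2) before correlating).
    """
    from .slicewise import filter_outliers

    distal = records[records["region"] == "distal"]
    if apply_outlier_filter:
        distal, _ = filter_outliers(distal)
    distal = distal.copy()
    distal["rd_ad"] = distal["rd"] / distal["ad"]
    means = distal.groupby("animal_id", as_index=False)[
        list(SCALARS_VS_HISTOLOGY)
    ].mean()
    merged = means.merge(
        histology[["animal_id", "axon_density"]], on="animal_id", how="inner"
    )
    if len(merged) < 3:
        raise ValueError("fewer than 3 animals with matched histology")
    density = merged["axon_density"].to_numpy(float)
    return {
        name: pearson(merged[name].to_numpy(float), density, name, "axon_density")
        for name in SCALARS_VS_HISTOLOGY
    }
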