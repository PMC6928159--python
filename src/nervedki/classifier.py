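"""Linear recovery classifier in the RD-vs-AD plane.

A soft-margin linear SVM (large cost, unscaled physical units) is trained
on week-4 distal slice means — crush nerves labeled recovered, cut/repair
labeled non-recovered — yielding a decision line RD = slope*AD + intercept.
Bootstrap resampling quantifies the boundary uncertainty, the slope is
converted to an equivalent FA threshold under cylindrical symmetry, and
calibrated recovery probabilities come from a Platt sigmoid fit with
smoothed targets, which stays well-posed on fully separable training data
(where plain logistic regression degenerates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .dki import fa_from_ratio

__all__ = [
    "LinearBoundary",
    "PlattModel",
    "fit_boundary",
    "bootstrap_boundary",
    "fit_platt",
    "recovery_probability",
    "fa_threshold",
    "classify_study",
]

RECOVERED = "recovered"
NON_RECOVERED = "non_recovered"


@dataclass
class LinearBoundary:
    """Decision line in the (AD, RD) plane.

    ``w`` and ``offset`` define the signed decision value
    f(x) = w . (AD, RD) + offset with the sign convention f > 0 <=>
    recovered side; records with RD < slope*AD + intercept are recovered.
    """

    slope: float
    intercept: float
    w: np.ndarray  # (w_AD, w_RD)
    offset: float
    cost: float = 1e6
    slope_sd: float | None = None
    intercept_sd: float | None = None

    def decision_value(self, ad, rd):
        return self.w[0] * np.asarray(ad) + self.w[1] * np.asarray(rd) + self.offset


@dataclass
class PlattModel:
    """Sigmoid map from decision values to recovery probabilities:
    P(recovered | f) = 1 / (1 + exp(A f + B)), with A < 0 so probability
    increases with f."""

    A: float
    B: float
    n_iter: int = 0

    def probability(self, f):
        from scipy.special import expit

        z = self.A * np.asarray(f, dtype=float) + self.B
        return expit(-z)


def _as_binary(labels) -> np.ndarray:
    y = np.asarray([1 if lab in (RECOVERED, 1, True) else 0 for lab in labels])
    if len(np.unique(y)) < 2:
        raise ValueError(
            "cannot define boundary: training data contain a single class"
        )
    return y


def fit_boundary(points, labels, cost: float = 1e6) -> LinearBoundary:
    """Fit the linear SVM boundary on (AD, RD) points.

    Features are left in physical units (um^2/ms) so the reported slope and
    intercept are physically interpretable; the large default cost makes
    the soft-margin fit approximate the maximum-margin separator on
    separable data.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("points must be (n, 2): columns AD, RD")
    y = _as_binary(labels)
    clf = SVC(kernel="linear", C=cost, tol=1e-6)
    clf.fit(X, y)
    w = clf.coef_[0].copy()
    b = float(clf.intercept_[0])
    if abs(w[1]) < 1e-12 * np.linalg.norm(w):
        raise ValueError("degenerate boundary: vertical in the RD-vs-AD plane")
    # sklearn already orients the decision function positive toward y=1
    # (recovered); keep that convention.
    slope = -w[0] / w[1]
    intercept = -b / w[1]
    return LinearBoundary(
        slope=float(slope), intercept=float(intercept), w=w, offset=b, cost=cost
    )


def bootstrap_boundary(
    points, labels, n_boot: int = 1000, seed: int = 0, cost: float = 1e6
) -> tuple[float, float, pd.DataFrame]:
    """Stratified bootstrap of the boundary: resample with replacement
    within each class, refit, and return (slope SD, intercept SD, samples).

    Stratification guarantees both classes appear in every resample.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    X = np.asarray(points, dtype=float)
    y = _as_binary(labels)
    idx_pos = np.nonzero(y == 1)[0]
    idx_neg = np.nonzero(y == 0)[0]
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_boot):
        take = np.concatenate([
            rng.choice(idx_pos, size=idx_pos.size, replace=True),
            rng.choice(idx_neg, size=idx_neg.size, replace=True),
        ])
        try:
            bd = fit_boundary(X[take], y[take], cost=cost)
        except ValueError:
            continue  # degenerate resample (e.g. all points identical)
        rows.append({"replicate": i, "slope": bd.slope, "intercept": bd.intercept})
    samples = pd.DataFrame(rows)
    return (
        float(samples["slope"].std(ddof=1)),
        float(samples["intercept"].std(ddof=1)),
        samples,
    )


def _platt_objective(z: np.ndarray, t: np.ndarray) -> float:
    # stable cross-entropy with targets t against p = 1/(1+exp(z))
    out = np.where(z >= 0, t * z + np.log1p(np.exp(-z)),
                   (t - 1.0) * z + np.log1p(np.exp(z)))
    return float(np.sum(out))


def fit_platt(decision_values, labels, max_iter: int = 100,
              tol: float = 1e-12) -> PlattModel:
    """Platt sigmoid calibration with smoothed targets.

    Maximizes the Bernoulli likelihood of targets
    t+ = (N+ + 1)/(N+ + 2) and t- = 1/(N- + 2) under
    P(recovered | f) = 1/(1 + exp(A f + B)) by Newton iteration with
    backtracking line search.  The smoothed targets keep the optimum finite
    on perfectly separable decision values, where an unsmoothed logistic
    fit would diverge.
    """
    f = np.asarray(decision_values, dtype=float)
    y = _as_binary(labels)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))
    A = 0.0
    B = np.log((n_neg + 1.0) / (n_pos + 1.0))
    z = A * f + B
    obj = _platt_objective(z, t)
    it = 0
    for it in range(1, max_iter + 1):
        p = 1.0 / (1.0 + np.exp(z))
        d = t - p  # dF/dz
        g = np.array([np.sum(d * f), np.sum(d)])
        if np.max(np.abs(g)) < 1e-10:
            break
        h = p * (1.0 - p)
        H = np.array([
            [np.sum(h * f * f) + 1e-12, np.sum(h * f)],
            [np.sum(h * f), np.sum(h) + 1e-12],
        ])
        step = np.linalg.solve(H, -g)
        # backtracking line search on the objective
        stepsize = 1.0
        for _ in range(64):
            A_new, B_new = A + stepsize * step[0], B + stepsize * step[1]
            z_new = A_new * f + B_new
            obj_new = _platt_objective(z_new, t)
            if obj_new < obj + 1e-4 * stepsize * (g @ step):
                break
            stepsize /= 2.0
        else:
            if np.max(np.abs(g)) < 1e-6:
                break  # at the optimum to machine precision
            raise RuntimeError(
                f"Platt fit line search failed at iteration {it}: "
                f"gradient {g}, objective {obj:.6g}"
            )
        A, B, z, obj = A_new, B_new, z_new, obj_new
    else:
        raise RuntimeError(
            f"Platt fit did not converge in {max_iter} iterations "
            f"(final gradient norm {np.max(np.abs(g)):.3g})"
        )
    return PlattModel(A=float(A), B=float(B), n_iter=it)


def recovery_probability(
    record, boundary: LinearBoundary, platt: PlattModel
) -> dict:
    """Assess one slice record: signed decision value, calibrated recovery
    probability, and side label (f > 0 => recovered; f = 0 resolved by
    probability >= 0.5)."""
    try:
        ad, rd = float(record["ad"]), float(record["rd"])
    except (KeyError, TypeError) as err:
        raise KeyError("record needs 'ad' and 'rd' fields") from err
    if not (np.isfinite(ad) and np.isfinite(rd)):
        raise ValueError("record has non-finite AD/RD")
    f = float(boundary.decision_value(ad, rd))
    p = float(platt.probability(f))
    if f > 0:
        side = RECOVERED
    elif f < 0:
        side = NON_RECOVERED
    else:
        side = RECOVERED if p >= 0.5 else NON_RECOVERED
    return {"decision_value": f, "probability": p, "side": side}


def fa_threshold(
    boundary: LinearBoundary, bootstrap_samples: pd.DataFrame | None = None
) -> tuple[float, float | None]:
    """Equivalent FA threshold of the boundary slope.

    Uses the zero-offset reduction: a line RD = slope*AD through the origin
    is a pure RD/AD ratio, which maps to a unique FA under cylindrical
    symmetry.  The fitted intercept is deliberately ignored (and is small
    in practice); the SD propagates fa_from_ratio over bootstrap slopes.
    """
    if boundary.slope < 0:
        raise ValueError("negative slope: FA threshold undefined")
    thr = fa_from_ratio(boundary.slope)
    sd = None
    if bootstrap_samples is not None and len(bootstrap_samples):
        slopes = bootstrap_samples["slope"].to_numpy(dtype=float)
        valid = slopes >= 0
        if valid.sum() >= 2:
            sd = float(np.std(fa_from_ratio(slopes[valid]), ddof=1))
    return float(thr), sd


def classify_study(
    records: pd.DataFrame,
    boundary: LinearBoundary,
    platt: PlattModel,
    call_threshold: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assess every slice record and summarize per nerve.

    The per-nerve summary covers distal slices only: mean recovery
    probability, fraction of slices on the recovered side, and a binary
    call (mean probability > ``call_threshold``).  Nerves without distal
    records are marked not assessable (NaN summary, ``assessable=False``).
    """
    if len(records) == 0:
        return records.copy(), pd.DataFrame(
            columns=["animal_id", "cohort", "week", "mean_probability",
                     "recovered_fraction", "recovered_call", "assessable"]
        )
    out = records.copy()
    f = boundary.decision_value(
        records["ad"].to_numpy(float), records["rd"].to_numpy(float)
    )
    out["decision_value"] = f
    out["probability"] = platt.probability(f)
    out["side"] = np.where(
        f > 0, RECOVERED,
        np.where(f < 0, NON_RECOVERED,
                 np.where(out["probability"] >= 0.5, RECOVERED, NON_RECOVERED)),
    )
    summaries = []
    for (animal, cohort, week), grp in out.groupby(
        ["animal_id", "cohort", "week"], sort=True
    ):
        distal = grp[grp["region"] == "distal"]
        if len(distal) == 0:
            summaries.append({
                "animal_id": animal, "cohort": cohort, "week": week,
                "mean_probability": np.nan, "recovered_fraction": np.nan,
                "recovered_call": False, "assessable": False,
            })
            continue
        mean_p = float(distal["probability"].mean())
        summaries.append({
            "animal_id": animal, "cohort": cohort, "week": week,
            "mean_probability": mean_p,
            "recovered_fraction": float(
                (distal["side"] == RECOVERED).mean()
            ),
            "recovered_call": bool(mean_p > call_threshold),
            "assessable": True,
        })
    return out, pd.DataFrame(summaries)


def train_from_records(
    records: pd.DataFrame,
    cost: float = 1e6,
    n_boot: int = 1000,
    seed: int = 0,
    week: int = 4,
) -> tuple[LinearBoundary, PlattModel, pd.DataFrame]:
    """Train boundary + calibration the way the study design prescribes:
    distal slices at the given week, crush = recovered vs cut/repair =
    non-recovered.  Returns (boundary with bootstrap SDs, Platt model,
    bootstrap samples)."""
    train = records[
        (records["region"] == "distal")
        & (records["week"] == week)
        & (records["cohort"].isin(["crush", "cut_repair"]))
    ]
    if len(train) == 0:
        raise ValueError(f"no distal training records at week {week}")
    X = train[["ad", "rd"]].to_numpy(float)
    y = [RECOVERED if c == "crush" else NON_RECOVERED for c in train["cohort"]]
    boundary = fit_boundary(X, y, cost=cost)
    slope_sd, intercept_sd, samples = bootstrap_boundary(
        X, y, n_boot=n_boot, seed=seed, cost=cost
    )
    boundary.slope_sd = slope_sd
    boundary.intercept_sd = intercept_sd
    platt = fit_platt(boundary.decision_value(X[:, 0], X[:, 1]), y)
    return boundary, platt, samples
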