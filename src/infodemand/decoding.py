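"""Decoding sampling efficiency from personality/demographic predictors.

A linear classifier (SVM by default, logistic as a replication) is trained
to predict whether a participant's behavioral summary lies above or below
the cohort median, from 15 standardized questionnaire scores plus 3
demographic codes.  Performance is summarized as *excess accuracy*: per
bootstrap iteration the classifier is trained on a random half, tested on
the other half, and the same split is refit with shuffled training labels;
excess = accuracy(true) - accuracy(shuffled), in percentage points.
Predictors are standardized on the training half only.  Coefficient means
and 95% percentile intervals over iterations give per-trait effect sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PREDICTOR_COLUMNS


@dataclass(frozen=True)
class DecodingResult:
    method: str
    target: str
    n_participants: int
    n_boot: int
    excess_mean: float                  # percentage points
    excess_ci: tuple[float, float]
    excess_per_iteration: np.ndarray
    coefficients: pd.DataFrame          # per predictor: mean, ci_lo, ci_hi, significant
    class_balance: float                # fraction labeled "high" after the median split

    @property
    def excess_significant(self) -> bool:
        lo, hi = self.excess_ci
        return not (lo <= 0.0 <= hi)


def median_split(values: np.ndarray) -> np.ndarray:
    """High/low labels: strictly above the median -> high (deterministic ties)."""
    values = np.asarray(values, dtype=float)
    return (values > np.median(values)).astype(int)


def _make_classifier(method: str):
    from sklearn.linear_model import LogisticRegression
    from sklearn.svm import SVC

    if method == "svm_linear":
        return SVC(kernel="linear", C=1.0)
    if method == "logistic":
        return LogisticRegression(C=1.0, max_iter=1000)
    raise ValueError("method must be 'svm_linear' or 'logistic'")


def decode(profiles: pd.DataFrame, target: pd.Series, *, target_name: str = "target",
           method: str = "svm_linear", n_boot: int = 100,
           rng: np.random.Generator | None = None,
           predictors: tuple[str, ...] = PREDICTOR_COLUMNS) -> DecodingResult:
    """Bootstrap decoding of a median-split behavioral target.

    ``profiles`` must contain ``participant_id`` and the predictor columns;
    ``target`` is a continuous per-participant summary indexed by
    participant id.  Participants with missing predictors or target are
    dropped (logged via a warning).
    """
    if rng is None:
        rng = np.random.default_rng()
    data = profiles.set_index("participant_id")[list(predictors)].join(
        target.rename("_target"), how="inner")
    n_before = len(data)
    data = data.dropna()
    if len(data) < n_before:
        warnings.warn(f"dropped {n_before - len(data)} participants with missing values",
                      RuntimeWarning, stacklevel=2)
    if len(data) < 50:
        raise ValueError(f"need >= 50 complete participants, have {len(data)}")
    y_cont = data["_target"].to_numpy(float)
    if np.ptp(y_cont) == 0:
        raise ValueError("constant behavioral target; median split undefined")
    X = data[list(predictors)].to_numpy(float)
    y = median_split(y_cont)
    if y.min() == y.max():
        raise ValueError("median split produced a single class")
    n = len(y)
    n_train = n // 2
    excess = np.empty(n_boot)
    coefs = np.empty((n_boot, X.shape[1]))
    clf = _make_classifier(method)
    for it in range(n_boot):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr, Xte = (X[tr] - mu) / sd, (X[te] - mu) / sd
        ytr = y[tr]
        if ytr.min() == ytr.max():  # degenerate split; rare, resample
            excess[it] = 0.0
            coefs[it] = 0.0
            continue
        clf.fit(Xtr, ytr)
        acc_true = float(np.mean(clf.predict(Xte) == y[te]))
        coefs[it] = np.ravel(clf.coef_)
        y_shuf = rng.permutation(ytr)
        if y_shuf.min() == y_shuf.max():
            acc_shuf = float(np.mean(np.full_like(y[te], y_shuf[0]) == y[te]))
        else:
            clf.fit(Xtr, y_shuf)
            acc_shuf = float(np.mean(clf.predict(Xte) == y[te]))
        excess[it] = 100.0 * (acc_true - acc_shuf)
    ci = (float(np.percentile(excess, 2.5)), float(np.percentile(excess, 97.5)))
    coef_tab = pd.DataFrame({
        "predictor": list(predictors),
        "mean": coefs.mean(axis=0),
        "ci_lo": np.percentile(coefs, 2.5, axis=0),
        "ci_hi": np.percentile(coefs, 97.5, axis=0),
    })
    coef_tab["significant"] = ~((coef_tab["ci_lo"] <= 0) & (coef_tab["ci_hi"] >= 0))
    return DecodingResult(method=method, target=target_name, n_participants=n,
                          n_boot=n_boot, excess_mean=float(excess.mean()),
                          excess_ci=ci, excess_per_iteration=excess,
                          coefficients=coef_tab, class_balance=float(y.mean()))


def pooled_parameters(fits: pd.DataFrame, block: str = "Observe1") -> pd.DataFrame:
    """Pool uncertainty sensitivity across models for one block.

    EV-sensitive participants contribute (a, b); EV-insensitive ones
    contribute c as the uncertainty parameter with the EV slope set to 0.
    """
    sel = fits[fits["block"] == block].set_index("participant_id")
    ev_sensitive = sel["label"] == "EV_sensitive"
    return pd.DataFrame({
        "uncertainty_param": np.where(ev_sensitive, sel["a"], sel["c"]),
        "ev_param": np.where(ev_sensitive, sel["b"], 0.0),
        "label": sel["label"],
    }, index=sel.index)


def variance_explained(profiles: pd.DataFrame, targets: dict[str, pd.Series],
                       predictors: tuple[str, ...] = PREDICTOR_COLUMNS,
                       scores: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Leave-one-score-out R-squared attribution.

    For every target: R2 of a linear regression on all predictors minus R2
    of the same regression without the score of interest, per score.
    """
    from sklearn.linear_model import LinearRegression

    if scores is None:
        scores = predictors
    rows = []
    base = profiles.set_index("participant_id")
    for name, target in targets.items():
        data = base[list(predictors)].join(target.rename("_y"), how="inner").dropna()
        X = data[list(predictors)].to_numpy(float)
        y = data["_y"].to_numpy(float)
        full_r2 = LinearRegression().fit(X, y).score(X, y)
        for sc in scores:
            keep = [p for p in predictors if p != sc]
            Xr = data[keep].to_numpy(float)
            r2 = LinearRegression().fit(Xr, y).score(Xr, y)
            rows.append({"target": name, "score": sc, "full_r2": full_r2,
                         "delta_r2": full_r2 - r2})
    return pd.DataFrame(rows)


def quartile_strategy_table(profiles: pd.DataFrame, fits: pd.DataFrame,
                            order: pd.Series | dict,
                            score: str = "big5_extraversion") -> dict:
    """Strategy membership by quartile of a personality score.

    Participants are grouped by whether both instrumental blocks were
    Uncertainty-only ("efficient") or both EV-sensitive/Random
    ("inefficient"); mixed patterns are excluded.  Returns, per score
    quartile, the percentage of its members in each group, plus a monotone
    trend test (Spearman of quartile index vs efficient membership).
    """
    labels = fits[fits["block"].isin(("Estimate", "Intervene"))].pivot(
        index="participant_id", columns="block", values="label")
    scores = profiles.set_index("participant_id")[score].dropna()
    common = labels.index.intersection(scores.index)
    if len(common) < 8:
        raise ValueError(f"need >= 8 participants with labels and scores, have {len(common)}")
    labels, scores = labels.loc[common], scores.loc[common]
    unc = "Uncertainty_only"
    efficient = (labels["Estimate"] == unc) & (labels["Intervene"] == unc)
    inefficient = (labels["Estimate"].isin(("EV_sensitive", "Random"))
                   & labels["Intervene"].isin(("EV_sensitive", "Random")))
    quart = pd.qcut(scores.rank(method="first"), 4, labels=False)
    table = {}
    for q in range(4):
        members = quart == q
        nq = int(members.sum())
        table[f"q{q + 1}"] = {
            "n": nq,
            "pct_efficient": 100.0 * float(efficient[members].mean()) if nq else np.nan,
            "pct_inefficient": 100.0 * float(inefficient[members].mean()) if nq else np.nan,
            "empty": nq == 0,
        }
    both = efficient | inefficient
    if efficient[both].nunique() > 1 and both.sum() >= 8:
        rho, p = stats.spearmanr(quart[both], efficient[both].astype(int))
        trend = {"spearman_r": float(rho), "p": float(p)}
    else:
        trend = {"spearman_r": np.nan, "p": np.nan}
    return {"score": score, "quartiles": table, "trend": trend,
            "n_efficient": int(efficient.sum()), "n_inefficient": int(inefficient.sum())}
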