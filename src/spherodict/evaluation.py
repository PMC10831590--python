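"""Descriptive and model-based comparison of tagging schemes.

Covers four layers:

* share tables — how many visits each topic tags before and after spherical
  enhancement, with percent increases;
* agreement — phi correlation between the two binary indicator schemes and
  *consistency*, the share of structured lead-symptom (LS) tags that the
  free-text NLP tags also capture;
* association — linear probability models (OLS on a binary outcome, with
  coefficients read as probability differences):

  .. math::

      \\text{Model 1: } Y_i = \\alpha + \\beta X_i + \\gamma Z_i + \\varepsilon_i

      \\text{Model 2: } Y_i = \\alpha + \\beta X_i + \\delta W_i + \\varepsilon_i

      \\text{Model 3: } Y_i = \\alpha + \\beta X_i + \\gamma Z_i
                             + \\delta W_i + \\varepsilon_i

  where :math:`X_i` are demographic/organisational covariates, :math:`Z_i`
  the NLP cluster indicators and :math:`W_i` the LS cluster indicators;
* prediction — seeded 2:1 train-test logistic regression reporting F1 on the
  positive class and AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import train_test_split

#: Covariate columns picked up from the visit table when present.
NUMERIC_COVARIATES = ("age", "ed_census", "waiting_time")
BINARY_COVARIATES = ("female", "ems", "police", "accident", "night", "late")
CATEGORICAL_COVARIATES = ("team",)


# ---------------------------------------------------------------------------
# share tables


def percent_increase(initial: int, enhanced: int) -> float | None:
    """Relative growth of a tag count, in percent of the initial count.

    ``(enhanced - initial) / initial * 100`` rounded to 2 decimals; negative
    when the count fell (the no-tag row shrinks under enhancement).  An
    initial count of zero has no defined increase: returns None.
    """
    if initial < 0 or enhanced < 0:
        raise ValueError("counts must be non-negative")
    if initial == 0:
        return None
    return round((enhanced - initial) / initial * 100.0, 2)


def topic_share_table(
    tags_initial: pd.DataFrame, tags_enhanced: pd.DataFrame, n: int | None = None
) -> pd.DataFrame:
    """Per-label tag counts and shares before/after dictionary enhancement.

    Adds a ``No tag`` row counting visits with all-zero indicator rows in
    each matrix.  Shares are percentages of the sample size ``n`` (defaults
    to the number of visits).
    """
    if list(tags_initial.index) != list(tags_enhanced.index):
        raise ValueError("tag matrices cover different visit ids")
    if list(tags_initial.columns) != list(tags_enhanced.columns):
        raise ValueError("tag matrices carry different labels")
    if n is None:
        n = len(tags_initial)

    rows = []
    for label in tags_initial.columns:
        i0 = int(tags_initial[label].sum())
        i1 = int(tags_enhanced[label].sum())
        rows.append((label, i0, i1))
    rows.append(
        (
            "No tag",
            int((tags_initial.sum(axis=1) == 0).sum()),
            int((tags_enhanced.sum(axis=1) == 0).sum()),
        )
    )
    out = pd.DataFrame(rows, columns=["label", "initial_count", "enhanced_count"])
    out["initial_share_pct"] = (out["initial_count"] / n * 100).round(2)
    out["enhanced_share_pct"] = (out["enhanced_count"] / n * 100).round(2)
    out["increase_n"] = out["enhanced_count"] - out["initial_count"]
    out["increase_pct"] = [
        percent_increase(i, e)
        for i, e in zip(out["initial_count"], out["enhanced_count"])
    ]
    return out.set_index("label")


# ---------------------------------------------------------------------------
# agreement


def correlation(ls: np.ndarray, nlp: np.ndarray) -> float:
    """Pearson correlation of two binary indicators (the phi coefficient)."""
    ls = np.asarray(ls, dtype=float)
    nlp = np.asarray(nlp, dtype=float)
    if ls.shape != nlp.shape or ls.size < 2:
        raise ValueError("indicators must share a length of at least 2")
    if ls.std() == 0 or nlp.std() == 0:
        raise ValueError("correlation undefined: an indicator is constant")
    return float(stats.pearsonr(ls, nlp).statistic)


def consistency(ls: np.ndarray, nlp: np.ndarray) -> float | None:
    """Share of LS-tagged visits also tagged by the NLP scheme.

    ``|{i : ls_i = 1 and nlp_i = 1}| / sum(ls)`` — asymmetric on purpose:
    the structured lead symptom is the established benchmark, so it is the
    denominator.  Undefined (None) when no visit carries the LS tag.
    """
    ls = np.asarray(ls, dtype=int)
    nlp = np.asarray(nlp, dtype=int)
    if ls.shape != nlp.shape:
        raise ValueError("indicators must share a length")
    total = int(ls.sum())
    if total == 0:
        return None
    return float(((ls == 1) & (nlp == 1)).sum() / total)


# ---------------------------------------------------------------------------
# design matrices


def build_design(
    visits: pd.DataFrame,
    nlp: pd.DataFrame | None = None,
    ls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the regression design: intercept, covariates X, then Z and W.

    Binary covariates enter as-is; the categorical team enters as indicator
    columns with the alphabetically first level as reference; the shift
    enters via ``night`` and ``late`` with the early shift as reference.
    Cluster indicators get ``nlp:`` / ``ls:`` prefixes so the two schemes
    never collide.
    """
    parts = [pd.Series(1.0, index=visits.index, name="const")]
    for col in NUMERIC_COVARIATES:
        if col in visits.columns:
            parts.append(visits[col].astype(float))
    for col in BINARY_COVARIATES:
        if col in visits.columns:
            parts.append(visits[col].astype(float))
    for col in CATEGORICAL_COVARIATES:
        if col in visits.columns:
            dummies = pd.get_dummies(
                visits[col].astype(str), prefix=col, drop_first=True, dtype=float
            )
            parts.append(dummies)
    X = pd.concat(parts, axis=1)
    for prefix, tags in (("nlp", nlp), ("ls", ls)):
        if tags is not None:
            block = tags.reset_index(drop=True).astype(float)
            block.columns = [f"{prefix}:{c}" for c in block.columns]
            block.index = visits.index
            X = pd.concat([X, block], axis=1)
    return X


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        # pivoted QR points at the dependent columns
        from scipy.linalg import qr

        _, _, piv = qr(arr, mode="economic", pivoting=True)
        bad = sorted(X.columns[piv[rank:]])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


@dataclass
class ModelResult:
    """Fitted outcome model with the coefficient blocks kept addressable."""

    model_id: int
    estimator: str  # "lpm" | "logistic"
    outcome: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    r_squared: float
    resid: np.ndarray
    n: int

    @property
    def alpha(self) -> float:
        return float(self.params["const"])

    def gamma(self) -> pd.Series:
        """NLP-cluster coefficients."""
        return self.params[[c for c in self.params.index if c.startswith("nlp:")]]

    def delta(self) -> pd.Series:
        """LS-cluster coefficients."""
        return self.params[[c for c in self.params.index if c.startswith("ls:")]]

    def beta(self) -> pd.Series:
        """Covariate coefficients (everything except intercept and clusters)."""
        keep = [
            c
            for c in self.params.index
            if c != "const" and not c.startswith(("nlp:", "ls:"))
        ]
        return self.params[keep]

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params, "se": self.bse, "p": self.pvalues}
        )


def _design_for_model(visits, tags_nlp, tags_ls, model_id):
    if model_id == 1:
        return build_design(visits, nlp=tags_nlp)
    if model_id == 2:
        return build_design(visits, ls=tags_ls)
    if model_id == 3:
        return build_design(visits, nlp=tags_nlp, ls=tags_ls)
    raise ValueError(f"model id must be 1, 2 or 3, got {model_id}")


def fit_lpm(
    visits: pd.DataFrame,
    tags_nlp: pd.DataFrame | None,
    tags_ls: pd.DataFrame | None,
    outcome: str,
    model_id: int = 1,
    se_type: str = "classical",
) -> ModelResult:
    """Fit one of the three nested linear probability models by OLS.

    Model 1 uses NLP clusters (Z), model 2 LS clusters (W), model 3 both.
    ``se_type="robust"`` switches to heteroskedasticity-consistent (HC1)
    standard errors — the LPM error is heteroskedastic by construction.
    Coefficients are probability differences against the reference visit.
    """
    col = f"y_{outcome}" if f"y_{outcome}" in visits.columns else outcome
    y = visits[col].to_numpy(dtype=float)
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError(f"outcome {col!r} must be binary 0/1")
    X = _design_for_model(visits, tags_nlp, tags_ls, model_id)
    _check_full_rank(X)
    fit = sm.OLS(y, X).fit(
        cov_type="HC1" if se_type == "robust" else "nonrobust"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero total variation
        r2 = float(fit.rsquared)
    if not np.isfinite(r2):  # constant outcome: zero total variation
        r2 = 0.0
    return ModelResult(
        model_id=model_id,
        estimator="lpm",
        outcome=outcome,
        params=fit.params,
        bse=fit.bse,
        pvalues=fit.pvalues,
        r_squared=r2,
        resid=np.asarray(fit.resid),
        n=int(fit.nobs),
    )


def nesting_check(results: tuple[ModelResult, ModelResult, ModelResult]) -> bool:
    """True iff the full model's R-squared dominates both restricted models.

    For OLS this holds algebraically whenever all three models are fitted on
    the same sample, so a False here indicates a sample mismatch upstream.
    """
    r1, r2, r3 = results
    if not (r1.outcome == r2.outcome == r3.outcome):
        raise ValueError("nesting check needs a common outcome")
    if not (r1.n == r2.n == r3.n):
        raise ValueError("nesting check needs a common sample")
    return r3.r_squared >= max(r1.r_squared, r2.r_squared) - 1e-10


@dataclass
class PredictionReport:
    """Held-out logistic prediction quality for one outcome/model pair."""

    outcome: str
    model_id: int
    split: float
    seed: int
    f1_ones: float
    auc: float


def predict_evaluate(
    visits: pd.DataFrame,
    tags_nlp: pd.DataFrame | None,
    tags_ls: pd.DataFrame | None,
    outcome: str,
    model_id: int = 1,
    split: float = 2 / 3,
    seed: int = 0,
) -> PredictionReport:
    """Logistic regression with a seeded train-test split.

    ``split`` is the training fraction (default 2/3, the 2:1 split).  The
    split is random and unstratified.  On the held-out third the report
    carries the AUC of the predicted probabilities and the F1-score of the
    positive class at a 0.5 probability threshold.
    """
    col = f"y_{outcome}" if f"y_{outcome}" in visits.columns else outcome
    y = visits[col].to_numpy(dtype=float)
    X = _design_for_model(visits, tags_nlp, tags_ls, model_id)
    X = X.drop(columns="const")  # sklearn fits its own intercept
    X_tr, X_te, y_tr, y_te = train_test_split(
        X.to_numpy(dtype=float), y, train_size=split, random_state=seed, shuffle=True
    )
    if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
        raise ValueError(
            "train or test split contains a single outcome class; try another seed"
        )
    clf = LogisticRegression(penalty=None, max_iter=2000, solver="lbfgs")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separable data never converges exactly
        clf.fit(X_tr, y_tr)
    prob = clf.predict_proba(X_te)[:, 1]
    return PredictionReport(
        outcome=outcome,
        model_id=model_id,
        split=split,
        seed=seed,
        f1_ones=float(f1_score(y_te, (prob >= 0.5).astype(int), pos_label=1)),
        auc=float(roc_auc_score(y_te, prob)),
    )
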