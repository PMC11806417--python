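"""Age/sex-corrected normative w-scores.

A w-score standardizes a patient's measure against a control-fitted linear
norm:

    w = (observed - predicted) / residual_sd

where ``predicted`` and ``residual_sd`` come from an ordinary least
squares regression of the outcome on age and sex fitted in controls only.
By construction control w-scores have mean 0 (OLS residuals with an
intercept) and SD 1 (when the residual SD uses the same (n - 1)
estimator), so a w-score behaves as a standard normal deviate in the
normative population: 1.96 corresponds to the 2.5th upper-tail
percentile, 1.65 to the 5th and 1.04 to the 15th.

For outcomes where *lower* values are abnormal (neuromelanin volume, LC
contrast) the severity index is ``-w``; for outcomes where *higher*
values are abnormal (free water fraction) it is ``+w``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .stats import _encode_sex

__all__ = [
    "ControlNormative",
    "ControlNormativeResults",
    "WScoreResult",
    "wscore_percentile",
    "control_wscore_check",
    "DEFAULT_WSCORE_OUTCOMES",
]

# outcome -> direction of abnormality ("low" = lower values are worse)
DEFAULT_WSCORE_OUTCOMES = {
    "fwf_psn_avg": "high",
    "nm_psn_avg": "low",
    "lc_middle_avg": "low",
}


def wscore_percentile(w: float) -> float:
    """Upper-tail normative percentile, 100 * (1 - Phi(w))."""
    return float(100.0 * (1.0 - norm.cdf(w)))


@dataclass(frozen=True)
class WScoreResult:
    observed: float
    predicted: float
    w: float
    percentile: float


class ControlNormative:
    """Linear normative model of one outcome on age + sex, fitted in controls.

    Parameters
    ----------
    controls : DataFrame with the outcome, ``age`` and ``sex`` columns.
    outcome : name of the outcome column.
    min_controls : minimum complete control rows (default 5).
    """

    def __init__(self, controls: pd.DataFrame, outcome: str, min_controls: int = 5):
        sub = controls[[outcome, "age", "sex"]].dropna()
        if len(sub) < min_controls:
            raise ValueError(f"need >= {min_controls} complete controls, got {len(sub)}")
        self.outcome = outcome
        self.y = sub[outcome].to_numpy(dtype=float)
        self.X = np.column_stack(
            [np.ones(len(sub)), sub["age"].to_numpy(dtype=float), _encode_sex(sub["sex"])]
        )
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("rank-deficient control design (age/sex not both varying)")

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, outcome: str, group_col: str = "group", control_level: str = "HC"
    ) -> "ControlNormative":
        return cls(data[data[group_col] == control_level], outcome)

    def fit(self) -> "ControlNormativeResults":
        beta, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        resid = self.y - self.X @ beta
        residual_sd = float(np.std(resid, ddof=1))
        if residual_sd <= 1e-12 * max(1.0, float(np.max(np.abs(self.y)))):
            raise ValueError(f"degenerate norm for {self.outcome!r}: zero residual SD in controls")
        return ControlNormativeResults(
            outcome=self.outcome,
            intercept=float(beta[0]),
            age_slope=float(beta[1]),
            sex_effect=float(beta[2]),
            residual_sd=residual_sd,
            n_controls=len(self.y),
            _control_y=self.y,
            _control_X=self.X,
        )


@dataclass
class ControlNormativeResults:
    """Fitted control norm: coefficients, residual SD, and w-score mapping."""

    outcome: str
    intercept: float
    age_slope: float
    sex_effect: float
    residual_sd: float
    n_controls: int
    _control_y: np.ndarray = None
    _control_X: np.ndarray = None

    @property
    def params(self) -> np.ndarray:
        return np.array([self.intercept, self.age_slope, self.sex_effect])

    def predict(self, age, sex) -> np.ndarray:
        sexnum = _encode_sex(pd.Series(np.atleast_1d(sex)))
        age = np.atleast_1d(np.asarray(age, dtype=float))
        return self.intercept + self.age_slope * age + self.sex_effect * sexnum

    def wscore(self, observed: float, age: float, sex) -> WScoreResult:
        pred = float(self.predict(age, sex)[0])
        w = (float(observed) - pred) / self.residual_sd
        return WScoreResult(observed=float(observed), predicted=pred, w=w, percentile=wscore_percentile(w))

    def wscore_frame(self, data: pd.DataFrame, direction: str = "low") -> pd.DataFrame:
        """w-scores for every row of ``data`` (needs outcome, age, sex).

        ``direction`` is the abnormality direction of the outcome
        ("low": lower observed values are worse; the severity index is
        ``-w`` and the percentile is taken on the lower tail).
        """
        if direction not in ("low", "high"):
            raise ValueError("direction must be 'low' or 'high'")
        rows = []
        for _, r in data.iterrows():
            if pd.isna(r[self.outcome]) or pd.isna(r["age"]):
                continue
            res = self.wscore(r[self.outcome], r["age"], r["sex"])
            severity = -res.w if direction == "low" else res.w
            rows.append(
                {
                    "subject_id": r.get("subject_id"),
                    "group": r.get("group"),
                    "outcome": self.outcome,
                    "observed": res.observed,
                    "predicted": res.predicted,
                    "w": res.w,
                    "percentile": res.percentile,
                    "severity": severity,
                    "severity_percentile": wscore_percentile(severity),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        return (
            f"Control norm for {self.outcome} (n = {self.n_controls} controls)\n"
            f"  predicted = {self.intercept:.5g} + {self.age_slope:.5g} * age + "
            f"{self.sex_effect:.5g} * sex(M=1)\n"
            f"  residual SD = {self.residual_sd:.5g}"
        )


def plot_wscores(wscores: pd.DataFrame, ax=None):
    """Strip plot of per-subject severity w-scores by outcome and group.

    Expects the long frame produced by
    :meth:`ControlNormativeResults.wscore_frame` (columns ``outcome``,
    ``group``, ``severity``, optionally ``dat_abnormal``).  Subjects with
    an abnormal DAT scan are drawn filled.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    outcomes = list(dict.fromkeys(wscores["outcome"]))
    offsets = {"iRBD": -0.15, "PD": 0.15}
    rng = np.random.default_rng(0)
    for i, outcome in enumerate(outcomes):
        for group, off in offsets.items():
            sub = wscores[(wscores["outcome"] == outcome) & (wscores["group"] == group)]
            if sub.empty:
                continue
            x = i + off + 0.04 * rng.standard_normal(len(sub))
            abnormal = sub.get("dat_abnormal")
            filled = abnormal.fillna(False).to_numpy(dtype=bool) if abnormal is not None else np.zeros(len(sub), bool)
            ax.scatter(x[~filled], sub["severity"][~filled], facecolors="none",
                       edgecolors="C0" if group == "iRBD" else "C1", label=None)
            ax.scatter(x[filled], sub["severity"][filled],
                       color="C0" if group == "iRBD" else "C1")
    for level, style in ((1.04, ":"), (1.65, "--"), (1.96, "-")):
        ax.axhline(level, color="grey", linestyle=style, linewidth=0.8)
    ax.set_xticks(range(len(outcomes)))
    ax.set_xticklabels(outcomes, rotation=20)
    ax.set_ylabel("severity w-score (higher = more abnormal)")
    return ax


def control_wscore_check(results: ControlNormativeResults) -> tuple[float, float]:
    """Recompute w for the fitting controls; returns (mean, SD).

    Mean is 0 exactly (OLS residuals with an intercept sum to zero) and
    SD is 1 exactly under the matched (n - 1) estimator.
    """
    resid = results._control_y - results._control_X @ results.params
    w = resid / results.residual_sd
    return float(np.mean(w)), float(np.std(w, ddof=1))
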