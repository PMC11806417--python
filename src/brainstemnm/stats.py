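"""Group inference for ROI measures.

The central object is :class:`PermutationAncova`, an ANCOVA-type general
linear model with a three-level group factor (HC, iRBD, PD coded as two
dummy columns against a reference) and age + sex as covariates.  The
omnibus group effect is the partial F comparing the full model against
the covariates-only model; its p-value is computed by Freedman-Lane
residual permutation (permute the reduced-model residuals, add back the
reduced-model fit, refit, and take the tail proportion with the +1
smoothing correction).  Post hoc inference runs the six one-tailed
directional pairwise contrasts with a Bonferroni family-wise correction
(x6, capped at 1).

Correlation families are Pearson r with Benjamini-Hochberg FDR adjustment
over exactly the listed family; Levene's test and the demographics tests
(chi-square, Kruskal-Wallis, Mann-Whitney) wrap scipy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GlmSpec",
    "OmnibusResult",
    "ContrastResult",
    "PermutationAncova",
    "PermutationAncovaResults",
    "levene",
    "correlation_family",
    "demographics_tests",
    "bonferroni_family_alpha",
    "bh_adjust",
]

GROUP_LEVELS = ("HC", "iRBD", "PD")


def bonferroni_family_alpha(alpha: float = 0.05, n_contrasts: int = 6) -> float:
    """Per-contrast corrected alpha level for the directional family."""
    return alpha / n_contrasts


@dataclass
class GlmSpec:
    """Specification of one omnibus ANCOVA-type permutation GLM."""

    outcome: str
    factor: str = "group"
    covariates: tuple = ("age", "sex")
    n_perm: int = 10000
    seed: int = 0
    scheme: str = "freedman-lane"  # or "manly" (full-outcome permutation)
    group_levels: tuple = GROUP_LEVELS

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.scheme not in ("freedman-lane", "manly"):
            raise ValueError("scheme must be 'freedman-lane' or 'manly'")


@dataclass(frozen=True)
class OmnibusResult:
    F: float
    df: tuple
    p_param: float
    p_perm: float
    n_used: int
    n_dropped: int


@dataclass(frozen=True)
class ContrastResult:
    label: str  # e.g. "HC > iRBD"
    T: float
    p_perm: float
    p_fwer: float


def _encode_sex(s: pd.Series) -> np.ndarray:
    if s.dtype.kind in "ifu":
        return s.to_numpy(dtype=float)
    mapping = {"M": 1.0, "male": 1.0, "F": 0.0, "female": 0.0}
    try:
        return s.map(mapping).to_numpy(dtype=float)
    except Exception as exc:  # pragma: no cover
        raise ValueError(f"cannot encode sex column: {exc}") from exc


class PermutationAncova:
    """ANCOVA-type GLM with permutation inference for the group factor.

    Parameters
    ----------
    data : DataFrame
        Must contain the outcome, the group factor and the covariates.
        Rows with missing values in any used column are dropped (counted).
    spec : GlmSpec
        Outcome/covariate names, permutation count, seed and scheme.
    """

    def __init__(self, data: pd.DataFrame, spec: GlmSpec):
        self.spec = spec
        cols = [spec.outcome, spec.factor, *spec.covariates]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        sub = data[cols].copy()
        n0 = len(sub)
        sub = sub.dropna()
        self.n_dropped = n0 - len(sub)
        observed_levels = [g for g in spec.group_levels if g in set(sub[spec.factor])]
        if len(observed_levels) < 2:
            raise ValueError("factor must have at least 2 observed levels")
        self.levels = tuple(observed_levels)
        self._build_design(sub)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str, **kwargs) -> "PermutationAncova":
        return cls(data, GlmSpec(outcome=outcome, **kwargs))

    def _build_design(self, sub: pd.DataFrame) -> None:
        spec = self.spec
        self.y = sub[spec.outcome].to_numpy(dtype=float)
        n = self.y.size
        cov_cols = []
        for c in spec.covariates:
            cov_cols.append(_encode_sex(sub[c]) if c == "sex" else sub[c].to_numpy(dtype=float))
        Z = np.column_stack([np.ones(n)] + cov_cols)  # reduced design: intercept + covariates
        dummies = []
        self.dummy_names = []
        for lev in self.levels[1:]:
            dummies.append((sub[spec.factor] == lev).to_numpy(dtype=float))
            self.dummy_names.append(lev)
        X = np.column_stack([Z] + dummies)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("rank-deficient design matrix")
        df_between = len(dummies)
        df_resid = n - X.shape[1]
        if df_resid < 1:
            raise ValueError("fewer than 1 residual degree of freedom")
        self.X, self.Z, self.n = X, Z, n
        self.df = (df_between, df_resid)
        self.group = sub[spec.factor].to_numpy()

    # -- linear algebra helpers -------------------------------------------
    @staticmethod
    def _residual_maker(M: np.ndarray) -> np.ndarray:
        return np.eye(M.shape[0]) - M @ np.linalg.pinv(M)

    def _f_stats(self, Y: np.ndarray) -> np.ndarray:
        """Partial F for the group factor, for each row of Y (2-D)."""
        rss_f = np.einsum("ij,jk,ik->i", Y, self._Rf, Y)
        rss_r = np.einsum("ij,jk,ik->i", Y, self._Rr, Y)
        df1, df2 = self.df
        # roundoff floor: a constant (or perfectly fitted) outcome has both
        # RSS values at numerical zero and must give F = 0, not 0/0 noise
        tol = Y.shape[1] * np.max(np.abs(Y), axis=1) ** 2 * 1e-20
        extra = np.maximum(rss_r - rss_f, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (extra / df1) / (rss_f / df2)
        return np.where(extra <= tol, 0.0, np.nan_to_num(F, nan=0.0, posinf=np.inf))

    def fit(self) -> "PermutationAncovaResults":
        """Fit the GLM and run the permutation inference."""
        X, Z, y = self.X, self.Z, self.y
        self._Rf = self._residual_maker(X)
        self._Rr = self._residual_maker(Z)
        self._pinvX = np.linalg.pinv(X)
        self._XtXinv = np.linalg.pinv(X.T @ X)

        F_obs = float(self._f_stats(y[None, :])[0])
        df1, df2 = self.df
        p_param = float(sps.f.sf(F_obs, df1, df2))

        rng = np.random.default_rng(self.spec.seed)
        n_perm = self.spec.n_perm
        idx = np.argsort(rng.random((n_perm, self.n)), axis=1)
        if self.spec.scheme == "freedman-lane":
            gamma = np.linalg.pinv(Z) @ y
            fitted_r = Z @ gamma
            resid_r = y - fitted_r
            Ystar = fitted_r[None, :] + resid_r[idx]
        else:  # manly: permute the outcome itself
            Ystar = y[idx]

        F_star = self._f_stats(Ystar)
        p_perm = (1.0 + float(np.sum(F_star >= F_obs - 1e-12))) / (n_perm + 1.0)
        omnibus = OmnibusResult(
            F=F_obs, df=self.df, p_param=p_param, p_perm=p_perm, n_used=self.n, n_dropped=self.n_dropped
        )

        contrasts = self._contrasts(y, Ystar)
        beta = self._pinvX @ y
        return PermutationAncovaResults(model=self, omnibus=omnibus, contrasts=contrasts, params=beta)

    def _contrast_vector(self, a: str, b: str) -> np.ndarray:
        """c such that c'beta = mean(a) - mean(b), adjusted for covariates."""
        p = self.X.shape[1]
        c = np.zeros(p)
        base = self.Z.shape[1]
        for i, lev in enumerate(self.dummy_names):
            if lev == a:
                c[base + i] += 1.0
            if lev == b:
                c[base + i] -= 1.0
        return c

    def _contrasts(self, y: np.ndarray, Ystar: np.ndarray) -> list[ContrastResult]:
        df2 = self.df[1]
        pairs = [(a, b) for a, b in permutations(self.levels, 2)]
        n_family = len(pairs)
        beta_obs = self._pinvX @ y
        rss_obs = float(y @ self._Rf @ y)
        sigma2_obs = rss_obs / df2
        beta_star = Ystar @ self._pinvX.T  # (n_perm, p)
        rss_star = np.einsum("ij,jk,ik->i", Ystar, self._Rf, Ystar)
        sigma2_star = rss_star / df2
        out = []
        for a, b in pairs:
            c = self._contrast_vector(a, b)
            cXXc = float(c @ self._XtXinv @ c)
            with np.errstate(divide="ignore", invalid="ignore"):
                t_obs = float((c @ beta_obs) / np.sqrt(sigma2_obs * cXXc)) if sigma2_obs > 0 else 0.0
                t_star = (beta_star @ c) / np.sqrt(sigma2_star * cXXc)
            t_star = np.nan_to_num(t_star, nan=0.0, posinf=0.0, neginf=0.0)
            p_perm = (1.0 + float(np.sum(t_star >= t_obs - 1e-12))) / (self.spec.n_perm + 1.0)
            out.append(
                ContrastResult(
                    label=f"{a} > {b}", T=t_obs, p_perm=p_perm, p_fwer=min(1.0, n_family * p_perm)
                )
            )
        return out


@dataclass
class PermutationAncovaResults:
    """Fitted omnibus + post hoc results with a text summary."""

    model: PermutationAncova
    omnibus: OmnibusResult
    contrasts: list
    params: np.ndarray

    def contrast(self, label: str) -> ContrastResult:
        for c in self.contrasts:
            if c.label == label:
                return c
        raise KeyError(label)

    def contrasts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"contrast": c.label, "T": c.T, "p_perm": c.p_perm, "p_fwer": c.p_fwer} for c in self.contrasts]
        )

    def summary(self) -> str:
        o = self.omnibus
        lines = [
            f"Permutation ANCOVA: {self.model.spec.outcome}",
            f"  groups: {', '.join(self.model.levels)}  (n = {o.n_used}, dropped {o.n_dropped})",
            f"  omnibus F({o.df[0]}, {o.df[1]}) = {o.F:.3f}   p_param = {o.p_param:.4f}   "
            f"p_perm = {o.p_perm:.4f}  [{self.model.spec.n_perm} permutations, "
            f"seed {self.model.spec.seed}, {self.model.spec.scheme}]",
            f"  post hoc one-tailed contrasts (Bonferroni x{len(self.contrasts)}, "
            f"corrected alpha {bonferroni_family_alpha(0.05, len(self.contrasts)):.5f}):",
        ]
        for c in self.contrasts:
            lines.append(f"    {c.label:<12s} T = {c.T:7.3f}   p_perm = {c.p_perm:.4f}   p_FWER = {c.p_fwer:.4f}")
        return "\n".join(lines)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-safe)."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def levene(data: pd.DataFrame, outcome: str, group: str = "group") -> tuple[float, float]:
    """Levene's homogeneity-of-variance test (mean-centred)."""
    groups = [g[outcome].dropna().to_numpy() for _, g in data.groupby(group, observed=True)]
    groups = [g for g in groups if g.size >= 2]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 2 observations each")
    W, p = sps.levene(*groups, center="mean")
    return float(W), float(p)


def correlation_family(
    data: pd.DataFrame,
    pairs: list[tuple[str, str]],
    subset: pd.Series | None = None,
) -> pd.DataFrame:
    """Pearson correlations with BH-FDR adjustment over the listed family.

    Incomplete observations are dropped pairwise; each pair needs >= 3
    complete cases.  Returns columns pair, x, y, r, df, p, p_fdr.
    """
    d = data[subset] if subset is not None else data
    rows = []
    for x, y in pairs:
        sub = d[[x, y]].dropna()
        if len(sub) < 3:
            raise ValueError(f"pair ({x}, {y}) has fewer than 3 complete observations")
        if sub[x].nunique() == 1 or sub[y].nunique() == 1:
            raise ValueError(f"pair ({x}, {y}) has a constant column; r undefined")
        r, p = sps.pearsonr(sub[x], sub[y])
        rows.append({"pair": f"{x}~{y}", "x": x, "y": y, "r": float(r), "df": len(sub) - 2, "p": float(p)})
    fam = pd.DataFrame(rows)
    fam["p_fdr"] = bh_adjust(fam["p"].to_numpy())
    return fam


def demographics_tests(data: pd.DataFrame, group: str = "group") -> pd.DataFrame:
    """Cohort-description tests: sex chi-square, age Kruskal-Wallis, and
    Mann-Whitney for two-group clinical scores (patients only)."""
    rows = []
    tab = pd.crosstab(data[group], data["sex"])
    chi2, p, _, _ = sps.chi2_contingency(tab, correction=False)
    rows.append({"test": "sex chi-square", "statistic": float(chi2), "p": float(p)})
    ages = [g["age"].dropna().to_numpy() for _, g in data.groupby(group, observed=True)]
    H, p = sps.kruskal(*ages)
    rows.append({"test": "age Kruskal-Wallis", "statistic": float(H), "p": float(p)})
    for col in ("moca", "updrs1", "updrs2", "updrs3"):
        if col in data.columns:
            pats = data[data[group].isin(["iRBD", "PD"])]
            a = pats.loc[pats[group] == "iRBD", col].dropna()
            b = pats.loc[pats[group] == "PD", col].dropna()
            if len(a) and len(b):
                U, p = sps.mannwhitneyu(a, b, alternative="two-sided")
                rows.append({"test": f"{col} Mann-Whitney", "statistic": float(U), "p": float(p)})
    if "rbdsq" in data.columns:
        grs = [g["rbdsq"].dropna().to_numpy() for _, g in data.groupby(group, observed=True)]
        if len(grs) >= 2:
            H, p = sps.kruskal(*grs)
            rows.append({"test": "rbdsq Kruskal-Wallis", "statistic": float(H), "p": float(p)})
    return pd.DataFrame(rows)
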