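"""Beta regression (logit link, mean–precision parameterisation) plus the
model-building toolkit around it: interval squeezing, variance inflation
factors, exhaustive AICc model selection with collinearity exclusions,
likelihood-ratio tests, leverage diagnostics, and estimated marginal means
with post hoc contrasts.

The response y ∈ (0,1) follows Beta(μφ, (1−μ)φ) with logit(μ) = xᵀβ and a
constant precision φ.  Maximum-likelihood estimation is delegated to
``statsmodels`` (``BetaModel``); the surface here adds the quantities that
ecological practice reports: a pseudo-R² defined as the squared Pearson
correlation between the linear predictor and logit(y), hat values from the
weighted projection matrix of the final scoring step, AICc, and
response-scale (inverse-logit) coefficient reporting.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit, polygamma
from statsmodels.othermod.betareg import BetaModel

__all__ = [
    "squeeze_unit_interval",
    "BetaRegression",
    "BetaRegressionResults",
    "ConvergenceError",
    "likelihood_ratio_test",
    "vif",
    "aicc",
    "dredge_aicc",
    "ModelSelectionTable",
    "emmeans_categories",
    "EmmResult",
    "leverage",
]

VIF_CAP = 1e6


class ConvergenceError(RuntimeError):
    """Raised when the ML optimisation fails; carries the optimiser trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


def squeeze_unit_interval(y, mode: str = "fst"):
    """Map a response into the open interval (0, 1).

    ``mode='fst'``: values <= 0 become 0.001 (the convention for negative
    differentiation estimates) and values >= 1 become 0.999.
    ``mode='proportion'``: the Smithson–Verkuilen transform
    (y(n−1)+0.5)/n, applied only when some y hits the boundary.
    """
    y = np.asarray(y, float)
    if mode == "fst":
        return np.clip(np.where(y <= 0.0, 0.001, y), None, 1.0 - 1e-3)
    if mode == "proportion":
        if ((y <= 0.0) | (y >= 1.0)).any():
            n = y.size
            return (y * (n - 1) + 0.5) / n
        return y.copy()
    raise ValueError("mode must be 'fst' or 'proportion'")


class BetaRegression:
    """Beta-regression model specification (statsmodels-style).

    Parameters
    ----------
    endog
        Response strictly inside (0, 1); boundary values raise with a
        pointer to :func:`squeeze_unit_interval`.
    exog
        Design frame of predictors *without* an intercept column; the
        constant is added automatically.
    factor_levels
        Optional mapping ``{factor_name: [levels...]}`` recorded when the
        design was built from a categorical predictor (used by
        :func:`emmeans_categories`).
    """

    def __init__(self, endog, exog: pd.DataFrame | None = None,
                 factor_levels: dict[str, list[str]] | None = None):
        y = np.asarray(endog, float)
        if ((y <= 0.0) | (y >= 1.0)).any():
            raise ValueError(
                "response on the boundary of (0,1); apply squeeze_unit_interval first"
            )
        if exog is None:
            exog = pd.DataFrame(index=range(len(y)))
        exog = pd.DataFrame(exog).reset_index(drop=True)
        if "const" not in exog.columns:
            exog = exog.copy()
            exog.insert(0, "const", 1.0)
        if exog.isna().any().any():
            raise ValueError("missing predictor cells are not allowed")
        self.endog = y
        self.exog = exog.astype(float)
        self.factor_levels = factor_levels or {}
        self.exog_names = list(exog.columns)

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, response: str,
                       predictors: list[str] | None = None,
                       factor: str | None = None) -> "BetaRegression":
        """Build the design from a long table; one categorical factor is
        dummy-coded (first level as reference)."""
        predictors = list(predictors or [])
        cols = {}
        factor_levels = {}
        for p in predictors:
            cols[p] = frame[p].to_numpy(float)
        if factor is not None:
            levels = list(pd.unique(frame[factor].astype(str)))
            factor_levels[factor] = levels
            for lev in levels[1:]:
                cols[f"{factor}[{lev}]"] = (
                    frame[factor].astype(str) == lev
                ).to_numpy(float)
        X = pd.DataFrame(cols, index=range(len(frame)))
        return cls(frame[response].to_numpy(float), X, factor_levels)

    # -- fitting ----------------------------------------------------------
    def fit(self, maxiter: int = 500) -> "BetaRegressionResults":
        sm_model = BetaModel(self.endog, self.exog)
        res = sm_model.fit(method="bfgs", maxiter=maxiter, disp=0)
        if not res.mle_retvals.get("converged", True):
            res = sm_model.fit(start_params=res.params, method="nm",
                               maxiter=5 * maxiter, disp=0)
            if not res.mle_retvals.get("converged", True):
                raise ConvergenceError("beta-regression ML did not converge",
                                       trace=res.mle_retvals)
        return BetaRegressionResults(self, res)


@dataclass
class BetaRegressionResults:
    """Fitted beta regression: coefficients on the logit scale, precision,
    diagnostics and reporting helpers."""

    model: BetaRegression
    _sm: object = field(repr=False)

    # -- core estimates ---------------------------------------------------
    @property
    def params(self) -> pd.Series:
        k = len(self.model.exog_names)
        return pd.Series(np.asarray(self._sm.params)[:k], index=self.model.exog_names)

    @property
    def bse(self) -> pd.Series:
        k = len(self.model.exog_names)
        return pd.Series(np.asarray(self._sm.bse)[:k], index=self.model.exog_names)

    @property
    def pvalues(self) -> pd.Series:
        k = len(self.model.exog_names)
        return pd.Series(np.asarray(self._sm.pvalues)[:k], index=self.model.exog_names)

    @property
    def cov_params(self) -> pd.DataFrame:
        k = len(self.model.exog_names)
        cov = np.asarray(self._sm.cov_params())[:k, :k]
        return pd.DataFrame(cov, index=self.model.exog_names,
                            columns=self.model.exog_names)

    @property
    def phi(self) -> float:
        """Precision parameter (the log-link precision back-transformed)."""
        return float(np.exp(np.asarray(self._sm.params)[-1]))

    @property
    def llf(self) -> float:
        return float(self._sm.llf)

    @property
    def nobs(self) -> int:
        return int(len(self.model.endog))

    @property
    def k_params(self) -> int:
        return len(self.model.exog_names) + 1  # + precision

    @property
    def df_model(self) -> int:
        return len(self.model.exog_names)

    # -- fitted quantities ------------------------------------------------
    @property
    def linear_predictor(self) -> np.ndarray:
        return self.model.exog.to_numpy() @ self.params.to_numpy()

    @property
    def fitted_means(self) -> np.ndarray:
        return expit(self.linear_predictor)

    @property
    def pseudo_r2(self) -> float:
        """Squared correlation between xᵀβ̂ and logit(y)."""
        eta = self.linear_predictor
        z = logit(self.model.endog)
        if np.std(eta) == 0.0:
            return 0.0
        return float(np.corrcoef(eta, z)[0, 1] ** 2)

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k_params

    @property
    def aicc(self) -> float:
        return aicc(self.llf, self.k_params, self.nobs)

    def hat_values(self) -> np.ndarray:
        """Diagonal of W^{1/2} X (XᵀWX)⁻¹ Xᵀ W^{1/2} at the ML fit.

        The Fisher-scoring working weights for the mean submodel are
        w = φ [ψ₁(μφ) + ψ₁((1−μ)φ)] (dμ/dη)² with dμ/dη = μ(1−μ) for the
        logit link.
        """
        X = self.model.exog.to_numpy()
        mu = self.fitted_means
        phi = self.phi
        w = phi * (polygamma(1, mu * phi) + polygamma(1, (1 - mu) * phi)) \
            * (mu * (1 - mu)) ** 2
        sw = np.sqrt(w)
        Xw = X * sw[:, None]
        xtx_inv = np.linalg.pinv(Xw.T @ Xw)
        return np.einsum("ij,jk,ik->i", Xw, xtx_inv, Xw)

    def coefficients_response_scale(self) -> pd.Series:
        """Inverse-logit of each coefficient (the field's reporting
        convention for logit-scale estimates)."""
        return self.params.map(lambda b: float(expit(b)))

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        rows = pd.DataFrame({
            "estimate (logit)": self.params,
            "std err": self.bse,
            "p": self.pvalues,
            "inv-logit": self.coefficients_response_scale(),
        })
        lines = [
            "Beta regression (logit link, constant precision)",
            f"  n = {self.nobs}, log-likelihood = {self.llf:.4f}",
            f"  phi = {self.phi:.4f}, pseudo-R2 = {self.pseudo_r2:.4f}",
            f"  AIC = {self.aic:.3f}, AICc = {self.aicc:.3f}",
            rows.round(4).to_string(),
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Inference helpers
# ---------------------------------------------------------------------------

def likelihood_ratio_test(fit_full: BetaRegressionResults,
                          fit_null: BetaRegressionResults
                          ) -> tuple[float, int, float]:
    """LRT of nested beta regressions: χ² = 2(ℓ_full − ℓ_null)."""
    if fit_full.nobs != fit_null.nobs:
        raise ValueError("models fitted on different numbers of rows")
    full_cols = set(fit_full.model.exog_names)
    null_cols = set(fit_null.model.exog_names)
    if not null_cols <= full_cols:
        raise ValueError("null model is not nested in the full model")
    df = fit_full.k_params - fit_null.k_params
    if df < 0:
        raise ValueError("null model has more parameters than the full model")
    chi2 = max(0.0, 2.0 * (fit_full.llf - fit_null.llf))
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def vif(predictors: pd.DataFrame) -> pd.DataFrame:
    """Variance inflation factors: VIF_j = 1 / (1 − R²_j).

    R²_j comes from the OLS regression of predictor j on the others (with
    intercept).  Perfectly collinear predictors are reported at the cap
    with ``capped=True``.
    """
    X = pd.DataFrame(predictors).astype(float)
    cols = list(X.columns)
    recs = []
    for j, col in enumerate(cols):
        y = X[col].to_numpy()
        others = X.drop(columns=[col]).to_numpy()
        design = np.column_stack([np.ones(len(y)), others])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        tss = ((y - y.mean()) ** 2).sum()
        r2 = 0.0 if tss == 0 else 1.0 - resid @ resid / tss
        if r2 >= 1.0 - 1.0 / VIF_CAP:
            recs.append(dict(predictor=col, vif=VIF_CAP, capped=True))
        else:
            recs.append(dict(predictor=col, vif=1.0 / (1.0 - r2), capped=False))
    return pd.DataFrame(recs)


def aicc(llf: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: −2ℓ + 2k + 2k(k+1)/(n−k−1)."""
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class ModelSelectionTable:
    table: pd.DataFrame
    best: BetaRegressionResults
    exclusion_groups: list[set] = field(default_factory=list)


def dredge_aicc(frame: pd.DataFrame, response: str, candidates: list[str],
                exclusion_groups: list[set | list] | None = None,
                factor: str | None = None) -> ModelSelectionTable:
    """Exhaustive subset selection ranked by AICc.

    Every subset of ``candidates`` is fitted except those containing two
    or more members of any exclusion group (the device used to keep, e.g.,
    the min/max/mean variants of one variable out of the same model).  A
    categorical ``factor`` is part of every candidate model.
    """
    groups = [set(g) for g in (exclusion_groups or [])]
    rows = []
    fits: list[BetaRegressionResults] = []
    subsets = []
    for r in range(len(candidates) + 1):
        for sub in itertools.combinations(candidates, r):
            if any(len(g & set(sub)) >= 2 for g in groups):
                continue
            subsets.append(sub)
    for sub in subsets:
        reg = BetaRegression.from_dataframe(frame, response, list(sub), factor=factor)
        fit = reg.fit()
        fits.append(fit)
        rows.append(dict(predictors=" + ".join(sub) if sub else "(intercept)",
                         n_predictors=len(sub), k=fit.k_params,
                         loglik=fit.llf, AICc=fit.aicc))
    table = pd.DataFrame(rows)
    table["delta_AICc"] = table["AICc"] - table["AICc"].min()
    table = table.sort_values("AICc", kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    best = fits[int(np.argmin([f.aicc for f in fits]))]
    return ModelSelectionTable(table, best, groups)


# ---------------------------------------------------------------------------
# Estimated marginal means
# ---------------------------------------------------------------------------

@dataclass
class EmmResult:
    means: pd.DataFrame        # level, emmean (response scale), CI
    contrasts: pd.DataFrame    # pairwise contrasts on the link scale
    adjust: str


def _adjust_p(z: np.ndarray, n_levels: int, adjust: str) -> np.ndarray:
    raw = 2.0 * stats.norm.sf(np.abs(z))
    if adjust == "none":
        return raw
    if adjust == "bonferroni":
        m = n_levels * (n_levels - 1) // 2
        return np.minimum(1.0, raw * m)
    if adjust == "tukey":
        # studentized-range on |z|*sqrt(2); asymptotic (large df)
        return stats.studentized_range.sf(np.abs(z) * math.sqrt(2.0),
                                          n_levels, 1e6)
    raise ValueError("adjust must be 'none', 'bonferroni' or 'tukey'")


def emmeans_categories(fit: BetaRegressionResults, factor: str,
                       adjust: str = "tukey", conf_level: float = 0.95
                       ) -> EmmResult:
    """Marginal means per factor level and pairwise post hoc contrasts.

    Each level's link-scale prediction is evaluated with the remaining
    covariates at their sample means, then inverse-logit transformed; the
    contrasts are tested on the link scale with the chosen multiplicity
    adjustment.
    """
    levels = fit.model.factor_levels.get(factor)
    if not levels:
        raise ValueError(f"model was not built with factor {factor!r}")
    names = fit.model.exog_names
    Xbar = fit.model.exog.mean()
    beta = fit.params.to_numpy()
    cov = fit.cov_params.to_numpy()
    zq = stats.norm.ppf(0.5 + conf_level / 2.0)

    def design_for(level: str) -> np.ndarray:
        x = Xbar.copy()
        for lev in levels[1:]:
            x[f"{factor}[{lev}]"] = 1.0 if lev == level else 0.0
        return x[names].to_numpy()

    recs = []
    xs = {}
    for lev in levels:
        x = design_for(lev)
        xs[lev] = x
        eta = float(x @ beta)
        se = float(np.sqrt(x @ cov @ x))
        recs.append(dict(level=lev, emmean=float(expit(eta)),
                         link_estimate=eta, link_se=se,
                         ci_low=float(expit(eta - zq * se)),
                         ci_high=float(expit(eta + zq * se))))
    means = pd.DataFrame(recs)

    crecs = []
    zvals = []
    for a, b in itertools.combinations(levels, 2):
        d = xs[a] - xs[b]
        est = float(d @ beta)
        se = float(np.sqrt(d @ cov @ d))
        z = est / se if se > 0 else 0.0
        zvals.append(z)
        crecs.append(dict(contrast=f"{a} - {b}", estimate=est, se=se, z=z))
    contrasts = pd.DataFrame(crecs)
    contrasts["p_adjusted"] = _adjust_p(np.asarray(zvals), len(levels), adjust)
    return EmmResult(means, contrasts, adjust)


def leverage(fit: BetaRegressionResults) -> pd.DataFrame:
    """Hat values with the conventional 2(k+1)/n high-leverage flag."""
    h = fit.hat_values()
    cut = 2.0 * (fit.df_model + 1) / fit.nobs
    return pd.DataFrame({"hat": h, "high_leverage": h > cut})
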