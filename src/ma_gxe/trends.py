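"""Temperature-trend models for variance components and category proportions.

Variance components are regressed on temperature with a general linear model
containing linear and quadratic terms; per-term marginal (Type II) F tests
drive stepwise simplification (quadratic first, then linear, alpha = 0.05 by
default). Category proportions are modelled as binomial counts with a logit
link, fitted by iteratively reweighted least squares; the trend test is the
likelihood-ratio chi-square of the linear model against the intercept-only
model.

Temperature is centered at its mean before forming the quadratic column (a
conditioning choice only); reported coefficients are back-transformed to the
raw Celsius scale, so fitted values and test statistics are invariant to the
centering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .io import ValidationError

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class TermTest:
    """Marginal test of one model term (full model, before simplification)."""

    term: str  # "linear_T" or "quadratic_T"
    estimate: float  # raw-scale coefficient in the full model
    statistic: float  # F (gaussian) or LR chi2 (binomial)
    df: tuple[int, ...]  # (num, den) for F, (1,) for chi2
    p: float
    retained: bool


@dataclass
class TrendFit:
    """Result of a temperature-trend fit.

    ``coefficients`` are the final (simplified) model's coefficients on the
    raw temperature scale, keyed by ``intercept`` / ``linear_T`` /
    ``quadratic_T``; ``terms`` records the full-model marginal tests and
    which terms survived simplification.
    """

    response: str
    kind: str  # "gaussian" | "binomial"
    temperatures: np.ndarray
    terms: list[TermTest]
    coefficients: dict[str, float]
    fitted: np.ndarray
    model_df: int
    alpha: float = ALPHA_DEFAULT
    lr_chi2: float | None = None  # binomial: linear vs intercept-only
    lr_p: float | None = None
    separation: bool = False
    notes: tuple[str, ...] = ()

    @property
    def retained_terms(self) -> tuple[str, ...]:
        return tuple(t.term for t in self.terms if t.retained)

    @property
    def slope(self) -> float:
        return self.coefficients.get("linear_T", 0.0)

    @property
    def slope_sign(self) -> int:
        return int(np.sign(self.slope))

    def predict(self, temperatures: Sequence[float]) -> np.ndarray:
        t = np.asarray(temperatures, dtype=float)
        eta = (
            self.coefficients.get("intercept", 0.0)
            + self.coefficients.get("linear_T", 0.0) * t
            + self.coefficients.get("quadratic_T", 0.0) * t**2
        )
        if self.kind == "binomial":
            return 1.0 / (1.0 + np.exp(-eta))
        return eta

    def summary(self) -> str:
        lines = [
            f"Trend fit: {self.response} ({self.kind}, alpha={self.alpha:g})",
            f"  retained terms: {', '.join(self.retained_terms) or 'intercept only'}",
            "  term          estimate      statistic   df        p       retained",
        ]
        for t in self.terms:
            df = "x".join(str(d) for d in t.df)
            lines.append(
                f"  {t.term:<12} {t.estimate: .6g}  {t.statistic: .5g}   "
                f"{df:<8} {t.p: .4g}  {'yes' if t.retained else 'no'}"
            )
        if self.lr_chi2 is not None:
            lines.append(
                f"  LR chi2 (linear vs null) = {self.lr_chi2:.5g}, p = {self.lr_p:.4g}"
            )
        for note in self.notes:
            lines.append(f"  note: {note}")
        return "\n".join(lines)


def _design_columns(t_centered: np.ndarray, terms: Sequence[str]) -> np.ndarray:
    cols = [np.ones_like(t_centered)]
    if "linear_T" in terms:
        cols.append(t_centered)
    if "quadratic_T" in terms:
        cols.append(t_centered**2)
    return np.column_stack(cols)


def _raw_scale(params: Sequence[float], terms: Sequence[str], center: float) -> dict[str, float]:
    """Back-transform centered-polynomial coefficients to the raw T scale."""
    b = dict(zip(["intercept", *terms], params))
    b0 = b.get("intercept", 0.0)
    b1 = b.get("linear_T", 0.0)
    b2 = b.get("quadratic_T", 0.0)
    out = {"intercept": b0 - b1 * center + b2 * center**2}
    if "linear_T" in terms:
        out["linear_T"] = b1 - 2.0 * b2 * center
    if "quadratic_T" in terms:
        out["quadratic_T"] = b2
    return out


def _ols_ssr(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return beta, float(resid @ resid)


def fit_component_trend(
    values: Sequence[float],
    temperatures: Sequence[float],
    *,
    response: str = "component",
    alpha: float = ALPHA_DEFAULT,
) -> TrendFit:
    """OLS of a per-temperature quantity on T and T^2 with stepwise removal.

    Marginal (drop-one) F tests are computed on the full model; the quadratic
    term is removed first if non-significant, the model refitted, then the
    linear term tested against the intercept-only model. A significant
    quadratic keeps the linear term in the model (marginality).
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(temperatures, dtype=float)
    if y.shape != t.shape or y.ndim != 1:
        raise ValidationError("values and temperatures must be equal-length 1-d")
    n = y.size
    if n < 4:
        raise ValidationError(f"need >= 4 temperature points for a quadratic fit, got {n}")
    center = float(t.mean())
    tc = t - center

    x_full = _design_columns(tc, ("linear_T", "quadratic_T"))
    beta_full, ssr_full = _ols_ssr(y, x_full)
    df_resid = n - 3
    scale = float(y @ y) + 1.0

    def marginal_f(ssr_reduced: float) -> tuple[float, float]:
        num = max(ssr_reduced - ssr_full, 0.0)
        mse = ssr_full / df_resid
        if mse <= 1e-30 * scale:
            # Degenerate (interpolating) fit: an exactly-zero extra SS means
            # the term adds nothing; otherwise it is indispensable.
            if num <= 1e-30 * scale:
                return 0.0, 1.0
            return float("inf"), 0.0
        f = num / mse
        return f, float(sps.f.sf(f, 1, df_resid))

    _, ssr_no_quad = _ols_ssr(y, _design_columns(tc, ("linear_T",)))
    _, ssr_no_lin = _ols_ssr(y, _design_columns(tc, ("quadratic_T",)))
    f_quad, p_quad = marginal_f(ssr_no_quad)
    f_lin, p_lin = marginal_f(ssr_no_lin)
    raw_full = _raw_scale(beta_full, ("linear_T", "quadratic_T"), center)

    # stepwise simplification: quadratic first, then linear
    if p_quad < alpha:
        retained = ("linear_T", "quadratic_T")
        final_terms = retained
        final_beta = beta_full
    else:
        x_lin = _design_columns(tc, ("linear_T",))
        beta_lin, ssr_lin = _ols_ssr(y, x_lin)
        _, ssr_null = _ols_ssr(y, _design_columns(tc, ()))
        df_lin = n - 2
        mse_lin = ssr_lin / df_lin
        num = max(ssr_null - ssr_lin, 0.0)
        if mse_lin <= 1e-30 * scale:
            p_lin_seq = 1.0 if num <= 1e-30 * scale else 0.0
            f_lin_seq = 0.0 if num <= 1e-30 * scale else float("inf")
        else:
            f_lin_seq = num / mse_lin
            p_lin_seq = float(sps.f.sf(f_lin_seq, 1, df_lin))
        if p_lin_seq < alpha:
            retained = ("linear_T",)
            final_terms = retained
            final_beta = beta_lin
        else:
            retained = ()
            final_terms = ()
            final_beta = np.array([y.mean()])

    coefficients = _raw_scale(final_beta, final_terms, center)
    fitted = _design_columns(tc, final_terms) @ final_beta
    terms = [
        TermTest("linear_T", raw_full["linear_T"], f_lin, (1, df_resid), p_lin,
                 "linear_T" in retained),
        TermTest("quadratic_T", raw_full["quadratic_T"], f_quad, (1, df_resid), p_quad,
                 "quadratic_T" in retained),
    ]
    return TrendFit(
        response=response,
        kind="gaussian",
        temperatures=t,
        terms=terms,
        coefficients=coefficients,
        fitted=fitted,
        model_df=1 + len(final_terms),
        alpha=alpha,
    )


def fit_proportion_trend(
    counts: Sequence[float],
    totals: Sequence[float] | int,
    temperatures: Sequence[float],
    *,
    response: str = "proportion",
    alpha: float = ALPHA_DEFAULT,
    test_quadratic: bool = True,
    tol: float = 1e-10,
    maxiter: int = 100,
) -> TrendFit:
    """Binomial-logit trend of a per-temperature category count.

    Fits count/total ~ logit^-1(a + b T) by IRLS and reports the
    likelihood-ratio chi-square (1 df) of the linear model against the
    intercept-only model. A quadratic term is optionally added and
    LR-tested the same way; it is retained only if significant. Complete
    separation (all-zero or all-total counts) is flagged: the slope is then
    reported as sign-only (zero) with a warning instead of a divergent IRLS
    estimate.
    """
    k = np.asarray(counts, dtype=float)
    t = np.asarray(temperatures, dtype=float)
    if np.isscalar(totals):
        ntot = np.full_like(k, float(totals))
    else:
        ntot = np.asarray(totals, dtype=float)
    if not (k.shape == ntot.shape == t.shape):
        raise ValidationError("counts, totals and temperatures must align")
    if t.size < 3:
        raise ValidationError("need >= 3 temperature points for a proportion trend")
    if ((k < 0) | (k > ntot)).any():
        raise ValidationError("counts must satisfy 0 <= count <= total")

    center = float(t.mean())
    tc = t - center

    if (k == 0).all() or (k == ntot).all():
        p_hat = float(k.sum() / ntot.sum())
        p_clip = min(max(p_hat, 1e-12), 1 - 1e-12)
        warnings.warn(
            f"{response}: all counts are {'zero' if p_hat < 0.5 else 'at total'}; "
            "slope is unidentified (complete separation), reported as 0",
            stacklevel=2,
        )
        intercept = float(np.log(p_clip / (1 - p_clip)))
        return TrendFit(
            response=response,
            kind="binomial",
            temperatures=t,
            terms=[TermTest("linear_T", 0.0, 0.0, (1,), 1.0, False)],
            coefficients={"intercept": intercept, "linear_T": 0.0},
            fitted=np.full_like(t, p_hat),
            model_df=1,
            alpha=alpha,
            lr_chi2=0.0,
            lr_p=1.0,
            separation=True,
            notes=("complete separation: slope sign-only",),
        )

    endog = np.column_stack([k, ntot - k])

    def glm_fit(terms: tuple[str, ...]):
        x = _design_columns(tc, terms)
        model = sm.GLM(endog, x, family=sm.families.Binomial())
        return model.fit(maxiter=maxiter, tol=tol, scale=1.0)

    res_lin = glm_fit(("linear_T",))
    lr = float(res_lin.null_deviance - res_lin.deviance)
    lr_p = float(sps.chi2.sf(lr, 1))

    terms_list = [
        TermTest(
            "linear_T",
            _raw_scale(res_lin.params, ("linear_T",), center)["linear_T"],
            lr,
            (1,),
            lr_p,
            True,
        )
    ]
    final_terms: tuple[str, ...] = ("linear_T",)
    final_res = res_lin
    notes: tuple[str, ...] = ()
    if test_quadratic:
        res_quad = glm_fit(("linear_T", "quadratic_T"))
        lr_q = float(res_lin.deviance - res_quad.deviance)
        p_q = float(sps.chi2.sf(max(lr_q, 0.0), 1))
        keep_quad = p_q < alpha
        terms_list.append(
            TermTest(
                "quadratic_T",
                _raw_scale(res_quad.params, ("linear_T", "quadratic_T"), center)["quadratic_T"],
                max(lr_q, 0.0),
                (1,),
                p_q,
                keep_quad,
            )
        )
        if keep_quad:
            final_terms = ("linear_T", "quadratic_T")
            final_res = res_quad
        else:
            notes = ("quadratic term did not improve the linear model",)

    coefficients = _raw_scale(final_res.params, final_terms, center)
    return TrendFit(
        response=response,
        kind="binomial",
        temperatures=t,
        terms=terms_list,
        coefficients=coefficients,
        fitted=np.asarray(final_res.fittedvalues, dtype=float),
        model_df=1 + len(final_terms),
        alpha=alpha,
        lr_chi2=lr,
        lr_p=lr_p,
        separation=False,
        notes=notes,
    )


def trend_frame(fits: Sequence[TrendFit]):
    """Long table of term tests: response,term,estimate,statistic,df,p,retained."""
    import pandas as pd

    rows = []
    for fit in fits:
        for t in fit.terms:
            rows.append(
                {
                    "response": fit.response,
                    "term": t.term,
                    "estimate": t.estimate,
                    "statistic": t.statistic,
                    "df": "x".join(str(d) for d in t.df),
                    "p": t.p,
                    "retained": "yes" if t.retained else "no",
                }
            )
    return pd.DataFrame(rows)
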