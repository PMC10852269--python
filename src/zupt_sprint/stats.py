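"""Method-agreement statistics: Bland–Altman, rater reconciliation, regressions.

These mirror the statistical machinery used to validate stride estimates
against a camera reference: limits of agreement are bias ± 1.96·SD of the
differences; three independent raters of the same video are reconciled by a
2% relative-spread rule; the effect of speed and body mass on the errors is
quantified with standardized regression coefficients binned into
small/medium/large effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class AgreementResult:
    """Bland–Altman bias and 95% limits of agreement of paired differences."""

    bias: float
    loa_low: float
    loa_high: float
    sd: float
    n: int


def bland_altman(method_a, method_b) -> AgreementResult:
    """Agreement between two methods: differences d = a − b, LoA = bias ± 1.96·SD.

    SD is the sample (n−1) standard deviation.  When the inputs are already
    percentage errors the result is on the percent scale.
    """
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(
        bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, sd=sd, n=len(d)
    )


def reconcile_raters(triple, tol_percent: float = 2.0) -> float | None:
    """Consensus of three independent measurements of one quantity.

    Spread is the relative range (max − min)/mean·100.  If the three agree
    within ``tol_percent`` the consensus is their mean; otherwise the value
    farthest from the mean of the other two is dropped and the remaining pair
    is accepted if it agrees within tolerance.  ``None`` signals that the
    trial must be re-analyzed.
    """
    x = np.asarray(triple, dtype=float)
    if x.shape != (3,) or np.any(x <= 0):
        raise ValueError("need three positive measurements")

    def spread(v: np.ndarray) -> float:
        return float((v.max() - v.min()) / v.mean() * 100.0)

    if spread(x) < tol_percent:
        return float(x.mean())
    others_mean = (x.sum() - x) / 2.0
    drop = int(np.argmax(np.abs(x - others_mean)))
    pair = np.delete(x, drop)
    if spread(pair) < tol_percent:
        return float(pair.mean())
    return None


def effect_label(beta: float) -> str:
    """Standardized-β effect-size bin: small < 0.295 ≤ medium < 0.495 ≤ large.

    The conventional bin edges (0.29/0.30 and 0.49/0.50) leave gaps; the
    midpoints are used so every value is classifiable.
    """
    b = abs(beta)
    if b < 0.295:
        return "small"
    if b < 0.495:
        return "medium"
    return "large"


@dataclass
class RegressionResult:
    """OLS summary with standardized coefficients and effect-size labels."""

    p_value: float
    adj_r2: float
    beta: dict[str, float]
    labels: dict[str, str] = field(default_factory=dict)
    coef: dict[str, float] = field(default_factory=dict)
    pvalues: dict[str, float] = field(default_factory=dict)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("predictor is constant")
    return (x - x.mean()) / sd


def regress_errors(errors, speed, mass=None) -> RegressionResult:
    """OLS of percentage errors on speed (simple) or speed + mass (multiple).

    Standardized β are slopes of the z-scored fit (for a single predictor
    this equals the Pearson correlation).  The headline p-value is the slope
    t-test for the simple model and the model F-test for the multiple model;
    per-predictor p-values are also reported.
    """
    y = np.asarray(errors, dtype=float)
    predictors = {"speed": np.asarray(speed, dtype=float)}
    if mass is not None:
        predictors["mass"] = np.asarray(mass, dtype=float)
    if len(y) < 5:
        raise ValueError("need at least 5 observations")

    X = pd.DataFrame(predictors)
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    Xz = pd.DataFrame({k: _standardize(v) for k, v in predictors.items()})
    fit_z = sm.OLS(_standardize(y), sm.add_constant(Xz)).fit()

    beta = {k: float(fit_z.params[k]) for k in predictors}
    p_value = float(fit.pvalues["speed"]) if mass is None else float(fit.f_pvalue)
    return RegressionResult(
        p_value=p_value,
        adj_r2=float(fit.rsquared_adj),
        beta=beta,
        labels={k: effect_label(b) for k, b in beta.items()},
        coef={k: float(fit.params[k]) for k in predictors},
        pvalues={k: float(fit.pvalues[k]) for k in predictors},
    )


def regression_table(
    errors_by_label: dict[str, np.ndarray],
    speeds_by_label: dict[str, np.ndarray],
    masses: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simple + multiple regression summary, one pair of rows per error series.

    Columns mirror the conventional validation report: model p-value, adjusted
    R², standardized β for speed and (in the multiple model) body mass.
    """
    rows = []
    for label, errors in errors_by_label.items():
        speed = speeds_by_label[label]
        simple = regress_errors(errors, speed)
        rows.append(
            {
                "error": label,
                "model": "simple",
                "p_value": simple.p_value,
                "adj_r2": simple.adj_r2,
                "beta_speed": simple.beta["speed"],
                "beta_mass": np.nan,
            }
        )
        if masses is not None:
            multiple = regress_errors(errors, speed, masses)
            rows.append(
                {
                    "error": label,
                    "model": "multiple",
                    "p_value": multiple.p_value,
                    "adj_r2": multiple.adj_r2,
                    "beta_speed": multiple.beta["speed"],
                    "beta_mass": multiple.beta["mass"],
                }
            )
    return pd.DataFrame(rows)


def summarize_agreement(reports: dict[str, np.ndarray]) -> pd.DataFrame:
    """Bland–Altman table (bias ± LoA) for several labelled error series."""
    rows = []
    for label, errors in reports.items():
        res = bland_altman(np.asarray(errors, dtype=float), np.zeros(len(errors)))
        rows.append(
            {
                "label": label,
                "bias": res.bias,
                "loa_low": res.loa_low,
                "loa_high": res.loa_high,
                "sd": res.sd,
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)
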