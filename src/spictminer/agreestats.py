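"""Agreement and epidemiological statistics for screening evaluation.

Covers the evaluation toolkit used to compare algorithmic screening against
physician gold labels and to describe a screened cohort:

* percent agreement and Cohen's kappa (with large-sample SE, 95% CI, and the
  interpretation bands >0.7 good / 0.4–0.7 moderate / <0.4 poor);
* screening yield as prevalence per 100 patients (half-up rounding to one
  decimal, matching how such tables are printed);
* 2×2 association: cross-product odds ratio with Wald log-scale CI
  (Haldane–Anscombe +0.5 correction when a cell is empty, flagged) and the
  two-sided Fisher exact test;
* multiple logistic regression, reported as per-covariate odds ratios with
  Wald CIs and p-values.

The kappa machinery is implemented directly from the defining formulas;
Fisher's exact test and the logistic fit delegate to scipy and statsmodels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class SeparationError(ValueError):
    """Perfect separation: the logistic MLE does not exist."""


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Rater-agreement table: a both+, b r1+/r2-, c r1-/r2+, d both-."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_labels(cls, rater1, rater2) -> "ConfusionMatrix2x2":
        r1 = np.asarray(rater1, dtype=bool)
        r2 = np.asarray(rater2, dtype=bool)
        if r1.shape != r2.shape:
            raise ValueError("label vectors must have equal length")
        return cls(
            a=int(np.sum(r1 & r2)),
            b=int(np.sum(r1 & ~r2)),
            c=int(np.sum(~r1 & r2)),
            d=int(np.sum(~r1 & ~r2)),
        )


def percent_agreement(cm: ConfusionMatrix2x2) -> float:
    """Observed agreement as a percentage, 100·(a+d)/n."""
    if cm.n == 0:
        raise ValueError("empty table: n must be > 0")
    return 100.0 * (cm.a + cm.d) / cm.n


def cohens_kappa(cm: ConfusionMatrix2x2):
    """Cohen's kappa with large-sample SE and 95% CI.

    kappa = (po − pe)/(1 − pe) with po = (a+d)/n and
    pe = ((a+b)(a+c) + (c+d)(b+d))/n²; se = sqrt(po(1−po)/(n(1−pe)²));
    the Wald CI kappa ± 1.96·se is clipped to [−1, 1].
    """
    n = cm.n
    if n == 0:
        raise ValueError("empty table: n must be > 0")
    po = (cm.a + cm.d) / n
    pe = ((cm.a + cm.b) * (cm.a + cm.c) + (cm.c + cm.d) * (cm.b + cm.d)) / n**2
    if pe >= 1.0:
        raise ValueError("expected agreement pe = 1: kappa is undefined")
    kappa = (po - pe) / (1 - pe)
    se = math.sqrt(po * (1 - po) / (n * (1 - pe) ** 2))
    lo = max(-1.0, kappa - Z95 * se)
    hi = min(1.0, kappa + Z95 * se)
    return kappa, se, (lo, hi)


def interpret_kappa(kappa: float) -> str:
    """Band a kappa value: >0.7 good, 0.4–0.7 moderate, <0.4 poor."""
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must be in [-1, 1], got {kappa}")
    if kappa > 0.7:
        return "good"
    if kappa >= 0.4:
        return "moderate"
    return "poor"


@dataclass(frozen=True)
class AgreementResult:
    matrix: ConfusionMatrix2x2
    percent_agreement: float
    kappa: float
    kappa_se: float
    kappa_ci95: tuple
    band: str

    def to_json_dict(self) -> dict:
        return {
            "confusion_matrix": {"a": self.matrix.a, "b": self.matrix.b,
                                 "c": self.matrix.c, "d": self.matrix.d},
            "n": self.matrix.n,
            "percent_agreement": self.percent_agreement,
            "kappa": self.kappa,
            "kappa_se": self.kappa_se,
            "kappa_ci95": list(self.kappa_ci95),
            "band": self.band,
        }


def agreement(cm: ConfusionMatrix2x2) -> AgreementResult:
    """Full inter-rater summary for one 2×2 agreement table."""
    kappa, se, ci = cohens_kappa(cm)
    return AgreementResult(
        matrix=cm,
        percent_agreement=percent_agreement(cm),
        kappa=kappa,
        kappa_se=se,
        kappa_ci95=ci,
        band=interpret_kappa(kappa),
    )


def prevalence_per_100(n_met: int, n_total: int) -> float:
    """Screening yield per 100 patients, rounded half-up to 1 decimal."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_met <= n_total:
        raise ValueError("need 0 <= n_met <= n_total")
    raw = Decimal(100 * n_met) / Decimal(n_total)
    return float(raw.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# 2x2 association


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure × outcome table: a E-/O-, b E-/O+, c E+/O-, d E+/O+.

    Any fixed assignment of the four cells works as long as ``a·d`` pairs
    concordant and ``b·c`` pairs discordant cells; the cross-product ratio
    is then ad/(bc).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("table counts must be non-negative")


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci95: tuple
    corrected: bool  # Haldane–Anscombe +0.5 applied because of a zero cell


def odds_ratio(t: TwoByTwo) -> OddsRatioResult:
    """Cross-product odds ratio ad/(bc) with Wald log-scale 95% CI.

    Zero cells get the Haldane–Anscombe +0.5 continuity correction applied
    to all four cells; the result is flagged ``corrected``.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    oratio = (a * d) / (b * c)
    se_log = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(oratio) - Z95 * se_log)
    hi = math.exp(math.log(oratio) + Z95 * se_log)
    return OddsRatioResult(odds_ratio=oratio, ci95=(lo, hi), corrected=corrected)


def fisher_exact_p(t: TwoByTwo) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of all
    tables with the observed margins no more probable than the observed one."""
    _, p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
    return float(p)


# ---------------------------------------------------------------------------
# logistic regression


def logistic_association(outcome, covariates) -> pd.DataFrame:
    """Multiple logistic regression of a binary outcome on coded covariates.

    Parameters
    ----------
    outcome
        Binary vector (0/1).
    covariates
        DataFrame (or 2-D array) of numerically coded covariates; categorical
        factors must already be reference-coded into dummies.

    Returns
    -------
    DataFrame indexed by covariate with columns ``or_`` (exponentiated
    coefficient), ``ci_lo``, ``ci_hi`` (Wald 95%), and ``p``.

    Raises
    ------
    SeparationError
        When the outcome is perfectly separated by the covariates (the MLE
        does not exist) or the fit otherwise fails to converge.
    """
    import warnings

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import (
        PerfectSeparationError,
        PerfectSeparationWarning,
    )

    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    X = pd.DataFrame(covariates).copy()
    X = X.astype(float)
    Xc = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, Xc)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = model.fit(disp=0, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning,
            np.linalg.LinAlgError) as exc:
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise SeparationError("logistic fit did not converge (possible separation)")
    params = res.params.drop("const")
    conf = res.conf_int().drop("const")
    pvals = res.pvalues.drop("const")
    out = pd.DataFrame({
        "or_": np.exp(params),
        "ci_lo": np.exp(conf[0]),
        "ci_hi": np.exp(conf[1]),
        "p": pvals,
    })
    out.index.name = "covariate"
    return out
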