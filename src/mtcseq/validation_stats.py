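"""Blinded-validation statistics: confusion counts, exact binomial
confidence intervals, and one-sample proportion power.

Sensitivity and specificity of the locked classifier are summarized with
two-sided 95% Clopper-Pearson (exact binomial) intervals; the study's
sample-size argument is a one-sample proportion power analysis with the
arcsine-transformation effect size h = 2*asin(sqrt(p1)) - 2*asin(sqrt(p0)).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .classify import ScoreVector


@dataclass
class PowerStatement:
    p0: float
    p1: float
    n: int
    alpha: float
    sided: str
    power: float


@dataclass
class ValidationReport:
    """Confusion counts with exact intervals and the power statement."""

    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    ci_sens: tuple[float, float]
    ci_spec: tuple[float, float]
    power_statement: PowerStatement

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ci_sens"] = list(self.ci_sens)
        d["ci_spec"] = list(self.ci_spec)
        return d

    def text(self) -> str:
        """Human-readable one-liner in clinical reporting style."""
        ls, us = (100 * b for b in self.ci_sens)
        lp, up = (100 * b for b in self.ci_spec)
        return (
            f"{100 * self.sensitivity:.0f}% sensitivity "
            f"({self.tp}/{self.tp + self.fn}; CI = {ls:.1f}-{us:.1f}%) and "
            f"{100 * self.specificity:.0f}% specificity "
            f"({self.tn}/{self.tn + self.fp}; CI = {lp:.1f}-{up:.1f}%)"
        )


def confusion(calls: ScoreVector | np.ndarray,
              reference: np.ndarray) -> tuple[int, int, int, int]:
    """(tp, fn, tn, fp) against reference labels ("MTC" / "non-MTC")."""
    c = calls.calls if isinstance(calls, ScoreVector) else np.asarray(calls)
    reference = np.asarray(reference)
    if len(reference) == 0:
        raise ValueError("empty cohort")
    if len(c) != len(reference):
        raise ValueError("one reference label per sample required")
    bad = set(reference) - {"MTC", "non-MTC"}
    if bad:
        raise ValueError(f"sample without valid reference label: {sorted(bad)}")
    pos = c == "positive"
    is_mtc = reference == "MTC"
    tp = int(np.sum(pos & is_mtc))
    fn = int(np.sum(~pos & is_mtc))
    tn = int(np.sum(~pos & ~is_mtc))
    fp = int(np.sum(pos & ~is_mtc))
    return tp, fn, tn, fp


def clopper_pearson(successes: int, trials: int,
                    level: float = 0.95) -> tuple[float, float]:
    """Two-sided exact (Clopper-Pearson) binomial interval.

    Beta-quantile construction; the x = 0 and x = n edges use the one-sided
    closed forms (lower = 0 and upper = 1 respectively, with the other
    bound (alpha/2)^(1/n)-style).
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials and trials >= 1")
    alpha = 1.0 - level
    x, n = successes, trials
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lower, upper


def proportion_power(p0: float, p1: float, n: int, alpha: float = 0.05,
                     sided: str = "greater") -> float:
    """Power of the one-sample proportion test, arcsine approximation.

    Effect size h = 2*asin(sqrt(p1)) - 2*asin(sqrt(p0)); one-sided power is
    Phi(h*sqrt(n) - z_{1-alpha}), the two-sided analog replaces alpha by
    alpha/2 (and accrues both tails).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 < p0 < 1) or not (0 < p1 <= 1):
        raise ValueError("proportions must be in (0, 1] with p0 < 1")
    if sided not in ("greater", "two-sided"):
        raise ValueError("sided must be 'greater' or 'two-sided'")
    if sided == "greater" and p1 < p0:
        raise ValueError("p1 < p0 contradicts a one-sided 'greater' test")
    h = 2.0 * np.arcsin(np.sqrt(p1)) - 2.0 * np.arcsin(np.sqrt(p0))
    root_n = np.sqrt(n)
    if sided == "greater":
        return float(stats.norm.cdf(h * root_n - stats.norm.ppf(1 - alpha)))
    z = stats.norm.ppf(1 - alpha / 2)
    return float(stats.norm.cdf(h * root_n - z)
                 + stats.norm.cdf(-h * root_n - z))


def validation_report(calls: ScoreVector, reference: np.ndarray,
                      level: float = 0.95, power_p0: float = 0.90,
                      power_alpha: float = 0.05) -> ValidationReport:
    """Full validation summary of a locked model on a blinded cohort.

    The power statement answers the design question: with the observed
    number of disease cases, what was the power to reject a null
    sensitivity of ``power_p0`` had the classifier achieved 100%?
    """
    tp, fn, tn, fp = confusion(calls, reference)
    n_pos = tp + fn
    n_neg = tn + fp
    sens = tp / n_pos if n_pos else float("nan")
    spec = tn / n_neg if n_neg else float("nan")
    power = proportion_power(power_p0, 1.0, n_pos, power_alpha, "greater")
    return ValidationReport(
        tp=tp, fn=fn, tn=tn, fp=fp,
        sensitivity=sens, specificity=spec,
        ci_sens=clopper_pearson(tp, n_pos, level),
        ci_spec=clopper_pearson(tn, n_neg, level),
        power_statement=PowerStatement(
            p0=power_p0, p1=1.0, n=n_pos, alpha=power_alpha,
            sided="greater", power=power),
    )
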