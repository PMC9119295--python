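"""Evaluation battery: confusion metrics, paired tests, covariate screens.

Gathers every statistic used to judge the graininess call against the
hCG outcome and against the Gardner >=3BB comparator: the confusion
matrix with accuracy / precision / recall / specificity and the F-beta
family (beta = 0.5, 1, 2), McNemar's chi-squared for the paired
comparison of two classifiers, the two-proportion chi-squared test
(Yates-corrected, as in R's ``prop.test``), Welch / Student t-tests, and
the Pearson test of no correlation.

Rates and F-measures are displayed at 2 decimals and abortion rates at
the nearest percent; full-precision values are always retained in the
JSON report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "PairedComparison",
    "EvalReport",
    "confusion",
    "metrics",
    "fbeta",
    "mcnemar",
    "paired_comparison",
    "prop_test_2x2",
    "t_tests",
    "correlation_screen",
    "evaluate_predictor",
]

P_FLOOR = 2.2e-16  # R's default display floor for tiny p-values


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 tally; positive class = hCG-positive, predicted-positive =
    grainy (or Gardner >= 3BB)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricReport:
    """Rates and the F-beta family for one predictor.

    Metrics with a zero denominator are ``None`` and listed in
    ``undefined`` rather than raising.
    """

    accuracy: float | None
    precision: float | None
    recall: float | None
    specificity: float | None
    f_half: float | None
    f1: float | None
    f2: float | None
    rounding: int = 2
    undefined: list[str] = field(default_factory=list)

    def rounded(self) -> dict[str, float | None]:
        out = {}
        for name in ("accuracy", "precision", "recall", "specificity",
                     "f_half", "f1", "f2"):
            v = getattr(self, name)
            out[name] = None if v is None else round(v, self.rounding)
        return out


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionMatrix:
    """Standard 2x2 tally of binary prediction against binary truth."""
    pred = np.asarray(pred).astype(int)
    truth = np.asarray(truth).astype(int)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("pred and truth must be aligned 1-D vectors")
    if pred.size == 0:
        raise ValueError("empty vectors")
    return ConfusionMatrix(
        tp=int(((pred == 1) & (truth == 1)).sum()),
        fp=int(((pred == 1) & (truth == 0)).sum()),
        fn=int(((pred == 0) & (truth == 1)).sum()),
        tn=int(((pred == 0) & (truth == 0)).sum()),
    )


def fbeta(precision: float, recall: float, beta: float) -> float:
    """F-beta = (1 + b^2) P R / (b^2 P + R); beta<1 weights precision,
    beta>1 weights recall."""
    denom = beta ** 2 * precision + recall
    if denom <= 0:
        raise ValueError("F-beta undefined when beta^2*P + R == 0")
    return (1 + beta ** 2) * precision * recall / denom


def metrics(cm: ConfusionMatrix, rounding: int = 2) -> MetricReport:
    """Accuracy, precision, recall, specificity and F_{0.5,1,2} from a 2x2."""
    undefined: list[str] = []

    def rate(num: int, den: int, name: str) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    accuracy = rate(cm.tp + cm.tn, cm.total, "accuracy")
    precision = rate(cm.tp, cm.tp + cm.fp, "precision")
    recall = rate(cm.tp, cm.tp + cm.fn, "recall")
    specificity = rate(cm.tn, cm.tn + cm.fp, "specificity")
    fs: dict[float, float | None] = {}
    for beta in (0.5, 1.0, 2.0):
        name = {0.5: "f_half", 1.0: "f1", 2.0: "f2"}[beta]
        if (precision is None or recall is None
                or beta ** 2 * precision + recall <= 0):
            undefined.append(name)
            fs[beta] = None
        else:
            fs[beta] = fbeta(precision, recall, beta)
    return MetricReport(accuracy=accuracy, precision=precision, recall=recall,
                        specificity=specificity, f_half=fs[0.5], f1=fs[1.0],
                        f2=fs[2.0], rounding=rounding, undefined=undefined)


def mcnemar(only_a_correct: int, only_b_correct: int,
            correction: bool = True) -> tuple[float, float]:
    """McNemar's chi-squared from the discordant-pair counts.

    With the continuity correction (default, as in R's ``mcnemar.test``)
    chi2 = (|b - c| - 1)^2 / (b + c); without, chi2 = (b - c)^2 / (b + c).
    p is the upper tail of chi-squared with 1 df. |b - c| - 1 is clamped
    at zero so the correction can only move the statistic toward the
    null (R's literal formula gives chi2 > 0 when b == c).
    """
    b, c = int(only_a_correct), int(only_b_correct)
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    if b + c == 0:
        raise ValueError("McNemar undefined with no discordant pairs")
    if correction:
        chi2 = max(abs(b - c) - 1, 0) ** 2 / (b + c)
    else:
        chi2 = (b - c) ** 2 / (b + c)
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class PairedComparison:
    """Per-embryo agreement of two classifiers plus McNemar's test."""

    both_correct: int
    only_a_correct: int
    only_b_correct: int
    both_wrong: int
    chi2: float | None
    p: float | None

    @property
    def total(self) -> int:
        return (self.both_correct + self.only_a_correct
                + self.only_b_correct + self.both_wrong)


def paired_comparison(pred_a: np.ndarray, pred_b: np.ndarray,
                      truth: np.ndarray,
                      correction: bool = True) -> PairedComparison:
    """Compare two predictors on the same embryos via McNemar's test."""
    pred_a = np.asarray(pred_a).astype(int)
    pred_b = np.asarray(pred_b).astype(int)
    truth = np.asarray(truth).astype(int)
    if not (pred_a.shape == pred_b.shape == truth.shape):
        raise ValueError("vectors must be aligned")
    a_ok = pred_a == truth
    b_ok = pred_b == truth
    counts = dict(
        both_correct=int((a_ok & b_ok).sum()),
        only_a_correct=int((a_ok & ~b_ok).sum()),
        only_b_correct=int((~a_ok & b_ok).sum()),
        both_wrong=int((~a_ok & ~b_ok).sum()),
    )
    if counts["only_a_correct"] + counts["only_b_correct"] == 0:
        return PairedComparison(**counts, chi2=None, p=None)
    chi2, p = mcnemar(counts["only_a_correct"], counts["only_b_correct"],
                      correction=correction)
    return PairedComparison(**counts, chi2=chi2, p=p)


def prop_test_2x2(x1: int, n1: int, x2: int, n2: int,
                  correction: bool = True) -> tuple[float, float, str]:
    """Chi-squared test of equal proportions (R ``prop.test`` style).

    Returns ``(chi2, p, display)`` where ``display`` renders tiny
    p-values as ``"< 2.2e-16"``.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("trial counts must be positive")
        if not 0 <= x <= n:
            raise ValueError("successes must lie in [0, n]")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        # degenerate margins: proportions identical by construction
        return 0.0, 1.0, "1"
    res = stats.chi2_contingency(table, correction=correction)
    chi2, p = float(res.statistic), float(res.pvalue)
    display = f"< {P_FLOOR:g}" if p < P_FLOOR else f"{p:.3g}"
    return chi2, p, display


def t_tests(a: np.ndarray, b: np.ndarray,
            variant: str = "welch") -> tuple[float, float, float]:
    """Two-sided two-sample t-test; ``variant`` is ``"welch"`` or
    ``"student"``. Returns (t, df, p); Welch df by Welch–Satterthwaite."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    equal_var = variant == "student"
    if equal_var and a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("degenerate variance for Student's t-test")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def correlation_screen(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the two-sided test of no correlation
    (t = r sqrt((n-2)/(1-r^2)))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need aligned samples of size >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance sample")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class AbortionComparison:
    """Abortion rate among predicted-positive implantations vs all
    implantations."""

    events_predicted: int
    n_predicted: int
    events_actual: int
    n_actual: int
    rate_predicted: float
    rate_actual: float
    chi2: float | None
    p: float | None

    def rate_predicted_pct(self) -> int:
        return round(100 * self.rate_predicted)

    def rate_actual_pct(self) -> int:
        return round(100 * self.rate_actual)


@dataclass
class EvalReport:
    """Bundled evaluation of one predictor against the hCG outcome."""

    confusion: ConfusionMatrix
    metrics: MetricReport
    abortion: AbortionComparison | None = None

    def to_dict(self) -> dict:
        d = {
            "confusion": {"tp": self.confusion.tp, "fp": self.confusion.fp,
                          "fn": self.confusion.fn, "tn": self.confusion.tn},
            "metrics": {
                name: getattr(self.metrics, name)
                for name in ("accuracy", "precision", "recall", "specificity",
                             "f_half", "f1", "f2")},
            "metrics_rounded": self.metrics.rounded(),
            "undefined": self.metrics.undefined,
        }
        if self.abortion is not None:
            d["abortion"] = {
                "events_predicted": self.abortion.events_predicted,
                "n_predicted": self.abortion.n_predicted,
                "events_actual": self.abortion.events_actual,
                "n_actual": self.abortion.n_actual,
                "rate_predicted": self.abortion.rate_predicted,
                "rate_actual": self.abortion.rate_actual,
                "rate_predicted_pct": self.abortion.rate_predicted_pct(),
                "rate_actual_pct": self.abortion.rate_actual_pct(),
                "chi2": self.abortion.chi2,
                "p": self.abortion.p,
            }
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def evaluate_predictor(pred: np.ndarray, truth: np.ndarray,
                       abortion: np.ndarray | None = None,
                       rounding: int = 2) -> EvalReport:
    """Confusion + metric family, plus the abortion-rate comparison.

    When per-embryo abortion outcomes are supplied (observed only for
    truth-positive embryos; missing elsewhere), the abortion rate among
    predicted-positive AND truth-positive embryos is compared with the
    rate among all truth-positive embryos by the two-proportion test.
    """
    pred = np.asarray(pred).astype(int)
    truth = np.asarray(truth).astype(int)
    cm = confusion(pred, truth)
    rep = metrics(cm, rounding=rounding)
    ab = None
    if abortion is not None:
        abortion = np.asarray(abortion, dtype=float)
        if abortion.shape != truth.shape:
            raise ValueError("abortion vector not aligned")
        actual_mask = (truth == 1) & np.isfinite(abortion)
        pred_mask = actual_mask & (pred == 1)
        n_actual = int(actual_mask.sum())
        n_pred = int(pred_mask.sum())
        if n_actual > 0 and n_pred > 0:
            ev_actual = int(abortion[actual_mask].sum())
            ev_pred = int(abortion[pred_mask].sum())
            if pred_mask.sum() == actual_mask.sum():
                chi2, p = 0.0, 1.0  # identical subsets: rates coincide
            else:
                chi2, p, _ = prop_test_2x2(ev_pred, n_pred, ev_actual, n_actual)
            ab = AbortionComparison(
                events_predicted=ev_pred, n_predicted=n_pred,
                events_actual=ev_actual, n_actual=n_actual,
                rate_predicted=ev_pred / n_pred, rate_actual=ev_actual / n_actual,
                chi2=chi2, p=p)
    return EvalReport(confusion=cm, metrics=rep, abortion=ab)
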