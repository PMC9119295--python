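"""Graininess classification and the Gardner >=3BB comparator rule.

For each screened component an ROC analysis over the embryo scores
yields an oriented threshold; an embryo is called *grainy* when it
strictly exceeds the threshold on at least one rule component (an OR
rule). Orientation is chosen per component so that the grainy side is
the side with the higher mean score in the hCG-positive group.

The comparator is the conventional morphological standard: a blastocyst
is "good quality" when its Gardner score is >= 3BB, i.e. expansion stage
at least 3 with inner-cell-mass and trophectoderm grades both A or B.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from .eigen import EigenModel
from .screening import ComponentScreen

__all__ = [
    "RocResult",
    "RuleComponent",
    "GraininessRule",
    "GardnerScore",
    "GardnerParseError",
    "roc_analysis",
    "derive_rule",
    "combined_scores",
    "combined_auc",
    "classify_graininess",
    "parse_gardner",
    "gardner_at_least_3bb",
]


@dataclass
class RocResult:
    """ROC curve, AUC and the chosen operating point for one score vector.

    ``orientation`` is +1 when larger scores are called positive, -1 when
    the scale had to be flipped; ``chosen_cutoff`` is expressed on the
    *original* score scale, so the positive call is
    ``orientation * (score - chosen_cutoff) > 0``.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    chosen_cutoff: float
    orientation: int


@dataclass(frozen=True)
class RuleComponent:
    index: int  # 1-based component index
    cutoff: float  # original score scale
    orientation: int  # +1 / -1
    scale: float  # per-component score SD, for standardized exceedance
    auc: float


@dataclass
class GraininessRule:
    """Oriented thresholds on selected components, combined by OR."""

    components: list[RuleComponent]
    criterion: str = "youden"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("a graininess rule needs at least one component")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "criterion": self.criterion,
            "alpha": self.alpha,
            "components": [
                {"index": c.index, "cutoff": c.cutoff,
                 "orientation": c.orientation, "scale": c.scale, "auc": c.auc}
                for c in self.components],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GraininessRule":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            components=[RuleComponent(**c) for c in payload["components"]],
            criterion=payload.get("criterion", "youden"),
            alpha=payload.get("alpha", 0.05))


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann–Whitney AUC with ties counted as 1/2."""
    n1 = int(labels.sum())
    n0 = labels.size - n1
    ranks = rankdata(scores)
    u = float(ranks[labels == 1].sum()) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def roc_analysis(scores: np.ndarray, labels: np.ndarray,
                 orientation: int | None = None,
                 criterion: str = "youden") -> RocResult:
    """ROC analysis of one continuous score against a binary outcome.

    Candidate cutoffs are the midpoints between consecutive distinct
    sorted scores plus -inf and +inf. The AUC uses the rank
    (Mann–Whitney) formula with tie correction. When ``orientation`` is
    None it is chosen so AUC >= 0.5 (and recorded). The operating point
    maximizes Youden's J = TPR - FPR (criterion ``"youden"``) or the
    distance to the top-left corner (``"closest-topleft"``); J ties break
    toward higher TPR, then smaller |cutoff|.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be aligned")
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    if criterion not in ("youden", "closest-topleft"):
        raise ValueError(f"unknown cutoff criterion {criterion!r}")

    if orientation is None:
        auc_raw = _rank_auc(scores, labels)
        orientation = 1 if auc_raw >= 0.5 else -1
    elif orientation not in (1, -1):
        raise ValueError("orientation must be +1 or -1")
    oriented = orientation * scores
    auc = _rank_auc(oriented, labels)

    distinct = np.unique(oriented)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    cuts = np.concatenate([[-np.inf], mids, [np.inf]])
    # positive call: oriented score strictly above the cutoff
    calls = oriented[None, :] > cuts[:, None]
    tp = (calls & (labels == 1)).sum(axis=1)
    fp = (calls & (labels == 0)).sum(axis=1)
    tpr = tp / n1
    fpr = fp / n0

    if criterion == "youden":
        goodness = tpr - fpr
    else:
        goodness = -np.hypot(1.0 - tpr, fpr)
    # tie-breaks: higher TPR, then smaller |cutoff|
    order = np.lexsort((np.abs(cuts), -tpr, -goodness))
    chosen_t = float(cuts[order[0]])
    chosen = orientation * chosen_t  # back to original score scale

    return RocResult(thresholds=cuts, tpr=tpr, fpr=fpr, auc=float(auc),
                     chosen_cutoff=chosen, orientation=int(orientation))


def derive_rule(model: EigenModel, screens: list[ComponentScreen],
                labels: np.ndarray, criterion: str = "youden",
                alpha: float = 0.05, max_components: int | None = 2,
                min_relative_auc: float = 0.5,
                fallback_top: int = 0) -> GraininessRule:
    """Build the OR-rule from the KS-selected components.

    For each selected component the grainy orientation points toward the
    higher hCG-positive mean score; the cutoff comes from
    :func:`roc_analysis` under that orientation.

    An OR rule loses specificity with every threshold it adds, so when
    the screen selects more than ``max_components`` components only the
    most outcome-informative ones — highest oriented per-component AUC —
    are kept; default 2, the standard two-axis rule. (A KS hit can be a
    pure spread difference with AUC near 0.5, useless for a one-sided
    threshold.) Components reaching less than ``min_relative_auc`` of
    the best component's discrimination (AUC - 0.5) are also dropped, so
    a weak axis cannot dilute a strong one; the best component is always
    kept. Pass ``max_components=None`` and ``min_relative_auc=0`` to
    keep every selected component. If no component was selected and
    ``fallback_top`` > 0, the top components by KS D are used instead
    (the fallback is recorded in the rule's criterion tag).
    """
    labels = np.asarray(labels).astype(int)
    chosen = [s for s in screens if s.selected]
    tag = criterion
    if not chosen and fallback_top > 0:
        chosen = sorted(screens, key=lambda s: -s.ks_D)[:fallback_top]
        tag = f"{criterion}+topD-fallback"
    if not chosen:
        raise ValueError("no component selected at the screening level")

    comps = []
    pos = labels == 1
    for s in chosen:
        col = model.scores[:, s.component_index - 1]
        orientation = 1 if col[pos].mean() >= col[~pos].mean() else -1
        roc = roc_analysis(col, labels, orientation=orientation,
                           criterion=criterion)
        comps.append(RuleComponent(
            index=s.component_index, cutoff=roc.chosen_cutoff,
            orientation=orientation, scale=float(col.std(ddof=1)),
            auc=roc.auc))
    comps = sorted(comps, key=lambda c: (-c.auc, c.index))
    if max_components is not None:
        comps = comps[:max_components]
    if min_relative_auc > 0 and len(comps) > 1:
        floor = 0.5 + min_relative_auc * (comps[0].auc - 0.5)
        comps = [comps[0]] + [c for c in comps[1:] if c.auc >= floor]
    comps = sorted(comps, key=lambda c: c.index)
    return GraininessRule(components=comps, criterion=tag, alpha=alpha)


def _rule_scores(scores: np.ndarray, rule: GraininessRule) -> np.ndarray:
    """Oriented exceedance per rule component, columns aligned to the rule."""
    scores = np.asarray(scores, dtype=float)
    cols = []
    for c in rule.components:
        if not 1 <= c.index <= scores.shape[1]:
            raise ValueError(f"component {c.index} missing from the score matrix")
        cols.append(c.orientation * (scores[:, c.index - 1] - c.cutoff))
    return np.stack(cols, axis=1)


def combined_scores(scores: np.ndarray, rule: GraininessRule,
                    method: str = "max_exceedance",
                    labels: np.ndarray | None = None) -> np.ndarray:
    """One scalar score per embryo combining the rule components.

    ``"max_exceedance"`` (default): the maximum over components of the
    orientation-aligned standardized exceedance
    ``orientation * (score - cutoff) / scale`` — the continuous analogue
    of the OR rule. ``"logistic"``: a logistic regression on the oriented
    standardized scores (requires ``labels``).
    """
    exceed = _rule_scores(scores, rule)
    scales = np.array([max(c.scale, 1e-12) for c in rule.components])
    standardized = exceed / scales
    if method == "max_exceedance":
        return standardized.max(axis=1)
    if method == "logistic":
        if labels is None:
            raise ValueError("logistic combination requires labels")
        from sklearn.linear_model import LogisticRegression
        lr = LogisticRegression(C=1e6, max_iter=1000)
        lr.fit(standardized, np.asarray(labels).astype(int))
        return lr.decision_function(standardized)
    raise ValueError(f"unknown combination method {method!r}")


def combined_auc(scores: np.ndarray, labels: np.ndarray, rule: GraininessRule,
                 method: str = "max_exceedance") -> float:
    """AUC of the combined (multi-component) score against the outcome."""
    if len(rule.components) < 1:
        raise ValueError("rule has no components")
    combo = combined_scores(scores, rule, method=method, labels=labels)
    return roc_analysis(combo, np.asarray(labels).astype(int),
                        orientation=1).auc


def classify_graininess(scores: np.ndarray, rule: GraininessRule) -> np.ndarray:
    """OR-rule call: grainy iff any oriented score strictly exceeds its cutoff.

    Boundary values (score exactly at the cutoff) are non-grainy.
    """
    return (_rule_scores(scores, rule) > 0).any(axis=1).astype(int)


class GardnerParseError(ValueError):
    """Raised when a Gardner score string cannot be parsed."""


@dataclass(frozen=True)
class GardnerScore:
    """Parsed Gardner score: expansion stage 1–6 plus ICM/TE grades.

    ICM and TE letter grades (A/B/C) exist only from the full-blastocyst
    stage onward (expansion >= 3); earlier stages carry the bare
    expansion digit.
    """

    expansion: int
    icm: str | None = None
    te: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.expansion <= 6:
            raise GardnerParseError(
                f"expansion {self.expansion} out of range 1..6")
        has_grades = self.icm is not None and self.te is not None
        if self.expansion >= 3 and not has_grades:
            raise GardnerParseError(
                "expansion >= 3 requires ICM and TE grades")
        if self.expansion < 3 and (self.icm is not None or self.te is not None):
            raise GardnerParseError(
                "ICM/TE grades are not assigned below expansion 3")
        for grade in (self.icm, self.te):
            if grade is not None and grade not in "ABC":
                raise GardnerParseError(f"grade {grade!r} not in A/B/C")

    def __str__(self) -> str:
        return f"{self.expansion}{self.icm or ''}{self.te or ''}"


_GARDNER_RE = re.compile(r"^\s*(\d)\s*(?:([A-Ca-c])\s*([A-Ca-c]))?\s*$")


def parse_gardner(text: str) -> GardnerScore:
    """Parse a Gardner score string such as ``"4AB"`` or ``"2"``.

    Case-insensitive, whitespace-tolerant. Expansion must be 1–6;
    ICM/TE grades are required for expansion >= 3 and forbidden below.
    """
    m = _GARDNER_RE.match(str(text))
    if not m:
        raise GardnerParseError(f"malformed Gardner score {text!r}")
    expansion = int(m.group(1))
    icm = m.group(2).upper() if m.group(2) else None
    te = m.group(3).upper() if m.group(3) else None
    try:
        return GardnerScore(expansion=expansion, icm=icm, te=te)
    except GardnerParseError as exc:
        raise GardnerParseError(f"invalid Gardner score {text!r}: {exc}") from exc


def gardner_at_least_3bb(score: GardnerScore | str) -> bool:
    """Good-quality call: expansion >= 3 with ICM and TE both A or B.

    Expansion-only scores (stages 1–2, which carry no ICM/TE grades) are
    automatically below 3BB.
    """
    if isinstance(score, str):
        score = parse_gardner(score)
    return (score.expansion >= 3
            and score.icm in ("A", "B")
            and score.te in ("A", "B"))
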