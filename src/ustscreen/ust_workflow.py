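"""Hierarchical universal-screening workflow over miRNA pair ratios.

The screening hierarchy has four decision nodes, each a pair-combination
detector fitted on the appropriate subject subsets:

* ``gi_vs_control`` — GI-system patients vs controls, screened over the
  GI-enriched + ubiquitous sub-panel;
* ``pulmonary_vs_control`` — pulmonary-system patients vs controls, over the
  pulmonary-enriched + ubiquitous sub-panel;
* ``gi_vs_pulmonary`` — GI patients vs pulmonary patients, full panel;
* ``cancer_vs_inflammation`` — all cancers vs all inflammatory diseases,
  full panel.

Applying the model, each system node votes independently (a subject may be
flagged for one, both, or neither system); only flagged subjects proceed to
the cancer-vs-inflammation node — a subject with no detected pathology gets
no type call. The test deliberately stops at organ system + broad pathology
type: it screens, it does not diagnose a specific disease.

Also here: the population-screening arithmetic (expected true/false positives
and PPV for a test of given sensitivity/specificity applied to a population
with given prevalence) that motivates organ-level screening over large
batteries of disease-specific tests.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ValidationError
from .panel_io import CqDataset, aggregate_replicates
from .pair_ratio import all_pair_ratios, pair_label
from .pair_screen import screen_pairs
from .roc_analysis import PairCombinationClassifier

NODES = ("gi_vs_control", "pulmonary_vs_control", "gi_vs_pulmonary", "cancer_vs_inflammation")

#: enrichment classes screened at each system-detection node
_NODE_CLASSES = {
    "gi_vs_control": ("gi_enriched", "ubiquitous"),
    "pulmonary_vs_control": ("pulmonary_enriched", "ubiquitous"),
    "gi_vs_pulmonary": None,  # full panel
    "cancer_vs_inflammation": None,
}


@dataclass
class NodeDetector:
    """Frozen parameters of one decision node's pair-combination detector."""

    trained: bool
    members: list[tuple[str, str]] = field(default_factory=list)
    means: list[float] = field(default_factory=list)
    sds: list[float] = field(default_factory=list)
    signs: list[float] = field(default_factory=list)
    weights: list[float] = field(default_factory=list)
    cutoff: float = float("nan")
    auc: float = float("nan")
    accuracy: float = float("nan")
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    panel_size: int = 0
    n_case: int = 0
    n_control: int = 0


@dataclass
class UstModel:
    """Fitted hierarchy of pair-based detectors, JSON-serializable."""

    detectors: dict[str, NodeDetector]
    family_alpha: float
    pairs_per_node: int
    training_summary: dict[str, list[dict]] = field(default_factory=dict)

    @property
    def trained_nodes(self) -> list[str]:
        return [n for n in NODES if self.detectors[n].trained]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "family_alpha": self.family_alpha,
            "pairs_per_node": self.pairs_per_node,
            "detectors": {n: asdict(d) for n, d in self.detectors.items()},
            "training_summary": self.training_summary,
        }
        text = json.dumps(payload, indent=2, allow_nan=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "UstModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        detectors = {}
        for name, d in payload["detectors"].items():
            d = dict(d)
            d["members"] = [tuple(m) for m in d["members"]]
            detectors[name] = NodeDetector(**d)
        return cls(
            detectors=detectors,
            family_alpha=payload["family_alpha"],
            pairs_per_node=payload["pairs_per_node"],
            training_summary=payload.get("training_summary", {}),
        )


@dataclass
class UstCall:
    """Per-subject screening outcome."""

    subject_id: str
    flagged_systems: tuple[str, ...]
    pathology_type: str  # cancer | inflammation | undetermined
    node_scores: dict[str, dict]


@dataclass(frozen=True)
class ScreeningScenario:
    """A population, a disease prevalence, and a test's operating point."""

    population_size: float
    prevalence: float
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValidationError("population_size must be >= 1")
        for name in ("prevalence", "sensitivity", "specificity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class ScreeningProjection:
    expected_true_positives: float
    expected_false_positives: float
    ppv: float  # NaN when no positives at all


def screening_projection(s: ScreeningScenario) -> ScreeningProjection:
    """Expected screening outcome in a population.

    TP = N * prevalence * sensitivity; FP = N * (1-prevalence) *
    (1-specificity); PPV = TP / (TP + FP) (missing when both are zero).
    The arithmetic behind "a 100%-sensitive, 99%-specific test for a
    1-in-10,000 disease applied to a million people finds its 100 cases and
    alarms ~10,000 healthy subjects".
    """
    tp = s.population_size * s.prevalence * s.sensitivity
    fp = s.population_size * (1.0 - s.prevalence) * (1.0 - s.specificity)
    ppv = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    return ScreeningProjection(tp, fp, ppv)


# ---------------------------------------------------------------------------
# node bookkeeping


def _node_subsets(subjects: pd.DataFrame) -> dict[str, tuple[pd.Index, pd.Index]]:
    """(case_ids, control_ids) per node from the cohort sheet."""
    gi = subjects.index[subjects["organ_system"] == "gi"]
    pulm = subjects.index[subjects["organ_system"] == "pulmonary"]
    ctrl = subjects.index[
        (subjects["organ_system"] == "none") & (subjects["pathology_type"] == "none")
    ]
    cancer = subjects.index[subjects["pathology_type"] == "cancer"]
    infl = subjects.index[subjects["pathology_type"] == "inflammation"]
    return {
        "gi_vs_control": (gi, ctrl),
        "pulmonary_vs_control": (pulm, ctrl),
        "gi_vs_pulmonary": (gi, pulm),
        "cancer_vs_inflammation": (cancer, infl),
    }


def _node_panel(ds: CqDataset, node: str) -> list[str]:
    classes = _NODE_CLASSES[node]
    if classes is None:
        return ds.mirna_names
    cls = ds.panel_classes()
    return [m for m in ds.mirna_names if cls[m] in classes]


def _ensure_aggregated(ds: CqDataset) -> CqDataset:
    return ds if ds.aggregated is not None else aggregate_replicates(ds)


# ---------------------------------------------------------------------------
# estimator


class UstClassifier(BaseEstimator):
    """Sklearn-style estimator for the hierarchical screening test.

    ``fit`` takes a :class:`CqDataset` (labels travel inside the dataset's
    cohort sheet, so y is unused and accepted only for API compatibility);
    ``predict`` returns one :class:`UstCall` per subject. Training is fully
    deterministic: screening, pair selection and cutoff placement involve no
    randomness.
    """

    def __init__(self, family_alpha: float = 0.05, pairs_per_node: int = 3,
                 combination_method: str = "mean"):
        self.family_alpha = family_alpha
        self.pairs_per_node = pairs_per_node
        self.combination_method = combination_method

    def fit(self, ds: CqDataset, y=None):
        if self.pairs_per_node < 1:
            raise ValidationError("pairs_per_node must be >= 1")
        ds = _ensure_aggregated(ds)
        subjects = ds.subjects_frame()
        subsets = _node_subsets(subjects)
        detectors: dict[str, NodeDetector] = {}
        summary: dict[str, list[dict]] = {}
        for node in NODES:
            case_ids, ctrl_ids = subsets[node]
            panel = _node_panel(ds, node)
            detector = NodeDetector(trained=False, panel_size=len(panel))
            if len(case_ids) >= 2 and len(ctrl_ids) >= 2 and len(panel) >= 2:
                sub = ds.aggregated.loc[list(case_ids) + list(ctrl_ids), panel]
                matrix = all_pair_ratios(sub)
                labels = pd.Series(
                    [True] * len(case_ids) + [False] * len(ctrl_ids), index=sub.index
                )
                results = screen_pairs(
                    matrix, labels, family_alpha=self.family_alpha, panel_size=len(panel)
                )
                summary[node] = [
                    {"pair": r.label, "p_value": r.p_value, "auc": r.auc,
                     "significant": r.significant}
                    for r in results[: max(self.pairs_per_node, 5)]
                ]
                members = [r.pair for r in results if r.significant][: self.pairs_per_node]
                if members:
                    clf = PairCombinationClassifier(
                        members=members, method=self.combination_method
                    ).fit(matrix.values, labels)
                    detector = NodeDetector(
                        trained=True,
                        members=[tuple(m) for m in clf.members_],
                        means=[float(v) for v in clf.means_],
                        sds=[float(v) for v in clf.sds_],
                        signs=[float(v) for v in clf.signs_],
                        weights=[float(v) for v in clf.weights_],
                        cutoff=float(clf.cutoff_),
                        auc=float(clf.auc_),
                        accuracy=float(clf.accuracy_),
                        sensitivity=float(clf.sensitivity_),
                        specificity=float(clf.specificity_),
                        panel_size=len(panel),
                        n_case=len(case_ids),
                        n_control=len(ctrl_ids),
                    )
            if not detector.trained:
                warnings.warn(f"UST node {node!r} untrained (no significant pair or missing class)")
            detectors[node] = detector
        self.model_ = UstModel(
            detectors=detectors,
            family_alpha=self.family_alpha,
            pairs_per_node=self.pairs_per_node,
            training_summary=summary,
        )
        if not any(d.trained for d in detectors.values()):
            warnings.warn("no UST node could be trained")
        return self

    def predict(self, ds: CqDataset) -> list[UstCall]:
        if not hasattr(self, "model_"):
            raise ValidationError("UstClassifier is not fitted")
        return apply_ust(self.model_, ds)


def node_scores(detector: NodeDetector, aggregated: pd.DataFrame) -> pd.Series:
    """Combined score per subject for one node (NaN where the node abstains)."""
    if not detector.trained:
        return pd.Series(np.nan, index=aggregated.index)
    zs = []
    for (num, den), mean, sd, sign in zip(
        detector.members, detector.means, detector.sds, detector.signs
    ):
        if num not in aggregated.columns or den not in aggregated.columns:
            return pd.Series(np.nan, index=aggregated.index)
        # log10 ratio straight from the Cq difference: log10(2^-dCq * 100)
        logs = -(aggregated[num] - aggregated[den]) * math.log10(2.0) + 2.0
        z = sign * (logs - mean) / (sd if sd > 0 else 1.0)
        zs.append(z if sd > 0 else z * 0.0)
    z = pd.concat(zs, axis=1)
    score = z.to_numpy() @ np.asarray(detector.weights)
    score = pd.Series(score, index=aggregated.index)
    score[z.isna().any(axis=1)] = np.nan
    return score


def apply_ust(model: UstModel, ds: CqDataset) -> list[UstCall]:
    """Run the hierarchical workflow on every subject in the dataset.

    System nodes vote pathology/no-pathology by comparing the combined score
    to the node cutoff (higher = more case-like). Subjects flagged for at
    least one system proceed to cancer-vs-inflammation typing; others remain
    untyped. Nodes abstain for subjects missing any detector miRNA.
    """
    if not any(model.detectors[n].trained for n in ("gi_vs_control", "pulmonary_vs_control")):
        raise ValidationError("model has no trained system-detection node")
    ds = _ensure_aggregated(ds)
    agg = ds.aggregated
    scores = {node: node_scores(model.detectors[node], agg) for node in NODES}

    calls: list[UstCall] = []
    for sid in agg.index:
        detail: dict[str, dict] = {}
        flagged: list[str] = []
        for node, system in (("gi_vs_control", "gi"), ("pulmonary_vs_control", "pulmonary")):
            det = model.detectors[node]
            s = scores[node].get(sid, np.nan)
            abstained = (not det.trained) or (s != s)
            vote = bool(s > det.cutoff) if not abstained else None
            detail[node] = {"score": None if s != s else float(s),
                            "cutoff": det.cutoff if det.trained else None,
                            "vote": vote, "abstained": abstained}
            if vote:
                flagged.append(system)
        ptype = "undetermined"
        if flagged:
            det = model.detectors["cancer_vs_inflammation"]
            s = scores["cancer_vs_inflammation"].get(sid, np.nan)
            abstained = (not det.trained) or (s != s)
            vote = bool(s > det.cutoff) if not abstained else None
            detail["cancer_vs_inflammation"] = {
                "score": None if s != s else float(s),
                "cutoff": det.cutoff if det.trained else None,
                "vote": vote, "abstained": abstained,
            }
            if not abstained:
                ptype = "cancer" if vote else "inflammation"
        calls.append(
            UstCall(
                subject_id=str(sid),
                flagged_systems=tuple(flagged),
                pathology_type=ptype,
                node_scores=detail,
            )
        )
    return calls


def fit_ust(ds: CqDataset, family_alpha: float = 0.05, pairs_per_node: int = 3) -> UstModel:
    """Thin functional wrapper over :class:`UstClassifier`."""
    return UstClassifier(family_alpha=family_alpha, pairs_per_node=pairs_per_node).fit(ds).model_


def evaluate_nodes(model: UstModel, ds: CqDataset) -> dict[str, float]:
    """Per-node classification accuracy of the fitted detectors on a dataset.

    For each trained node, scores its case/control subject subsets and reports
    the fraction of correct votes among non-abstaining subjects. Run on the
    training cohort this is resubstitution accuracy; on a freshly simulated
    cohort it is held-out accuracy.
    """
    ds = _ensure_aggregated(ds)
    subsets = _node_subsets(ds.subjects_frame())
    out: dict[str, float] = {}
    for node in NODES:
        det = model.detectors[node]
        if not det.trained:
            out[node] = float("nan")
            continue
        case_ids, ctrl_ids = subsets[node]
        s = node_scores(det, ds.aggregated)
        votes = s > det.cutoff
        usable_case = s.reindex(case_ids).dropna().index
        usable_ctrl = s.reindex(ctrl_ids).dropna().index
        n = len(usable_case) + len(usable_ctrl)
        if n == 0:
            out[node] = float("nan")
            continue
        correct = votes[usable_case].sum() + (~votes[usable_ctrl]).sum()
        out[node] = float(correct / n)
    return out


def calls_to_frame(calls: Sequence[UstCall]) -> pd.DataFrame:
    """Flatten screening calls for CSV export."""
    return pd.DataFrame(
        {
            "subject_id": [c.subject_id for c in calls],
            "flagged_systems": ["+".join(c.flagged_systems) for c in calls],
            "pathology_type": [c.pathology_type for c in calls],
        }
    )
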