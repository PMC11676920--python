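"""Exploring results: representatives, flow comparisons, label validation.

These helpers operate on a completed run. Re-grouping at a different
Jaccard threshold touches only the stored similarity matrix, never the
clustering itself, so threshold sweeps (e.g. starting at 0.9 and walking
down) are cheap.

Validation against a known binary label follows the majority-class rule:
each cluster predicts its majority label (ties resolve to the positive
label), and sensitivity = TP / (TP + FN), specificity = TN / (TN + FP)
are computed from the pooled confusion counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consensus import JaccardMatrix, group_and_represent

__all__ = [
    "ValidationReport",
    "res_stratification",
    "sankey_data",
    "validate_stratification",
    "cluster_to_data",
]


@dataclass
class ValidationReport:
    """Sensitivity/specificity of a stratification against binary labels."""

    stratification_name: str
    positive_label: object
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int
    cluster_to_label: dict

    def to_dict(self) -> dict:
        return {
            "stratification": self.stratification_name,
            "positive_label": str(self.positive_label),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "confusion": {"TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn},
            "cluster_to_label": {str(k): str(v) for k, v in self.cluster_to_label.items()},
        }


def res_stratification(
    jaccard: JaccardMatrix, threshold: float = 0.7, min_size: int = 2
) -> list:
    """Groups + representatives at a (possibly new) similarity threshold.

    Only re-runs the grouping on the stored Jaccard matrix. By default
    only multi-member groups are reported: a single stratification with no
    parameter-robust sibling is weak evidence; pass ``min_size=1`` to see
    singletons too.
    """
    return group_and_represent(jaccard, threshold=threshold, min_size=min_size)


def sankey_data(source_assignment, target) -> pd.DataFrame:
    """Flow table between two stratifications (or one vs known labels).

    One row per (source cluster, target cluster/label) pair with the
    patient count; counts sum to the cohort size.
    """
    a = pd.Series(np.asarray(source_assignment), name="source")
    b = pd.Series(np.asarray(target), name="target")
    if len(a) != len(b):
        raise ValueError("assignments must cover the same patients")
    flows = (
        pd.DataFrame({"source": a.to_numpy(), "target": b.to_numpy()})
        .value_counts()
        .rename("count")
        .reset_index()
        .sort_values(["source", "target"], kind="stable")
        .reset_index(drop=True)
    )
    return flows


def validate_stratification(
    assignment, labels, positive_label, name: str = ""
) -> ValidationReport:
    """Majority-class validation of a stratification against binary labels."""
    assignment = np.asarray(assignment)
    labels = np.asarray(labels)
    if len(assignment) != len(labels):
        raise ValueError("assignment and labels must cover the same patients")
    uniq_labels = pd.unique(labels)
    if len(uniq_labels) != 2:
        raise ValueError(
            f"validation requires binary labels, got {len(uniq_labels)} distinct values"
        )
    if positive_label not in uniq_labels:
        raise ValueError(f"positive label {positive_label!r} not found in labels")
    negative_label = next(l for l in uniq_labels if l != positive_label)

    cluster_to_label = {}
    predicted = np.empty(len(labels), dtype=object)
    for c in np.unique(assignment):
        in_c = assignment == c
        n_pos = int((labels[in_c] == positive_label).sum())
        n_neg = int(in_c.sum()) - n_pos
        majority = positive_label if n_pos >= n_neg else negative_label  # tie -> positive
        cluster_to_label[int(c) if np.issubdtype(assignment.dtype, np.integer) else c] = majority
        predicted[in_c] = majority

    is_pos = labels == positive_label
    pred_pos = predicted == positive_label
    tp = int((is_pos & pred_pos).sum())
    fn = int((is_pos & ~pred_pos).sum())
    tn = int((~is_pos & ~pred_pos).sum())
    fp = int((~is_pos & pred_pos).sum())
    sensitivity = tp / (tp + fn) if (tp + fn) else 0.0
    specificity = tn / (tn + fp) if (tn + fp) else 0.0
    return ValidationReport(
        stratification_name=name,
        positive_label=positive_label,
        sensitivity=float(sensitivity),
        specificity=float(specificity),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        cluster_to_label=cluster_to_label,
    )


def cluster_to_data(study, candidates, selected_names) -> pd.DataFrame:
    """Join selected stratifications back onto the original raw table.

    Adds one integer column (clusters numbered from 1) per selected
    candidate; row order is preserved. Unknown names are rejected with the
    list of available ones.
    """
    by_name = {c.name: c for c in candidates if not c.failed}
    out = study.raw.copy()
    for name in selected_names:
        if name not in by_name:
            raise KeyError(
                f"unknown stratification {name!r}; available: {sorted(by_name)}"
            )
        out[name] = np.asarray(by_name[name].assignment) + 1
    return out
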