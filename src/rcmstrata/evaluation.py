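"""Agreement metrics and interface-depth estimation.

Two label sets over the same sections (e.g. an expert's reference labels
and the automatic classification) are compared through a fixed-order 4x4
confusion matrix and overall/grouped accuracies.  The depth of each
inter-strata interface in a stack is estimated by counting labelled
sections: the boundary below stratum set S lies at
(number of sections labelled with a stratum in S) * spacing_um.
This counting definition is order-free, so it remains well defined even
for non-monotone prediction sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import StackPrediction
from .stack_io import Stratum, STRATA_NAMES, STRATA_ORDER

INTERFACE_NAMES = ("sc_ve_um", "ve_dej_um", "dej_pd_um")


class EvaluationError(ValueError):
    pass


@dataclass
class ConfusionMatrix:
    """4x4 counts; rows = reference stratum, columns = compared stratum."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4, 4):
            raise EvaluationError(f"confusion matrix must be 4x4, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)

    def class_accuracy(self, stratum: Stratum) -> float:
        """Fraction of reference sections of one stratum labelled correctly."""
        row = self.counts[int(stratum)]
        return float(row[int(stratum)] / row.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=STRATA_NAMES, columns=STRATA_NAMES)

    def __str__(self) -> str:
        return self.to_frame().to_string()


def _as_label_frame(labels) -> pd.DataFrame:
    """Accept a LabelTable or a DataFrame with the label-table columns."""
    df = labels.frame if hasattr(labels, "frame") else pd.DataFrame(labels)
    df = df.copy()
    df["stack_id"] = df["stack_id"].astype(str)
    df["stratum"] = pd.Series(
        [s if isinstance(s, Stratum) else Stratum.parse(s) for s in df["stratum"]],
        index=df.index,
        dtype=object,
    )
    return df[["stack_id", "section_index", "stratum"]]


def _aligned(reference, compared) -> pd.DataFrame:
    ref = _as_label_frame(reference).rename(columns={"stratum": "reference"})
    cmp_ = _as_label_frame(compared).rename(columns={"stratum": "compared"})
    merged = ref.merge(cmp_, on=["stack_id", "section_index"], how="outer")
    if merged["reference"].isna().any() or merged["compared"].isna().any():
        raise EvaluationError(
            "reference and compared labels do not cover the same sections"
        )
    return merged


def confusion_and_accuracy(reference_labels, compared_labels) -> tuple[ConfusionMatrix, float]:
    """Confusion matrix and overall accuracy between two label sets."""
    merged = _aligned(reference_labels, compared_labels)
    counts = np.zeros((4, 4), dtype=np.int64)
    for r, c in zip(merged["reference"], merged["compared"]):
        counts[int(r), int(c)] += 1
    cm = ConfusionMatrix(counts)
    return cm, cm.accuracy


def grouped_accuracy(
    labels,
    predictions,
    metadata: pd.DataFrame | None = None,
    group_keys: Sequence[str] = ("stratum",),
) -> pd.DataFrame:
    """Accuracy per combination of grouping keys, as a tidy table.

    Keys may be "stratum" (the reference label), "stack_id", or any
    column of ``metadata`` (joined on stack_id, e.g. age_group,
    body_site, phototype).
    """
    merged = _aligned(labels, predictions)
    merged["correct"] = merged["reference"] == merged["compared"]
    merged["stratum"] = [s.name for s in merged["reference"]]
    if metadata is not None:
        missing = set(merged["stack_id"]) - set(metadata["stack_id"].astype(str))
        if missing:
            raise EvaluationError(f"metadata missing for stacks {sorted(missing)[:5]}")
        merged = merged.merge(metadata.astype({"stack_id": str}), on="stack_id")
    for key in group_keys:
        if key not in merged.columns:
            raise EvaluationError(f"unknown grouping key {key!r}")
    out = (
        merged.groupby(list(group_keys), sort=True, observed=True)
        .agg(n_sections=("correct", "size"), n_correct=("correct", "sum"))
        .reset_index()
    )
    out["accuracy"] = out["n_correct"] / out["n_sections"]
    return out


def per_stack_accuracy(labels, predictions) -> pd.DataFrame:
    """Accuracy for each stack (group_keys = stack_id)."""
    return grouped_accuracy(labels, predictions, group_keys=("stack_id",))


@dataclass
class InterfaceDepths:
    """Depths (um, from section 0) of the three inter-strata interfaces."""

    sc_ve_um: float
    ve_dej_um: float
    dej_pd_um: float

    def as_array(self) -> np.ndarray:
        return np.array([self.sc_ve_um, self.ve_dej_um, self.dej_pd_um])


def estimate_interfaces(
    section_labels: Sequence[Stratum], spacing_um: float = 2.0
) -> InterfaceDepths:
    """Interface depths from per-section labels by stratum counting.

    sc_ve = #SC * spacing; ve_dej = (#SC + #VE) * spacing;
    dej_pd = (#SC + #VE + #DEJ) * spacing.  Counts are taken anywhere in
    the stack, so the estimate is invariant to section order.
    """
    labels = [s if isinstance(s, Stratum) else Stratum.parse(s) for s in section_labels]
    if not labels:
        raise EvaluationError("cannot estimate interfaces for an empty stack")
    counts = np.bincount([int(s) for s in labels], minlength=4)
    cum = np.cumsum(counts[:3]) * spacing_um
    return InterfaceDepths(*map(float, cum))


def interface_agreement(
    auto_depths: Sequence[InterfaceDepths],
    reference_depths: Sequence[InterfaceDepths],
) -> pd.DataFrame:
    """Per-interface MAE and Pearson r across stacks, plus pooled MAE.

    Returns a table with one row per interface (and an "all" row for the
    pooled MAE).  Pearson r is reported as NaN when the reference depths
    have zero variance (undefined rather than 1).
    """
    auto = np.array([d.as_array() for d in auto_depths])
    ref = np.array([d.as_array() for d in reference_depths])
    if auto.shape != ref.shape:
        raise EvaluationError("auto and reference depth sets differ in shape")
    if auto.shape[0] < 2:
        raise EvaluationError("need at least 2 stacks for agreement statistics")
    rows = []
    for j, name in enumerate(INTERFACE_NAMES):
        err = np.abs(auto[:, j] - ref[:, j])
        if np.ptp(ref[:, j]) == 0 or np.ptp(auto[:, j]) == 0:
            r = np.nan
        else:
            r = stats.pearsonr(auto[:, j], ref[:, j]).statistic
        rows.append({"interface": name, "mae_um": float(err.mean()), "pearson_r": r})
    rows.append(
        {
            "interface": "all",
            "mae_um": float(np.abs(auto - ref).mean()),
            "pearson_r": np.nan,
        }
    )
    return pd.DataFrame(rows)


def probability_depth_profile(stack_prediction: StackPrediction) -> pd.DataFrame:
    """Tidy (depth_um, p_SC, p_VE, p_DEJ, p_PD) table for one stack."""
    probs = stack_prediction.probabilities
    depths = np.arange(probs.shape[0]) * stack_prediction.spacing_um
    out = pd.DataFrame(probs, columns=[f"p_{s}" for s in STRATA_NAMES])
    out.insert(0, "depth_um", depths)
    return out


def prediction_label_frame(predictions: Sequence[StackPrediction]) -> pd.DataFrame:
    """Predicted labels of many stacks in label-table layout."""
    rows = []
    for sp in predictions:
        for i, lab in enumerate(sp.labels):
            rows.append({"stack_id": sp.stack_id, "section_index": i, "stratum": lab})
    return pd.DataFrame(rows)
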