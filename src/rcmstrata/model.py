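"""Strata classification: one-vs-rest L1 logistic regression and
participant-partitioned model selection.

Each en-face section's unit-L2 bag-of-features histogram is classified
into one of the four strata with four binary L1-penalised logistic
regressions (one per stratum); the per-class sigmoid scores are
renormalised to a probability 4-vector.  Model selection uses k-fold
cross-validation partitioned on participants — no individual contributes
sections to both the training and validation side of a fold — with a grid
over the dictionary shape (levels, splits) and the regularisation
constant C.  Every fit stage records the participant ids it saw so that
the absence of leakage is auditable after the fact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .dictionary import VisualDictionary, learn_hierarchical_dictionary
from .encoder import (
    SectionEncoding,
    encode_section,
    encode_with_rotations,
    encodings_to_matrix,
    pool_rotations,
)
from .patch_features import (
    INTENSITY_SCALE,
    WhiteningModel,
    apply_whitening,
    downsample_section,
    extract_random_patches,
    fit_whitening,
    normalize_patches,
    PatchSet,
)
from .stack_io import DepthStack, LabelTable, Stratum, STRATA_ORDER

DEFAULT_C = 100.0
DEFAULT_C_GRID = tuple(10.0**i for i in range(6))
DEFAULT_SPLITS_GRID = (4, 6, 8, 10, 12, 14, 16, 18)
FULL_SPLITS_GRID = tuple(range(4, 19))


class ModelError(ValueError):
    pass


class MissingClassError(ModelError):
    """A stratum is absent from the training labels."""


class PartitionError(ModelError):
    """A participant appears on both sides of a fold or split."""


class LeakageError(ModelError):
    """A fit stage saw sections from evaluation participants."""


@dataclass
class StrataClassifier:
    """Four binary one-vs-rest L1 logistic models, one per stratum."""

    weights: np.ndarray  # (4, K)
    intercepts: np.ndarray  # (4,)
    C: float

    @property
    def n_features(self) -> int:
        return int(self.weights.shape[1])

    def save(self, path) -> None:
        np.savez(path, weights=self.weights, intercepts=self.intercepts, C=self.C)

    @classmethod
    def load(cls, path) -> "StrataClassifier":
        with np.load(path) as z:
            return cls(weights=z["weights"], intercepts=z["intercepts"], C=float(z["C"]))


def train_classifier(
    encodings: np.ndarray | list[SectionEncoding],
    labels: list[Stratum],
    C: float = DEFAULT_C,
) -> StrataClassifier:
    """Fit the one-vs-rest L1 logistic regression on encoded sections."""
    X = encodings if isinstance(encodings, np.ndarray) else encodings_to_matrix(encodings)
    y = np.array([int(s) for s in labels])
    if X.shape[0] != y.shape[0]:
        raise ModelError(f"{X.shape[0]} encodings but {y.shape[0]} labels")
    present = set(y.tolist())
    missing = [s.name for s in STRATA_ORDER if int(s) not in present]
    if missing:
        raise MissingClassError(f"strata absent from training data: {missing}")
    weights = np.zeros((4, X.shape[1]))
    intercepts = np.zeros(4)
    for s in STRATA_ORDER:
        binary = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear", max_iter=1000)
        binary.fit(X, (y == int(s)).astype(int))
        weights[int(s)] = binary.coef_[0]
        intercepts[int(s)] = binary.intercept_[0]
    return StrataClassifier(weights=weights, intercepts=intercepts, C=C)


def predict(
    classifier: StrataClassifier,
    pooled_encodings: np.ndarray | list[SectionEncoding],
) -> tuple[list[Stratum], np.ndarray]:
    """Predict strata labels and probability 4-vectors for sections.

    Per-class sigmoid scores are renormalised to sum to 1; the argmax
    label breaks ties in favour of the anatomically shallowest stratum.
    """
    X = (
        pooled_encodings
        if isinstance(pooled_encodings, np.ndarray)
        else encodings_to_matrix(pooled_encodings)
    )
    if X.shape[1] != classifier.n_features:
        raise ModelError(
            f"encoding length {X.shape[1]} does not match classifier "
            f"feature count {classifier.n_features}"
        )
    scores = X @ classifier.weights.T + classifier.intercepts
    sig = 1.0 / (1.0 + np.exp(-scores))
    probs = sig / sig.sum(axis=1, keepdims=True)
    # argmax returns the first maximum; columns are in anatomical order,
    # so ties resolve to the shallowest stratum.
    labels = [Stratum(int(i)) for i in np.argmax(probs, axis=1)]
    return labels, probs


@dataclass
class StackPrediction:
    """Per-section predicted strata and probabilities for one stack."""

    stack_id: str
    labels: list[Stratum]
    probabilities: np.ndarray  # (n_sections, 4)
    spacing_um: float = 2.0


@dataclass
class PipelineParams:
    """All tunable constants of the representation + classifier pipeline."""

    downsample_factor: int = 4
    patch_size: int = 7
    patch_norm_reg: float = 1.0
    zca_eps: float = 0.1
    energy_fraction: float = 0.95
    kmeans_iter: int = 10
    n_levels: int = 3
    n_splits: int = 18
    C: float = DEFAULT_C
    stride: int = 1
    n_random_patches: int = 100


@dataclass
class TrainedPipeline:
    """Whitening + dictionary + classifier with a fit-stage audit trail."""

    whitening: WhiteningModel
    dictionary: VisualDictionary
    classifier: StrataClassifier
    params: PipelineParams
    fit_participants: dict[str, frozenset] = field(default_factory=dict)


def _collect_training_patches(
    stacks: list[DepthStack], params: PipelineParams, rng: np.random.Generator
) -> PatchSet:
    """Random patches from every section of every training stack."""
    all_patches = []
    p = params.patch_size
    for stack in stacks:
        for section in stack.sections:
            small = downsample_section(section, params.downsample_factor)
            ps = extract_random_patches(
                small * INTENSITY_SCALE, params.n_random_patches, p, rng
            )
            all_patches.append(ps.patches)
    return PatchSet(np.vstack(all_patches), p)


def train_pipeline(
    stacks: list[DepthStack],
    labels: LabelTable,
    params: PipelineParams,
    rng_seed: int | np.random.Generator = 0,
) -> TrainedPipeline:
    """Learn whitening, dictionary and classifier from labelled stacks.

    Training encodings include the three right-angle rotations of every
    section as separate examples carrying the section's label.  The
    participant ids seen by each fit stage are recorded for the
    no-leakage audit.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    ids = frozenset(s.participant_id for s in stacks)
    raw = _collect_training_patches(stacks, params, rng)
    normed = normalize_patches(raw, params.patch_norm_reg)
    whitening = fit_whitening(
        normed, params.zca_eps, params.energy_fraction, params.patch_norm_reg
    )
    whitened = apply_whitening(whitening, normed)
    dictionary = learn_hierarchical_dictionary(
        whitened.patches, params.n_levels, params.n_splits, params.kmeans_iter, rng
    )
    X_rows, y = [], []
    for stack in stacks:
        stack_labels = labels.for_stack(stack.stack_id)
        if len(stack_labels) != stack.n_sections:
            raise ModelError(
                f"stack {stack.stack_id!r}: {len(stack_labels)} labels for "
                f"{stack.n_sections} sections"
            )
        for idx, section in enumerate(stack.sections):
            small = downsample_section(section, params.downsample_factor)
            for enc in encode_with_rotations(
                small, whitening, dictionary, params.stride,
                stack_id=stack.stack_id, section_index=idx,
            ):
                X_rows.append(enc.histogram)
                y.append(stack_labels[idx])
    classifier = train_classifier(np.stack(X_rows), y, params.C)
    return TrainedPipeline(
        whitening=whitening,
        dictionary=dictionary,
        classifier=classifier,
        params=params,
        fit_participants={"whitening": ids, "dictionary": ids, "classifier": ids},
    )


def predict_stack(pipeline: TrainedPipeline, stack: DepthStack) -> StackPrediction:
    """Predict every section of a stack from rotation-pooled encodings."""
    params = pipeline.params
    pooled = []
    for idx, section in enumerate(stack.sections):
        small = downsample_section(section, params.downsample_factor)
        encs = encode_with_rotations(
            small, pipeline.whitening, pipeline.dictionary, params.stride,
            stack_id=stack.stack_id, section_index=idx,
        )
        pooled.append(pool_rotations(encs))
    labels, probs = predict(pipeline.classifier, pooled)
    return StackPrediction(
        stack_id=stack.stack_id,
        labels=labels,
        probabilities=probs,
        spacing_um=stack.spacing_um,
    )


def assert_no_leakage(pipeline: TrainedPipeline, eval_participants) -> None:
    """Raise LeakageError if any fit stage saw an evaluation participant."""
    eval_ids = frozenset(eval_participants)
    for stage, ids in pipeline.fit_participants.items():
        leaked = ids & eval_ids
        if leaked:
            raise LeakageError(
                f"fit stage {stage!r} used evaluation participants {sorted(leaked)}"
            )


def holdout_split(
    participants: pd.DataFrame,
    counts: dict[str, int] | float,
    rng_seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Stratified-by-age-group random participant split.

    ``participants`` needs columns participant_id and age_group.
    ``counts`` gives the number of held-out (test) participants per age
    group, or a single fraction applied to every group.  Returns
    (train_ids, test_ids), disjoint and seed-reproducible.
    """
    df = participants.drop_duplicates("participant_id")
    rng = np.random.default_rng(rng_seed)
    test_ids: list[str] = []
    for group, grp in df.groupby("age_group", sort=True):
        ids = sorted(grp["participant_id"])
        if isinstance(counts, dict):
            if group not in counts:
                continue
            n = counts[group]
        else:
            n = int(round(counts * len(ids)))
        if n > len(ids):
            raise ModelError(
                f"requested {n} held-out participants from age group "
                f"{group!r} with only {len(ids)} members"
            )
        test_ids.extend(rng.choice(ids, size=n, replace=False))
    test = sorted(test_ids)
    train = sorted(set(df["participant_id"]) - set(test))
    return train, test


@dataclass
class GridSearchPlan:
    """Search space and CV layout for pipeline model selection."""

    levels_grid: tuple[int, ...] = (1, 2, 3)
    splits_grid: tuple[int, ...] = DEFAULT_SPLITS_GRID
    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    n_folds: int = 10
    base_params: PipelineParams = field(default_factory=PipelineParams)


def make_participant_folds(
    participant_ids, n_folds: int, rng_seed: int
) -> list[list[str]]:
    """Shuffle participants by seed and split into near-equal folds."""
    ids = sorted(set(participant_ids))
    if len(ids) < n_folds:
        raise PartitionError(
            f"{len(ids)} participants cannot form {n_folds} disjoint folds"
        )
    rng = np.random.default_rng(rng_seed)
    perm = list(rng.permutation(ids))
    return [list(f) for f in np.array_split(perm, n_folds)]


def grid_search(
    train_stacks: list[DepthStack],
    labels: LabelTable,
    plan: GridSearchPlan,
    rng_seed: int = 0,
) -> tuple[tuple[int, int, float], pd.DataFrame]:
    """Participant-partitioned k-fold CV over (n_levels, n_splits, C).

    The dictionary and whitening are re-learned on each fold's training
    participants only; validation sections are encoded with rotation
    pooling.  Returns the grid point with maximum mean accuracy across
    folds (ties to the first point in grid order: levels, then splits,
    then C ascending) plus the full CV table.
    """
    folds = make_participant_folds(
        [s.participant_id for s in train_stacks], plan.n_folds, rng_seed
    )
    flat = [pid for fold in folds for pid in fold]
    if len(flat) != len(set(flat)):
        raise PartitionError("a participant appears in more than one fold")
    rows = []
    for fold_idx, val_ids in enumerate(folds):
        val_set = set(val_ids)
        fit_stacks = [s for s in train_stacks if s.participant_id not in val_set]
        val_stacks = [s for s in train_stacks if s.participant_id in val_set]
        for n_levels, n_splits in itertools.product(plan.levels_grid, plan.splits_grid):
            # classifier-independent stages are shared across the C grid
            fold_seed = np.random.SeedSequence(
                [rng_seed, fold_idx, n_levels, n_splits]
            )
            rng = np.random.default_rng(fold_seed)
            for C in plan.C_grid:
                params = PipelineParams(
                    **{
                        **plan.base_params.__dict__,
                        "n_levels": n_levels,
                        "n_splits": n_splits,
                        "C": C,
                    }
                )
                pipe = train_pipeline(
                    fit_stacks, labels, params, np.random.default_rng(fold_seed)
                )
                assert_no_leakage(pipe, val_set)
                correct = total = 0
                for stack in val_stacks:
                    pred = predict_stack(pipe, stack)
                    truth = labels.for_stack(stack.stack_id)
                    correct += sum(p == t for p, t in zip(pred.labels, truth))
                    total += len(truth)
                rows.append(
                    {
                        "fold": fold_idx,
                        "n_levels": n_levels,
                        "n_splits": n_splits,
                        "C": C,
                        "n_val_sections": total,
                        "accuracy": correct / total if total else np.nan,
                    }
                )
    table = pd.DataFrame(rows)
    return select_best(table), table


def select_best(cv_table: pd.DataFrame) -> tuple[int, int, float]:
    """Grid point with maximal mean CV accuracy.

    Ties go to the first point in grid order: fewest levels, then fewest
    splits, then smallest C.
    """
    mean_acc = (
        cv_table.groupby(["n_levels", "n_splits", "C"], sort=True)["accuracy"]
        .mean()
        .reset_index()
    )
    best_row = mean_acc.loc[mean_acc["accuracy"].idxmax()]
    return (int(best_row["n_levels"]), int(best_row["n_splits"]), float(best_row["C"]))
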