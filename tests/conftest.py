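"""Shared fixtures: reference confusion counts and a mini trained pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rcmstrata import (
    PipelineParams,
    SyntheticStackSpec,
    generate_stack,
    train_pipeline,
)

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


# Published reference comparison on a 5319-section confocal test set, used
# as a worked-example fixture: rows = second expert labelling (reference),
# columns = compared labelling, strata order SC, VE, DEJ, PD.
AUTOMATIC_CONFUSION = np.array(
    [
        [1209, 58, 3, 23],
        [71, 1085, 154, 7],
        [0, 143, 1298, 160],
        [3, 0, 143, 962],
    ]
)

# Same reference against the expert's own first labelling session.
INTRAOBSERVER_CONFUSION = np.array(
    [
        [1292, 1, 0, 0],
        [23, 1285, 9, 0],
        [0, 56, 1523, 22],
        [0, 0, 26, 1082],
    ]
)

STRATA = ("SC", "VE", "DEJ", "PD")


def counts_to_label_frames(counts: np.ndarray) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand a 4x4 confusion-count matrix into per-section label frames."""
    ref_rows, cmp_rows = [], []
    idx = 0
    for i, ref in enumerate(STRATA):
        for j, cmp_ in enumerate(STRATA):
            for _ in range(int(counts[i, j])):
                ref_rows.append({"stack_id": "s", "section_index": idx, "stratum": ref})
                cmp_rows.append({"stack_id": "s", "section_index": idx, "stratum": cmp_})
                idx += 1
    return pd.DataFrame(ref_rows), pd.DataFrame(cmp_rows)


@pytest.fixture(scope="session")
def automatic_confusion() -> np.ndarray:
    return AUTOMATIC_CONFUSION.copy()


@pytest.fixture(scope="session")
def intraobserver_confusion() -> np.ndarray:
    return INTRAOBSERVER_CONFUSION.copy()


@pytest.fixture(scope="session")
def small_stack():
    """One small synthetic stack (96 px, 12 sections) with labels."""
    spec = SyntheticStackSpec(
        width_px=96, height_px=96, strata_thicknesses=(3, 3, 3, 3), rng_seed=7
    )
    stack, labels, truth = generate_stack(spec, stack_id="small", participant_id="pA")
    return stack, labels, truth


@pytest.fixture(scope="session")
def mini_pipeline(small_stack):
    """A small trained pipeline (1-level 6-split dictionary) for encoder tests."""
    stack, labels, _ = small_stack
    params = PipelineParams(
        downsample_factor=1, n_levels=1, n_splits=6, stride=2, n_random_patches=60
    )
    return train_pipeline([stack], labels, params, rng_seed=0), params
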