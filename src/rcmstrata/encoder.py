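"""Bag-of-features encoding of en-face sections.

A section is represented by the histogram of visual-word counts over all
its dense patches, term-frequency normalised to unit L2 length.  Training
uses the section plus its three right-angle rotations as separate
examples; at prediction time the four rotation histograms are pooled by
averaging (and renormalised to the unit sphere).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dictionary import VisualDictionary, quantize
from .patch_features import (
    INTENSITY_SCALE,
    PatchError,
    WhiteningModel,
    apply_whitening,
    extract_dense_patches,
    normalize_patches,
)

ROTATIONS = (0, 90, 180, 270)
POOLED = "POOLED"


class EncodingError(ValueError):
    pass


@dataclass
class SectionEncoding:
    """Unit-L2 visual-word histogram of one en-face section."""

    histogram: np.ndarray  # (K,), non-negative, unit L2 norm
    stack_id: str = ""
    section_index: int = 0
    rotation: int | str = 0

    def __post_init__(self) -> None:
        self.histogram = np.asarray(self.histogram, dtype=np.float64)


def encode_section(
    section: np.ndarray,
    whitening_model: WhiteningModel,
    dictionary: VisualDictionary,
    stride: int = 1,
    *,
    stack_id: str = "",
    section_index: int = 0,
    rotation: int | str = 0,
    exhaustive: bool = False,
) -> SectionEncoding:
    """Encode one (already down-sampled) section as a unit-L2 histogram.

    The section is expected in the [0, 1] storage range; patches are
    expressed in 8-bit intensity units before normalisation so the
    normalisation/whitening regularisers act on their calibrated scale.
    """
    patches = extract_dense_patches(
        np.asarray(section) * INTENSITY_SCALE, whitening_model.patch_size, stride
    )
    patches = normalize_patches(patches, whitening_model.patch_norm_reg)
    patches = apply_whitening(whitening_model, patches)
    words = quantize(dictionary, patches.patches, exhaustive=exhaustive)
    counts = np.bincount(words, minlength=dictionary.n_words).astype(np.float64)
    norm = np.linalg.norm(counts)
    return SectionEncoding(
        histogram=counts / norm,
        stack_id=stack_id,
        section_index=section_index,
        rotation=rotation,
    )


def encode_with_rotations(
    section: np.ndarray,
    whitening_model: WhiteningModel,
    dictionary: VisualDictionary,
    stride: int = 1,
    *,
    stack_id: str = "",
    section_index: int = 0,
    exhaustive: bool = False,
) -> list[SectionEncoding]:
    """Encode a square section and its 90/180/270 degree rotations."""
    section = np.asarray(section)
    if section.shape[0] != section.shape[1]:
        raise EncodingError(
            f"rotation augmentation requires a square section, got {section.shape}"
        )
    out = []
    for n_rot, angle in enumerate(ROTATIONS):
        out.append(
            encode_section(
                np.rot90(section, n_rot),
                whitening_model,
                dictionary,
                stride,
                stack_id=stack_id,
                section_index=section_index,
                rotation=angle,
                exhaustive=exhaustive,
            )
        )
    return out


def pool_rotations(
    encodings: list[SectionEncoding], renormalize: bool = True
) -> SectionEncoding:
    """Average the four rotation histograms of one section.

    The mean histogram is renormalised to unit L2 by default so pooled
    test vectors live on the same sphere as training vectors.
    """
    if len(encodings) != len(ROTATIONS):
        raise EncodingError(f"expected {len(ROTATIONS)} encodings, got {len(encodings)}")
    keys = {(e.stack_id, e.section_index) for e in encodings}
    if len(keys) != 1:
        raise EncodingError(f"cannot pool encodings of different sections: {keys}")
    mean = np.mean([e.histogram for e in encodings], axis=0)
    if renormalize:
        norm = np.linalg.norm(mean)
        if norm > 0:
            mean = mean / norm
    e0 = encodings[0]
    return SectionEncoding(
        histogram=mean,
        stack_id=e0.stack_id,
        section_index=e0.section_index,
        rotation=POOLED,
    )


def encodings_to_matrix(encodings: list[SectionEncoding]) -> np.ndarray:
    """Stack encodings into an (n_sections, K) design matrix."""
    return np.stack([e.histogram for e in encodings])
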