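"""Patch extraction, contrast normalisation and regularised ZCA whitening.

En-face sections are first down-sampled (truncated-sinc / Lanczos
pre-filter against aliasing), then represented through small square
patches.  Patches are brightness/contrast normalised per patch and
decorrelated with a zero-component-analysis (ZCA) whitening transform
learned from a large sample of patches.  ZCA is the symmetric whitening
W = V (L + eps I)^(-1/2) V^T that keeps whitened patches close to image
space; only the leading eigenvectors carrying ``energy_fraction`` of the
spectrum are retained, which suppresses numerically unstable low-energy
axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

DEFAULT_PATCH_SIZE = 7
DEFAULT_PATCH_NORM_REG = 1.0
DEFAULT_ZCA_EPS = 0.1
DEFAULT_ENERGY_FRACTION = 0.95
DEFAULT_DOWNSAMPLE_FACTOR = 4

#: The per-patch variance regulariser (1) and whitening epsilon (0.1) are
#: calibrated to 8-bit intensity units; sections stored in [0, 1] are
#: rescaled by this factor before patch extraction in the pipeline.
INTENSITY_SCALE = 255.0


class PatchError(ValueError):
    pass


@dataclass
class PatchSet:
    """Flattened p*p patch vectors with optional per-patch provenance."""

    patches: np.ndarray  # (n_patches, p*p)
    patch_size: int
    stack_id: str | None = None
    section_index: int | None = None

    def __post_init__(self) -> None:
        self.patches = np.atleast_2d(np.asarray(self.patches, dtype=np.float64))
        if self.patches.shape[1] != self.patch_size**2:
            raise PatchError(
                f"patch vectors have length {self.patches.shape[1]}, "
                f"expected {self.patch_size**2}"
            )

    def __len__(self) -> int:
        return int(self.patches.shape[0])


def downsample_section(image: np.ndarray, factor: int = DEFAULT_DOWNSAMPLE_FACTOR) -> np.ndarray:
    """Down-sample an image by ``factor`` per axis with a Lanczos pre-filter.

    The Lanczos (truncated-sinc) kernel is scaled with the decimation
    factor so frequencies above the new Nyquist limit are suppressed
    before resampling.  If ``factor`` does not divide a dimension the
    image is cropped to the largest multiple first.
    """
    if factor < 1 or int(factor) != factor:
        raise PatchError(f"downsample factor must be a positive integer, got {factor}")
    factor = int(factor)
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise PatchError(f"expected a 2-D image, got shape {image.shape}")
    if factor == 1:
        return image.copy()
    h, w = image.shape
    image = image[: (h // factor) * factor, : (w // factor) * factor]
    if image.size == 0:
        raise PatchError("image smaller than the downsample factor")
    out_size = (image.shape[1] // factor, image.shape[0] // factor)  # PIL is (w, h)
    pil = Image.fromarray(image.astype(np.float32), mode="F")
    small = pil.resize(out_size, resample=Image.Resampling.LANCZOS)
    return np.asarray(small, dtype=np.float64)


def extract_random_patches(
    section: np.ndarray,
    n_patches: int,
    patch_size: int = DEFAULT_PATCH_SIZE,
    rng_seed: int | np.random.Generator = 0,
) -> PatchSet:
    """Extract ``n_patches`` patches at uniform-random in-bounds positions."""
    section = np.asarray(section, dtype=np.float64)
    h, w = section.shape
    p = patch_size
    if h < p or w < p:
        raise PatchError(f"section {h}x{w} smaller than patch size {p}")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    rows = rng.integers(0, h - p + 1, size=n_patches)
    cols = rng.integers(0, w - p + 1, size=n_patches)
    rr = rows[:, None, None] + np.arange(p)[None, :, None]
    cc = cols[:, None, None] + np.arange(p)[None, None, :]
    patches = section[rr, cc].reshape(n_patches, p * p)
    return PatchSet(patches, p)


def extract_dense_patches(
    section: np.ndarray, patch_size: int = DEFAULT_PATCH_SIZE, stride: int = 1
) -> PatchSet:
    """Extract all in-bounds patches on a stride grid, row-major order."""
    if stride < 1:
        raise PatchError(f"stride must be >= 1, got {stride}")
    section = np.asarray(section, dtype=np.float64)
    h, w = section.shape
    p = patch_size
    if h < p or w < p:
        raise PatchError(f"section {h}x{w} smaller than patch size {p}")
    windows = np.lib.stride_tricks.sliding_window_view(section, (p, p))
    windows = windows[::stride, ::stride]
    patches = windows.reshape(-1, p * p)
    return PatchSet(np.ascontiguousarray(patches), p)


def normalize_patches(
    patch_set: PatchSet, patch_norm_reg: float = DEFAULT_PATCH_NORM_REG
) -> PatchSet:
    """Normalise each patch to zero mean and regularised unit variance.

    x -> (x - mean(x)) / sqrt(var(x) + reg), with the population (1/N)
    variance over the patch's pixels.  The regulariser keeps low-variance
    patches finite instead of amplifying their noise.
    """
    x = patch_set.patches
    mean = x.mean(axis=1, keepdims=True)
    var = x.var(axis=1, keepdims=True)  # population convention
    out = (x - mean) / np.sqrt(var + patch_norm_reg)
    return PatchSet(out, patch_set.patch_size, patch_set.stack_id, patch_set.section_index)


@dataclass
class WhiteningModel:
    """Learned regularised ZCA whitening transform.

    ``transform_matrix`` is the symmetric p^2 x p^2 matrix
    V_r (L_r + eps I)^(-1/2) V_r^T built from the top-r eigenpairs of the
    sample covariance of the normalised training patches, where r is the
    smallest number of leading eigenvalues carrying at least
    ``energy_fraction`` of the total spectrum.
    """

    mean_vector: np.ndarray
    transform_matrix: np.ndarray
    eigenvalues: np.ndarray  # full descending spectrum (clipped at 0)
    rank: int
    patch_size: int
    patch_norm_reg: float = DEFAULT_PATCH_NORM_REG
    zca_eps: float = DEFAULT_ZCA_EPS
    energy_fraction: float = DEFAULT_ENERGY_FRACTION

    def save(self, path) -> None:
        np.savez(
            path,
            mean_vector=self.mean_vector,
            transform_matrix=self.transform_matrix,
            eigenvalues=self.eigenvalues,
            rank=self.rank,
            patch_size=self.patch_size,
            patch_norm_reg=self.patch_norm_reg,
            zca_eps=self.zca_eps,
            energy_fraction=self.energy_fraction,
        )

    @classmethod
    def load(cls, path) -> "WhiteningModel":
        with np.load(path) as z:
            return cls(
                mean_vector=z["mean_vector"],
                transform_matrix=z["transform_matrix"],
                eigenvalues=z["eigenvalues"],
                rank=int(z["rank"]),
                patch_size=int(z["patch_size"]),
                patch_norm_reg=float(z["patch_norm_reg"]),
                zca_eps=float(z["zca_eps"]),
                energy_fraction=float(z["energy_fraction"]),
            )


def energy_rank(eigenvalues: np.ndarray, energy_fraction: float) -> int:
    """Smallest r with sum of top-r eigenvalues >= fraction of the total."""
    lam = np.sort(np.clip(np.asarray(eigenvalues, dtype=np.float64), 0, None))[::-1]
    total = lam.sum()
    if total <= 0:
        return 0
    cum = np.cumsum(lam) / total
    return int(np.searchsorted(cum, energy_fraction - 1e-12) + 1)


def fit_whitening(
    patch_set: PatchSet,
    zca_eps: float = DEFAULT_ZCA_EPS,
    energy_fraction: float = DEFAULT_ENERGY_FRACTION,
    patch_norm_reg: float = DEFAULT_PATCH_NORM_REG,
) -> WhiteningModel:
    """Learn the regularised, energy-truncated ZCA transform.

    Eigendecomposes the sample covariance (1/N convention) of the
    already-normalised patches, truncates to the energy rank first, then
    regularises the retained eigenvalues with ``zca_eps``.
    """
    x = patch_set.patches
    d = x.shape[1]
    if x.shape[0] < d:
        warnings.warn(
            f"only {x.shape[0]} patches for a {d}-dimensional covariance; "
            "whitening transform will be rank deficient",
            stacklevel=2,
        )
    mean = x.mean(axis=0)
    xc = x - mean
    cov = (xc.T @ xc) / x.shape[0]
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0, None)
    vec = vec[:, order]
    r = energy_rank(lam, energy_fraction)
    v_r = vec[:, :r]
    lam_r = lam[:r]
    transform = (v_r / np.sqrt(lam_r + zca_eps)) @ v_r.T
    return WhiteningModel(
        mean_vector=mean,
        transform_matrix=transform,
        eigenvalues=lam,
        rank=r,
        patch_size=patch_set.patch_size,
        patch_norm_reg=patch_norm_reg,
        zca_eps=zca_eps,
        energy_fraction=energy_fraction,
    )


def apply_whitening(model: WhiteningModel, patch_set: PatchSet) -> PatchSet:
    """Apply the learned transform: x -> W (x - mean)."""
    x = patch_set.patches
    if x.shape[1] != model.transform_matrix.shape[0]:
        raise PatchError(
            f"patch dimension {x.shape[1]} does not match whitening model "
            f"dimension {model.transform_matrix.shape[0]}"
        )
    out = (x - model.mean_vector) @ model.transform_matrix.T
    return PatchSet(out, patch_set.patch_size, patch_set.stack_id, patch_set.section_index)
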