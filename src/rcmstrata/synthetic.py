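"""Seeded synthetic RCM-like depth stacks with known labels and interfaces.

Each stratum gets a parametric texture echoing its confocal appearance:

* SC — bright, coarse, high-variance speckle (keratinised surface).
* VE — honeycomb: bright borders of a jittered cell mosaic around dark
  keratinocyte interiors.
* DEJ — dermal papillae: dark discs ringed by bright basal-cell annuli,
  on a honeycomb-like background.
* PD — oriented fibrillar band-pass noise (papillary collagen).

The textures are deliberately simple and parametric; the goal is
verifying the classification pipeline end to end with known ground
truth, not photorealism.  Sections are generated directly at the
250x250 working scale (2 um/px) by default.  Texture parameters can be
shared at the participant level so participant-partitioned
cross-validation is a real generalisation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .evaluation import InterfaceDepths, estimate_interfaces
from .stack_io import DepthStack, LabelTable, Stratum


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticStackSpec:
    """All knobs of one synthetic depth stack."""

    width_px: int = 250
    height_px: int = 250
    spacing_um: float = 2.0
    #: sections per stratum in order (SC, VE, DEJ, PD)
    strata_thicknesses: tuple[int, int, int, int] = (10, 15, 12, 13)
    noise_sigma: float = 0.05
    furrow_depth_sections: int = 0
    # per-stratum texture parameters
    speckle_grain_px: float = 4.0
    ve_cell_diameter_px: float = 12.0
    papilla_radius_px: float = 10.0
    papilla_count: int = 25
    fibril_orientation_deg: float = 30.0
    fibril_bandwidth_deg: float = 45.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.strata_thicknesses) != 4 or any(
            t < 1 for t in self.strata_thicknesses
        ):
            raise SyntheticError(
                f"need four strata thicknesses >= 1, got {self.strata_thicknesses}"
            )

    @property
    def n_sections(self) -> int:
        return int(sum(self.strata_thicknesses))


def _standardize(img: np.ndarray) -> np.ndarray:
    return (img - img.mean()) / (img.std() + 1e-12)


def _honeycomb(
    shape: tuple[int, int], cell_diameter: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Bright-border cell mosaic; returns (image, border mask)."""
    h, w = shape
    step = max(cell_diameter, 3.0)
    gy, gx = np.meshgrid(
        np.arange(-step, h + step, step), np.arange(-step, w + step, step), indexing="ij"
    )
    jitter = rng.uniform(-0.35 * step, 0.35 * step, size=(2,) + gy.shape)
    seeds = np.column_stack([(gy + jitter[0]).ravel(), (gx + jitter[1]).ravel()])
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pix = np.column_stack([yy.ravel(), xx.ravel()])
    d, _ = cKDTree(seeds).query(pix, k=2)
    margin = (d[:, 1] - d[:, 0]).reshape(h, w)
    border = margin < 0.22 * step
    img = np.where(border, 0.78, 0.16)
    img = img + 0.04 * rng.standard_normal(shape)
    return np.clip(img, 0, 1), border


def _render_with_masks(
    stratum: Stratum, spec: SyntheticStackSpec, rng: np.random.Generator
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Render one stratum texture plus its ground-truth structure masks."""
    shape = (spec.height_px, spec.width_px)
    h, w = shape
    if stratum == Stratum.SC:
        blob = gaussian_filter(rng.standard_normal(shape), spec.speckle_grain_px)
        img = np.clip(0.62 + 0.30 * _standardize(blob), 0, 1)
        masks = {"bright": img > 0.62}
    elif stratum == Stratum.VE:
        img, border = _honeycomb(shape, spec.ve_cell_diameter_px, rng)
        masks = {"border": border, "interior": ~border}
    elif stratum == Stratum.DEJ:
        # background is the basal layer: a markedly finer honeycomb than
        # the spinous keratinocytes of the VE
        img, border = _honeycomb(shape, 0.55 * spec.ve_cell_diameter_px, rng)
        img = 0.85 * img
        disc = np.zeros(shape, dtype=bool)
        annulus = np.zeros(shape, dtype=bool)
        yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        r = spec.papilla_radius_px
        centers_y = rng.uniform(r + 3, h - r - 3, size=spec.papilla_count)
        centers_x = rng.uniform(r + 3, w - r - 3, size=spec.papilla_count)
        for cy, cx in zip(centers_y, centers_x):
            dist = np.hypot(yy - cy, xx - cx)
            disc |= dist < r
            annulus |= (dist >= r) & (dist < r + 3)
        annulus &= ~disc
        img[disc] = 0.08
        img[annulus] = 0.92
        masks = {"disc": disc, "annulus": annulus, "border": border}
    elif stratum == Stratum.PD:
        noise = rng.standard_normal(shape)
        fy = np.fft.fftfreq(h)[:, None]
        fx = np.fft.fftfreq(w)[None, :]
        freq = np.hypot(fy, fx)
        angle = np.degrees(np.arctan2(fy, fx))
        theta = spec.fibril_orientation_deg % 180.0
        # angular wedge perpendicular to the fibre direction
        diff = np.abs(((angle - (theta + 90.0)) + 90.0) % 180.0 - 90.0)
        wedge = np.exp(-0.5 * (diff / spec.fibril_bandwidth_deg) ** 2)
        radial = np.exp(-0.5 * ((freq - 0.12) / 0.05) ** 2)
        spectrum = np.fft.fft2(noise) * wedge * radial
        fib = np.real(np.fft.ifft2(spectrum))
        img = np.clip(0.45 + 0.16 * _standardize(fib), 0, 1)
        masks = {}
    else:  # pragma: no cover - enum is total
        raise SyntheticError(f"unknown stratum {stratum!r}")
    if spec.noise_sigma > 0:
        img = img + spec.noise_sigma * rng.standard_normal(shape)
    return np.clip(img, 0, 1), masks


def render_stratum_texture(
    stratum: Stratum, spec: SyntheticStackSpec, rng: np.random.Generator
) -> np.ndarray:
    """Render one en-face texture image in [0, 1] for a stratum."""
    img, _ = _render_with_masks(stratum, spec, rng)
    return img


def section_strata(spec: SyntheticStackSpec) -> list[Stratum]:
    """Stratum of every section, superficial to deep."""
    out: list[Stratum] = []
    for stratum, thickness in zip(Stratum, spec.strata_thicknesses):
        out.extend([stratum] * thickness)
    return out


def generate_stack(
    spec: SyntheticStackSpec,
    *,
    stack_id: str = "synthetic",
    participant_id: str = "p0",
    body_site: str = "dorsal",
    age_group: str = "20-30",
    phototype: str | None = "II",
) -> tuple[DepthStack, LabelTable, InterfaceDepths]:
    """Generate one stack plus its label table and true interface depths.

    With ``furrow_depth_sections`` > 0 a localised disc region of each
    shallow section is overwritten with the texture found
    ``furrow_depth_sections`` deeper, emulating a skin furrow carrying
    deeper strata up into superficial sections.  Labels keep the
    one-stratum-per-section convention of the surrounding skin.
    """
    rng = np.random.default_rng(spec.rng_seed)
    strata = section_strata(spec)
    sections = []
    for stratum in strata:
        img, _ = _render_with_masks(stratum, spec, rng)
        sections.append(img)
    if spec.furrow_depth_sections > 0:
        h, w = spec.height_px, spec.width_px
        cy, cx = rng.uniform(0.3, 0.7) * h, rng.uniform(0.3, 0.7) * w
        radius = 0.18 * min(h, w)
        yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        furrow = np.hypot(yy - cy, xx - cx) < radius
        for i in range(len(sections)):
            j = min(i + spec.furrow_depth_sections, len(sections) - 1)
            if strata[j] != strata[i]:
                deep_img, _ = _render_with_masks(strata[j], spec, rng)
                sections[i] = np.where(furrow, deep_img, sections[i])
    stack = DepthStack(
        sections=np.stack(sections),
        spacing_um=spec.spacing_um,
        stack_id=stack_id,
        participant_id=participant_id,
        body_site=body_site,
        age_group=age_group,
        phototype=phototype,
    )
    labels = LabelTable(
        pd.DataFrame(
            {
                "stack_id": stack_id,
                "section_index": np.arange(len(strata)),
                "stratum": strata,
            }
        )
    )
    truth = estimate_interfaces(strata, spec.spacing_um)
    return stack, labels, truth


#: participant-level parameter ranges (low, high); integers drawn inclusive.
DEFAULT_SPEC_RANGES: dict[str, tuple[float, float]] = {
    "sc_thickness": (6, 12),
    "ve_thickness": (10, 18),
    "dej_thickness": (8, 14),
    "pd_thickness": (8, 16),
    "ve_cell_diameter_px": (10.0, 14.0),
    "papilla_radius_px": (8.0, 12.0),
    "papilla_count": (20, 35),
    "speckle_grain_px": (3.0, 5.0),
    "fibril_orientation_deg": (0.0, 180.0),
    "fibril_bandwidth_deg": (30.0, 60.0),
}


@dataclass
class SyntheticCohort:
    """A cohort of synthetic stacks with labels, truth and metadata."""

    stacks: list[DepthStack]
    labels: LabelTable
    truth: dict[str, InterfaceDepths]
    metadata: pd.DataFrame
    specs: dict[str, SyntheticStackSpec] = field(default_factory=dict)


def _draw(rng: np.random.Generator, rng_range, integer: bool = False):
    lo, hi = rng_range
    if lo > hi:
        raise SyntheticError(f"invalid range ({lo}, {hi})")
    if integer:
        return int(rng.integers(int(lo), int(hi) + 1))
    return float(rng.uniform(lo, hi))


AGE_GROUPS = ("20-30", "50-70")
BODY_SITES = ("dorsal", "volar")
PHOTOTYPES = ("I", "II", "III")


def generate_cohort(
    n_participants: int,
    stacks_per_participant: int = 1,
    spec_ranges: dict[str, tuple[float, float]] | None = None,
    rng_seed: int = 0,
    base_spec: SyntheticStackSpec | None = None,
) -> SyntheticCohort:
    """Generate a participant-structured cohort of synthetic stacks.

    Strata thicknesses and texture parameters are drawn once per
    participant from ``spec_ranges`` and shared across that participant's
    stacks (each stack still has its own pixel noise), so partitioning
    folds by participant genuinely tests generalisation to unseen skin.
    """
    if n_participants < 2:
        raise SyntheticError("need at least 2 participants")
    ranges = dict(DEFAULT_SPEC_RANGES)
    if spec_ranges:
        unknown = set(spec_ranges) - set(ranges)
        if unknown:
            raise SyntheticError(f"unknown spec_ranges keys {sorted(unknown)}")
        ranges.update(spec_ranges)
    base = base_spec if base_spec is not None else SyntheticStackSpec()
    rng = np.random.default_rng(rng_seed)
    stacks: list[DepthStack] = []
    label_frames = []
    truth: dict[str, InterfaceDepths] = {}
    specs: dict[str, SyntheticStackSpec] = {}
    meta_rows = []
    for p in range(n_participants):
        pid = f"p{p:03d}"
        age_group = AGE_GROUPS[p % len(AGE_GROUPS)]
        phototype = PHOTOTYPES[int(rng.integers(len(PHOTOTYPES)))]
        participant_spec = replace(
            base,
            strata_thicknesses=(
                _draw(rng, ranges["sc_thickness"], integer=True),
                _draw(rng, ranges["ve_thickness"], integer=True),
                _draw(rng, ranges["dej_thickness"], integer=True),
                _draw(rng, ranges["pd_thickness"], integer=True),
            ),
            ve_cell_diameter_px=_draw(rng, ranges["ve_cell_diameter_px"]),
            papilla_radius_px=_draw(rng, ranges["papilla_radius_px"]),
            papilla_count=_draw(rng, ranges["papilla_count"], integer=True),
            speckle_grain_px=_draw(rng, ranges["speckle_grain_px"]),
            fibril_orientation_deg=_draw(rng, ranges["fibril_orientation_deg"]),
            fibril_bandwidth_deg=_draw(rng, ranges["fibril_bandwidth_deg"]),
        )
        for s in range(stacks_per_participant):
            stack_id = f"{pid}_s{s}"
            body_site = BODY_SITES[s % len(BODY_SITES)]
            stack_spec = replace(
                participant_spec, rng_seed=int(rng.integers(2**31 - 1))
            )
            stack, labels, depths = generate_stack(
                stack_spec,
                stack_id=stack_id,
                participant_id=pid,
                body_site=body_site,
                age_group=age_group,
                phototype=phototype,
            )
            stacks.append(stack)
            label_frames.append(labels.frame)
            truth[stack_id] = depths
            specs[stack_id] = stack_spec
            meta_rows.append(
                {
                    "stack_id": stack_id,
                    "participant_id": pid,
                    "body_site": body_site,
                    "age_group": age_group,
                    "phototype": phototype,
                }
            )
    labels = LabelTable(pd.concat(label_frames, ignore_index=True))
    return SyntheticCohort(
        stacks=stacks,
        labels=labels,
        truth=truth,
        metadata=pd.DataFrame(meta_rows),
        specs=specs,
    )
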