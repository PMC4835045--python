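"""Reading and writing RCM depth stacks, label tables and predictions.

A depth stack is an ordered sequence of grayscale en-face sections imaged
at increasing depth below the skin surface.  Section index 0 is the most
superficial section and the depth of section ``i`` is ``i * spacing_um``
micrometres below the first imaged section.  Each section is assumed to
contain a single anatomical stratum; the four strata follow the fixed
anatomical order SC < VE < DEJ < PD (superficial to deep).
"""

from __future__ import annotations

import enum
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile


class StackIOError(ValueError):
    """Base class for stack/label I/O contract violations."""


class DimensionError(StackIOError):
    """Sections of one stack do not share identical dimensions."""


class EmptyStackError(StackIOError):
    """No sections found at the given path."""


class FormatError(StackIOError):
    """Input images are not grayscale or otherwise malformed."""


class LabelParseError(StackIOError):
    """A label table row could not be parsed."""


class DuplicateLabelError(StackIOError):
    """Two rows label the same (stack_id, section_index)."""


class CompletenessError(StackIOError):
    """A prediction table does not cover every section."""


class LabelOrderWarning(UserWarning):
    """Strata labels within a stack are not monotone with depth."""


@enum.unique
class Stratum(enum.IntEnum):
    """The four anatomical strata, ordered superficial to deep.

    SC: stratum corneum, VE: viable epidermis, DEJ: dermal-epidermal
    junction, PD: papillary dermis.  The integer values encode the
    canonical anatomical order, so comparisons like ``Stratum.SC <
    Stratum.PD`` hold.
    """

    SC = 0
    VE = 1
    DEJ = 2
    PD = 3

    @classmethod
    def parse(cls, token) -> "Stratum":
        """Parse a stratum symbol case-insensitively (or its ordinal)."""
        if isinstance(token, (int, np.integer)):
            try:
                return cls(int(token))
            except ValueError:
                raise LabelParseError(f"unknown stratum ordinal {token!r}") from None
        try:
            return cls[str(token).strip().upper()]
        except KeyError:
            raise LabelParseError(
                f"unknown stratum token {token!r}; expected one of "
                f"{[s.name for s in cls]}"
            ) from None


#: Strata in canonical anatomical order (column/row order of all tables).
STRATA_ORDER: tuple[Stratum, ...] = tuple(Stratum)
STRATA_NAMES: tuple[str, ...] = tuple(s.name for s in Stratum)


@dataclass
class DepthStack:
    """An ordered stack of grayscale en-face sections plus metadata."""

    sections: np.ndarray  # (n_sections, height, width) float array in [0, 1]
    spacing_um: float = 2.0
    stack_id: str = "stack"
    participant_id: str = ""
    body_site: str = ""  # "dorsal" | "volar"
    age_group: str = ""
    phototype: str | None = None

    def __post_init__(self) -> None:
        self.sections = np.asarray(self.sections)
        if self.sections.ndim != 3:
            raise DimensionError(
                "sections must be a 3-D array (n_sections, height, width); "
                f"got shape {self.sections.shape}"
            )
        if self.sections.shape[0] == 0:
            raise EmptyStackError(f"stack {self.stack_id!r} has no sections")
        if not self.spacing_um > 0:
            raise StackIOError(f"spacing_um must be > 0, got {self.spacing_um}")

    @property
    def n_sections(self) -> int:
        return int(self.sections.shape[0])

    def depth_um(self, section_index: int) -> float:
        """Depth of a section below the first imaged section, in um."""
        return section_index * self.spacing_um


@dataclass
class LabelTable:
    """Validated per-section stratum labels for one or more stacks."""

    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["stack_id", "section_index", "stratum"]
        )
    )

    def __post_init__(self) -> None:
        df = self.frame.copy()
        required = ["stack_id", "section_index", "stratum"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise LabelParseError(f"label table missing columns {missing}")
        df["stack_id"] = df["stack_id"].astype(str)
        df["section_index"] = df["section_index"].astype(int)
        df["stratum"] = pd.Series(
            [s if isinstance(s, Stratum) else Stratum.parse(s) for s in df["stratum"]],
            index=df.index,
            dtype=object,  # keep Stratum objects; plain int64 would lose .name
        )
        dup = df.duplicated(subset=["stack_id", "section_index"])
        if dup.any():
            pairs = df.loc[dup, ["stack_id", "section_index"]].to_records(index=False)
            raise DuplicateLabelError(f"duplicate labels for {list(pairs)[:5]}")
        for stack_id, grp in df.groupby("stack_id"):
            order = grp.sort_values("section_index")["stratum"].to_numpy()
            if np.any(np.diff([int(s) for s in order]) < 0):
                warnings.warn(
                    f"stack {stack_id!r}: strata labels are not monotone "
                    "non-decreasing with depth",
                    LabelOrderWarning,
                    stacklevel=2,
                )
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def for_stack(self, stack_id: str) -> list[Stratum]:
        """Labels of one stack ordered by section index."""
        grp = self.frame[self.frame["stack_id"] == str(stack_id)]
        return list(grp.sort_values("section_index")["stratum"])


def _to_unit_range(img: np.ndarray) -> np.ndarray:
    """Map integer images to [0, 1] by dividing by the dtype maximum."""
    if img.dtype.kind in "ui":
        return img.astype(np.float64) / np.iinfo(img.dtype).max
    out = img.astype(np.float64)
    return out


def _check_grayscale(img: np.ndarray, origin: str) -> np.ndarray:
    if img.ndim == 3 and img.shape[-1] in (3, 4):
        # allow colour files that are actually gray (all channels equal)
        if np.array_equal(img[..., 0], img[..., 1]) and np.array_equal(
            img[..., 0], img[..., min(2, img.shape[-1] - 1)]
        ):
            return img[..., 0]
        raise FormatError(f"{origin}: colour images are not supported")
    if img.ndim != 2:
        raise FormatError(f"{origin}: expected a 2-D grayscale image, got shape {img.shape}")
    return img


_NUM_RE = re.compile(r"(\d+)")


def _natural_key(name: str) -> tuple:
    """Sort key treating digit runs numerically (s2 < s10)."""
    return tuple(int(t) if t.isdigit() else t for t in _NUM_RE.split(name))


IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"}


def read_stack(
    path: str | Path,
    spacing_um: float = 2.0,
    *,
    stack_id: str | None = None,
    **metadata,
) -> DepthStack:
    """Read a depth stack from a multi-page TIFF or a directory of images.

    Sections are ordered page order (TIFF) or natural filename order
    (directory), most superficial first.  Pixel values are mapped to the
    floating range [0, 1] by dividing by the dtype maximum.
    """
    path = Path(path)
    frames: list[np.ndarray] = []
    if path.is_dir():
        files = sorted(
            (f for f in path.iterdir() if f.suffix.lower() in IMAGE_SUFFIXES),
            key=lambda f: _natural_key(f.name),
        )
        if not files:
            raise EmptyStackError(f"no image files in directory {path}")
        for f in files:
            frames.append(_check_grayscale(iio.imread(f), str(f)))
    else:
        with tifffile.TiffFile(path) as tf:
            if len(tf.pages) == 0:
                raise EmptyStackError(f"no pages in TIFF {path}")
            for page in tf.pages:
                frames.append(_check_grayscale(page.asarray(), str(path)))
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise DimensionError(f"mixed section dimensions {sorted(shapes)} in {path}")
    sections = np.stack([_to_unit_range(f) for f in frames])
    return DepthStack(
        sections=sections,
        spacing_um=spacing_um,
        stack_id=stack_id if stack_id is not None else path.stem,
        **metadata,
    )


def write_stack(stack: DepthStack, path: str | Path) -> None:
    """Write a stack as an 8-bit multi-page TIFF (inverse of read_stack)."""
    data = np.clip(stack.sections, 0.0, 1.0)
    tifffile.imwrite(Path(path), (data * 255).round().astype(np.uint8))


def read_labels(path: str | Path) -> LabelTable:
    """Read a per-section label CSV with header stack_id,section_index,stratum."""
    df = pd.read_csv(path, dtype={"stack_id": str})
    return LabelTable(df)


def write_labels(labels: LabelTable, path: str | Path) -> None:
    df = labels.frame.copy()
    df["stratum"] = [s.name for s in df["stratum"]]
    df.to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-stack metadata CSV (stack_id, participant_id, ...)."""
    df = pd.read_csv(path, dtype=str)
    if "stack_id" not in df.columns or "participant_id" not in df.columns:
        raise StackIOError("metadata CSV requires stack_id and participant_id columns")
    return df


def write_predictions(stack_predictions: Iterable, path: str | Path) -> None:
    """Write per-section predictions as CSV.

    Columns: stack_id, section_index, predicted_stratum, p_SC, p_VE,
    p_DEJ, p_PD.  Every section of every stack must be covered.
    """
    rows = []
    preds = list(stack_predictions)
    if not preds:
        raise CompletenessError("no predictions to write")
    for sp in preds:
        n = len(sp.labels)
        if n == 0 or sp.probabilities.shape != (n, 4):
            raise CompletenessError(
                f"stack {sp.stack_id!r}: predictions do not cover all sections"
            )
        for i in range(n):
            rows.append(
                {
                    "stack_id": sp.stack_id,
                    "section_index": i,
                    "predicted_stratum": sp.labels[i].name,
                    **{
                        f"p_{s}": sp.probabilities[i, j]
                        for j, s in enumerate(STRATA_NAMES)
                    },
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    """Read a predictions CSV back as a DataFrame (labels parsed)."""
    df = pd.read_csv(path, dtype={"stack_id": str})
    df["predicted_stratum"] = [Stratum.parse(s) for s in df["predicted_stratum"]]
    return df
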