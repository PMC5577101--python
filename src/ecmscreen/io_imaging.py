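"""Field/well image I/O and plate-layout handling.

A high-content reader acquires four fields per well of a 384-well plate;
with 2 x 2 camera binning each field is 1104 x 1104 px. All downstream
image analysis operates on the *well image*: the four fields tiled into a
single 2208 x 2208 mosaic.

Conventions used throughout the package:

* arrays are indexed ``(row, col)``, 0-based, origin top-left;
* images are kept at native unsigned-integer camera scale — no rescaling
  on load (the branch inclusion band is defined on native counts);
* tiling is row-major by ``field_index``: field 0 top-left, 1 top-right,
  2 bottom-left, 3 bottom-right (configurable, see :func:`tile_fields`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import FilenameParseError, ImageFormatError, PlateLayoutError

#: Native field edge length (px) after 2 x 2 binning.
NATIVE_FIELD_SIZE = 1104

#: Default filename convention: ``{plate}_{well}_f{field}.tif``.
DEFAULT_FILENAME_REGEX = r"^(?P<plate>[^_]+)_(?P<well>[A-P]\d{2})_f(?P<field>\d)\.tiff?$"

_CONTROL_ROLES = {"unstimulated-control", "stimulated-control", "test"}


@dataclass(frozen=True)
class FieldImage:
    """One acquired field: an unsigned-integer intensity grid plus identity."""

    pixels: np.ndarray
    well_id: str
    field_index: int
    bit_depth: int

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 2:
            raise ImageFormatError(f"field image must be 2-D, got shape {px.shape}")
        if self.bit_depth not in (8, 16):
            raise ImageFormatError(f"bit depth must be 8 or 16, got {self.bit_depth}")
        if px.dtype not in (np.uint8, np.uint16):
            raise ImageFormatError(f"field pixels must be uint8/uint16, got {px.dtype}")
        if int(self.field_index) not in (0, 1, 2, 3):
            raise ImageFormatError(f"field_index must be 0-3, got {self.field_index}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class WellImage:
    """Tiled per-well mosaic; the unit of all image analysis."""

    pixels: np.ndarray
    well_id: str
    source_fields: tuple[int, ...] = (0, 1, 2, 3)
    pixel_size_um: float | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _dtype_for(bit_depth: int) -> np.dtype:
    return np.dtype(np.uint8 if bit_depth == 8 else np.uint16)


def read_field_image(path: str | Path, filename_regex: str = DEFAULT_FILENAME_REGEX) -> FieldImage:
    """Load a single-plane grayscale TIFF field, parsing well/field from its name.

    The filename pattern is a regex with named groups ``well`` and ``field``
    (``plate`` optional); override it for other acquisition conventions.
    """
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise ImageFormatError(f"{path} is not a readable TIFF: {exc}") from exc
    if arr.ndim == 3:
        raise ImageFormatError(f"{path}: unsupported channel count (shape {arr.shape}); expected single-plane grayscale")
    if arr.ndim != 2:
        raise ImageFormatError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        bit_depth = 8
    elif arr.dtype == np.uint16:
        bit_depth = 16
    else:
        raise ImageFormatError(f"{path}: unsupported sample format {arr.dtype}; expected uint8 or uint16")
    m = re.match(filename_regex, path.name)
    if not m or "well" not in m.groupdict() or "field" not in m.groupdict():
        raise FilenameParseError(f"cannot parse well/field from filename {path.name!r} with pattern {filename_regex!r}")
    return FieldImage(pixels=arr, well_id=m.group("well"), field_index=int(m.group("field")), bit_depth=bit_depth)


def write_field_image(path: str | Path, image: FieldImage) -> None:
    """Write a field losslessly as a single-plane grayscale TIFF."""
    tifffile.imwrite(Path(path), image.pixels.astype(_dtype_for(image.bit_depth), copy=False))


def tile_fields(fields: Sequence[FieldImage], order: Sequence[int] = (0, 1, 2, 3)) -> WellImage:
    """Tile the four fields of one well into a 2 x 2 row-major mosaic.

    ``order`` lists the field_index placed at (top-left, top-right,
    bottom-left, bottom-right). With native 1104 px fields the result is
    2208 x 2208.
    """
    if len(fields) != 4:
        raise ImageFormatError(f"exactly 4 fields required, got {len(fields)}")
    wells = {f.well_id for f in fields}
    if len(wells) != 1:
        raise ImageFormatError(f"fields belong to different wells: {sorted(wells)}")
    shapes = {f.pixels.shape for f in fields}
    if len(shapes) != 1:
        raise ImageFormatError(f"fields have mismatched sizes: {sorted(shapes)}")
    depths = {f.bit_depth for f in fields}
    if len(depths) != 1:
        raise ImageFormatError(f"fields have mismatched bit depths: {sorted(depths)}")
    idx = {f.field_index: f for f in fields}
    if set(idx) != {0, 1, 2, 3}:
        raise ImageFormatError(f"field_index values must be {{0,1,2,3}}, got {sorted(idx)}")
    if sorted(order) != [0, 1, 2, 3]:
        raise ImageFormatError(f"tiling order must be a permutation of 0-3, got {order}")
    tl, tr, bl, br = (idx[i].pixels for i in order)
    mosaic = np.block([[tl, tr], [bl, br]])
    return WellImage(pixels=mosaic, well_id=fields[0].well_id, source_fields=tuple(order))


def split_well(well: WellImage, bit_depth: int = 16) -> list[FieldImage]:
    """Slice a well mosaic back into its four quadrant fields (inverse of tiling)."""
    h, w = well.pixels.shape
    if h % 2 or w % 2:
        raise ImageFormatError(f"well image dimensions must be even to split, got {well.pixels.shape}")
    hh, hw = h // 2, w // 2
    quads = [well.pixels[:hh, :hw], well.pixels[:hh, hw:], well.pixels[hh:, :hw], well.pixels[hh:, hw:]]
    return [FieldImage(pixels=np.ascontiguousarray(q), well_id=well.well_id, field_index=i, bit_depth=bit_depth)
            for i, q in enumerate(quads)]


_CONC_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*([^\s]+)?\s*$")


def parse_concentration(text: str | float) -> tuple[float, str | None]:
    """Parse ``"10 ng/mL"`` -> ``(10.0, "ng/mL")``; bare numbers keep unit None."""
    if isinstance(text, (int, float)):
        return float(text), None
    m = _CONC_RE.match(str(text))
    if not m:
        raise PlateLayoutError(f"cannot parse concentration {text!r}")
    return float(m.group(1)), m.group(2)


@dataclass
class PlateLayout:
    """Well -> (experiment, stimulus, treatment, role, replicate) mapping.

    Thin wrapper over a validated DataFrame with the canonical columns; all
    aggregation (controls, replicates, dose series) is driven by this table.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED_COLUMNS = (
        "well_id", "experiment_id", "stimulus", "stimulus_conc", "stimulus_unit",
        "treatment", "treatment_conc", "treatment_unit", "role", "replicate",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise PlateLayoutError(f"plate map is missing columns: {missing}")
        dupes = self.table["well_id"][self.table["well_id"].duplicated()].tolist()
        if dupes:
            raise PlateLayoutError(f"duplicate well_id(s) in plate map: {sorted(set(dupes))}")
        bad_roles = self.table.loc[~self.table["role"].isin(_CONTROL_ROLES)]
        if len(bad_roles):
            raise PlateLayoutError(
                "unknown role(s) "
                f"{sorted(bad_roles['role'].unique())} in rows {bad_roles.index.tolist()}"
            )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def well_ids(self) -> list[str]:
        return self.table["well_id"].tolist()

    def wells_with_role(self, role: str) -> list[str]:
        return self.table.loc[self.table["role"] == role, "well_id"].tolist()

    def require_controls(self) -> None:
        """Check the layout supports percent-inhibition (both control roles present)."""
        for role in ("stimulated-control", "unstimulated-control"):
            if not self.wells_with_role(role):
                raise PlateLayoutError(f"plate map has no {role} wells; percent inhibition needs both control roles")


def read_plate_map(path: str | Path, require_controls: bool = False) -> PlateLayout:
    """Read and validate a plate-map CSV (see :attr:`PlateLayout.REQUIRED_COLUMNS`).

    Concentration columns may carry units inline ("10 ng/mL"); they are split
    into the numeric and unit columns on load.
    """
    df = pd.read_csv(path)
    for conc_col, unit_col in (("stimulus_conc", "stimulus_unit"), ("treatment_conc", "treatment_unit")):
        if conc_col in df.columns and df[conc_col].dtype == object:
            parsed = df[conc_col].map(lambda s: parse_concentration(s) if pd.notna(s) else (np.nan, None))
            df[conc_col] = [p[0] for p in parsed]
            if unit_col not in df.columns or df[unit_col].isna().all():
                df[unit_col] = [p[1] for p in parsed]
    layout = PlateLayout(df)
    if require_controls:
        layout.require_controls()
    return layout
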