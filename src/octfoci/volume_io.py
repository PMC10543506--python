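"""Readers and writers for volumes, surfaces, masks, ledgers, counts and config.

On-disk formats are deliberately plain so fixtures are inspectable and
diff-able:

* OCT volumes — multi-page 16-bit grayscale TIFF, one page per B-scan, page
  rows = depth, page columns = A-scans.
* Binary masks — single-page 8-bit TIFF with values 0 / 255.
* Surfaces — CSV ``bscan,ascan,z_ilm,z_rpe``, one row per lateral position,
  heights in fractional depth-voxels (0-based).
* Foci truth ledgers, lesion tables, per-slab counts — CSV.
* Configuration — YAML mappings; unknown keys warn, missing keys take the
  documented defaults.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import FormatError, SegmentationError

logger = logging.getLogger(__name__)

LEDGER_COLUMNS = ["focus_id", "b", "a", "d", "radius_px", "peak_intensity", "expected_slab"]


@dataclass
class OCTVolume:
    """A 3-D OCT intensity grid indexed (b-scan, a-scan, depth).

    Depth index increases from the vitreous (inner retina) toward the choroid
    (outer), so the ILM surface height is smaller than the RPE height.
    ``extent_mm`` is the lateral field of view (square scan region).
    """

    intensity: np.ndarray  # (n_bscans, n_ascans, n_depth), unsigned 16-bit
    extent_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.intensity.ndim != 3 or min(self.intensity.shape) < 1:
            raise ValueError("intensity must be a non-empty 3-D grid")
        if np.any(np.asarray(self.intensity) < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_bscans(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_ascans(self) -> int:
        return self.intensity.shape[1]

    @property
    def n_depth(self) -> int:
        return self.intensity.shape[2]

    @property
    def mm_per_ascan(self) -> float:
        return self.extent_mm / self.n_ascans

    @property
    def mm_per_bscan(self) -> float:
        return self.extent_mm / self.n_bscans


@dataclass
class SurfaceMap:
    """Per-(b-scan, a-scan) ILM and RPE surface heights in fractional voxels."""

    z_ilm: np.ndarray  # (n_bscans, n_ascans), float
    z_rpe: np.ndarray

    def __post_init__(self) -> None:
        self.z_ilm = np.asarray(self.z_ilm, dtype=float)
        self.z_rpe = np.asarray(self.z_rpe, dtype=float)
        if self.z_ilm.shape != self.z_rpe.shape or self.z_ilm.ndim != 2:
            raise ValueError("z_ilm and z_rpe must be 2-D arrays of equal shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.z_ilm.shape

    @property
    def thickness(self) -> np.ndarray:
        return self.z_rpe - self.z_ilm

    def validate(self, vol: OCTVolume | None = None) -> None:
        """Reject inverted/degenerate surfaces and out-of-volume heights."""
        bad = self.z_ilm >= self.z_rpe
        if bad.any():
            b, a = np.argwhere(bad)[0]
            raise SegmentationError(
                f"gross segmentation error: z_ilm >= z_rpe at (bscan={b}, ascan={a})"
            )
        if vol is not None:
            if self.shape != (vol.n_bscans, vol.n_ascans):
                raise FormatError(
                    f"surface grid {self.shape} does not match volume lateral grid "
                    f"({vol.n_bscans}, {vol.n_ascans})"
                )
            if self.z_ilm.min() < 0 or self.z_rpe.max() >= vol.n_depth:
                raise SegmentationError("surface heights outside the volume depth range")


# ---------------------------------------------------------------------------
# volumes

def write_volume(vol: OCTVolume, path: str | Path) -> None:
    """Write a volume as a multi-page 16-bit TIFF (one page per B-scan)."""
    arr = np.asarray(vol.intensity)
    if arr.dtype != np.uint16:
        if arr.min() < 0 or arr.max() > np.iinfo(np.uint16).max:
            raise FormatError("volume intensities not representable as 16-bit")
        arr = arr.astype(np.uint16)
    # page layout: rows = depth, cols = a-scans
    pages = np.transpose(arr, (0, 2, 1))
    tifffile.imwrite(str(path), pages, photometric="minisblack")


def read_volume(path: str | Path, extent_mm: float = 6.0) -> OCTVolume:
    """Read a multi-page 16-bit TIFF volume written by :func:`write_volume`."""
    path = Path(path)
    try:
        with tifffile.TiffFile(str(path)) as tif:
            shapes = {p.shape for p in tif.pages}
            if len(shapes) != 1:
                raise FormatError(f"{path}: pages have differing shapes {sorted(shapes)}")
            pages = tif.asarray()
    except FormatError:
        raise
    except Exception as exc:  # tifffile raises several internal types
        raise FormatError(f"{path}: not a readable TIFF volume ({exc})") from exc
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise FormatError(f"{path}: expected grayscale pages, got shape {pages.shape}")
    if pages.dtype != np.uint16:
        raise FormatError(f"{path}: unsupported bit depth {pages.dtype}, expected uint16")
    intensity = np.transpose(pages, (0, 2, 1))  # (B, D, A) -> (B, A, D)
    return OCTVolume(intensity=intensity, extent_mm=extent_mm)


# ---------------------------------------------------------------------------
# binary masks

def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean lateral mask as an 8-bit 0/255 TIFF."""
    arr = (np.asarray(mask, dtype=bool).astype(np.uint8)) * 255
    tifffile.imwrite(str(path), arr, photometric="minisblack")


def read_mask(path: str | Path) -> np.ndarray:
    path = Path(path)
    try:
        arr = tifffile.imread(str(path))
    except Exception as exc:
        raise FormatError(f"{path}: not a readable TIFF mask ({exc})") from exc
    if arr.ndim != 2:
        raise FormatError(f"{path}: mask must be a single 2-D page")
    return np.asarray(arr) > 0


# ---------------------------------------------------------------------------
# surfaces

def write_surfaces(surf: SurfaceMap, path: str | Path) -> None:
    n_b, n_a = surf.shape
    b, a = np.meshgrid(np.arange(n_b), np.arange(n_a), indexing="ij")
    df = pd.DataFrame(
        {
            "bscan": b.ravel(),
            "ascan": a.ravel(),
            "z_ilm": surf.z_ilm.ravel(),
            "z_rpe": surf.z_rpe.ravel(),
        }
    )
    df.to_csv(path, index=False)


def read_surfaces(path: str | Path, vol: OCTVolume) -> SurfaceMap:
    """Read a surface CSV and validate it against ``vol``.

    Every lateral position of the volume must be present exactly once; the
    first missing position is named in the error.  Inverted or degenerate
    surfaces (z_ilm >= z_rpe anywhere) are rejected as gross segmentation
    errors so no downstream stage ever sees them.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: unreadable CSV ({exc})") from exc
    required = {"bscan", "ascan", "z_ilm", "z_rpe"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    n_b, n_a = vol.n_bscans, vol.n_ascans
    z_ilm = np.full((n_b, n_a), np.nan)
    z_rpe = np.full((n_b, n_a), np.nan)
    bi = df["bscan"].to_numpy(dtype=int)
    ai = df["ascan"].to_numpy(dtype=int)
    if bi.min(initial=0) < 0 or ai.min(initial=0) < 0 or bi.max(initial=0) >= n_b or ai.max(initial=0) >= n_a:
        raise FormatError(f"{path}: lateral indices outside the volume grid")
    z_ilm[bi, ai] = df["z_ilm"].to_numpy(dtype=float)
    z_rpe[bi, ai] = df["z_rpe"].to_numpy(dtype=float)
    missing = np.isnan(z_ilm) | np.isnan(z_rpe)
    if missing.any():
        b, a = np.argwhere(missing)[0]
        raise FormatError(
            f"{path}: missing surface heights, first at (bscan={b}, ascan={a})"
        )
    surf = SurfaceMap(z_ilm=z_ilm, z_rpe=z_rpe)
    surf.validate(vol)
    return surf


# ---------------------------------------------------------------------------
# foci truth ledgers, lesion tables, counts

def write_ledger(ledger: pd.DataFrame, path: str | Path) -> None:
    ledger.to_csv(path, index=False, columns=LEDGER_COLUMNS)


def read_ledger(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(LEDGER_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: ledger missing columns {sorted(missing)}")
    return df[LEDGER_COLUMNS]


def write_lesions(lesions: pd.DataFrame, path: str | Path) -> None:
    lesions.to_csv(path, index=False)


def read_lesions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "eye_id" not in df.columns or "total" not in df.columns:
        raise FormatError(f"{path}: counts file missing eye_id/total columns")
    return df


# ---------------------------------------------------------------------------
# configuration

def load_config(path: str | Path) -> dict:
    """Load a YAML configuration mapping (empty file -> empty dict)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: top-level config must be a mapping")
    return data


def save_config(data: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def warn_unknown_keys(data: dict, known: set[str], context: str) -> None:
    unknown = set(data) - known
    if unknown:
        logger.warning("%s: ignoring unknown config keys %s", context, sorted(unknown))
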