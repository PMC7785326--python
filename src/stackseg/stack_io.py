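"""Reading and writing hyper-labeled stacks, masks, and dataset manifests.

A *hyper-labeled stack* is a set of co-registered single-cell channel
images: three fluorescence markers (cytoplasm, membrane, mitochondria) and
up to seven transmitted-light (brightfield) focal planes acquired at signed
defocus offsets in micrometres.  Channel identity is carried by NAME, never
by page index, so stacks with missing channels remain usable; the canonical
order below is only a presentation order.

On disk a stack is a multi-page TIFF with one page per channel.  Each page
stores a JSON description tag ``{"channel": name, "max_value": v}``;
intensities are mapped to ``[0, 1]`` on read using ``max_value`` (falling
back to the dtype maximum).  Masks are single-cell binary PNGs with values
``{0, 255}`` on disk and ``{0, 1}`` in memory.  Manifests are CSV.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

#: Canonical channel names in canonical presentation order.
CANONICAL_CHANNELS: tuple[str, ...] = (
    "cyto", "mem", "mito",
    "bf-10", "bf-5", "bf-3", "bf0", "bf+3", "bf+5", "bf+10",
)

FLUORESCENCE_CHANNELS: tuple[str, ...] = ("cyto", "mem", "mito")
BRIGHTFIELD_CHANNELS: tuple[str, ...] = (
    "bf-10", "bf-5", "bf-3", "bf0", "bf+3", "bf+5", "bf+10",
)
#: Out-of-focus brightfield planes (everything but the in-focus plane).
OOF_CHANNELS: tuple[str, ...] = ("bf-10", "bf-5", "bf-3", "bf+3", "bf+5", "bf+10")
LOWER_OOF_CHANNELS: tuple[str, ...] = ("bf-10", "bf-5", "bf-3")
UPPER_OOF_CHANNELS: tuple[str, ...] = ("bf+3", "bf+5", "bf+10")

#: Focal offset in micrometres for each brightfield channel name.
FOCAL_OFFSETS_UM: dict[str, float] = {
    "bf-10": -10.0, "bf-5": -5.0, "bf-3": -3.0, "bf0": 0.0,
    "bf+3": 3.0, "bf+5": 5.0, "bf+10": 10.0,
}


class StackIOError(Exception):
    """Base error for stack/mask/manifest I/O."""


class DuplicateChannelError(StackIOError):
    pass


class ShapeMismatchError(StackIOError):
    pass


class NonBinaryMaskError(StackIOError):
    pass


class UnknownChannelError(StackIOError):
    pass


def normalize_channel_name(name: str) -> str:
    """Normalize a channel name (unicode minus, case, whitespace)."""
    name = name.strip().replace("−", "-").replace("μ", "u")
    return name.lower()


def validate_channel_name(name: str) -> str:
    norm = normalize_channel_name(name)
    if norm not in CANONICAL_CHANNELS:
        raise UnknownChannelError(
            f"unknown channel {name!r}; valid names: {', '.join(CANONICAL_CHANNELS)}"
        )
    return norm


def canonical_sort(names) -> list[str]:
    """Sort channel names into canonical order; unknown names go last."""
    order = {n: i for i, n in enumerate(CANONICAL_CHANNELS)}
    return sorted(names, key=lambda n: order.get(n, len(order)))


@dataclass
class HyperStack:
    """Named, co-registered channel images of a single cell field.

    ``channels`` maps channel name -> float array of shape (H, W) with
    values in [0, 1].  Order of insertion is preserved.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise StackIOError("a HyperStack requires at least one channel")
        shapes = {v.shape for v in self.channels.values()}
        if len(shapes) != 1:
            raise ShapeMismatchError(f"channel shapes differ: {sorted(shapes)}")
        for name, img in self.channels.items():
            if img.ndim != 2:
                raise ShapeMismatchError(f"channel {name!r} is not 2-D")
            if not np.all(np.isfinite(img)):
                raise StackIOError(f"channel {name!r} contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


@dataclass
class MaskLabel:
    """Binary single-cell ground truth: 1 = cell, 0 = background."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        vals = np.unique(arr)
        if not np.isin(vals, [0, 1]).all():
            raise NonBinaryMaskError(f"mask contains non-binary values: {vals[:10]}")
        self.pixels = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def write_hyperstack(stack: HyperStack, path, dtype: str = "uint16") -> None:
    """Write a stack as a multi-page TIFF, one named page per channel.

    ``dtype`` is ``uint16`` (default; values quantized to 1/65535) or
    ``float32`` (lossless).  A JSON description tag per page records the
    channel name and the max value used for normalization.
    """
    path = Path(path)
    if dtype not in ("uint8", "uint16", "float32"):
        raise StackIOError(f"unsupported dtype {dtype!r}")
    try:
        with tifffile.TiffWriter(path) as tif:
            for name, img in stack.channels.items():
                img = np.asarray(img, dtype=np.float64)
                if img.min() < -1e-9 or img.max() > 1 + 1e-9:
                    raise StackIOError(
                        f"channel {name!r} out of [0, 1]: "
                        f"range [{img.min():.4g}, {img.max():.4g}]"
                    )
                img = np.clip(img, 0.0, 1.0)
                if dtype == "float32":
                    page = img.astype(np.float32)
                else:
                    top = np.iinfo(np.dtype(dtype)).max
                    page = np.round(img * top).astype(dtype)
                desc = json.dumps(
                    {"channel": name, "max_value": 1.0,
                     "pixel_size_um": stack.pixel_size_um,
                     "source_id": stack.source_id}
                )
                tif.write(page, description=desc, contiguous=False)
    except OSError as exc:
        raise StackIOError(f"cannot write stack to {path}: {exc}") from exc


def read_hyperstack(path, channel_names: list[str] | None = None) -> HyperStack:
    """Read a multi-page TIFF into a :class:`HyperStack`.

    Channel names come from the per-page JSON description tag; a
    ``channel_names`` list may be supplied for files written by other tools
    (one name per page, in page order).  Channels are re-ordered into
    canonical order where recognized.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            pages = list(tif.pages)
            raw: list[tuple[str, np.ndarray, float | None, dict]] = []
            for i, page in enumerate(pages):
                arr = page.asarray()
                meta: dict = {}
                desc = page.description
                if desc:
                    try:
                        meta = json.loads(desc)
                    except (ValueError, TypeError):
                        meta = {}
                if channel_names is not None:
                    name = channel_names[i]
                elif "channel" in meta:
                    name = str(meta["channel"])
                else:
                    name = f"page{i}"
                raw.append((normalize_channel_name(name), arr,
                            meta.get("max_value"), meta))
    except (OSError, tifffile.TiffFileError) as exc:
        raise StackIOError(f"cannot read stack from {path}: {exc}") from exc

    shapes = {arr.shape for _, arr, _, _ in raw}
    if len(shapes) != 1:
        raise ShapeMismatchError(f"pages of {path} have differing shapes: {sorted(shapes)}")
    names = [n for n, _, _, _ in raw]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise DuplicateChannelError(f"duplicate channel names in {path}: {sorted(dupes)}")

    channels: dict[str, np.ndarray] = {}
    pixel_size = None
    source_id = ""
    by_name = {n: (arr, maxv, meta) for n, arr, maxv, meta in raw}
    for name in canonical_sort(names):
        arr, maxv, meta = by_name[name]
        if np.issubdtype(arr.dtype, np.integer):
            # max_value metadata records the physical value that maps to
            # the dtype maximum; absent metadata falls back to dtype max.
            scale = float(maxv) if maxv else 1.0
            img = arr.astype(np.float32) * (scale / float(np.iinfo(arr.dtype).max))
        else:
            img = arr.astype(np.float32)
        channels[name] = np.clip(img, 0.0, 1.0)
        if meta.get("pixel_size_um") is not None:
            pixel_size = float(meta["pixel_size_um"])
        if meta.get("source_id"):
            source_id = str(meta["source_id"])
    return HyperStack(channels=channels, pixel_size_um=pixel_size,
                      source_id=source_id or path.stem)


def write_mask(mask: MaskLabel, path) -> None:
    """Write a binary mask as a {0, 255} PNG."""
    try:
        iio.imwrite(Path(path), (mask.pixels * 255).astype(np.uint8),
                    extension=".png")
    except OSError as exc:
        raise StackIOError(f"cannot write mask to {path}: {exc}") from exc


def read_mask(path) -> MaskLabel:
    """Read a {0, 255} PNG mask into in-memory {0, 1} form."""
    try:
        arr = iio.imread(Path(path))
    except (OSError, ValueError) as exc:
        raise StackIOError(f"cannot read mask from {path}: {exc}") from exc
    if arr.ndim == 3:  # collapse greyscale saved as RGB
        if not (arr == arr[..., :1]).all():
            raise NonBinaryMaskError(f"mask {path} is not greyscale")
        arr = arr[..., 0]
    vals = np.unique(arr)
    bad = vals[~np.isin(vals, [0, 255])]
    if bad.size:
        raise NonBinaryMaskError(
            f"mask {path} contains values other than 0/255: {bad[:10].tolist()}"
        )
    return MaskLabel(pixels=(arr == 255).astype(np.uint8))


MANIFEST_COLUMNS = ("image_path", "mask_path", "is_negative",
                    "cell_type_tag", "markers_present")


@dataclass
class DatasetManifest:
    """Rows of (image_path, mask_path, is_negative, tags), paths relative
    to ``root``."""

    frame: pd.DataFrame
    root: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.frame.columns]
        if missing:
            raise StackIOError(f"manifest missing columns: {missing}")
        if self.frame["image_path"].duplicated().any():
            dupes = self.frame["image_path"][self.frame["image_path"].duplicated()]
            raise StackIOError(f"duplicate image_path entries: {dupes.tolist()[:5]}")
        self.root = Path(self.root)

    def __len__(self) -> int:
        return len(self.frame)

    def image_path(self, i: int) -> Path:
        return self.root / self.frame.iloc[i]["image_path"]

    def mask_path(self, i: int) -> Path:
        return self.root / self.frame.iloc[i]["mask_path"]

    def is_negative(self, i: int) -> bool:
        return bool(self.frame.iloc[i]["is_negative"])

    def subset(self, indices) -> "DatasetManifest":
        return DatasetManifest(self.frame.iloc[list(indices)].reset_index(drop=True),
                               root=self.root)


def write_manifest(manifest: DatasetManifest, path) -> None:
    manifest.frame.to_csv(Path(path), index=False)


def read_manifest(path, check_paths: bool = True) -> DatasetManifest:
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise StackIOError(f"cannot read manifest {path}: {exc}") from exc
    frame["is_negative"] = frame["is_negative"].astype(bool)
    man = DatasetManifest(frame=frame, root=path.parent)
    if check_paths:
        for i in range(len(man)):
            for p in (man.image_path(i), man.mask_path(i)):
                if not os.path.exists(p):
                    raise StackIOError(f"manifest references missing file: {p}")
    return man
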