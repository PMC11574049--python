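"""Image and mask I/O: TIFF stacks, channel splitting, maximum-intensity projection.

All rasters use 0-based (row y, column x) indexing. Intensities are stored
as-is; no rescaling happens anywhere in this module.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

DEFAULT_PIXEL_SIZE_UM = 0.16
DEFAULT_Z_STEP_UM = 1.0

__all__ = [
    "AxisOrder",
    "ImageStack",
    "ChannelImage",
    "BinaryMask",
    "load_stack",
    "max_project",
    "read_mask",
    "write_mask",
    "DEFAULT_PIXEL_SIZE_UM",
    "DEFAULT_Z_STEP_UM",
]


class AxisOrder(str, enum.Enum):
    """Declared axis layout of a loaded stack."""

    ZYX = "ZYX"
    CZYX = "CZYX"


@dataclass
class ImageStack:
    """A z-stack of one or more channels of unsigned 16-bit intensities.

    ``voxels`` is always stored as a 4-D ``(c, z, y, x)`` array internally,
    regardless of the declared ``axis_order`` of the source file.
    """

    voxels: np.ndarray
    axis_order: AxisOrder
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    z_step_um: float = DEFAULT_Z_STEP_UM
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError("ImageStack voxels must be 4-D (c, z, y, x)")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("ImageStack requires an integer sample type")
        if self.voxels.min() < 0 or self.voxels.max() > 65535:
            raise ValueError("intensities must lie in [0, 65535]")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must equal channel count")

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.voxels.shape[2], self.voxels.shape[3]


@dataclass
class ChannelImage:
    """A single-channel 2-D intensity raster with pixel geometry."""

    pixels: np.ndarray
    channel_name: str = "ch0"
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("ChannelImage pixels must be 2-D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """A 2-D boolean raster marking foreground (e.g. nerve-fiber) pixels."""

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("BinaryMask pixels must be 2-D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def area_px(self) -> int:
        return int(self.pixels.sum())


def load_stack(
    path: str | Path,
    axis_order: AxisOrder | str = AxisOrder.ZYX,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    z_step_um: float = DEFAULT_Z_STEP_UM,
    channel_names: list[str] | None = None,
) -> ImageStack:
    """Read a single- or multi-page TIFF into an :class:`ImageStack`.

    ``axis_order`` declares how the file's dimensions map to (c, z, y, x):

    * ``ZYX``: 2-D page (z=1) or 3-D stack; single channel.
    * ``CZYX``: 3-D array read as (c, y, x) with z=1, or full 4-D.

    Intensities are preserved bit-exactly.
    """
    axis_order = AxisOrder(axis_order)
    try:
        arr = tifffile.imread(str(path))
    except Exception as exc:  # noqa: BLE001 - normalize I/O failures
        raise ValueError(f"unreadable TIFF: {path}: {exc}") from exc
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"non-integer sample type {arr.dtype} in {path}")

    if axis_order is AxisOrder.ZYX:
        if arr.ndim == 2:
            arr = arr[None, None]
        elif arr.ndim == 3:
            arr = arr[None]
        else:
            raise ValueError(
                f"ZYX axis order expects 2-D or 3-D data, got {arr.ndim}-D"
            )
    else:
        if arr.ndim == 3:
            arr = arr[:, None]
        elif arr.ndim != 4:
            raise ValueError(
                f"CZYX axis order expects 3-D or 4-D data, got {arr.ndim}-D"
            )

    return ImageStack(
        voxels=arr,
        axis_order=axis_order,
        pixel_size_um=pixel_size_um,
        z_step_um=z_step_um,
        channel_names=list(channel_names) if channel_names else [],
    )


def max_project(stack: ImageStack) -> list[ChannelImage]:
    """Maximum-intensity projection along z, one :class:`ChannelImage` per channel."""
    projected = stack.voxels.max(axis=1)
    return [
        ChannelImage(
            pixels=projected[c],
            channel_name=stack.channel_names[c],
            pixel_size_um=stack.pixel_size_um,
        )
        for c in range(stack.n_channels)
    ]


def read_mask(
    path: str | Path,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    reference_shape: tuple[int, int] | None = None,
) -> BinaryMask:
    """Read a mask raster (TIFF or PNG); any nonzero pixel is foreground."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(str(path)))
        if arr.ndim == 3:  # collapse RGB(A)
            arr = arr[..., :3].max(axis=-1)
    else:
        try:
            arr = tifffile.imread(str(path))
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"unreadable mask file: {path}: {exc}") from exc
    if arr.ndim != 2:
        raise ValueError(f"mask must be a single 2-D page, got {arr.ndim}-D")
    if reference_shape is not None and tuple(arr.shape) != tuple(reference_shape):
        raise ValueError(
            f"mask shape {arr.shape} does not match reference {tuple(reference_shape)}"
        )
    return BinaryMask(pixels=arr != 0, pixel_size_um=pixel_size_um)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit TIFF (0/255) or PNG; round-trips through read_mask."""
    path = Path(path)
    data = mask.pixels.astype(np.uint8) * 255
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        iio.imwrite(str(path), data)
    else:
        tifffile.imwrite(str(path), data)
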