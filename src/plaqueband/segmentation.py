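"""Raw stacks to per-channel binary masks.

Maximum-intensity projection, rolling-ball background subtraction
(implemented as grayscale opening with a flat disk), Gaussian denoising,
and automatic thresholding compose into ``segment_channel``, which records
the full parameter provenance of every mask it produces.

Default threshold method per channel role mirrors the staining protocol:
Otsu for the plaque dye, Intermodes for the neurite marker, Moments for
the microglial and lysosomal markers; Li is used on the microglia channel
for the skeleton-morphometry path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage.morphology import disk, opening

from .thresholds import ThresholdResult, auto_threshold

CHANNEL_ROLES = ("plaque", "microglia", "lysosome", "neurite", "other")

#: default auto-threshold method per channel role
DEFAULT_METHODS = {
    "plaque": "otsu",
    "neurite": "intermodes",
    "microglia": "moments",
    "lysosome": "moments",
    "other": "otsu",
}

#: threshold method used for the microglial-morphology (skeleton) path
MORPHOMETRY_METHOD = "li"


@dataclass
class ImageStack:
    """Multi-channel fluorescence image with physical pixel size.

    ``data`` is ``(channels, y, x)`` or ``(channels, z, y, x)``;
    ``channel_roles`` maps channel index to its biological role.
    """

    data: np.ndarray
    pixel_size_um: float
    channel_roles: dict[int, str]
    provenance: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError("data must be (C, Y, X) or (C, Z, Y, X)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not np.all(np.isfinite(self.data)) or self.data.min() < 0:
            raise ValueError("intensities must be finite and non-negative")
        for idx, role in self.channel_roles.items():
            if not 0 <= idx < self.data.shape[0]:
                raise ValueError(f"channel role index {idx} out of range")
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {role!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    def channel_index(self, role: str) -> int:
        for idx, r in self.channel_roles.items():
            if r == role:
                return idx
        raise KeyError(f"stack has no channel with role {role!r}")

    def channel(self, role: str) -> np.ndarray:
        """Maximum-intensity projection of the channel with the given role."""
        return max_projection(self)[self.channel_index(role)]


@dataclass
class SegmentationResult:
    """Binary mask plus the provenance of how it was produced."""

    mask: np.ndarray
    threshold: ThresholdResult
    params: dict = field(default_factory=dict)


def max_projection(stack: ImageStack) -> np.ndarray:
    """Per-channel maximum-intensity projection, ``(channels, y, x)``.

    Single-slice (3D) input is returned unchanged.
    """
    if stack.data.ndim == 3:
        return stack.data
    return stack.data.max(axis=1)


def subtract_background(image: np.ndarray, ball_radius_px: int = 25) -> np.ndarray:
    """Rolling-ball style background subtraction.

    The background estimate is the grayscale opening of the image with a
    flat disk of the given radius (a documented approximation of the
    rolling-ball algorithm); the estimate is subtracted and the result
    clipped at zero.  Structures smaller than the disk survive unchanged.
    """
    image = np.asarray(image, dtype=float)
    if ball_radius_px < 1:
        raise ValueError("ball_radius_px must be >= 1")
    if ball_radius_px > min(image.shape):
        raise ValueError(
            f"ball radius {ball_radius_px} exceeds the smallest image dimension "
            f"{min(image.shape)}"
        )
    background = opening(image, disk(ball_radius_px))
    return np.clip(image - background, 0, None)


def gaussian_smooth(image: np.ndarray, sigma_px: float = 2.0) -> np.ndarray:
    """Gaussian denoising with reflective boundaries; sigma 0 is identity."""
    image = np.asarray(image, dtype=float)
    if sigma_px < 0:
        raise ValueError("sigma_px must be >= 0")
    if sigma_px == 0:
        return image.copy()
    return ndi.gaussian_filter(image, sigma=sigma_px, mode="reflect")


def preprocess(
    image: np.ndarray, ball_radius_px: int | None = 25, sigma_px: float = 2.0
) -> np.ndarray:
    """Background subtraction followed by Gaussian smoothing.

    ``ball_radius_px=None`` skips background subtraction.
    """
    out = np.asarray(image, dtype=float)
    if ball_radius_px is not None:
        out = subtract_background(out, ball_radius_px)
    return gaussian_smooth(out, sigma_px)


def segment_channel(
    stack: ImageStack,
    channel_role: str,
    method: str | None = None,
    ball_radius_px: int | None = 25,
    sigma_px: float = 2.0,
) -> SegmentationResult:
    """Segment one channel of a stack into a binary mask.

    Projects across z, preprocesses, auto-thresholds with the role's
    default method (or an explicit override) and applies the
    strictly-greater-than foreground rule.
    """
    image = stack.channel(channel_role)
    method = method or DEFAULT_METHODS[channel_role]
    pre = preprocess(image, ball_radius_px, sigma_px)
    thr = auto_threshold(pre, method)
    mask = thr.apply(pre)
    return SegmentationResult(
        mask=mask,
        threshold=thr,
        params={
            "channel_role": channel_role,
            "method": method,
            "ball_radius_px": ball_radius_px,
            "sigma_px": sigma_px,
            "threshold": thr.threshold,
            "pixel_size_um": stack.pixel_size_um,
        },
    )


def write_stack(path, stack: ImageStack) -> None:
    """Write a stack as multi-channel TIFF with roles in the description."""
    meta = {
        "axes": "CYX" if stack.data.ndim == 3 else "CZYX",
        "pixel_size_um": stack.pixel_size_um,
        "channel_roles": {str(k): v for k, v in stack.channel_roles.items()},
        "provenance": stack.provenance,
    }
    tifffile.imwrite(
        path,
        stack.data.astype(np.float32),
        photometric="minisblack",
        planarconfig="separate",
        description=json.dumps(meta),
    )


def read_stack(path) -> ImageStack:
    """Read a multi-channel TIFF written by :func:`write_stack`."""
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc)
        roles = {int(k): v for k, v in meta["channel_roles"].items()}
        pixel_size = float(meta["pixel_size_um"])
    except (json.JSONDecodeError, TypeError, KeyError, AttributeError) as exc:
        raise ValueError(f"{path}: missing or malformed channel metadata") from exc
    return ImageStack(
        data=data,
        pixel_size_um=pixel_size,
        channel_roles=roles,
        provenance=meta.get("provenance", ""),
    )


def write_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as 8-bit TIFF (0/255)."""
    tifffile.imwrite(path, (np.asarray(mask, bool).astype(np.uint8) * 255))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path) > 0
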