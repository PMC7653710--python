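"""Plaque detection, burden, and quantification in the proximity band.

Detects beta-amyloid plaques as 8-connected components of the plaque-dye
mask, applies the minimum-diameter rule (equivalent diameter > 9.9 um),
computes section burden (% of the ROI covered by plaque), and quantifies
marker area / intensity / object counts both inside each plaque and in
the band extending 30 um out from the plaque outline (the open annulus;
interior quantities are always reported separately).

All geometry is in pixel units internally and converted to um / um^2 via
the pixel size; distances to the plaque are Euclidean distance-transform
distances from the plaque pixel set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .stats import TestResult, correlation

#: minimum equivalent diameter for a component to count as a plaque (um)
MIN_PLAQUE_DIAMETER_UM = 9.9

#: width of the plaque proximity band (um)
BAND_WIDTH_UM = 30.0

#: 8-connectivity structuring element for component labeling
STRUCTURE_8 = np.ones((3, 3), dtype=int)


@dataclass
class Plaque:
    """One detected plaque (geometry in pixel coordinates, sizes in um)."""

    id: int
    slices: tuple  # bounding-box (slice_y, slice_x) in the full image
    mask: np.ndarray  # boolean crop within the bounding box
    area_um2: float
    equivalent_diameter_um: float
    centroid_um: tuple  # (y, x) in um
    border_clipped: bool
    pixel_size_um: float

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    def full_mask(self, shape) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        out[self.slices] = self.mask
        return out

    def outline(self) -> np.ndarray:
        """Boundary pixels (mask minus its erosion), as a crop."""
        eroded = ndi.binary_erosion(self.mask, structure=STRUCTURE_8, border_value=0)
        return self.mask & ~eroded

    def contains_point_um(self, y_um: float, x_um: float) -> bool:
        """Whether a physical point falls on a plaque pixel (outline included)."""
        py = int(round(y_um / self.pixel_size_um))
        px = int(round(x_um / self.pixel_size_um))
        y0, x0 = self.slices[0].start, self.slices[1].start
        iy, ix = py - y0, px - x0
        if 0 <= iy < self.mask.shape[0] and 0 <= ix < self.mask.shape[1]:
            return bool(self.mask[iy, ix])
        return False


@dataclass
class BandMask:
    """The 0-30 um proximity band of one plaque, stored as a crop.

    ``dist_um`` holds the Euclidean distance (um) of every crop pixel from
    the plaque pixel set (0 on the plaque itself); the band is
    ``0 < dist <= width``, i.e. the open annulus excluding the interior.
    """

    plaque_id: int
    width_um: float
    y0: int
    x0: int
    mask: np.ndarray  # boolean crop: annulus pixels
    dist_um: np.ndarray  # float crop: EDT from the plaque, in um
    image_shape: tuple
    pixel_size_um: float
    clipped: bool

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size_um**2

    def full_mask(self) -> np.ndarray:
        out = np.zeros(self.image_shape, dtype=bool)
        h, w = self.mask.shape
        out[self.y0 : self.y0 + h, self.x0 : self.x0 + w] = self.mask
        return out

    def distance_at_um(self, y_um: float, x_um: float) -> float:
        """EDT distance (um) from the plaque at a physical point.

        Returns ``inf`` for points outside the stored crop.
        """
        py = int(round(y_um / self.pixel_size_um)) - self.y0
        px = int(round(x_um / self.pixel_size_um)) - self.x0
        if 0 <= py < self.dist_um.shape[0] and 0 <= px < self.dist_um.shape[1]:
            return float(self.dist_um[py, px])
        return float("inf")


@dataclass
class BurdenResult:
    roi_area_um2: float
    plaque_area_um2: float
    burden_percent: float


@dataclass
class BandQuantification:
    """Marker measurements inside one plaque and in its proximity band."""

    plaque_id: int
    marker_role: str
    band_width_um: float
    positive_area_inside_um2: float
    positive_area_band_um2: float
    mean_intensity_band: float
    object_count_band: int
    band_area_um2: float
    band_clipped: bool


@dataclass
class PlaqueMicrogliaCount:
    plaque_id: int
    n_within: int
    n_around: int

    @property
    def n_total(self) -> int:
        return self.n_within + self.n_around


def detect_plaques(
    plaque_mask: np.ndarray,
    pixel_size_um: float,
    min_diameter_um: float = MIN_PLAQUE_DIAMETER_UM,
) -> list[Plaque]:
    """Detect plaques as 8-connected components above the diameter cutoff.

    Components with equivalent diameter ``2*sqrt(A/pi) <= min_diameter_um``
    are discarded.  Plaques are ordered deterministically by centroid
    (row-major) and numbered from 0.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    mask = np.asarray(plaque_mask, dtype=bool)
    labels, n = ndi.label(mask, structure=STRUCTURE_8)
    if n == 0:
        return []
    objects = ndi.find_objects(labels)
    px_area = pixel_size_um**2
    candidates = []
    for lab, slc in enumerate(objects, start=1):
        crop = labels[slc] == lab
        area_um2 = crop.sum() * px_area
        d = 2.0 * np.sqrt(area_um2 / np.pi)
        if d <= min_diameter_um:
            continue
        ys, xs = np.nonzero(crop)
        cy = (ys.mean() + slc[0].start) * pixel_size_um
        cx = (xs.mean() + slc[1].start) * pixel_size_um
        clipped = (
            slc[0].start == 0
            or slc[1].start == 0
            or slc[0].stop == mask.shape[0]
            or slc[1].stop == mask.shape[1]
        )
        candidates.append((cy, cx, slc, crop, area_um2, d, clipped))
    candidates.sort(key=lambda c: (c[0], c[1]))
    plaques = []
    for pid, (cy, cx, slc, crop, area_um2, d, clipped) in enumerate(candidates):
        plaques.append(
            Plaque(
                id=pid,
                slices=slc,
                mask=crop,
                area_um2=float(area_um2),
                equivalent_diameter_um=float(d),
                centroid_um=(float(cy), float(cx)),
                border_clipped=clipped,
                pixel_size_um=pixel_size_um,
            )
        )
    return plaques


def plaque_burden(
    plaque_mask: np.ndarray, roi_mask: np.ndarray, pixel_size_um: float
) -> BurdenResult:
    """Percentage of the ROI covered by plaque-positive pixels."""
    plaque_mask = np.asarray(plaque_mask, dtype=bool)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    roi_px = int(roi_mask.sum())
    if roi_px == 0:
        raise ValueError("ROI mask is empty")
    plaque_px = int((plaque_mask & roi_mask).sum())
    px_area = pixel_size_um**2
    return BurdenResult(
        roi_area_um2=roi_px * px_area,
        plaque_area_um2=plaque_px * px_area,
        burden_percent=100.0 * plaque_px / roi_px,
    )


def band_mask(
    plaque: Plaque,
    width_um: float,
    image_shape: tuple,
    pixel_size_um: float,
) -> BandMask:
    """Proximity band of a plaque: pixels with ``0 < EDT <= width_um``.

    Computed on a window just large enough to hold the band, so the cost
    is independent of the section size.  ``clipped`` flags bands cut by
    the image border.
    """
    if width_um < 0:
        raise ValueError("width_um must be >= 0")
    pad = int(np.ceil(width_um / pixel_size_um)) + 2
    sy, sx = plaque.slices
    y0 = max(sy.start - pad, 0)
    y1 = min(sy.stop + pad, image_shape[0])
    x0 = max(sx.start - pad, 0)
    x1 = min(sx.stop + pad, image_shape[1])
    clipped = (
        sy.start - pad < 0
        or sx.start - pad < 0
        or sy.stop + pad > image_shape[0]
        or sx.stop + pad > image_shape[1]
    )
    window = np.zeros((y1 - y0, x1 - x0), dtype=bool)
    window[sy.start - y0 : sy.stop - y0, sx.start - x0 : sx.stop - x0] = plaque.mask
    dist = ndi.distance_transform_edt(~window) * pixel_size_um
    band = (dist > 0) & (dist <= width_um)
    return BandMask(
        plaque_id=plaque.id,
        width_um=width_um,
        y0=y0,
        x0=x0,
        mask=band,
        dist_um=dist,
        image_shape=tuple(image_shape),
        pixel_size_um=pixel_size_um,
        clipped=clipped,
    )


def quantify_band(
    marker_image: np.ndarray,
    marker_mask: np.ndarray,
    plaque: Plaque,
    band: BandMask,
    marker_role: str = "other",
    marker_labels: np.ndarray | None = None,
) -> BandQuantification:
    """Marker area, intensity and object count for one plaque's band.

    * positive area — marker-mask pixels inside the plaque / the band,
      converted to um^2;
    * mean intensity — mean of the raw marker image over *all* band
      pixels (not only marker-positive ones);
    * object count — connected components of the marker mask having at
      least one pixel in the band (pass precomputed ``marker_labels`` to
      amortize the labeling across plaques).
    """
    marker_mask = np.asarray(marker_mask, dtype=bool)
    if marker_mask.shape != band.image_shape:
        raise ValueError("marker mask and band geometry are not congruent")
    if marker_labels is None:
        marker_labels, _ = ndi.label(marker_mask, structure=STRUCTURE_8)
    h, w = band.mask.shape
    win = (slice(band.y0, band.y0 + h), slice(band.x0, band.x0 + w))
    mm_win = marker_mask[win]
    img_win = np.asarray(marker_image, dtype=float)[win]
    lab_win = marker_labels[win]
    px_area = band.pixel_size_um**2

    sy, sx = plaque.slices
    inside = marker_mask[sy, sx] & plaque.mask
    band_pos = mm_win & band.mask
    labels_in_band = np.unique(lab_win[band.mask & (lab_win > 0)])
    mean_int = float(img_win[band.mask].mean()) if band.mask.any() else float("nan")
    return BandQuantification(
        plaque_id=plaque.id,
        marker_role=marker_role,
        band_width_um=band.width_um,
        positive_area_inside_um2=float(inside.sum()) * px_area,
        positive_area_band_um2=float(band_pos.sum()) * px_area,
        mean_intensity_band=mean_int,
        object_count_band=int(len(labels_in_band)),
        band_area_um2=band.area_um2,
        band_clipped=band.clipped,
    )


def detect_somata(
    microglia_mask: np.ndarray,
    pixel_size_um: float,
    soma_min_area_um2: float = 20.0,
) -> list[tuple[float, float]]:
    """Microglial soma centroids (um) from the microglia mask.

    A soma is a connected component with area >= ``soma_min_area_um2``
    (the automated proxy for "clearly visible soma"); its centroid is
    returned in physical coordinates.
    """
    mask = np.asarray(microglia_mask, dtype=bool)
    labels, n = ndi.label(mask, structure=STRUCTURE_8)
    if n == 0:
        return []
    areas = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1)) * pixel_size_um**2
    keep = np.nonzero(areas >= soma_min_area_um2)[0] + 1
    centroids = ndi.center_of_mass(mask, labels, keep)
    return [(cy * pixel_size_um, cx * pixel_size_um) for cy, cx in centroids]


def count_plaque_microglia(
    soma_centroids_um: list[tuple[float, float]],
    plaques: list[Plaque],
    bands: list[BandMask],
) -> list[PlaqueMicrogliaCount]:
    """Assign microglial somata to plaques and count within/around.

    A soma on a plaque pixel (outline included) counts as *within* that
    plaque; a soma inside a band counts as *around*.  A soma falling in
    several plaques' bands is assigned to the plaque with the nearest
    outline (ties to the lower plaque id).  Unassigned somata are ignored.
    """
    by_id = {b.plaque_id: b for b in bands}
    counts = {p.id: [0, 0] for p in plaques}
    for (y_um, x_um) in soma_centroids_um:
        within_ids = [p.id for p in plaques if p.contains_point_um(y_um, x_um)]
        if within_ids:
            counts[min(within_ids)][0] += 1
            continue
        best = None
        for p in plaques:
            band = by_id.get(p.id)
            if band is None:
                continue
            d = band.distance_at_um(y_um, x_um)
            if 0 < d <= band.width_um and (best is None or d < best[0]):
                best = (d, p.id)
        if best is not None:
            counts[best[1]][1] += 1
    return [
        PlaqueMicrogliaCount(plaque_id=pid, n_within=w, n_around=a)
        for pid, (w, a) in sorted(counts.items())
    ]


def diameter_neurite_relation(
    plaques: list[Plaque], neurite_counts: list[int]
) -> tuple[float, float, int]:
    """Correlation of plaque equivalent diameter with neurite count.

    Returns ``(pearson_r, spearman_rho, n)``; constant counts yield NaN
    coefficients with a warning.
    """
    if len(plaques) != len(neurite_counts):
        raise ValueError("one neurite count per plaque required")
    if len(plaques) < 3:
        raise ValueError("need at least 3 plaques")
    d = np.array([p.equivalent_diameter_um for p in plaques])
    c = np.asarray(neurite_counts, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r: TestResult = correlation(d, c, "pearson")
        rho: TestResult = correlation(d, c, "spearman")
    if np.isnan(r.statistic):
        warnings.warn("neurite counts have zero variance; correlation undefined")
    return r.statistic, rho.statistic, len(plaques)
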