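"""Automatic histogram thresholding operators.

Implements the four auto-threshold methods used to segment the fluorescence
channels: Otsu (between-class variance), Li (minimum cross entropy),
Intermodes (iterated histogram smoothing until bimodality) and Moments
(Tsai's moment-preserving threshold).

All four operate on a 256-bin histogram of the image ("8-bit semantics").
For integer images whose value range spans at most 256 levels the bins are
the integer levels themselves, so thresholds are exact gray levels; for
float images the bins uniformly cover the observed range and the threshold
is reported at bin resolution.

Conventions, used everywhere in the package:

* foreground rule: a pixel is foreground iff ``pixel > t`` (strictly);
* tie-breaking: the smallest threshold among equal optima (Otsu);
* the threshold is reported as the representative value of the last
  background bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_BINS = 256

METHODS = ("otsu", "li", "intermodes", "moments")


class DegenerateHistogramError(ValueError):
    """Raised when an image has fewer than two distinct intensities."""


class IntermodesError(RuntimeError):
    """Raised when iterated smoothing fails to make the histogram bimodal."""


@dataclass
class ThresholdResult:
    """Outcome of an automatic threshold computation.

    ``threshold`` is in intensity units; foreground pixels are those with
    value strictly greater than it.  ``levels`` are the representative
    intensity values of the histogram bins and ``counts`` their occupancy.
    """

    method: str
    threshold: float
    levels: np.ndarray
    counts: np.ndarray
    extras: dict = field(default_factory=dict)

    def apply(self, image: np.ndarray) -> np.ndarray:
        """Binary mask under the strictly-greater-than foreground rule."""
        return np.asarray(image) > self.threshold


def histogram(image: np.ndarray, n_bins: int = N_BINS) -> tuple[np.ndarray, np.ndarray]:
    """256-level histogram of ``image``.

    Returns ``(levels, counts)`` where ``levels`` are representative bin
    values.  Integer images spanning at most ``n_bins`` levels keep their
    native integer levels; other images are binned uniformly over the
    observed range (bin centers as levels).
    """
    data = np.asarray(image)
    if not np.all(np.isfinite(data)):
        raise ValueError("image contains non-finite values")
    lo = float(data.min())
    hi = float(data.max())
    if lo == hi:
        raise DegenerateHistogramError(
            f"degenerate histogram: constant image (value {lo})"
        )
    if np.issubdtype(data.dtype, np.integer) and (hi - lo) < n_bins:
        levels = np.arange(int(lo), int(lo) + n_bins, dtype=float)
        counts = np.bincount((data - int(lo)).ravel(), minlength=n_bins).astype(float)
    else:
        counts, edges = np.histogram(data.ravel(), bins=n_bins, range=(lo, hi))
        levels = 0.5 * (edges[:-1] + edges[1:])
        counts = counts.astype(float)
    return levels, counts


def otsu_threshold(levels: np.ndarray, counts: np.ndarray) -> tuple[float, dict]:
    """Otsu's threshold: maximize between-class variance over all splits.

    Ties are broken toward the smallest threshold.
    """
    p = counts / counts.sum()
    w0 = np.cumsum(p)
    mu = np.cumsum(p * levels)
    mu_t = mu[-1]
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = np.where(valid, (mu_t * w0 - mu) ** 2 / (w0 * w1), -np.inf)
    if not np.any(valid):
        raise DegenerateHistogramError("degenerate histogram: single occupied bin")
    k = int(np.argmax(sigma_b))  # argmax returns the first (smallest) maximizer
    return float(levels[k]), {"between_class_variance": float(sigma_b[k]), "bin_index": k}


def li_threshold(
    levels: np.ndarray, counts: np.ndarray, tol: float = 1e-8, max_iter: int = 10_000
) -> tuple[float, dict]:
    """Li & Lee minimum cross-entropy threshold (iterative fixed point).

    Iterates ``t <- (mu_fg - mu_bg) / (ln mu_fg - ln mu_bg)`` where the
    class means are taken over the histogram, until convergence.  Levels
    are shifted to be strictly positive for the logarithms and the result
    shifted back.
    """
    shift = 0.0
    lv = levels.astype(float)
    if lv[0] <= 0:
        shift = 1.0 - lv[0]
        lv = lv + shift
    p = counts / counts.sum()
    t = float(np.sum(p * lv))  # start at the global mean
    for iteration in range(max_iter):
        bg = lv <= t
        fg = ~bg
        wb = p[bg].sum()
        wf = p[fg].sum()
        if wb == 0 or wf == 0:
            break
        mu_b = float(np.sum(p[bg] * lv[bg]) / wb)
        mu_f = float(np.sum(p[fg] * lv[fg]) / wf)
        t_next = (mu_f - mu_b) / (np.log(mu_f) - np.log(mu_b))
        if abs(t_next - t) < tol:
            t = t_next
            break
        t = t_next
    return t - shift, {"iterations": iteration + 1, "shift": shift}


def intermodes_threshold(
    levels: np.ndarray, counts: np.ndarray, max_iter: int = 10_000
) -> tuple[float, dict]:
    """Intermodes threshold (Prewitt & Mendelsohn).

    The histogram is repeatedly smoothed with a running 3-bin mean until
    exactly two local maxima remain; the threshold is the midpoint of the
    two modes.
    """
    h = counts.astype(float).copy()
    n = len(h)
    for iteration in range(max_iter):
        modes = _local_maxima(h)
        if len(modes) == 2:
            j1, j2 = modes
            t = 0.5 * (levels[j1] + levels[j2])
            return float(t), {"iterations": iteration, "modes": (int(j1), int(j2))}
        if len(modes) < 2:
            raise IntermodesError(
                f"histogram collapsed to {len(modes)} mode(s) after "
                f"{iteration} smoothing iterations; cannot locate two modes"
            )
        smoothed = np.empty_like(h)
        smoothed[0] = (2 * h[0] + h[1]) / 3.0
        smoothed[-1] = (h[-2] + 2 * h[-1]) / 3.0
        smoothed[1:-1] = (h[:-2] + h[1:-1] + h[2:]) / 3.0
        h = smoothed
    raise IntermodesError(
        f"histogram still has {len(_local_maxima(h))} modes after {max_iter} "
        "smoothing iterations"
    )


def _local_maxima(h: np.ndarray) -> list[int]:
    """Indices of local maxima (plateaus count once, at their left edge)."""
    maxima = []
    n = len(h)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and h[j + 1] == h[i]:
            j += 1
        left = h[i - 1] if i > 0 else -np.inf
        right = h[j + 1] if j + 1 < n else -np.inf
        if h[i] > left and h[i] > right and h[i] > 0:
            maxima.append(i)
        i = j + 1
    return maxima


def moments_threshold(levels: np.ndarray, counts: np.ndarray) -> tuple[float, dict]:
    """Tsai's moment-preserving threshold.

    Finds the two-level image (values ``z0 < z1`` with fractions ``p0``,
    ``1 - p0``) whose first three moments equal those of the gray-level
    histogram, then thresholds at the ``p0``-tile of the histogram.
    """
    p = counts / counts.sum()
    lv = levels.astype(float)
    m1 = float(np.sum(p * lv))
    m2 = float(np.sum(p * lv**2))
    m3 = float(np.sum(p * lv**3))
    cd = m2 - m1 * m1
    if cd <= 0:
        raise DegenerateHistogramError("degenerate histogram: zero variance")
    c0 = (m1 * m3 - m2 * m2) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        raise DegenerateHistogramError("moment equations have no real two-level solution")
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    p0 = (z1 - m1) / (z1 - z0)
    cum = np.cumsum(p)
    k = int(np.searchsorted(cum, p0))
    k = min(k, len(lv) - 1)
    return float(lv[k]), {
        "z0": float(z0),
        "z1": float(z1),
        "p0": float(p0),
        "moments": (m1, m2, m3),
        "bin_index": k,
    }


_DISPATCH = {
    "otsu": otsu_threshold,
    "li": li_threshold,
    "intermodes": intermodes_threshold,
    "moments": moments_threshold,
}


def auto_threshold(image: np.ndarray, method: str) -> ThresholdResult:
    """Compute an automatic threshold for ``image``.

    Parameters
    ----------
    image:
        Intensity image with at least two distinct values.
    method:
        One of ``"otsu"``, ``"li"``, ``"intermodes"``, ``"moments"``.
    """
    if method not in _DISPATCH:
        raise ValueError(f"unknown threshold method {method!r}; expected one of {METHODS}")
    levels, counts = histogram(image)
    t, extras = _DISPATCH[method](levels, counts)
    return ThresholdResult(method=method, threshold=t, levels=levels, counts=counts, extras=extras)
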