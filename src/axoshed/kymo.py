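"""Registration, nerve contour tracing, swath division and kymograph extraction.

The whole-nerve semi-automatic mode traces the outer contour of the ~30 um
optic nerve on a temporal projection, divides its interior into 0.9-1.8 um
parallel swaths aligned with the principal (eye-to-brain) axis, and extracts
one kymograph per swath by reducing intensity across the swath width.  The
sparse mode extracts a kymograph along a single user-supplied path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology
from skimage.registration import phase_cross_correlation

from .config import ConfigurationError
from .stacks import FrameStack

__all__ = [
    "NerveContour",
    "SwathSet",
    "Kymograph",
    "estimate_drift",
    "apply_shifts",
    "trace_nerve_contour",
    "build_swaths",
    "swath_label_map",
    "extract_kymograph",
    "extract_swath_kymographs",
]

SWATH_WIDTH_RANGE_UM = (0.9, 1.8)


@dataclass
class NerveContour:
    polygon: np.ndarray          # (N, 2) (y, x) pixel coords, closed implicitly
    principal_axis: np.ndarray   # unit (dy, dx)
    diameter_um: float
    pixel_size_um: float
    interior_mask: np.ndarray | None = None  # (Y, X) boolean

    def __post_init__(self):
        if self.diameter_um <= 0:
            raise ValueError("diameter_um must be positive")


@dataclass
class SwathSet:
    paths: list                 # per swath: (2, 2) array [(y0,x0), (y1,x1)]
    swath_width_um: float
    spacing_um: float
    perp_axis: np.ndarray       # unit vector perpendicular to the paths
    offsets_px: np.ndarray      # perpendicular offset of each path center

    def __len__(self):
        return len(self.paths)


@dataclass
class Kymograph:
    K: np.ndarray               # (T, S) intensity
    s_positions_um: np.ndarray  # strictly increasing arclength per column
    dt_s: float
    source: str = "path"

    def __post_init__(self):
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if np.any(np.diff(self.s_positions_um) <= 0):
            raise ValueError("s_positions_um must be strictly increasing")
        if self.K.shape[1] != len(self.s_positions_um):
            raise ValueError("K columns must match s_positions_um")


# ----------------------------------------------------------------- registration

def estimate_drift(stack: FrameStack, reference: str = "first",
                   channel_role: str | None = None,
                   upsample_factor: int = 10) -> np.ndarray:
    """Estimate per-frame translational drift by phase correlation.

    Returns the (T, 2) shifts *to apply* to each frame (the negative of the
    estimated drift) so that :func:`apply_shifts` registers the stack onto
    the reference (``first`` frame or temporal ``mean``).
    """
    if reference not in ("first", "mean"):
        raise ConfigurationError("reference must be 'first' or 'mean'")
    if channel_role is None:
        frames = stack.intensities.sum(axis=0)
    else:
        frames = stack.channel(channel_role)
    nt = frames.shape[0]
    if nt < 2:
        raise ValueError("need at least 2 frames")
    ref = frames[0] if reference == "first" else frames.mean(axis=0)
    shifts = np.zeros((nt, 2))
    if ref.std() == 0:
        warnings.warn("flat reference frame; returning zero shifts")
        return shifts
    for t in range(nt):
        if frames[t].std() == 0:
            warnings.warn(f"flat frame {t}; zero shift assumed")
            continue
        drift, _, _ = phase_cross_correlation(
            ref, frames[t], upsample_factor=upsample_factor,
            normalization=None)
        shifts[t] = drift  # shift moving frame by `drift` to match reference
    return shifts


def apply_shifts(stack: FrameStack, shifts: np.ndarray) -> FrameStack:
    """Translate each frame by its shift (bilinear); zero-fill out-of-field.

    The returned stack carries a ``valid_mask`` flagging in-field pixels.
    """
    shifts = np.asarray(shifts, dtype=float)
    nc, nt = stack.intensities.shape[:2]
    if shifts.shape != (nt, 2):
        raise ValueError("shifts must be (n_frames, 2)")
    out = np.empty_like(stack.intensities)
    valid = np.empty(stack.intensities.shape[1:], dtype=bool)
    ones = np.ones(stack.intensities.shape[2:], dtype=np.float32)
    for t in range(nt):
        if np.all(shifts[t] == 0):
            out[:, t] = stack.intensities[:, t]
            valid[t] = True
            continue
        for c in range(nc):
            out[c, t] = ndimage.shift(stack.intensities[c, t], shifts[t],
                                      order=1, mode="constant", cval=0.0)
        valid[t] = ndimage.shift(ones, shifts[t], order=0,
                                 mode="constant", cval=0.0) > 0.5
    return FrameStack(out, stack.pixel_size_um, stack.frame_interval_s,
                      dict(stack.channel_roles), valid_mask=valid)


# --------------------------------------------------------------------- contour

def trace_nerve_contour(projection: np.ndarray, pixel_size_um: float,
                        method: str = "otsu", quantile: float = 0.80,
                        manual_override: np.ndarray | None = None,
                        min_area_px: int = 64) -> NerveContour:
    """Trace the outer contour of the nerve on a temporal projection.

    Thresholds the projection (Otsu or an intensity quantile), keeps the
    largest connected component, and returns its boundary polygon, principal
    axis and diameter (extent across the minor axis).  A manual polygon
    bypasses detection.
    """
    projection = np.asarray(projection, dtype=float)
    if manual_override is not None:
        poly = np.asarray(manual_override, dtype=float)
        mask = _polygon_mask(poly, projection.shape)
        axis, diam_px = _axis_and_diameter(mask)
        return NerveContour(poly, axis, diam_px * pixel_size_um,
                            pixel_size_um, interior_mask=mask)
    if method == "otsu":
        if projection.max() == projection.min():
            raise ValueError("no nerve found: blank projection")
        thr = filters.threshold_otsu(projection)
    elif method == "quantile":
        thr = np.quantile(projection, quantile)
    else:
        raise ConfigurationError(f"unknown method {method!r}")
    mask = projection > thr
    mask = ndimage.binary_fill_holes(mask)
    labels = measure.label(mask)
    if labels.max() == 0:
        raise ValueError("no nerve found: nothing above threshold")
    sizes = np.bincount(labels.ravel())[1:]
    if sizes.max() < min_area_px:
        raise ValueError("no nerve found: largest component below min area")
    mask = labels == (1 + int(np.argmax(sizes)))
    contours = measure.find_contours(mask.astype(float), 0.5)
    poly = max(contours, key=len)
    axis, diam_px = _axis_and_diameter(mask)
    return NerveContour(poly, axis, diam_px * pixel_size_um, pixel_size_um,
                        interior_mask=mask)


def _polygon_mask(poly: np.ndarray, shape) -> np.ndarray:
    from skimage.draw import polygon as sk_polygon
    rr, cc = sk_polygon(poly[:, 0], poly[:, 1], shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _axis_and_diameter(mask: np.ndarray):
    ys, xs = np.nonzero(mask)
    pts = np.stack([ys, xs], axis=1).astype(float)
    pts -= pts.mean(axis=0)
    cov = np.cov(pts.T)
    w, v = np.linalg.eigh(cov)
    axis = v[:, np.argmax(w)]
    if axis[1] < 0:  # orient +x (eye-to-brain by convention)
        axis = -axis
    perp = np.array([-axis[1], axis[0]])
    proj = pts @ perp
    return axis, float(proj.max() - proj.min())


# ---------------------------------------------------------------------- swaths

def build_swaths(contour: NerveContour, swath_width_um: float = 1.5) -> SwathSet:
    """Divide the contour interior into abutting parallel swaths.

    Widths outside the 0.9-1.8 um range are clamped with a warning; swath
    paths run along the principal axis and tile the interior without
    overlap, so the count is approximately diameter / width.
    """
    if swath_width_um <= 0:
        raise ConfigurationError("swath width must be positive")
    lo, hi = SWATH_WIDTH_RANGE_UM
    if not lo <= swath_width_um <= hi:
        clamped = min(max(swath_width_um, lo), hi)
        warnings.warn(f"swath width {swath_width_um} um outside "
                      f"[{lo}, {hi}]; clamped to {clamped}")
        swath_width_um = clamped
    if contour.interior_mask is None:
        raise ValueError("contour has no interior mask")
    mask = contour.interior_mask
    axis = contour.principal_axis
    perp = np.array([-axis[1], axis[0]])
    ys, xs = np.nonzero(mask)
    pts = np.stack([ys, xs], axis=1).astype(float)
    centroid = pts.mean(axis=0)
    rel = pts - centroid
    p = rel @ perp           # perpendicular coordinate (px)
    a = rel @ axis           # along-axis coordinate (px)
    width_px = swath_width_um / contour.pixel_size_um
    n = int(np.ceil((p.max() - p.min()) / width_px))
    p0 = p.min()
    offsets, paths = [], []
    half_len = max(abs(a.min()), abs(a.max()))
    for i in range(n):
        c = p0 + (i + 0.5) * width_px
        center = centroid + c * perp
        paths.append(np.stack([center - half_len * axis,
                               center + half_len * axis]))
        offsets.append(c)
    return SwathSet(paths=paths, swath_width_um=swath_width_um,
                    spacing_um=swath_width_um, perp_axis=perp,
                    offsets_px=np.array(offsets))


def swath_label_map(contour: NerveContour, swaths: SwathSet) -> np.ndarray:
    """Label each interior pixel with its swath index (-1 elsewhere)."""
    mask = contour.interior_mask
    ys, xs = np.nonzero(mask)
    pts = np.stack([ys, xs], axis=1).astype(float)
    centroid = np.stack(np.nonzero(mask), axis=1).astype(float).mean(axis=0)
    p = (pts - centroid) @ swaths.perp_axis
    width_px = swaths.swath_width_um / contour.pixel_size_um
    p0 = swaths.offsets_px[0] - width_px / 2.0
    idx = np.floor((p - p0) / width_px).astype(int)
    idx = np.clip(idx, 0, len(swaths) - 1)
    out = np.full(mask.shape, -1, dtype=int)
    out[ys, xs] = idx
    return out


# ------------------------------------------------------------------- kymographs

def extract_kymograph(stack: FrameStack, path: np.ndarray,
                      width_um: float, channel_role: str = "mito",
                      reducer: str = "max", source: str = "path") -> Kymograph:
    """Sample intensity along a straight path, reduced across its width.

    ``path`` is ``[(y0, x0), (y1, x1)]`` in pixel coordinates; the +s
    direction runs from the first to the second endpoint (configure it as
    the eye-to-brain axis so +s is anterograde).
    """
    if reducer not in ("max", "mean"):
        raise ConfigurationError("reducer must be 'max' or 'mean'")
    path = np.asarray(path, dtype=float)
    p0, p1 = path[0], path[-1]
    length_px = float(np.hypot(*(p1 - p0)))
    if length_px < 2:
        raise ValueError("path shorter than 2 px")
    px = stack.pixel_size_um
    n_s = int(np.floor(length_px)) + 1
    u = (p1 - p0) / length_px
    perp = np.array([-u[1], u[0]])
    n_w = max(int(round(width_um / px)), 1)
    w_off = (np.arange(n_w) - (n_w - 1) / 2.0)
    s_px = np.linspace(0, length_px, n_s)
    centers = p0[None, :] + s_px[:, None] * u[None, :]      # (S, 2)
    coords = centers[None, :, :] + w_off[:, None, None] * perp[None, None, :]
    ci = np.stack([coords[..., 0].ravel(), coords[..., 1].ravel()])

    frames = stack.channel(channel_role)
    K = np.empty((frames.shape[0], n_s), dtype=float)
    for t in range(frames.shape[0]):
        samp = ndimage.map_coordinates(frames[t], ci, order=1,
                                       mode="constant", cval=0.0)
        samp = samp.reshape(n_w, n_s)
        K[t] = samp.max(axis=0) if reducer == "max" else samp.mean(axis=0)
    return Kymograph(K=K, s_positions_um=s_px * px,
                     dt_s=stack.frame_interval_s, source=source)


def extract_swath_kymographs(stack: FrameStack, swaths: SwathSet,
                             channel_role: str = "mito",
                             reducer: str = "max") -> list:
    """One kymograph per swath, sources tagged ``swath_<i>``."""
    return [
        extract_kymograph(stack, p, swaths.swath_width_um,
                          channel_role=channel_role, reducer=reducer,
                          source=f"swath_{i}")
        for i, p in enumerate(swaths.paths)
    ]
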