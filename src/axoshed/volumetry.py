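"""Axon-mask volumetry: percent of signal outside the axons and its
surface-versus-parenchyma split.

The diffuse cytoplasmic LC3b signal demarcates the axons; a binary mask is
built from it, and for each signal channel the percentage of supra-threshold
signal volume falling outside the mask is computed (voxel-wise, with an
object-wise variant assigning whole connected components by centroid).
Extra-axonal signal is further partitioned into a surface shell near the
nerve boundary versus the parenchyma, and the per-animal relation between
total-outside and on-surface percentages is summarized by an OLS trend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage import filters, measure, morphology

from .config import ConfigurationError
from .stacks import VolumeStack

__all__ = [
    "AxonMask",
    "OutsideFraction",
    "SurfacePartition",
    "build_axon_mask",
    "pct_outside",
    "partition_surface",
    "fit_surface_trend",
]


@dataclass
class AxonMask:
    mask: np.ndarray              # boolean (Z, Y, X)
    source_channel: str
    threshold_method: str
    threshold_value: float
    min_object_voxels: int
    closing_radius: int


@dataclass
class OutsideFraction:
    channel_role: str
    total_um3: float
    outside_um3: float
    pct_outside: float
    mode: str = "voxel"

    def __post_init__(self):
        if not np.isnan(self.pct_outside) and not (
                -1e-9 <= self.pct_outside <= 100 + 1e-9):
            raise ValueError("pct_outside out of [0, 100]")


@dataclass
class SurfacePartition:
    channel_role: str
    shell_depth_um: float
    pct_on_surface: float      # % of *outside* signal within the shell
    pct_in_parenchyma: float
    pct_total_outside: float   # % of all signal outside the axon mask


def _resolve_threshold(data: np.ndarray, threshold, quantile: float = 0.99):
    if isinstance(threshold, str):
        if threshold == "otsu":
            return float(filters.threshold_otsu(data))
        if threshold == "quantile":
            return float(np.quantile(data, quantile))
        if threshold == "robust":
            # background + 8 robust SDs, with the noise scale taken from the
            # upper quantile spread (robust to zero-clipped backgrounds);
            # Otsu degenerates when the foreground (sparse puncta) is a tiny
            # voxel fraction
            med = float(np.median(data))
            sd = float(np.quantile(data, 0.841)) - med
            return med + 8.0 * max(sd, 1e-6 * float(data.max()))
        raise ConfigurationError(f"unknown threshold method {threshold!r}")
    return float(threshold)


def build_axon_mask(volume: VolumeStack, method: str = "otsu",
                    channel_role: str = "lc3b",
                    min_object_voxels: int = 27,
                    closing_radius: int = 1,
                    quantile: float = 0.75) -> AxonMask:
    """Threshold the cytoplasmic LC3b channel into a binary axon mask.

    Components smaller than ``min_object_voxels`` are removed and the mask
    closed morphologically with the given radius (in voxels).
    """
    data = volume.channel(channel_role)
    if data.max() == data.min():
        raise ValueError("empty mask: blank channel")
    thr = _resolve_threshold(data, method, quantile)
    mask = data > thr
    if not mask.any():
        raise ValueError("empty mask: nothing above threshold")
    if min_object_voxels > 1:
        labels = measure.label(mask)
        sizes = np.bincount(labels.ravel())
        mask = sizes[labels] >= min_object_voxels
        mask &= labels > 0
    if closing_radius > 0:
        mask = ndimage.binary_closing(
            mask, structure=morphology.ball(closing_radius))
    if not mask.any():
        raise ValueError("empty mask after cleanup")
    return AxonMask(mask=mask, source_channel=channel_role,
                    threshold_method=str(method), threshold_value=thr,
                    min_object_voxels=min_object_voxels,
                    closing_radius=closing_radius)


def pct_outside(volume: VolumeStack, channel_role: str, mask: AxonMask,
                signal_threshold="robust", mode: str = "voxel") -> OutsideFraction:
    """Percent of supra-threshold signal volume outside the axon mask.

    ``mode='voxel'`` counts voxels individually; ``mode='object'`` assigns
    each connected supra-threshold component wholly inside or outside by its
    centroid.  Zero supra-threshold signal yields a NaN fraction with a
    warning.
    """
    if mode not in ("voxel", "object"):
        raise ConfigurationError("mode must be 'voxel' or 'object'")
    data = volume.channel(channel_role)
    if mask.mask.shape != data.shape:
        raise ValueError("mask shape does not match volume")
    thr = _resolve_threshold(data, signal_threshold)
    sig = data > thr
    vox = volume.voxel_volume_um3
    n_total = int(sig.sum())
    if n_total == 0:
        warnings.warn(f"no supra-threshold {channel_role} signal; "
                      "fraction undefined")
        return OutsideFraction(channel_role, 0.0, 0.0, float("nan"), mode)
    if mode == "voxel":
        n_outside = int((sig & ~mask.mask).sum())
    else:
        labels = measure.label(sig)
        n_outside = 0
        for region in measure.regionprops(labels):
            cz, cy, cx = (int(round(c)) for c in region.centroid)
            if not mask.mask[cz, cy, cx]:
                n_outside += region.num_pixels
    return OutsideFraction(
        channel_role=channel_role,
        total_um3=n_total * vox,
        outside_um3=n_outside * vox,
        pct_outside=100.0 * n_outside / n_total,
        mode=mode,
    )


def partition_surface(volume: VolumeStack, channel_role: str, mask: AxonMask,
                      nerve_mask: np.ndarray, d_um: float = 3.0,
                      signal_threshold="robust") -> SurfacePartition:
    """Split extra-axonal signal into nerve-surface shell vs parenchyma.

    Extra-axonal supra-threshold voxels within ``d_um`` of the nerve
    boundary (either side of it) are labelled surface; the rest parenchyma.
    ``nerve_mask`` is the filled nerve interior (from a structural channel
    or configuration).
    """
    if d_um <= 0:
        raise ConfigurationError("d_um must be positive")
    data = volume.channel(channel_role)
    if nerve_mask.shape != data.shape:
        raise ValueError("nerve_mask shape does not match volume")
    thr = _resolve_threshold(data, signal_threshold)
    sig = data > thr
    outside = sig & ~mask.mask
    n_out = int(outside.sum())
    n_total = int(sig.sum())
    if n_out == 0:
        warnings.warn("no extra-axonal signal; partition undefined")
        return SurfacePartition(channel_role, d_um, float("nan"),
                                float("nan"),
                                0.0 if n_total else float("nan"))
    sampling = (volume.z_step_um, volume.pixel_size_um, volume.pixel_size_um)
    # distance to the nerve boundary from both sides
    d_in = ndimage.distance_transform_edt(nerve_mask, sampling=sampling)
    d_ext = ndimage.distance_transform_edt(~nerve_mask, sampling=sampling)
    boundary_dist = np.where(nerve_mask, d_in, d_ext)
    on_surface = outside & (boundary_dist <= d_um)
    n_surf = int(on_surface.sum())
    return SurfacePartition(
        channel_role=channel_role, shell_depth_um=d_um,
        pct_on_surface=100.0 * n_surf / n_out,
        pct_in_parenchyma=100.0 * (n_out - n_surf) / n_out,
        pct_total_outside=100.0 * n_out / n_total,
    )


def fit_surface_trend(pairs) -> tuple:
    """OLS of per-animal (x = % total outside, y = % on surface) pairs.

    Returns ``(slope, intercept, r_squared)``; a flat response (zero total
    sum of squares) yields R-squared 0.  Requires at least 3 animals.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 3:
        raise ValueError("need >= 3 (x, y) pairs")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.ptp(y) == 0:
        slope, intercept = 0.0, float(y[0])
        return slope, intercept, 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
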