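"""Calibrated multichannel image containers and OME-TIFF I/O.

``FrameStack`` holds a single-plane time series (channel, time, y, x) and
``VolumeStack`` a z-scan (channel, z, y, x), both with physical pixel sizes
and a mapping from biological channel role (``mito``, ``optn``, ``lc3b``,
``membrane``) to array index.  Synthetic volumes may additionally carry a
per-voxel compartment label and a blob truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FrameStack",
    "VolumeStack",
    "COMPARTMENT_LABELS",
    "write_frame_stack",
    "read_frame_stack",
    "write_volume_stack",
    "read_volume_stack",
]

# voxel_truth labels for synthetic volumes
COMPARTMENT_LABELS = {"background": 0, "axon": 1, "parenchyma": 2, "surface": 3}


def _check_channels(intensities: np.ndarray, channel_roles: dict, ndim: int) -> None:
    if intensities.ndim != ndim:
        raise ValueError(f"expected {ndim}-D intensity array, got {intensities.ndim}-D")
    for role, idx in channel_roles.items():
        if not 0 <= idx < intensities.shape[0]:
            raise ValueError(f"channel role {role!r} -> index {idx} out of range")


@dataclass
class FrameStack:
    """Single-plane multichannel time series, axes (C, T, Y, X)."""

    intensities: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channel_roles: dict
    valid_mask: np.ndarray | None = None  # (T, Y, X) True where data valid

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        _check_channels(self.intensities, self.channel_roles, 4)
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_um and frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[1]

    @property
    def shape(self) -> tuple:
        return self.intensities.shape

    def channel(self, role: str) -> np.ndarray:
        """Return the (T, Y, X) array for a channel role."""
        return self.intensities[self.channel_roles[role]]


@dataclass
class VolumeStack:
    """Multichannel z-stack, axes (C, Z, Y, X)."""

    intensities: np.ndarray
    pixel_size_um: float
    z_step_um: float
    channel_roles: dict
    voxel_truth: np.ndarray | None = None  # (Z, Y, X) compartment labels
    blob_truth: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        _check_channels(self.intensities, self.channel_roles, 4)
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be positive")
        if self.voxel_truth is not None and (
            self.voxel_truth.shape != self.intensities.shape[1:]
        ):
            raise ValueError("voxel_truth shape does not match intensities")

    @property
    def voxel_volume_um3(self) -> float:
        return self.pixel_size_um**2 * self.z_step_um

    def channel(self, role: str) -> np.ndarray:
        """Return the (Z, Y, X) array for a channel role."""
        return self.intensities[self.channel_roles[role]]


# --------------------------------------------------------------------- OME-TIFF

def _roles_to_names(channel_roles: dict, n_channels: int) -> list:
    names = [f"channel_{i}" for i in range(n_channels)]
    for role, idx in channel_roles.items():
        names[idx] = role
    return names


def write_frame_stack(stack: FrameStack, path) -> None:
    tifffile.imwrite(
        str(path),
        stack.intensities,
        metadata={
            "axes": "CTYX",
            "PhysicalSizeX": stack.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
            "TimeIncrement": stack.frame_interval_s,
            "TimeIncrementUnit": "s",
            "Channel": {"Name": _roles_to_names(stack.channel_roles,
                                                stack.shape[0])},
        },
        ome=True,
    )


def write_volume_stack(stack: VolumeStack, path) -> None:
    tifffile.imwrite(
        str(path),
        stack.intensities,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": stack.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.z_step_um,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": _roles_to_names(stack.channel_roles,
                                                stack.intensities.shape[0])},
        },
        ome=True,
    )


def _read_ome(path, expect_axis: str):
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        meta = tifffile.xml2dict(tf.ome_metadata)["OME"]["Image"]
    pixels = meta["Pixels"]
    # reorder to C, <expect_axis>, Y, X
    want = "C" + expect_axis + "YX"
    order = [axes.index(a) for a in want]
    data = np.transpose(data, order)
    channels = pixels.get("Channel", [])
    if isinstance(channels, dict):
        channels = [channels]
    roles = {}
    for i, ch in enumerate(channels):
        name = ch.get("Name")
        if name:
            roles[name] = i
    return data, pixels, roles


def read_frame_stack(path) -> FrameStack:
    data, pixels, roles = _read_ome(path, "T")
    return FrameStack(
        intensities=data,
        pixel_size_um=float(pixels["PhysicalSizeX"]),
        frame_interval_s=float(pixels.get("TimeIncrement", 1.0)),
        channel_roles=roles,
    )


def read_volume_stack(path) -> VolumeStack:
    data, pixels, roles = _read_ome(path, "Z")
    return VolumeStack(
        intensities=data,
        pixel_size_um=float(pixels["PhysicalSizeX"]),
        z_step_um=float(pixels.get("PhysicalSizeZ", 1.0)),
        channel_roles=roles,
    )
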