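"""Synthetic optic-nerve scene generator with exhaustive ground truth.

Simulates the statistical structure the downstream analysis assumes:

* axonal cargo (mitochondria / OPTN puncta) moving along parallel axons in a
  ~30 um nerve, with a configurable stationary/anterograde/retrograde mixture
  (baseline: half stationary, a quarter each direction) and Gaussian speed
  distributions around the measured anterograde/retrograde means
  (0.63 / 0.78 um/s),
* state-dependent coupling between the mito channel and a partner (OPTN)
  channel,
* z-stacks in which a controlled voxel-volume fraction of punctate signal
  lies outside the axon tubes, split between nerve surface and parenchyma,
* axolemmal protrusion event series (swelling, loading, pinching-off,
  detached) at 30-s or 2-min intervals,
* Gaussian PSF blur, scaled-Poisson shot noise plus Gaussian read noise, and
  linear frame-to-frame drift.

Every generated object is accompanied by its ground truth so that recovery
by the measurement pipeline can be scored exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import ConfigurationError, SceneConfig
from .stacks import COMPARTMENT_LABELS, FrameStack, VolumeStack

__all__ = [
    "ParticleTruth",
    "ProtrusionEventTruth",
    "simulate_trajectories",
    "render_timelapse",
    "render_zstack",
    "inject_drift",
    "make_protrusion_series",
    "make_sparse_axon_image",
    "render_object_volume",
    "axon_lane_centers_um",
    "truth_table",
]

STATES = ("stationary", "anterograde", "retrograde")

# margins used when placing particles / building fields (um)
_EDGE_MARGIN_UM = 3.0
_FIELD_MARGIN_Y_UM = 4.0


@dataclass
class ParticleTruth:
    particle_id: int
    axon_id: int
    state: str
    speed_um_s: float           # signed; anterograde positive
    positions: np.ndarray       # arclength (um) per frame
    carries_partner: bool
    inside_axon: bool = True
    compartment: str = "axon"


@dataclass
class ProtrusionEventTruth:
    kind: str                   # swelling | loading | pinching_off | detached
    interval_s: float
    timepoints_s: np.ndarray
    pinch_index: int | None     # index of last attached timepoint
    distance_um: np.ndarray     # true bud-axon gap per timepoint
    bud_intensity: np.ndarray   # generative bud amplitude series (a.u.)
    contains_mito: bool = True


def _rngs(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def axon_lane_centers_um(cfg: SceneConfig) -> np.ndarray:
    """y coordinate (um) of each axon lane center in time-lapse geometry."""
    pitch = cfg.nerve_diameter_um / cfg.n_axons
    return _FIELD_MARGIN_Y_UM + (np.arange(cfg.n_axons) + 0.5) * pitch


# ----------------------------------------------------------------- trajectories

def _truncated_speed(rng, mean: float, sd: float, floor: float = 0.1) -> float:
    """Draw a moving speed; resample below `floor` so moving truth stays
    unambiguous against the 0.1 um/s classification boundary."""
    if sd == 0:
        return float(mean)
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v >= floor:
            return float(v)
    return float(max(mean, floor))


def simulate_trajectories(cfg: SceneConfig) -> list:
    """Simulate per-frame arclength positions for ``cfg.n_particles`` cargo.

    States are drawn from ``cfg.state_fractions``; movers advance at a
    constant drawn speed (anterograde positive), stationary particles jitter
    with a net velocity well below the 0.1 um/s boundary.  Start positions
    are chosen so movers remain inside the field for the whole movie.
    """
    rng, = _rngs(cfg.seed, 1)
    n = cfg.n_particles
    t = np.arange(cfg.n_frames) * cfg.frame_interval_s
    span = t[-1] - t[0]
    lo = _EDGE_MARGIN_UM
    hi = cfg.field_length_um - _EDGE_MARGIN_UM
    if hi <= lo:
        raise ConfigurationError("field_length_um too small for margins")

    states = rng.choice(3, size=n, p=cfg.state_fractions)
    axon_ids = rng.integers(0, cfg.n_axons, size=n)
    particles = []
    for i in range(n):
        state = STATES[states[i]]
        jitter = rng.normal(0.0, cfg.stationary_jitter_um, size=cfg.n_frames)
        if state == "stationary":
            # keep net velocity strictly below 0.09 um/s (truth unambiguous)
            while abs(jitter[-1] - jitter[0]) >= 0.09 * span:
                jitter = rng.normal(0.0, cfg.stationary_jitter_um,
                                    size=cfg.n_frames)
            x0 = rng.uniform(lo, hi)
            pos = x0 + jitter
            speed = (pos[-1] - pos[0]) / span
        else:
            mean = (cfg.speed_mean_antero_um_s if state == "anterograde"
                    else cfg.speed_mean_retro_um_s)
            v = _truncated_speed(rng, mean, cfg.speed_sd_um_s)
            if state == "retrograde":
                v = -v
            travel = v * span
            a, b = (lo, hi - travel) if v > 0 else (lo - travel, hi)
            if b <= a:
                raise ConfigurationError(
                    "field_length_um too small for drawn speeds")
            x0 = rng.uniform(a, b)
            pos = x0 + v * t
            speed = v
        carries = bool(rng.random() < cfg.coloc_coupling.get(state, 0.0))
        particles.append(ParticleTruth(
            particle_id=i, axon_id=int(axon_ids[i]), state=state,
            speed_um_s=float(speed), positions=pos, carries_partner=carries,
        ))
    return particles


def truth_table(particles: list) -> pd.DataFrame:
    """Tabulate particle ground truth (one row per particle)."""
    return pd.DataFrame(
        {
            "particle_id": [p.particle_id for p in particles],
            "axon_id": [p.axon_id for p in particles],
            "state": [p.state for p in particles],
            "speed_um_s": [p.speed_um_s for p in particles],
            "carries_partner": [p.carries_partner for p in particles],
            "compartment": [p.compartment for p in particles],
        }
    )


# --------------------------------------------------------------------- rendering

def _stamp_spots(img: np.ndarray, ys_px, xs_px, amp: float, sigma_px: float):
    """Add Gaussian spots to a 2-D image in place; skip spots fully outside."""
    ny, nx = img.shape
    r = max(int(np.ceil(4 * sigma_px)), 2)
    skipped = 0
    for y, x in zip(np.atleast_1d(ys_px), np.atleast_1d(xs_px)):
        iy, ix = int(round(y)), int(round(x))
        if iy + r < 0 or iy - r >= ny or ix + r < 0 or ix - r >= nx:
            skipped += 1
            continue
        y0, y1 = max(iy - r, 0), min(iy + r + 1, ny)
        x0, x1 = max(ix - r, 0), min(ix + r + 1, nx)
        yy = np.arange(y0, y1)[:, None] - y
        xx = np.arange(x0, x1)[None, :] - x
        img[y0:y1, x0:x1] += amp * np.exp(-(yy**2 + xx**2) / (2 * sigma_px**2))
    return skipped


def _apply_noise(clean: np.ndarray, rng, noise_model: dict) -> np.ndarray:
    scale = noise_model.get("poisson_scale", 1.0)
    sd = noise_model.get("gaussian_sd", 0.0)
    out = np.asarray(clean, dtype=np.float64)
    if scale and scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * scale) / scale
    if sd and sd > 0:
        out = out + rng.normal(0.0, sd, size=out.shape)
    return np.clip(out, 0.0, None)


def render_timelapse(particles: list, cfg: SceneConfig,
                     noise: bool = True) -> FrameStack:
    """Render particle trajectories into a (C, T, Y, X) time series.

    Channels: ``mito`` (all particles), ``optn`` (particles carrying the
    partner flag), ``lc3b`` (diffuse axoplasmic fill over the nerve band,
    used by contour tracing).
    """
    px = cfg.pixel_size_um
    ny = int(round((cfg.nerve_diameter_um + 2 * _FIELD_MARGIN_Y_UM) / px))
    nx = int(round(cfg.field_length_um / px))
    sigma_px = cfg.psf_sigma_um / px
    lanes = axon_lane_centers_um(cfg)

    clean = np.zeros((3, cfg.n_frames, ny, nx), dtype=np.float64)
    # diffuse cytoplasmic LC3b fill across the nerve cross-section
    y_um = (np.arange(ny) + 0.5) * px
    band = ((y_um >= _FIELD_MARGIN_Y_UM)
            & (y_um <= _FIELD_MARGIN_Y_UM + cfg.nerve_diameter_um))
    fill = ndimage.gaussian_filter1d(band.astype(float), sigma_px)
    clean[2] += (cfg.spot_amplitude / 3.0) * fill[None, :, None]

    skipped = 0
    for p in particles:
        y_px = lanes[p.axon_id] / px - 0.5
        xs = p.positions / px - 0.5
        for ti in range(cfg.n_frames):
            skipped += _stamp_spots(clean[0, ti], y_px, xs[ti],
                                    cfg.spot_amplitude, sigma_px)
            if p.carries_partner:
                _stamp_spots(clean[1, ti], y_px, xs[ti],
                             cfg.spot_amplitude, sigma_px)
    if skipped:
        warnings.warn(f"{skipped} spot renderings fell outside the field "
                      "and were skipped (truth retained)")

    if noise:
        rng = _rngs(cfg.seed + 1_000_003, 1)[0]
        out = _apply_noise(clean, rng, cfg.noise_model)
    else:
        out = clean
    return FrameStack(
        intensities=out.astype(np.float32),
        pixel_size_um=px,
        frame_interval_s=cfg.frame_interval_s,
        channel_roles={"mito": 0, "optn": 1, "lc3b": 2},
    )


# ------------------------------------------------------------------------ drift

def inject_drift(stack: FrameStack, drift_per_frame_px,
                 order: int = 1):
    """Shift frame ``t`` by ``t * drift`` (dy, dx) pixels.

    Returns the drifted stack and the (T, 2) table of true shifts applied.
    ``order=0`` gives nearest-neighbour (exact for integer drift), ``order=1``
    bilinear interpolation.  Cumulative drift beyond 25% of the field is an
    error.
    """
    dy, dx = float(drift_per_frame_px[0]), float(drift_per_frame_px[1])
    nt, ny, nx = stack.intensities.shape[1:]
    total = (nt - 1) * np.array([dy, dx])
    if abs(total[0]) > 0.25 * ny or abs(total[1]) > 0.25 * nx:
        raise ValueError("cumulative drift exceeds 25% of the field")
    shifts = np.arange(nt)[:, None] * np.array([dy, dx])[None, :]
    if dy == 0.0 and dx == 0.0:
        return FrameStack(stack.intensities.copy(), stack.pixel_size_um,
                          stack.frame_interval_s, dict(stack.channel_roles)), shifts
    out = np.empty_like(stack.intensities)
    for c in range(out.shape[0]):
        for t in range(nt):
            out[c, t] = ndimage.shift(stack.intensities[c, t], shifts[t],
                                      order=order, mode="constant", cval=0.0)
    drifted = FrameStack(out, stack.pixel_size_um, stack.frame_interval_s,
                         dict(stack.channel_roles))
    return drifted, shifts


# --------------------------------------------------------------------- z-stacks

def _zstack_tube_centers(cfg: SceneConfig):
    """(z, y) centers (um) of axon tubes in the nerve cross-section.

    Centers are snapped to voxel centers so that a punctum on the tube
    axis has the maximum possible margin to the tube wall in the coarse
    z sampling.
    """
    R = cfg.nerve_diameter_um / 2.0
    ring = 0.45 * R
    ang = 2 * np.pi * np.arange(cfg.zstack_n_axons) / cfg.zstack_n_axons
    cz = R + _EDGE_MARGIN_UM + ring * np.sin(ang)
    cy = R + _EDGE_MARGIN_UM + ring * np.cos(ang)
    cz = (np.round(cz / cfg.z_step_um - 0.5) + 0.5) * cfg.z_step_um
    cy = (np.round(cy / cfg.pixel_size_um - 0.5) + 0.5) * cfg.pixel_size_um
    return np.stack([cz, cy], axis=1)


def render_zstack(particles: list, cfg: SceneConfig,
                  noise: bool = True) -> VolumeStack:
    """Render a frame-averaged z-scan with a controlled extra-axonal split.

    The LC3b channel fills the axon tubes (the axon-mask source).  Punctate
    signal blobs are placed so that the fraction of blobs outside the tubes
    equals ``cfg.extra_axonal_fraction`` (deterministic allocation), and the
    outside blobs are split surface/parenchyma per
    ``cfg.surface_share_of_outside``.  Only stationary particles are
    rendered inside axons — frame averaging blurs movers out of z-scans.
    Per-voxel compartment labels and a blob truth table are attached.
    """
    f = cfg.extra_axonal_fraction
    if not 0.0 <= f <= 1.0:
        raise ConfigurationError("extra_axonal_fraction must be in [0, 1]")
    px = cfg.pixel_size_um
    zs = cfg.z_step_um
    R = cfg.nerve_diameter_um / 2.0
    zc = yc = R + _EDGE_MARGIN_UM
    nz = int(round((cfg.nerve_diameter_um + 2 * _EDGE_MARGIN_UM) / zs))
    nyx = int(round((cfg.nerve_diameter_um + 2 * _EDGE_MARGIN_UM) / px))
    nx = int(round(cfg.zstack_length_um / px))
    tube_r = cfg.zstack_axon_diameter_um / 2.0
    centers = _zstack_tube_centers(cfg)

    z_um = (np.arange(nz) + 0.5) * zs
    y_um = (np.arange(nyx) + 0.5) * px
    zz, yy = np.meshgrid(z_um, y_um, indexing="ij")
    r_nerve = np.hypot(zz - zc, yy - yc)
    tube_dist = np.min(
        np.stack([np.hypot(zz - c[0], yy - c[1]) for c in centers]), axis=0)
    tube_xsec = tube_dist <= tube_r  # (Z, Y) cross-section

    voxel_truth = np.zeros((nz, nyx, nx), dtype=np.uint8)
    voxel_truth[(r_nerve <= R)[..., None] & np.ones(nx, bool)] = (
        COMPARTMENT_LABELS["parenchyma"])
    shell = (r_nerve > R) & (r_nerve <= R + 1.5)
    voxel_truth[shell[..., None] & np.ones(nx, bool)] = (
        COMPARTMENT_LABELS["surface"])
    voxel_truth[tube_xsec[..., None] & np.ones(nx, bool)] = (
        COMPARTMENT_LABELS["axon"])

    rng = _rngs(cfg.seed + 2_000_003, 1)[0]

    # inside blobs: stationary particles, mapped onto tubes.  Puncta are
    # discrete organelles: enforce a minimum along-tube separation so blobs
    # never fuse (fused blobs would share supra-threshold voxels and bias
    # the constructed outside fraction).
    min_sep = 1.5
    inside = [p for p in particles if p.state == "stationary"]
    blob_rows = []
    placed: dict = {}
    for p in inside:
        tube = p.axon_id % cfg.zstack_n_axons
        x = float(np.mean(p.positions)) % cfg.zstack_length_um
        x = min(max(x, _EDGE_MARGIN_UM), cfg.zstack_length_um - _EDGE_MARGIN_UM)
        taken = placed.setdefault(tube, [])
        ok = all(abs(x - xo) >= min_sep for xo in taken)
        if not ok:
            for _ in range(200):
                x = rng.uniform(_EDGE_MARGIN_UM,
                                cfg.zstack_length_um - _EDGE_MARGIN_UM)
                if all(abs(x - xo) >= min_sep for xo in taken):
                    ok = True
                    break
        if not ok:
            continue  # tube is full; drop from the z-stack rendering
        taken.append(x)
        c = centers[tube]
        blob_rows.append((c[0], c[1], x, "axon", True, p.carries_partner))
    n_in = len(blob_rows)
    if n_in == 0:
        raise ConfigurationError("no stationary particles to render in z-stack")

    n_out = int(round(n_in * f / (1.0 - f))) if f < 1.0 else 0
    n_surface = int(round(n_out * cfg.surface_share_of_outside))
    p_coupl = cfg.coloc_coupling.get("stationary", 0.0)
    out_pos: list = []
    for i in range(n_out):
        on_surface = i < n_surface
        for _ in range(10000):
            x = rng.uniform(_EDGE_MARGIN_UM,
                            cfg.zstack_length_um - _EDGE_MARGIN_UM)
            if on_surface:
                ang = rng.uniform(0, 2 * np.pi)
                rr = R + 0.75
                z, y = zc + rr * np.sin(ang), yc + rr * np.cos(ang)
            else:
                z = rng.uniform(zc - (R - 4), zc + (R - 4))
                y = rng.uniform(yc - (R - 4), yc + (R - 4))
                if np.hypot(z - zc, y - yc) > R - 4 or (
                    np.min(np.hypot(centers[:, 0] - z, centers[:, 1] - y))
                    <= tube_r + 2.0
                ):
                    continue
            if all((z - zo)**2 + (y - yo)**2 + (x - xo)**2 >= min_sep**2
                   for zo, yo, xo in out_pos):
                break
        out_pos.append((z, y, x))
        comp = "surface" if on_surface else "parenchyma"
        blob_rows.append((z, y, x, comp, False, rng.random() < p_coupl))

    blob_truth = pd.DataFrame(
        blob_rows,
        columns=["z_um", "y_um", "x_um", "compartment", "inside_axon",
                 "carries_partner"],
    )
    # snap blob centers to voxel centers so every punctum has an identical
    # discrete footprint; the constructed outside volume fraction is then
    # exact up to noise rather than biased by z-grid phase
    for col, step in (("z_um", zs), ("y_um", px), ("x_um", px)):
        blob_truth[col] = (np.round(blob_truth[col] / step - 0.5) + 0.5) * step

    clean = np.zeros((3, nz, nyx, nx), dtype=np.float64)
    # lc3b: solid tube fill
    clean[2] += (cfg.spot_amplitude / 2.0) * tube_xsec[..., None]

    # blobs: small solid ellipsoids (0.4 um radius)
    rb = 0.4
    for row in blob_truth.itertuples():
        iz = np.unique(np.clip(np.arange(int((row.z_um - rb) / zs),
                                         int((row.z_um + rb) / zs) + 2),
                               0, nz - 1))
        iy = np.unique(np.clip(np.arange(int((row.y_um - rb) / px) - 1,
                                         int((row.y_um + rb) / px) + 2),
                               0, nyx - 1))
        ix = np.unique(np.clip(np.arange(int((row.x_um - rb) / px) - 1,
                                         int((row.x_um + rb) / px) + 2),
                               0, nx - 1))
        Z = (iz + 0.5) * zs - row.z_um
        Y = (iy + 0.5) * px - row.y_um
        X = (ix + 0.5) * px - row.x_um
        ell = ((Z[:, None, None] / max(rb, zs / 2))**2
               + (Y[None, :, None] / rb)**2
               + (X[None, None, :] / rb)**2) <= 1.0
        sub = np.ix_(iz, iy, ix)
        clean[0][sub] += cfg.spot_amplitude * ell
        if row.carries_partner:
            clean[1][sub] += cfg.spot_amplitude * ell

    sig = (0.6 / zs, cfg.psf_sigma_um / px, cfg.psf_sigma_um / px)
    for c in range(3):
        clean[c] = ndimage.gaussian_filter(clean[c], sigma=sig)

    if noise:
        # frame-averaged acquisition: read noise reduced
        nm = dict(cfg.noise_model)
        nm["gaussian_sd"] = nm.get("gaussian_sd", 0.0) / 2.0
        out = _apply_noise(clean, rng, nm)
    else:
        out = clean
    return VolumeStack(
        intensities=out.astype(np.float32),
        pixel_size_um=px,
        z_step_um=zs,
        channel_roles={"mito": 0, "optn": 1, "lc3b": 2},
        voxel_truth=voxel_truth,
        blob_truth=blob_truth,
    )


# --------------------------------------------------------- protrusion event series

_VALID_SCHEDULES = {(30.0, 300.0), (120.0, 600.0)}


def make_protrusion_series(kind: str, interval_s: float = 30.0,
                           duration_s: float = 300.0,
                           pinch_index: int | None = None,
                           contains_mito: bool = True,
                           pixel_size_um: float = 0.2,
                           z_step_um: float = 0.5,
                           amplitude: float = 10.0,
                           noise_sd: float = 0.0,
                           seed: int = 0):
    """Generate a sub-volume series of one axolemmal dystrophy event.

    ``kind`` is one of ``swelling`` (symmetric bulge, static intensities),
    ``loading`` (attached bud whose intensity rises while the axon directly
    beneath loses the same integrated amount), ``pinching_off`` (attached
    until ``pinch_index``, then the bud separates acutely), or ``detached``
    (separate throughout).  Sampling follows the repetitive z-scan schedules
    (30-s intervals for 5 min, or 2-min intervals for 10 min).

    Returns ``(volumes, axon_masks, truth)`` where ``volumes`` is a list of
    :class:`VolumeStack` (channels ``membrane``, ``optn``, ``mito``),
    ``axon_masks`` the true axon-tube mask per timepoint, and ``truth`` a
    :class:`ProtrusionEventTruth`.
    """
    if kind not in ("swelling", "loading", "pinching_off", "detached"):
        raise ConfigurationError(f"unknown event kind {kind!r}")
    if (float(interval_s), float(duration_s)) not in _VALID_SCHEDULES:
        raise ConfigurationError(
            "interval/duration must be 30 s / 5 min or 2 min / 10 min")
    n_tp = int(round(duration_s / interval_s)) + 1
    if kind == "pinching_off":
        if pinch_index is None:
            pinch_index = n_tp // 2
        if not 0 <= pinch_index < n_tp - 1:
            raise ConfigurationError("pinch_index out of range")
    else:
        pinch_index = None

    rng = np.random.default_rng(seed)
    # geometry (um)
    Lz, Ly, Lx = 8.0, 10.0, 20.0
    nz = int(round(Lz / z_step_um))
    ny_ = int(round(Ly / pixel_size_um))
    nx = int(round(Lx / pixel_size_um))
    z_um = (np.arange(nz) + 0.5) * z_step_um
    y_um = (np.arange(ny_) + 0.5) * pixel_size_um
    x_um = (np.arange(nx) + 0.5) * pixel_size_um
    ZZ, YY, XX = np.meshgrid(z_um, y_um, x_um, indexing="ij")
    zc, y_axon, x_bud = Lz / 2, 3.0, Lx / 2
    r_axon, r_bud = 0.8, 1.0

    axon = (np.hypot(ZZ - zc, YY - y_axon) <= r_axon)
    tp = np.arange(n_tp) * interval_s
    ramp = np.linspace(0.0, 1.0, n_tp)

    if kind == "swelling":
        dist = np.zeros(n_tp)
        bud_amp = np.full(n_tp, 1.5 * amplitude)
    elif kind == "loading":
        dist = np.zeros(n_tp)
        bud_amp = amplitude * (1.2 + 0.8 * ramp)
    elif kind == "pinching_off":
        dist = np.where(np.arange(n_tp) <= pinch_index, 0.0,
                        0.8 * (np.arange(n_tp) - pinch_index))
        bud_amp = np.full(n_tp, 1.8 * amplitude)
    else:  # detached
        dist = np.full(n_tp, 1.5)
        bud_amp = np.full(n_tp, 1.8 * amplitude)

    sig = (0.3 / z_step_um, 0.25 / pixel_size_um, 0.25 / pixel_size_um)
    beneath = axon & (np.abs(XX - x_bud) <= 1.0)
    v_bud = None
    volumes, masks = [], []
    for k in range(n_tp):
        if kind == "swelling":
            swell = (np.hypot(ZZ - zc, YY - y_axon) <= 1.3) & (
                np.abs(XX - x_bud) <= 1.5)
            shape_bud = swell & ~axon
            y_bud_c = y_axon
        else:
            overlap = 0.3 if dist[k] == 0 else -dist[k]
            y_bud_c = y_axon + r_axon + r_bud - overlap
            shape_bud = (np.sqrt((ZZ - zc)**2 + (YY - y_bud_c)**2
                                 + (XX - x_bud)**2) <= r_bud) & ~axon
        if v_bud is None:
            v_bud = shape_bud.sum()
        membrane = (axon | shape_bud).astype(float) * amplitude

        optn = np.zeros_like(membrane)
        optn[axon] = amplitude
        if kind == "loading":
            # conservative transfer: bud gain drawn from the axon beneath
            moved = (bud_amp[k] - bud_amp[0]) * v_bud
            optn[beneath] = max(amplitude - moved / max(beneath.sum(), 1), 0.1)
        elif kind == "swelling":
            optn[beneath] = 1.5 * amplitude
        optn[shape_bud] = bud_amp[k]

        mito = np.zeros_like(membrane)
        if contains_mito:
            mito[shape_bud] = amplitude

        arr = np.stack([membrane, optn, mito])
        for c in range(3):
            arr[c] = ndimage.gaussian_filter(arr[c], sigma=sig)
        if noise_sd > 0:
            arr = np.clip(arr + rng.normal(0, noise_sd, arr.shape), 0, None)
        volumes.append(VolumeStack(
            intensities=arr.astype(np.float32),
            pixel_size_um=pixel_size_um, z_step_um=z_step_um,
            channel_roles={"membrane": 0, "optn": 1, "mito": 2},
        ))
        masks.append(axon.copy())

    truth = ProtrusionEventTruth(
        kind=kind, interval_s=float(interval_s), timepoints_s=tp,
        pinch_index=pinch_index, distance_um=dist, bud_intensity=bud_amp,
        contains_mito=contains_mito,
    )
    return volumes, masks, truth


# ----------------------------------------------------------- sparse axon images

def make_sparse_axon_image(length_um: float,
                           protrusion_x_um=(),
                           mito_flags=(),
                           symmetric_x_um=(),
                           pixel_size_um: float = 0.2,
                           axon_radius_um: float = 0.8,
                           bump_radius_um: float = 1.8,
                           amplitude: float = 10.0,
                           noise_sd: float = 0.0,
                           seed: int = 0) -> dict:
    """Render a single sparse axon (2-D, one z-plane) with planted bumps.

    Asymmetric protrusions (half-discs on one side) are planted at
    ``protrusion_x_um`` with per-protrusion mitochondria content flags;
    symmetric swellings (bulge on both sides, not protrusions) at
    ``symmetric_x_um``.  Returns a dict with ``membrane`` and ``mito``
    images, the centerline row, and the planted truth.
    """
    protrusion_x_um = list(protrusion_x_um)
    mito_flags = list(mito_flags)
    if len(mito_flags) != len(protrusion_x_um):
        raise ConfigurationError("mito_flags must match protrusion_x_um")
    px = pixel_size_um
    ny = int(round(12.0 / px))
    nx = int(round(length_um / px))
    y0 = 6.0
    y_um = (np.arange(ny) + 0.5) * px
    x_um = (np.arange(nx) + 0.5) * px
    YY, XX = np.meshgrid(y_um, x_um, indexing="ij")

    membrane = (np.abs(YY - y0) <= axon_radius_um).astype(float)
    mito = np.zeros_like(membrane)
    for x, has_mito in zip(protrusion_x_um, mito_flags):
        bump = (np.hypot(YY - y0, XX - x) <= bump_radius_um) & (YY < y0)
        membrane[bump] = 1.0
        if has_mito:
            core = (np.hypot(YY - (y0 - axon_radius_um - 0.2), XX - x) <= 0.4)
            mito[core] = 1.0
    for x in symmetric_x_um:
        bulge = np.hypot(YY - y0, XX - x) <= bump_radius_um
        membrane[bulge] = 1.0

    sig = 0.25 / px
    membrane = ndimage.gaussian_filter(membrane * amplitude, sig)
    mito = ndimage.gaussian_filter(mito * amplitude, sig)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        membrane = np.clip(membrane + rng.normal(0, noise_sd, membrane.shape),
                           0, None)
        mito = np.clip(mito + rng.normal(0, noise_sd, mito.shape), 0, None)
    return {
        "membrane": membrane,
        "mito": mito,
        "centerline_row": int(round(y0 / px - 0.5)),
        "pixel_size_um": px,
        "truth": {
            "length_um": length_um,
            "protrusion_x_um": protrusion_x_um,
            "mito_flags": mito_flags,
            "symmetric_x_um": list(symmetric_x_um),
        },
    }


# ------------------------------------------------------------ shape phantoms

def render_object_volume(kind: str, radius_um: float, voxel_um: float,
                         length_um: float = 0.0) -> np.ndarray:
    """Voxelize a sphere or a capsule (spherocylinder) on an isotropic grid.

    Capsules model elongated axonal mitochondria (``length_um`` is the
    cylindrical section length); spheres model the rounder mitochondria
    found inside protrusions.
    """
    if kind not in ("sphere", "capsule"):
        raise ConfigurationError(f"unknown object kind {kind!r}")
    if kind == "sphere":
        length_um = 0.0
    half = radius_um + length_um / 2.0 + 2 * voxel_um
    n = int(np.ceil(2 * half / voxel_um)) + 1
    c = (n - 1) / 2.0
    idx = (np.arange(n) - c) * voxel_um
    Z, Y, X = np.meshgrid(idx, idx, idx, indexing="ij")
    ax = np.clip(np.abs(X) - length_um / 2.0, 0, None)
    return (np.sqrt(Z**2 + Y**2 + ax**2) <= radius_um)
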