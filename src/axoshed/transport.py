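"""Kymograph object detection, trace linking, movement classification and
two-channel trace co-localization.

Movement is scored over the whole 1-min record: a trace's net velocity is
its end-to-end displacement over its observed span, and an object counts as
moving when that velocity is 0.1 um/s or faster (boundary inclusive), with
positive velocity anterograde.  Summaries aggregate per animal first, as the
source analysis does.  Co-localization pairs traces across channels by
position overlap and stratifies the co-localized / solo split by the
reference channel's movement class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .config import ConfigurationError
from .kymo import Kymograph

__all__ = [
    "Trace",
    "MovementSummary",
    "ColocSummary",
    "detect_kymo_objects",
    "link_traces",
    "trace_velocity",
    "classify_movement",
    "summarize_movement",
    "traces_to_table",
    "match_traces",
    "deduplicate_stationary",
    "MOVING_THRESHOLD_UM_S",
]

MOVING_THRESHOLD_UM_S = 0.1
CLASSES = ("stationary", "anterograde", "retrograde")


@dataclass
class Trace:
    trace_id: int
    channel_role: str
    points: list                  # [(t_s, s_um), ...], t strictly increasing
    net_velocity_um_s: float = 0.0
    movement_class: str = "stationary"
    source: str | None = None     # kymograph / swath id

    @property
    def n_frames_observed(self) -> int:
        return len(self.points)

    @property
    def times(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def positions(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


@dataclass
class MovementSummary:
    per_animal: pd.DataFrame      # animal, group, pct per class, speeds
    group_stats: pd.DataFrame     # group x measure: mean, sem, n_animals


@dataclass
class ColocSummary:
    per_class: pd.DataFrame       # class, n_coloc, n_solo, frac_coloc
    pool_distribution: pd.DataFrame  # class shares within coloc / solo pools
    assignments: dict = field(default_factory=dict, repr=False)


# -------------------------------------------------------------------- detection

def detect_kymo_objects(kymo: Kymograph, min_prominence: float,
                        smooth_sigma_px: float = 1.0) -> list:
    """Per-time-row subpixel peak positions (um) above a prominence.

    Rows are lightly smoothed, peaks found by prominence, and positions
    refined by parabolic interpolation of the log-free intensity profile.
    """
    s = kymo.s_positions_um
    pitch = s[1] - s[0]
    out = []
    for row in kymo.K:
        prof = ndimage.gaussian_filter1d(row.astype(float), smooth_sigma_px) \
            if smooth_sigma_px > 0 else row.astype(float)
        idx, _ = signal.find_peaks(prof, prominence=min_prominence)
        pos = []
        for i in idx:
            if 0 < i < len(prof) - 1:
                denom = prof[i - 1] - 2 * prof[i] + prof[i + 1]
                delta = 0.0 if denom == 0 else \
                    0.5 * (prof[i - 1] - prof[i + 1]) / denom
                delta = float(np.clip(delta, -0.5, 0.5))
            else:
                delta = 0.0
            pos.append(s[0] + (i + delta) * pitch)
        out.append(np.array(sorted(pos)))
    return out


# ---------------------------------------------------------------------- linking

def _close_gaps(closed: list, dt_s: float, max_residual_um: float | None,
                tol_um: float = 0.6) -> list:
    """Merge time-disjoint track fragments that lie on one kymograph line.

    Detection dropouts longer than the frame-to-frame gap bridge split a
    single object into fragments; a later fragment is appended to an
    earlier one when it starts where the earlier one's fitted line
    predicts and the union still fits a line within the residual gate.
    """
    resid_gate = max_residual_um if max_residual_um is not None else 0.3
    frags = sorted(closed, key=lambda tr: tr.points[0][0])
    merged: list = []
    for tr in frags:
        t_start, s_start = tr.points[0]
        best = None
        for m in merged:
            if m.points[-1][0] >= t_start:
                continue
            if abs(m.predict(t_start) - s_start) > tol_um:
                continue
            pts = m.points + tr.points
            ts = np.array([p[0] for p in pts])
            ss = np.array([p[1] for p in pts])
            resid = ss - np.polyval(np.polyfit(ts, ss, 1), ts)
            if np.sqrt(np.mean(resid**2)) > resid_gate:
                continue
            if best is None or m.points[-1][0] > best.points[-1][0]:
                best = m
        if best is not None:
            best.points.extend(tr.points)
            best.last_frame = int(round(tr.points[-1][0] / dt_s))
        else:
            merged.append(tr)
    return merged


class _Active:
    __slots__ = ("points", "last_frame")

    def __init__(self, t, s, frame):
        self.points = [(t, s)]
        self.last_frame = frame

    def predict(self, t):
        (t0, s0), (tl, sl) = self.points[0], self.points[-1]
        if tl == t0:
            return sl
        v = (sl - s0) / (tl - t0)
        return sl + v * (t - tl)


def link_traces(peaks: list, dt_s: float, max_jump_um: float = 2.0,
                max_gap_frames: int = 2, min_trace_len: int = 5,
                max_residual_um: float = 0.3,
                channel_role: str = "mito", source: str | None = None):
    """Greedy frame-to-frame nearest-neighbour linking of kymograph peaks.

    Peaks are matched to the position each active trace predicts from its
    net velocity (velocity continuity resolves crossings); links longer than
    ``max_jump_um`` are broken, gaps up to ``max_gap_frames`` bridged, and
    traces observed fewer than ``min_trace_len`` frames are discarded (their
    count is returned).

    ``max_residual_um`` is a track-quality gate: a genuine constant-velocity
    object follows a straight kymograph line up to jitter and localization
    noise, so traces whose RMS deviation from their least-squares line
    exceeds the gate are chimeras built from peaks of several objects and
    are discarded (and counted).  Set to ``None`` to keep everything, e.g.
    when direction-reversing objects are expected.

    Returns ``(traces, n_discarded)``.
    """
    active: list[_Active] = []
    closed: list[_Active] = []
    for frame, pk in enumerate(peaks):
        t = frame * dt_s
        pk = np.asarray(pk, dtype=float)
        # candidate (cost, trace_idx, peak_idx), gap-scaled jump limit
        cands = []
        for ai, tr in enumerate(active):
            gap = frame - tr.last_frame
            limit = max_jump_um * gap
            pred = tr.predict(t)
            for pi, sp in enumerate(pk):
                d = abs(sp - pred)
                if d <= limit:
                    cands.append((d, ai, pi))
        cands.sort(key=lambda c: c[0])
        used_t, used_p = set(), set()
        for d, ai, pi in cands:
            if ai in used_t or pi in used_p:
                continue
            used_t.add(ai)
            used_p.add(pi)
            active[ai].points.append((t, float(pk[pi])))
            active[ai].last_frame = frame
        for pi, sp in enumerate(pk):
            if pi not in used_p:
                active.append(_Active(t, float(sp), frame))
        still = []
        for tr in active:
            if frame - tr.last_frame > max_gap_frames:
                closed.append(tr)
            else:
                still.append(tr)
        active = still
    closed.extend(active)
    closed = _close_gaps(closed, dt_s, max_residual_um)

    traces, n_discarded = [], 0
    for tr in closed:
        if len(tr.points) < min_trace_len:
            n_discarded += 1
            continue
        if max_residual_um is not None:
            ts = np.array([p[0] for p in tr.points])
            ss = np.array([p[1] for p in tr.points])
            resid = ss - np.polyval(np.polyfit(ts, ss, 1), ts)
            if np.sqrt(np.mean(resid**2)) > max_residual_um:
                n_discarded += 1
                continue
        t = Trace(trace_id=len(traces), channel_role=channel_role,
                  points=tr.points, source=source)
        t.net_velocity_um_s = trace_velocity(t)
        t.movement_class = classify_movement(t.net_velocity_um_s)
        traces.append(t)
    return traces, n_discarded


# ----------------------------------------------------------------- classification

def trace_velocity(trace: Trace) -> float:
    """Net signed velocity: end-to-end displacement over the observed span."""
    if trace.n_frames_observed < 2:
        raise ValueError("need at least 2 points")
    (t0, s0), (t1, s1) = trace.points[0], trace.points[-1]
    if t1 == t0:
        raise ValueError("zero trace duration")
    return (s1 - s0) / (t1 - t0)


def classify_movement(v_um_s: float,
                      threshold: float = MOVING_THRESHOLD_UM_S) -> str:
    """Moving iff |v| >= threshold (inclusive); sign gives the direction."""
    if threshold <= 0:
        raise ConfigurationError("threshold must be positive")
    if abs(v_um_s) >= threshold:
        return "anterograde" if v_um_s > 0 else "retrograde"
    return "stationary"


# --------------------------------------------------------------------- summaries

def traces_to_table(traces: list, animal: str = "a1",
                    condition: str = "ctrl") -> pd.DataFrame:
    return pd.DataFrame({
        "trace_id": [t.trace_id for t in traces],
        "animal": animal,
        "condition": condition,
        "channel_role": [t.channel_role for t in traces],
        "source": [t.source for t in traces],
        "movement_class": [t.movement_class for t in traces],
        "velocity_um_s": [t.net_velocity_um_s for t in traces],
    })


def summarize_movement(trace_table: pd.DataFrame) -> MovementSummary:
    """Per-animal class percentages and mean speeds, then group mean +/- SEM.

    ``trace_table`` needs columns ``animal``, ``condition``,
    ``movement_class`` and ``velocity_um_s``.  Speeds are unsigned means
    over moving traces only; groups with zero traces are omitted with a
    warning.  Per-animal percentages sum to 100 exactly.
    """
    required = {"animal", "condition", "movement_class", "velocity_um_s"}
    missing = required - set(trace_table.columns)
    if missing:
        raise ValueError(f"trace_table missing columns {sorted(missing)}")
    rows = []
    for (cond, animal), df in trace_table.groupby(["condition", "animal"]):
        n = len(df)
        if n == 0:
            warnings.warn(f"animal {animal} in {cond} has no traces; omitted")
            continue
        row = {"condition": cond, "animal": animal, "n_traces": n}
        for cls in CLASSES:
            row[f"pct_{cls}"] = 100.0 * (df["movement_class"] == cls).sum() / n
        for cls, col in (("anterograde", "speed_antero_um_s"),
                         ("retrograde", "speed_retro_um_s")):
            sub = df.loc[df["movement_class"] == cls, "velocity_um_s"]
            row[col] = float(np.abs(sub).mean()) if len(sub) else np.nan
        rows.append(row)
    per_animal = pd.DataFrame(rows)
    if per_animal.empty:
        warnings.warn("no animals with traces")
        return MovementSummary(per_animal, pd.DataFrame())
    measures = [c for c in per_animal.columns
                if c.startswith("pct_") or c.startswith("speed_")]
    stats = []
    for cond, df in per_animal.groupby("condition"):
        for m in measures:
            vals = df[m].dropna().to_numpy()
            stats.append({
                "condition": cond, "measure": m,
                "mean": float(np.mean(vals)) if len(vals) else np.nan,
                "sem": (float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                        if len(vals) > 1 else np.nan),
                "n_animals": len(vals),
            })
    return MovementSummary(per_animal, pd.DataFrame(stats))


# ----------------------------------------------------------------- co-localization

def _overlap_stats(ta: Trace, tb: Trace, max_dist_um: float):
    pos_b = dict(tb.points)
    dists = [abs(s - pos_b[t]) for t, s in ta.points if t in pos_b]
    if not dists:
        return 0.0, np.inf, 0
    close = [d for d in dists if d <= max_dist_um]
    cov = len(close) / ta.n_frames_observed
    mean_d = float(np.mean(close)) if close else np.inf
    return cov, mean_d, len(close)


def match_traces(traces_a: list, traces_b: list, max_dist_um: float = 0.5,
                 min_overlap_frac: float = 0.5) -> ColocSummary:
    """Mark reference (A) traces co-localized with a partner (B) trace.

    An A trace is co-localized when a B trace from the same kymograph lies
    within ``max_dist_um`` for at least ``min_overlap_frac`` of A's observed
    frames; assignment is one-to-one, greedy by mean distance with longer
    overlap breaking ties.  The summary is stratified by A's movement class.
    """
    cands = []
    for ia, ta in enumerate(traces_a):
        for ib, tb in enumerate(traces_b):
            if ta.source != tb.source:
                continue
            cov, mean_d, n_close = _overlap_stats(ta, tb, max_dist_um)
            if cov >= min_overlap_frac:
                cands.append((mean_d, -n_close, ia, ib))
    cands.sort()
    used_a, used_b, assign = set(), set(), {}
    for _, _, ia, ib in cands:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        assign[ia] = ib

    rows = []
    for cls in CLASSES:
        idx = [i for i, t in enumerate(traces_a) if t.movement_class == cls]
        n_coloc = sum(1 for i in idx if i in assign)
        n_solo = len(idx) - n_coloc
        rows.append({
            "movement_class": cls, "n_coloc": n_coloc, "n_solo": n_solo,
            "n_total": len(idx),
            "frac_coloc": n_coloc / len(idx) if idx else np.nan,
        })
    per_class = pd.DataFrame(rows)
    tot_c = per_class["n_coloc"].sum()
    tot_s = per_class["n_solo"].sum()
    pool = pd.DataFrame({
        "movement_class": list(CLASSES),
        "share_of_coloc_pool": [
            r["n_coloc"] / tot_c if tot_c else np.nan for _, r in
            per_class.iterrows()],
        "share_of_solo_pool": [
            r["n_solo"] / tot_s if tot_s else np.nan for _, r in
            per_class.iterrows()],
    })
    return ColocSummary(per_class, pool, assignments=assign)


# -------------------------------------------------------------- de-duplication

def deduplicate_stationary(traces: list, min_sep_um: float = 0.5) -> list:
    """Drop stationary traces duplicated across adjacent swaths.

    Large immotile objects straddling a swath boundary can be counted once
    per swath; traces of the same class whose mean positions fall within
    ``min_sep_um`` in adjacent swaths are collapsed to one.  Moving traces
    are never collapsed (swath geometry does not duplicate movers any more
    than stationary ones, but only the stationary duplication is flagged by
    the source analysis).
    """
    def swath_idx(src):
        try:
            return int(str(src).rsplit("_", 1)[1])
        except (IndexError, ValueError):
            return None

    kept, dropped = [], set()
    stationary = [(i, t) for i, t in enumerate(traces)
                  if t.movement_class == "stationary"
                  and swath_idx(t.source) is not None]
    for k, (i, t) in enumerate(stationary):
        if i in dropped:
            continue
        si = swath_idx(t.source)
        mi = float(np.mean(t.positions))
        for j, u in stationary[k + 1:]:
            if j in dropped:
                continue
            if abs(swath_idx(u.source) - si) == 1 and \
                    abs(float(np.mean(u.positions)) - mi) <= min_sep_um:
                dropped.add(j)
    return [t for i, t in enumerate(traces) if i not in dropped]
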