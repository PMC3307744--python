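"""Post-processing of egress and pulling trajectories.

Covers the analyses a channel-sampling study reports: per-channel egress
statistics (counts and occurrence ratios over snapshots), smoothed
force-versus-coordinate profiles, gate-dihedral "revolving door" event
detection, distance-criterion contact series, and RMSD convergence with
optimal (Kabsch) superposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geometry import dihedral_angles
from .ramd_engine import RAMDResult, classify_exit_channel_vector
from .smd_engine import WorkSeries
from .synthetic_system import ChannelSpec

__all__ = [
    "ChannelStats",
    "classify_exit_channel",
    "channel_statistics",
    "counts_from_results",
    "gate_dihedral_series",
    "contact_series",
    "force_profile",
    "rmsd_series",
]


@dataclass
class ChannelStats:
    """Per-channel egress statistics over snapshots.

    ``table`` has one row per channel with the per-snapshot counts, the
    row total, the occurrence ratio (fraction of all successful egresses),
    the percentage to one decimal and the rounded-integer percentage.
    """

    table: pd.DataFrame
    grand_total: int

    def ratio(self, channel: str) -> float:
        return float(self.table.loc[channel, "ratio"])

    def percent(self, channel: str, decimals: int = 1) -> float:
        return round(100.0 * self.ratio(channel), decimals)


def classify_exit_channel(result: RAMDResult, channels: list[ChannelSpec],
                          max_angle: float = 30.0) -> str:
    """Label the channel whose axis is angularly closest to the exit vector.

    Returns ``"other"`` when no axis lies within ``max_angle`` degrees;
    ties are broken by channel list order.  Only successful egress results
    can be classified.
    """
    if not result.success:
        raise ValueError("cannot classify a failed (non-egress) trajectory")
    return classify_exit_channel_vector(result.exit_vector, channels, max_angle)


def counts_from_results(results, channels=None) -> pd.DataFrame:
    """Per-channel, per-snapshot success counts from an ensemble."""
    rows = {}
    snaps = sorted({r.snapshot_index for r in results})
    for r in results:
        if not r.success:
            continue
        label = r.channel_label if r.channel_label is not None else "other"
        rows.setdefault(label, {s: 0 for s in snaps})
        rows[label][r.snapshot_index] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    df.columns = [f"snapshot_{c}" for c in df.columns]
    return df


def channel_statistics(counts: pd.DataFrame) -> ChannelStats:
    """Occurrence ratios from a table of per-channel, per-snapshot counts.

    ``counts`` rows are channels, columns snapshots, entries non-negative
    success counts.  ``ratio(channel) = total(channel) / grand_total``;
    percentages are reported to 0.1 and as rounded integers.
    """
    c = counts.to_numpy()
    if not np.issubdtype(c.dtype, np.number) or np.any(c < 0) \
            or np.any(c != np.round(c)):
        raise ValueError("counts must be non-negative integers")
    total = c.sum(axis=1).astype(int)
    grand = int(total.sum())
    if grand == 0:
        raise ValueError("all-zero count table: no successful egresses")
    ratio = total / grand
    table = counts.copy()
    table["total"] = total
    table["ratio"] = ratio
    table["percent_0.1"] = np.round(100.0 * ratio, 1)
    table["percent_int"] = np.round(100.0 * ratio).astype(int)
    return ChannelStats(table=table, grand_total=grand)


def gate_dihedral_series(traj, beads, event_threshold: float = 300.0,
                         event_window: int = 500):
    """Gate dihedral angle per frame and "revolving door" rotation events.

    Returns ``(angles, unwrapped, events)``: the signed dihedral in
    (−180, 180] per frame (NaN where a bonded triple is collinear), the
    unwrapped cumulative angle, and a list of frame indices at which the
    unwrapped angle has changed by at least ``event_threshold`` degrees
    within the last ``event_window`` frames (events do not overlap).
    """
    b = [int(i) for i in beads]
    if len(set(b)) != 4:
        raise ValueError("need 4 distinct bead indices")
    P = traj.positions
    if max(b) >= P.shape[1]:
        raise ValueError("bead index out of range for trajectory")
    ang = dihedral_angles(P[:, b[0]], P[:, b[1]], P[:, b[2]], P[:, b[3]])
    valid = ~np.isnan(ang)
    unwrapped = np.full_like(ang, np.nan)
    if valid.any():
        unwrapped[valid] = np.degrees(np.unwrap(np.radians(ang[valid])))
    events = []
    ref = 0
    u = unwrapped
    for j in range(len(u)):
        if np.isnan(u[j]):
            continue
        while j - ref > event_window or np.isnan(u[ref]):
            ref += 1
        lo = np.nanmin(u[ref:j + 1])
        hi = np.nanmax(u[ref:j + 1])
        if hi - lo >= event_threshold:
            events.append(j)
            ref = j
    return ang, unwrapped, events


def contact_series(traj, pairs, cutoff: float = 3.5, radii=None) -> np.ndarray:
    """Boolean contact series: inter-surface distance ≤ cutoff, per pair.

    ``radii`` are per-bead vdW radii (zeros when omitted); the returned
    array has shape (n_frames, n_pairs).
    """
    P = traj.positions
    n = P.shape[1]
    r = np.zeros(n) if radii is None else np.asarray(radii, dtype=float)
    out = np.empty((P.shape[0], len(pairs)), dtype=bool)
    for c, (i, j) in enumerate(pairs):
        d = np.linalg.norm(P[:, i] - P[:, j], axis=1) - (r[i] + r[j])
        out[:, c] = d <= cutoff
    return out


def force_profile(series: WorkSeries, smoothing_window: int = 1
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Pulling force re-indexed by λ with centered moving-average smoothing.

    ``smoothing_window`` must be odd and ≥ 1 (1 = identity) and no larger
    than the series length.
    """
    w = int(smoothing_window)
    if w < 1 or w % 2 == 0:
        raise ValueError("smoothing_window must be odd and >= 1")
    f = np.asarray(series.force, dtype=float)
    if w > len(f):
        raise ValueError("smoothing window larger than the series")
    if w == 1:
        return series.lam.copy(), f.copy()
    half = w // 2
    padded = np.pad(f, half, mode="edge")
    kernel = np.ones(w) / w
    smooth = np.convolve(padded, kernel, mode="valid")
    return series.lam.copy(), smooth


def rmsd_series(traj, reference_frame: int = 0, fit: bool = True) -> np.ndarray:
    """RMSD to a reference frame, optionally after optimal superposition.

    With ``fit=True`` each frame is superposed on the reference by the
    least-squares rotation+translation (Kabsch) before the RMSD; at least
    3 beads are required.  With ``fit=False`` raw coordinates are compared.
    """
    P = traj.positions
    ref = P[reference_frame]
    n = P.shape[1]
    if fit and n < 3:
        raise ValueError("fitting requires at least 3 beads")
    out = np.empty(P.shape[0])
    refc = ref - ref.mean(axis=0)
    for f in range(P.shape[0]):
        x = P[f]
        if fit:
            xc = x - x.mean(axis=0)
            H = xc.T @ refc
            U, S, Vt = np.linalg.svd(H)
            d = np.sign(np.linalg.det(Vt.T @ U.T))
            D = np.diag([1.0, 1.0, d])
            R = Vt.T @ D @ U.T
            diff = (R @ xc.T).T - refc
        else:
            diff = x - ref
        out[f] = np.sqrt(np.mean(np.sum(diff * diff, axis=1)))
    return out
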