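"""Helical structure of a dsDNA trajectory: base rise, helical width,
base pairs per turn, and groove widths.

The helical axis is approximated locally from short windows of
nucleotides (residues i..i+3 with their Watson-Crick partners): the
rigid screw transformation (Kabsch superposition) that maps each
window onto the window shifted by one base pair has the local helix
axis as its rotation axis, its rotation angle is the local twist and
its axial translation the local rise.  This recovers the construction
parameters of an ideal helix exactly, for any twist and any azimuthal
bead placement.  Three terminal bases on each end are excluded to
avoid end effects.  From the local axis:

* base rise     = axial spacing of consecutive base-pair centres,
* twist         = angle between consecutive base-pair vectors projected
                  perpendicular to the axis; bp/turn = 360/mean twist,
* helical width = twice the mean radial distance of backbone beads from
                  the axis (bead centres, no excluded-volume radius).

Groove widths are cross-strand backbone-backbone bead-centre distances
at a designated base-pair step.  The two groove-defining index offsets
are the local minima (one on each side of the Watson-Crick pairing
offset) of the trajectory-mean distance profile; in this bead-centre
convention the *wider* separation is reported as the minor groove,
matching the printed convention of the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..parameters import DnaParameterSet
from ..topology import Topology
from .hybridization import classify_hybridized


@dataclass
class StructuralReport:
    """Mean +- SD of the local structural observables (frame statistics)."""

    base_rise: float
    base_rise_sd: float
    helical_width: float
    helical_width_sd: float
    bp_per_turn: float
    bp_per_turn_sd: float
    n_frames: int
    n_melted_excluded: int


def _duplex_arrays(topology: Topology):
    c1, c2 = topology.duplex_chains
    res1 = topology.residues[c1]
    res2 = topology.residues[c2][::-1]      # strand-1 pairing order
    b1 = np.array([r["base"] for r in res1])
    b2 = np.array([r["base"] for r in res2])
    p1 = np.array([r["bb"] for r in res1])
    p2 = np.array([r["bb"] for r in res2])
    return b1, b2, p1, p2


def _kabsch(a, b):
    """Rotation R and translation t with b ~ a @ R.T + t (least squares)."""
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cb - r @ ca
    return r, t


def _frame_helix(pos, b1, b2, p1, p2, end_excl, window=4):
    """Local screw-transformation analysis of one frame.

    For each interior base pair i, the window of ``window`` residues
    (both strands, backbone + base beads) starting at i is superposed
    onto the window starting at i+1; the resulting rigid motion is a
    screw about the local helix axis.
    """
    n = len(b1)
    cen = 0.5 * (pos[b1] + pos[b2])
    lo = end_excl
    hi = n - window - end_excl
    rises, twists, radii = [], [], []
    for i in range(lo, hi):
        idx_a = []
        idx_b = []
        for k in range(window):
            idx_a += [b1[i + k], b2[i + k], p1[i + k], p2[i + k]]
            idx_b += [b1[i + 1 + k], b2[i + 1 + k], p1[i + 1 + k],
                      p2[i + 1 + k]]
        r, t = _kabsch(pos[idx_a], pos[idx_b])
        cos_th = np.clip((np.trace(r) - 1.0) / 2.0, -1.0, 1.0)
        theta = np.arccos(cos_th)
        if theta < 1e-8:
            continue                      # degenerate: pure translation
        u = np.array([r[2, 1] - r[1, 2], r[0, 2] - r[2, 0],
                      r[1, 0] - r[0, 1]]) / (2.0 * np.sin(theta))
        if np.dot(t, u) < 0:              # orient along increasing index
            u = -u
        twists.append(float(np.degrees(theta)))
        rises.append(float(np.dot(cen[i + 1] - cen[i], u)))
        # a point on the screw axis: (I - R) x = t - (t.u) u
        rhs = t - np.dot(t, u) * u
        x0, *_ = np.linalg.lstsq(np.eye(3) - r, rhs, rcond=None)
        for pb in (p1[i], p2[i]):
            d = pos[pb] - x0
            radii.append(float(np.linalg.norm(d - np.dot(d, u) * u)))
    return np.mean(rises), np.mean(twists), 2.0 * np.mean(radii)


def helical_parameters(frames, topology: Topology, end_excl: int = 3,
                       params: DnaParameterSet | None = None,
                       exclude_melted: bool = True) -> StructuralReport:
    """Structural report over hybridized frames of a duplex trajectory.

    ``frames``: (F, N, 3) positions.  Melted frames are excluded and
    counted.  Requires a duplex of >= 14 bp (enough interior tetrads).
    """
    topology.require_duplex()
    if topology.n_bp < 14:
        raise ValueError("helical analysis needs a duplex of >= 14 bp")
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    b1, b2, p1, p2 = _duplex_arrays(topology)
    rises, twists, widths = [], [], []
    n_mel = 0
    for pos in frames:
        if exclude_melted and not classify_hybridized(
                pos, topology, params).hybridized:
            n_mel += 1
            continue
        r, t, w = _frame_helix(pos, b1, b2, p1, p2, end_excl)
        rises.append(r)
        twists.append(t)
        widths.append(w)
    if not rises:
        raise ValueError("no hybridized frames to analyse")
    rises, twists, widths = map(np.array, (rises, twists, widths))
    bpt = 360.0 / twists
    return StructuralReport(float(rises.mean()), float(rises.std()),
                            float(widths.mean()), float(widths.std()),
                            float(bpt.mean()), float(bpt.std()),
                            len(rises), n_mel)


def groove_widths(frames, topology: Topology, step_index: int = 19,
                  max_offset: int = 10, end_excl: int = 3):
    """Minor and major groove widths at a base-pair step (1-based).

    Returns ``((minor_mean, minor_sd), (major_mean, major_sd))`` in A,
    bead-centre distances.  The groove offsets are calibrated on the
    trajectory-mean cross-strand profile (see module docstring).
    """
    topology.require_duplex()
    n = topology.n_bp
    i = step_index - 1
    if i < end_excl or i >= n - end_excl:
        raise ValueError(
            f"step {step_index} is closer than {end_excl} bases to a terminus")
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    _, _, p1, p2 = _duplex_arrays(topology)
    ks = [k for k in range(-max_offset, max_offset + 1) if 0 <= i + k < n]
    prof = {k: np.linalg.norm(frames[:, p1[i], :] - frames[:, p2[i + k], :],
                              axis=1) for k in ks}
    mean = {k: prof[k].mean() for k in ks}

    def local_minima(side):
        out = []
        for k in ks:
            if side(k) and (k - 1 in mean) and (k + 1 in mean):
                if mean[k] < mean[k - 1] and mean[k] < mean[k + 1]:
                    out.append(k)
        return out

    lows = local_minima(lambda k: k < 0)
    highs = local_minima(lambda k: k > 0)
    if not lows or not highs:
        raise ValueError("no groove minima found on both sides of the "
                         "pairing offset; duplex too short or distorted")
    k_neg = min(lows, key=lambda k: mean[k])
    k_pos = min(highs, key=lambda k: mean[k])
    g1 = (float(prof[k_neg].mean()), float(prof[k_neg].std()))
    g2 = (float(prof[k_pos].mean()), float(prof[k_pos].std()))
    minor, major = (g1, g2) if g1[0] >= g2[0] else (g2, g1)
    return minor, major
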