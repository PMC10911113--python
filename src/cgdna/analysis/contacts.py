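"""Intermolecular contact maps.

A contact between two bead groups exists in a frame when *any* bead
pair across the groups lies within the cutoff.  The default cutoff is
1.5 x the mean pair vdW diameter (configurable), recorded in the
result's metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ContactMap:
    """Group-by-group contact probabilities in [0, 1]."""

    probability: np.ndarray          # (len(groups_a), len(groups_b))
    labels_a: list
    labels_b: list
    metadata: dict = field(default_factory=dict)


def contact_map(frames, groups_a: list, groups_b: list, *,
                cutoff: float | None = None, sigmas=None,
                factor: float = 1.5, labels_a=None, labels_b=None) -> ContactMap:
    """Contact probability between two lists of bead-index groups.

    Parameters
    ----------
    frames:
        (F, N, 3) positions (a single frame is accepted).
    cutoff:
        Fixed distance cutoff (A); if omitted, the per-pair cutoff is
        ``factor * (sigma_i + sigma_j)/2`` from the per-bead ``sigmas``
        array (default sigma 5.5 A for every bead).
    """
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    if not groups_a or not groups_b:
        raise ValueError("contact groups must be non-empty")
    ga = [np.asarray(g, int) for g in groups_a]
    gb = [np.asarray(g, int) for g in groups_b]
    for g in ga + gb:
        if g.size == 0:
            raise ValueError("contact groups must be non-empty")
    n_beads = frames.shape[1]
    if sigmas is None:
        sigmas = np.full(n_beads, 5.5)
    sigmas = np.asarray(sigmas, float)

    prob = np.zeros((len(ga), len(gb)))
    for ia, a in enumerate(ga):
        for ib, b in enumerate(gb):
            if cutoff is not None:
                cut = np.full((a.size, b.size), float(cutoff))
            else:
                cut = factor * 0.5 * (sigmas[a][:, None] + sigmas[b][None, :])
            hit = 0
            for pos in frames:
                d = np.linalg.norm(pos[a][:, None, :] - pos[b][None, :, :],
                                   axis=-1)
                if np.any(d < cut):
                    hit += 1
            prob[ia, ib] = hit / frames.shape[0]
    la = labels_a if labels_a is not None else list(range(len(ga)))
    lb = labels_b if labels_b is not None else list(range(len(gb)))
    return ContactMap(prob, la, lb,
                      {"cutoff": cutoff, "factor": factor,
                       "n_frames": int(frames.shape[0])})
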