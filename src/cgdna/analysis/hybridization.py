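"""Hybridized/melted classification of a DNA duplex.

A hydrogen bond is counted as formed when two complementary HB sites
(base beads in the 2-bead model, dummy sites in the 3-bead model) on
*opposite* strands are closer than 1.5 sigma_HB for their pair type.  A
strand is hybridized when at least half of its sites are engaged
(engaged >= ceil(n_sites / 2)); the duplex state can be required of
either or both strands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..parameters import DnaParameterSet
from ..topology import Topology, THREE_BEAD, complementary


@dataclass
class HybridizationRecord:
    engaged: tuple          # per-strand counts of engaged HB sites
    n_sites: int
    strand_hybridized: tuple
    hybridized: bool        # duplex-level state


def classify_hybridized(coords, topology: Topology,
                        params: DnaParameterSet | None = None,
                        duplex_rule: str = "both") -> HybridizationRecord:
    """Classify the hybridization state of a duplex configuration.

    Parameters
    ----------
    coords:
        (N, 3) positions or a :class:`~cgdna.geometry.CoordinateSet`.
    duplex_rule:
        ``"both"`` (default; the duplex counts as melted when either
        strand is melted) or ``"either"``.
    """
    params = params or DnaParameterSet()
    topology.require_duplex()
    pos = np.asarray(getattr(coords, "positions", coords), float)
    c1, c2 = topology.duplex_chains
    sites1, sites2 = topology.hb_sites(c1), topology.hb_sites(c2)
    sp1 = [topology.beads[i].species for i in sites1]
    sp2 = [topology.beads[i].species for i in sites2]
    n = len(sites1)

    p1, p2 = pos[sites1], pos[sites2]
    dist = np.linalg.norm(p1[:, None, :] - p2[None, :, :], axis=-1)
    eng1 = np.zeros(n, bool)
    eng2 = np.zeros(len(sites2), bool)
    for a in range(n):
        for b in range(len(sites2)):
            if complementary(sp1[a], sp2[b]):
                sig = params.hb_params(sp1[a], sp2[b])[0]
                if dist[a, b] < 1.5 * sig:
                    eng1[a] = True
                    eng2[b] = True
    thresh = math.ceil(n / 2)
    s1 = int(eng1.sum()) >= thresh
    s2 = int(eng2.sum()) >= math.ceil(len(sites2) / 2)
    hyb = (s1 and s2) if duplex_rule == "both" else (s1 or s2)
    return HybridizationRecord((int(eng1.sum()), int(eng2.sum())), n,
                               (s1, s2), hyb)
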