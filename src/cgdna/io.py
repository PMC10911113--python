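"""Text formats: XYZ trajectories, tabular topologies, LAMMPS-style data
files, and tidy CSV exports of analysis results.

The tabular topology format is self-describing: ``#`` comment header,
a ``[meta]`` section (variant, duplex flag), then ``[beads]``,
``[bonds]`` and ``[angles]`` sections with tab-separated columns.
Coordinates in XYZ files are written with 17 significant digits so a
write/read round trip reproduces energies to machine precision.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .geometry import CoordinateSet
from .topology import Bead, Topology


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def _bead_name(bead: Bead) -> str:
    if bead.kind == "backbone":
        return "P"
    if bead.kind == "base":
        return bead.species
    if bead.kind == "hb":
        return bead.species           # lower-case a/t/c/g
    return "C" + bead.species         # amino acids: CA, CK, ...


def write_xyz(path: str, topology: Topology, frames, box=None,
              comment: str = "") -> None:
    """Write one or more frames as extended XYZ (names encode species)."""
    frames = np.asarray(frames, float)
    if frames.ndim == 2:
        frames = frames[None]
    names = [_bead_name(b) for b in topology.beads]
    with open(path, "w") as fh:
        for f, pos in enumerate(frames):
            fh.write(f"{len(names)}\n")
            binfo = "" if box is None else " box=" + ",".join(
                f"{x:.6g}" for x in np.atleast_1d(box))
            fh.write(f"frame={f}{binfo} {comment}\n")
            for name, (x, y, z) in zip(names, pos):
                fh.write(f"{name} {x:.17g} {y:.17g} {z:.17g}\n")


def read_xyz(path: str) -> tuple[np.ndarray, list]:
    """Read an XYZ trajectory -> ((F, N, 3) array, per-frame comments)."""
    frames, comments = [], []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        n = int(lines[i])
        comments.append(lines[i + 1])
        pos = np.array([[float(v) for v in lines[i + 2 + k].split()[1:4]]
                        for k in range(n)])
        frames.append(pos)
        i += 2 + n
    return np.array(frames), comments


# ---------------------------------------------------------------------------
# tabular topology
# ---------------------------------------------------------------------------

def write_topology(path: str, topology: Topology) -> None:
    """Documented tabular text export of a topology.

    Bead indices are 0-based, 5'->3' within each strand; backbone bead
    i belongs to the same residue as base bead i (and dummy bead i for
    the 3-bead variant).
    """
    with open(path, "w") as fh:
        fh.write("# cgdna topology: 0-based bead indices, 5'->3' per strand\n")
        fh.write("[meta]\n")
        meta = {"variant": topology.variant, "duplex": topology.duplex,
                "duplex_chains": list(topology.duplex_chains)
                if topology.duplex_chains else None,
                "residues": topology.residues}
        fh.write(json.dumps(meta) + "\n")
        fh.write("[beads]\n")
        fh.write("index\tkind\tspecies\tmass\tcharge\tchain\tresindex\n")
        for b in topology.beads:
            fh.write(f"{b.index}\t{b.kind}\t{b.species}\t{b.mass:.17g}\t"
                     f"{b.charge:.17g}\t{b.chain}\t{b.resindex}\n")
        fh.write("[bonds]\n")
        fh.write("i\tj\tclass\n")
        for i, j, c in topology.bonds:
            fh.write(f"{i}\t{j}\t{c}\n")
        fh.write("[angles]\n")
        fh.write("i\tj\tk\tclass\n")
        for i, j, k, c in topology.angles:
            fh.write(f"{i}\t{j}\t{k}\t{c}\n")


def read_topology(path: str) -> Topology:
    """Read a topology written by :func:`write_topology`."""
    top = Topology()
    section = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith("["):
                section = line.strip("[]")
                header_skipped = section == "meta"
                continue
            if section == "meta":
                meta = json.loads(line)
                top.variant = meta["variant"]
                top.duplex = meta["duplex"]
                top.duplex_chains = (tuple(meta["duplex_chains"])
                                     if meta["duplex_chains"] else None)
                top.residues = meta["residues"]
                continue
            if not header_skipped:
                header_skipped = True
                continue
            parts = line.split("\t")
            if section == "beads":
                top.beads.append(Bead(int(parts[0]), parts[1], parts[2],
                                      float(parts[3]), float(parts[4]),
                                      int(parts[5]), int(parts[6])))
            elif section == "bonds":
                top.bonds.append((int(parts[0]), int(parts[1]), parts[2]))
            elif section == "angles":
                top.angles.append((int(parts[0]), int(parts[1]),
                                   int(parts[2]), parts[3]))
    return top


# ---------------------------------------------------------------------------
# LAMMPS-style data export
# ---------------------------------------------------------------------------

def write_lammps_data(path: str, topology: Topology, coords: CoordinateSet
                      ) -> None:
    """Export as a LAMMPS data file (atom_style full) for cross-checks.

    Atom types are numbered per distinct (kind, species); bond/angle
    types per class; the mapping is written as comments.
    """
    species = sorted({(b.kind, b.species) for b in topology.beads})
    stype = {s: i + 1 for i, s in enumerate(species)}
    bclasses = sorted({c for *_, c in topology.bonds})
    aclasses = sorted({c for *_, c in topology.angles})
    btype = {c: i + 1 for i, c in enumerate(bclasses)}
    atype = {c: i + 1 for i, c in enumerate(aclasses)}
    box = coords.box
    masses = {}
    for b in topology.beads:
        masses.setdefault(stype[(b.kind, b.species)], b.mass)
    with open(path, "w") as fh:
        fh.write("# cgdna topology export\n")
        for s, i in stype.items():
            fh.write(f"# atom type {i} = {s[0]}:{s[1]}\n")
        for c, i in btype.items():
            fh.write(f"# bond type {i} = {c}\n")
        for c, i in atype.items():
            fh.write(f"# angle type {i} = {c}\n")
        fh.write(f"\n{topology.n_beads} atoms\n{len(topology.bonds)} bonds\n"
                 f"{len(topology.angles)} angles\n\n")
        fh.write(f"{len(species)} atom types\n{len(bclasses)} bond types\n"
                 f"{len(aclasses)} angle types\n\n")
        fh.write(f"0.0 {box[0]:.6f} xlo xhi\n0.0 {box[1]:.6f} ylo yhi\n"
                 f"0.0 {box[2]:.6f} zlo zhi\n\nMasses\n\n")
        for i in sorted(masses):
            fh.write(f"{i} {masses[i]:.4f}\n")
        fh.write("\nAtoms # full\n\n")
        for b, (x, y, z) in zip(topology.beads, coords.positions):
            fh.write(f"{b.index + 1} {b.chain + 1} "
                     f"{stype[(b.kind, b.species)]} {b.charge:.4f} "
                     f"{x:.8f} {y:.8f} {z:.8f}\n")
        if topology.bonds:
            fh.write("\nBonds\n\n")
            for n, (i, j, c) in enumerate(topology.bonds, 1):
                fh.write(f"{n} {btype[c]} {i + 1} {j + 1}\n")
        if topology.angles:
            fh.write("\nAngles\n\n")
            for n, (i, j, k, c) in enumerate(topology.angles, 1):
                fh.write(f"{n} {atype[c]} {i + 1} {j + 1} {k + 1}\n")


# ---------------------------------------------------------------------------
# compact trajectory store
# ---------------------------------------------------------------------------

class TrajectoryStore:
    """Compact binary store for frames + energies with the metadata
    needed to re-run bit-identically (config hash, seed, code version).

    The payload is a NumPy ``.npz`` archive; metadata rides along in a
    JSON sidecar entry.  This is a runtime artifact format — use the
    XYZ/CSV writers for portable text output.
    """

    def __init__(self, frames, epot, ekin, metadata: dict):
        self.frames = np.asarray(frames)
        self.epot = np.asarray(epot)
        self.ekin = np.asarray(ekin)
        self.metadata = dict(metadata)

    @classmethod
    def from_trajectory(cls, traj, config_hash: str = "",
                        extra: dict | None = None) -> "TrajectoryStore":
        from . import __version__
        meta = {"config_hash": config_hash, "seed": traj.seed,
                "temperature_K": traj.temperature,
                "dt_sample_ps": traj.dt_sample_ps,
                "code_version": __version__}
        meta.update(extra or {})
        return cls(traj.frames, traj.epot, traj.ekin, meta)

    def save(self, path: str) -> None:
        np.savez_compressed(path, frames=self.frames, epot=self.epot,
                            ekin=self.ekin,
                            metadata=np.frombuffer(
                                json.dumps(self.metadata).encode(),
                                dtype=np.uint8))

    @classmethod
    def load(cls, path: str) -> "TrajectoryStore":
        with np.load(path) as z:
            meta = json.loads(z["metadata"].tobytes().decode())
            return cls(z["frames"], z["epot"], z["ekin"], meta)


# ---------------------------------------------------------------------------
# tidy exports
# ---------------------------------------------------------------------------

def melting_to_csv(path: str, curve, cv_curve=None) -> None:
    df = pd.DataFrame({"temperature_K": curve.temperatures,
                       "fraction_melted": curve.fraction_melted})
    if cv_curve is not None:
        df["cv_kcal_mol_K"] = cv_curve.cv
    df.to_csv(path, index=False)


def pmf_to_text(path: str, profile) -> None:
    """Two-column PMF profile (r in A, F in kcal/mol); b in the header."""
    with open(path, "w") as fh:
        fh.write(f"# r_A  F_kcal_mol   (b = {profile.b:.4f} A, "
                 f"T = {profile.temperature:.2f} K)\n")
        for r, f in zip(profile.r, profile.f):
            fh.write(f"{r:.6f} {f:.8f}\n")


def contact_map_to_csv(path: str, cmap) -> None:
    df = pd.DataFrame(cmap.probability, index=cmap.labels_a,
                      columns=cmap.labels_b)
    df.to_csv(path)
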