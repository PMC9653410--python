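"""Trajectory reading, bead selection, midplane centering and leaflet assignment.

Real coarse-grained trajectories (GRO/PDB topology with XTC/TRR/DCD
coordinates) are read through MDAnalysis; synthetic systems round-trip
through a documented HDF5 layout.  Either route emits the same normalized
:class:`~memfluct.frames.MembraneFrame` sequence:

* one headgroup bead per lipid (PO4 for phospholipids and sphingomyelin,
  the hydroxy bead for cholesterol),
* coordinates wrapped into the box, the membrane recentered per frame so the
  mean z of all phosphate beads is zero (bilayer midplane at z = 0),
* leaflet labels assigned by the sign of the headgroup z, kept stable
  across frames unless a bead crosses the midplane by more than 5 A.

HDF5 layout (one file per trajectory)::

    /time            (F,)       float64, us
    /box             (F, 3)     float64, A
    /lipids/xyz      (F, N, 3)  float64, A
    /lipids/type     (F, N)     fixed-width UTF-8 (per frame: planted
                                enrichment reassigns types over time)
    /lipids/leaflet  (F, N)     int8, +1 outer / -1 inner
    /dimers/<id>/beads     (F, M, 3) float64
    /dimers/<id>/protomer  (M,)      int8
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np

from .frames import (
    CHOLESTEROL,
    INNER,
    OUTER,
    DimerRecord,
    MembraneFrame,
    wrap_positions,
)

#: Default MARTINI headgroup bead per lipid type.
DEFAULT_HEADGROUP_BEADS: dict[str, str] = {
    "POPC": "PO4",
    "POPE": "PO4",
    "POPG": "PO4",
    "POPS": "PO4",
    "POPI": "PO4",
    "DPSM": "PO4",
    "CHOL": "ROH",
}

#: z excursion (A) beyond which a headgroup that crossed the midplane is
#: considered to have genuinely flipped leaflets.
FLIP_TOLERANCE = 5.0


@dataclass
class SelectionConfig:
    """Which beads to read and how to normalize the frames."""

    headgroup_beads: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_HEADGROUP_BEADS)
    )
    protein_bead: str = "BB"
    window: tuple[int, int] | None = None   # frame index range [start, stop)
    recenter: bool = True


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def recenter_midplane(frame: MembraneFrame) -> MembraneFrame:
    """Shift z so the mean of all phosphate beads is zero (idempotent).

    Cholesterol is excluded from the midplane definition to match the
    phosphate-centric height analyses; its hydroxy bead is shifted along
    with everything else.
    """
    mask = frame.phosphate_mask()
    if not mask.any():
        raise ValueError("frame has no phosphate-bearing lipids to define a midplane")
    shift = frame.positions[mask, 2].mean()
    new = frame.select(np.ones(frame.n_lipids, bool))
    new.positions[:, 2] -= shift
    new.dimers = [
        DimerRecord(d.dimer_id, d.beads - np.array([0.0, 0.0, shift]), d.protomer.copy())
        for d in frame.dimers
    ]
    return new


def assign_leaflets(
    frame: MembraneFrame, previous: np.ndarray | None = None
) -> MembraneFrame:
    """Label leaflets by the sign of the headgroup z of a midplane-centered frame.

    If ``previous`` labels are given, a lipid keeps its previous label
    unless its headgroup has crossed the midplane by more than
    ``FLIP_TOLERANCE`` (genuine flip); this keeps labels stable against
    thermal excursions near z = 0.
    """
    z = frame.positions[:, 2]
    signs = np.where(z >= 0, OUTER, INNER).astype(np.int8)
    if previous is not None:
        previous = np.asarray(previous, dtype=np.int8)
        crossed = (signs != previous) & (np.abs(z) > FLIP_TOLERANCE)
        signs = np.where(crossed, signs, previous).astype(np.int8)
    new = frame.select(np.ones(frame.n_lipids, bool))
    new.leaflet = signs
    return new


def normalize_frames(
    frames: Sequence[MembraneFrame], recenter: bool = True
) -> list[MembraneFrame]:
    """Recenter and leaflet-label a frame sequence with stable labels."""
    out: list[MembraneFrame] = []
    prev: np.ndarray | None = None
    for f in frames:
        g = recenter_midplane(f) if recenter else f
        g = assign_leaflets(g, previous=prev)
        prev = g.leaflet
        out.append(g)
    return out


# ---------------------------------------------------------------------------
# MDAnalysis route
# ---------------------------------------------------------------------------

def load_trajectory(
    topology: str | Path,
    trajectory: str | Path | None = None,
    selection: SelectionConfig | None = None,
) -> list[MembraneFrame]:
    """Read a trajectory into normalized MembraneFrames.

    ``topology`` may be a GRO/PDB file (with coordinates in XTC/TRR/DCD
    given as ``trajectory``) or the HDF5 layout written by
    :func:`write_frames_hdf5`, in which case ``trajectory`` is ignored.
    """
    topology = Path(topology)
    selection = selection or SelectionConfig()
    if topology.suffix.lower() in {".h5", ".hdf5"}:
        frames = read_frames_hdf5(topology)
        if selection.window is not None:
            start, stop = selection.window
            frames = frames[start:stop]
            if not frames:
                raise ValueError("empty frame window")
        return frames
    return _load_mdanalysis(topology, trajectory, selection)


def _load_mdanalysis(topology, trajectory, selection: SelectionConfig):
    import MDAnalysis as mda

    if trajectory is None:
        u = mda.Universe(str(topology))
    else:
        u = mda.Universe(str(topology), str(trajectory))

    beads = selection.headgroup_beads
    lipid_resnames = set(beads)
    residues = u.residues
    lipid_res = residues[np.isin(residues.resnames, sorted(lipid_resnames))]
    present = set(np.unique(lipid_res.resnames))

    head_atoms = []
    types = []
    unresolved = []
    for res in lipid_res:
        bead_name = beads[res.resname]
        sel = res.atoms[res.atoms.names == bead_name]
        if len(sel) != 1:
            unresolved.append(res.resname)
            continue
        head_atoms.append(sel[0].index)
        types.append(res.resname)
    if unresolved:
        missing = sorted(set(unresolved))
        raise ValueError(
            "could not resolve a unique headgroup bead for lipid types: "
            + ", ".join(missing)
        )
    if not head_atoms:
        raise ValueError(f"no lipids found; topology resnames: {sorted(present)}")
    head_idx = np.array(head_atoms)
    types = np.array(types, dtype="U8")

    # Protein backbone beads grouped by residue (GRO keeps no segment info);
    # one residue per protomer, consecutive protomer residues pair into
    # C2 dimers (protomer A, protomer B).
    prot = u.atoms[u.atoms.names == selection.protein_bead]
    dimer_groups: list[tuple[np.ndarray, np.ndarray]] = []
    if len(prot):
        residx = prot.resindices
        uniq = list(dict.fromkeys(residx))          # preserve file order
        for k in range(0, len(uniq) - 1, 2):
            a = prot[residx == uniq[k]].indices
            b = prot[residx == uniq[k + 1]].indices
            dimer_groups.append((a, b))

    start, stop = selection.window or (0, len(u.trajectory))
    raw: list[MembraneFrame] = []
    for ts in u.trajectory[start:stop]:
        box = ts.dimensions[:3].astype(float)
        pos = u.atoms.positions.astype(float)
        head = pos[head_idx].copy()
        # wrap in-plane only; z stays continuous about the bilayer midplane
        head[:, :2] = wrap_positions(head[:, :2], box[:2])
        dimers = []
        for k, (ia, ib) in enumerate(dimer_groups):
            bead_pos = np.vstack([pos[ia], pos[ib]])
            protomer = np.concatenate([np.zeros(len(ia), int), np.ones(len(ib), int)])
            dimers.append(DimerRecord(f"D{k + 1}", bead_pos, protomer))
        raw.append(
            MembraneFrame(
                time=float(ts.time) / 1e6,      # MDAnalysis ps -> us
                box=box,
                positions=head,
                types=types.copy(),
                leaflet=np.zeros(len(head_idx), np.int8),
                dimers=dimers,
            )
        )
    if not raw:
        raise ValueError("empty frame window")
    return normalize_frames(raw, recenter=selection.recenter)


# ---------------------------------------------------------------------------
# HDF5 layout
# ---------------------------------------------------------------------------

def write_frames_hdf5(frames: Sequence[MembraneFrame], path: str | Path) -> None:
    frames = list(frames)
    if not frames:
        raise ValueError("no frames to write")
    n = frames[0].n_lipids
    for f in frames:
        if f.n_lipids != n:
            raise ValueError("HDF5 layout requires a constant lipid count")
    with h5py.File(path, "w") as h5:
        h5.create_dataset("time", data=np.array([f.time for f in frames]))
        h5.create_dataset("box", data=np.stack([f.box for f in frames]))
        lip = h5.create_group("lipids")
        lip.create_dataset("xyz", data=np.stack([f.positions for f in frames]))
        lip.create_dataset(
            "type",
            data=np.char.encode(
                np.stack([f.types.astype("U8") for f in frames]), "utf-8"
            ),
        )
        lip.create_dataset(
            "leaflet", data=np.stack([f.leaflet for f in frames]).astype(np.int8)
        )
        dim = h5.create_group("dimers")
        for d0 in frames[0].dimers:
            g = dim.create_group(d0.dimer_id)
            g.create_dataset(
                "beads",
                data=np.stack([f.get_dimer(d0.dimer_id).beads for f in frames]),
            )
            g.create_dataset("protomer", data=d0.protomer.astype(np.int8))


def read_frames_hdf5(path: str | Path) -> list[MembraneFrame]:
    with h5py.File(path, "r") as h5:
        time = h5["time"][:]
        box = h5["box"][:]
        xyz = h5["lipids/xyz"][:]
        types = np.char.decode(h5["lipids/type"][:], "utf-8").astype("U8")
        if types.ndim == 1:        # older single-snapshot layout
            types = np.broadcast_to(types, (len(time), len(types)))
        leaflet = h5["lipids/leaflet"][:]
        dimers = []
        if "dimers" in h5:
            for did in h5["dimers"]:
                dimers.append(
                    (
                        did,
                        h5[f"dimers/{did}/beads"][:],
                        h5[f"dimers/{did}/protomer"][:].astype(int),
                    )
                )
    frames = []
    for i in range(len(time)):
        frames.append(
            MembraneFrame(
                time=float(time[i]),
                box=box[i].copy(),
                positions=xyz[i].copy(),
                types=types[i].copy(),
                leaflet=leaflet[i].copy(),
                dimers=[DimerRecord(did, b[i].copy(), p.copy()) for did, b, p in dimers],
            )
        )
    return frames


# ---------------------------------------------------------------------------
# GRO / XTC export (via MDAnalysis)
# ---------------------------------------------------------------------------

def write_gro_xtc(
    frames: Sequence[MembraneFrame],
    gro_path: str | Path,
    xtc_path: str | Path | None = None,
) -> None:
    """Write a GRO snapshot (first frame) and optionally an XTC of all frames.

    Each lipid becomes a single atom named after its headgroup bead, each
    protein bead an atom named ``BB``; protomers are separate segments so
    the reader can rebuild dimers.  XTC stores float32 positions at 0.001-nm
    precision, so the round trip is approximate, unlike the HDF5 layout.
    """
    import MDAnalysis as mda

    frames = list(frames)
    f0 = frames[0]
    n_lip = f0.n_lipids
    dim_sizes = [len(d.beads) for d in f0.dimers]
    n_atoms = n_lip + sum(dim_sizes)
    n_res = n_lip + sum(2 for _ in f0.dimers)

    names = np.where(f0.types == CHOLESTEROL, "ROH", "PO4").astype(object)
    resnames = list(f0.types)
    segidx_per_res = [0] * n_lip
    residx_per_atom = list(range(n_lip))
    seg_names = ["MEMB"]
    res_i = n_lip
    for d in f0.dimers:
        for p in (0, 1):
            seg_names.append(f"{d.dimer_id}{'AB'[p]}")
            resnames.append("PROT")
            segidx_per_res.append(len(seg_names) - 1)
            n_beads = int((d.protomer == p).sum())
            names = np.append(names, ["BB"] * n_beads)
            residx_per_atom.extend([res_i] * n_beads)
            res_i += 1

    u = mda.Universe.empty(
        n_atoms,
        n_residues=n_res,
        n_segments=len(seg_names),
        atom_resindex=np.array(residx_per_atom),
        residue_segindex=np.array(segidx_per_res),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(x) for x in names])
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", np.arange(1, n_res + 1))
    u.add_TopologyAttr("segids", seg_names)

    def frame_coords(f: MembraneFrame) -> np.ndarray:
        parts = [f.positions]
        for d in f.dimers:
            parts.append(d.beads[d.protomer == 0])
            parts.append(d.beads[d.protomer == 1])
        return np.vstack(parts).astype(np.float32)

    u.atoms.positions = frame_coords(f0)
    u.dimensions = [*f0.box, 90.0, 90.0, 90.0]
    u.atoms.write(str(gro_path))

    if xtc_path is not None:
        with mda.Writer(str(xtc_path), n_atoms) as w:
            for f in frames:
                u.atoms.positions = frame_coords(f)
                u.dimensions = [*f.box, 90.0, 90.0, 90.0]
                u.trajectory.ts.time = f.time * 1e6      # us -> ps
                w.write(u.atoms)
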