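"""Core in-memory containers for coarse-grained membrane analysis.

A :class:`MembraneFrame` is one time point of a membrane system reduced to
the beads the analyses actually touch: one headgroup bead per lipid
(phosphodiester PO4 for phospholipids and sphingomyelin, the hydroxy bead
for cholesterol) plus, optionally, the backbone beads of any protein dimers
embedded in the bilayer.  Coordinates are in Angstrom, wrapped into the
half-open box ``[0, L)`` in x and y; z is continuous with the bilayer
midplane conventionally at z = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

#: Leaflet labels: +1 for the outer (extracellular) leaflet, -1 for the inner.
OUTER = 1
INNER = -1

LEAFLET_NAMES = {OUTER: "outer", INNER: "inner"}
LEAFLET_CODES = {v: k for k, v in LEAFLET_NAMES.items()}

#: Lipid types carrying a phosphodiester (PO4) bead.  Cholesterol is located
#: by its hydroxy bead instead and is excluded from phosphate-based analyses.
PHOSPHATE_TYPES = ("POPC", "POPE", "POPG", "POPS", "POPI", "DPSM")
CHOLESTEROL = "CHOL"


@dataclass
class DimerRecord:
    """Backbone beads of one protein dimer.

    ``protomer`` labels each bead row with 0 or 1, identifying the two
    protomers of the C2-symmetric dimer.
    """

    dimer_id: str
    beads: np.ndarray            # (M, 3) float
    protomer: np.ndarray         # (M,) int in {0, 1}

    def centroid_xy(self) -> np.ndarray:
        return self.beads[:, :2].mean(axis=0)

    def protomer_centroids(self) -> tuple[np.ndarray, np.ndarray]:
        a = self.beads[self.protomer == 0].mean(axis=0)
        b = self.beads[self.protomer == 1].mean(axis=0)
        return a, b


@dataclass
class MembraneFrame:
    """One trajectory frame reduced to headgroup beads and protein beads.

    Attributes
    ----------
    time : float
        Time stamp in microseconds.
    box : np.ndarray
        Box lengths (x, y, z) in Angstrom.
    positions : np.ndarray
        ``(n_lipids, 3)`` headgroup coordinates, x/y wrapped into the box.
    types : np.ndarray
        ``(n_lipids,)`` lipid type names (e.g. ``"POPC"``).
    leaflet : np.ndarray
        ``(n_lipids,)`` leaflet labels, ``+1`` outer / ``-1`` inner.
    dimers : list of DimerRecord
    """

    time: float
    box: np.ndarray
    positions: np.ndarray
    types: np.ndarray
    leaflet: np.ndarray
    dimers: list[DimerRecord] = field(default_factory=list)

    @property
    def n_lipids(self) -> int:
        return len(self.positions)

    def leaflet_mask(self, leaflet: int | str) -> np.ndarray:
        code = LEAFLET_CODES.get(leaflet, leaflet)
        return self.leaflet == code

    def phosphate_mask(self) -> np.ndarray:
        return self.types != CHOLESTEROL

    def select(self, mask: np.ndarray) -> "MembraneFrame":
        """Copy of the frame restricted to the lipids selected by ``mask``."""
        return replace(
            self,
            positions=self.positions[mask].copy(),
            types=self.types[mask].copy(),
            leaflet=self.leaflet[mask].copy(),
            dimers=list(self.dimers),
        )

    def get_dimer(self, dimer_id: str) -> DimerRecord | None:
        for d in self.dimers:
            if d.dimer_id == dimer_id:
                return d
        return None


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement for an orthorhombic box."""
    delta = np.asarray(delta, dtype=float)
    return delta - box * np.round(delta / box)


def wrap_positions(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into the half-open box ``[0, L)`` along each axis."""
    wrapped = np.mod(positions, box)
    # mod can return L exactly when a coordinate is a tiny negative float
    return np.where(wrapped >= box, wrapped - box, wrapped)


def nearest_bead_distance(
    points: np.ndarray, beads: np.ndarray, box: np.ndarray
) -> np.ndarray:
    """3-D minimum-image distance from each point to its nearest bead.

    Used for the 7-Angstrom annular-shell lipid counting and for the
    protein-exclusion shells of the fluctuation analysis.  Brute force over
    the (typically small) bead set.
    """
    points = np.asarray(points, dtype=float)
    beads = np.asarray(beads, dtype=float)
    delta = points[:, None, :] - beads[None, :, :]
    delta = minimum_image(delta, box)
    return np.sqrt((delta**2).sum(axis=2)).min(axis=1)


def nearest_dimer_distance(frame: MembraneFrame, dimer_ids=None) -> np.ndarray:
    """Distance from each lipid headgroup to the nearest bead of any dimer.

    Returns ``inf`` everywhere if the frame carries no (matching) dimer.
    """
    dimers = frame.dimers
    if dimer_ids is not None:
        wanted = set(dimer_ids)
        dimers = [d for d in dimers if d.dimer_id in wanted]
    if not dimers:
        return np.full(frame.n_lipids, np.inf)
    beads = np.vstack([d.beads for d in dimers])
    return nearest_bead_distance(frame.positions, beads, frame.box)


def select_window(
    frames: Sequence[MembraneFrame], window: tuple[float, float] | None
) -> list[MembraneFrame]:
    """Frames whose time stamp lies in ``[t0, t1]`` (microseconds)."""
    if window is None:
        return list(frames)
    t0, t1 = window
    out = [f for f in frames if t0 <= f.time <= t1]
    if not out:
        raise ValueError(f"no frames in time window [{t0}, {t1}] us")
    return out


def lipid_type_counts(frames: Iterable[MembraneFrame]) -> dict[str, float]:
    """Mean per-frame count of each lipid type."""
    totals: dict[str, float] = {}
    n = 0
    for f in frames:
        n += 1
        types, counts = np.unique(f.types, return_counts=True)
        for t, c in zip(types, counts):
            totals[str(t)] = totals.get(str(t), 0.0) + float(c)
    return {t: c / n for t, c in totals.items()}
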