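"""Leaflet height maps, radial deformation envelopes and bilayer diagnostics.

The central object is the 2-D leaflet height map: headgroup z positions
(midplane at z = 0) accumulated on an (x, y) grid of 2 x 2 A bins and
averaged over an analysis window, which visualizes the elevation/depression
pattern a membrane protein imprints on each leaflet.  The radial envelope
tracks the per-frame maximum and minimum headgroup height in concentric
rings around a protein center, time-averaged, and quantifies how far the
deformation propagates.  Diagnostics (thickness map, area series,
peak-normalized z mass profiles) monitor overall membrane health.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .frames import (
    CHOLESTEROL,
    INNER,
    LEAFLET_CODES,
    LEAFLET_NAMES,
    OUTER,
    MembraneFrame,
    minimum_image,
    select_window,
)

#: Footprint mask: bins whose center is within this distance (A) of a
#: protein bead's xy projection are flagged as protein-occupied.
FOOTPRINT_PAD = 2.0


def _bin_edges(length: float, bin_size: float) -> np.ndarray:
    """Half-open bins of width ``bin_size``; the last bin may be short."""
    edges = np.arange(0.0, length, bin_size)
    if edges[-1] < length:
        edges = np.append(edges, length)
    return edges


@dataclass
class HeightMap:
    leaflet: int
    bin_size: float
    x_edges: np.ndarray
    y_edges: np.ndarray
    mean_z: np.ndarray        # (nx, ny); NaN where no sample ever landed
    counts: np.ndarray        # (nx, ny) accumulated samples
    footprint: np.ndarray     # (nx, ny) bool, protein-occupied bins
    window: tuple[float, float] | None = None

    @property
    def leaflet_name(self) -> str:
        return LEAFLET_NAMES[self.leaflet]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: x, y, leaflet, mean_z, count, footprint."""
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        xx, yy = np.meshgrid(xc, yc, indexing="ij")
        return pd.DataFrame(
            {
                "x": xx.ravel(),
                "y": yy.ravel(),
                "leaflet": self.leaflet_name,
                "mean_z": self.mean_z.ravel(),
                "count": self.counts.ravel().astype(int),
                "footprint": self.footprint.ravel(),
            }
        )


@dataclass
class RadialEnvelope:
    radii: np.ndarray          # ring centers, A
    mean_max: np.ndarray       # time-averaged per-frame max z; NaN if absent
    mean_min: np.ndarray
    frames_counted: np.ndarray
    ring_width: float
    leaflet: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "radius": self.radii,
                "leaflet": LEAFLET_NAMES[self.leaflet],
                "mean_max_z": self.mean_max,
                "mean_min_z": self.mean_min,
                "frames": self.frames_counted.astype(int),
            }
        )


@dataclass
class MembraneDiagnostics:
    thickness: np.ndarray               # (nx, ny); NaN where either leaflet empty
    x_edges: np.ndarray
    y_edges: np.ndarray
    area_series: pd.DataFrame           # time, area
    mass_profiles: pd.DataFrame         # z, species, density (peak-normalized)


def compute_height_map(
    frames: Sequence[MembraneFrame],
    leaflet: int | str,
    bin_size: float = 2.0,
    window: tuple[float, float] | None = None,
) -> HeightMap:
    """Time-averaged headgroup height per 2-D bin for one leaflet.

    Bins never visited by a lipid are NaN (missing), not zero — a protein
    footprint must not alias as height 0.  Protein-occupied bins are
    additionally reported in the ``footprint`` mask, built from beads whose
    z lies on the leaflet's side of the midplane.
    """
    frames = select_window(frames, window)
    code = LEAFLET_CODES.get(leaflet, leaflet)
    box = frames[0].box
    xe = _bin_edges(box[0], bin_size)
    ye = _bin_edges(box[1], bin_size)
    zsum = np.zeros((len(xe) - 1, len(ye) - 1))
    count = np.zeros_like(zsum)
    any_lipid = False
    prot_xy: list[np.ndarray] = []
    for f in frames:
        m = f.leaflet_mask(code)
        if m.any():
            any_lipid = True
            p = f.positions[m]
            h, _, _ = np.histogram2d(p[:, 0], p[:, 1], bins=(xe, ye), weights=p[:, 2])
            c, _, _ = np.histogram2d(p[:, 0], p[:, 1], bins=(xe, ye))
            zsum += h
            count += c
        for d in f.dimers:
            side = d.beads[:, 2] > 0 if code == OUTER else d.beads[:, 2] < 0
            if side.any():
                prot_xy.append(d.beads[side, :2])
    if not any_lipid:
        raise ValueError(f"leaflet {LEAFLET_NAMES[code]} is empty in every frame")
    with np.errstate(invalid="ignore"):
        mean_z = np.where(count > 0, zsum / np.maximum(count, 1), np.nan)
    footprint = _footprint_mask(xe, ye, prot_xy, box)
    return HeightMap(code, bin_size, xe, ye, mean_z, count, footprint, window)


def _footprint_mask(xe, ye, bead_xy: list[np.ndarray], box) -> np.ndarray:
    mask = np.zeros((len(xe) - 1, len(ye) - 1), bool)
    if not bead_xy:
        return mask
    beads = np.unique(np.vstack(bead_xy), axis=0)
    xc = 0.5 * (xe[:-1] + xe[1:])
    yc = 0.5 * (ye[:-1] + ye[1:])
    xx, yy = np.meshgrid(xc, yc, indexing="ij")
    centers = np.column_stack([xx.ravel(), yy.ravel()])
    d = minimum_image(centers[:, None, :] - beads[None, :, :], box[:2])
    near = (np.hypot(d[..., 0], d[..., 1]) <= FOOTPRINT_PAD).any(axis=1)
    return near.reshape(mask.shape)


def compute_radial_envelope(
    frames: Sequence[MembraneFrame],
    dimer_id: str,
    leaflet: int | str,
    ring_width: float = 5.0,
    max_radius: float | None = None,
    window: tuple[float, float] | None = None,
) -> RadialEnvelope:
    """Time average of the per-frame max and min headgroup z per radial ring.

    The per-frame extremes are recorded first and then averaged over
    frames (not pooled), so the envelope reflects the typical instantaneous
    range.  Rings that contain no lipid in a frame simply do not contribute
    to that ring's average; rings never populated are NaN — e.g. the inner
    rings of a leaflet whose lipids are excluded by the protein footprint.
    """
    frames = select_window(frames, window)
    code = LEAFLET_CODES.get(leaflet, leaflet)
    box = frames[0].box
    half = min(box[0], box[1]) / 2.0
    if max_radius is None:
        max_radius = half
    elif max_radius > half:
        warnings.warn(
            f"max_radius {max_radius} beyond half box width; truncated to {half}",
            stacklevel=2,
        )
        max_radius = half
    edges = np.arange(0.0, max_radius + ring_width, ring_width)
    n_rings = len(edges) - 1
    sum_max = np.zeros(n_rings)
    sum_min = np.zeros(n_rings)
    n_frames = np.zeros(n_rings)
    for f in frames:
        d = f.get_dimer(dimer_id)
        if d is None:
            raise ValueError(f"dimer {dimer_id!r} not present in frame at t={f.time}")
        center = d.centroid_xy()
        m = f.leaflet_mask(code)
        p = f.positions[m]
        delta = minimum_image(p[:, :2] - center, box[:2])
        r = np.hypot(delta[:, 0], delta[:, 1])
        ring = np.floor(r / ring_width).astype(int)
        ok = (ring >= 0) & (ring < n_rings)
        for k in np.unique(ring[ok]):
            z = p[ok & (ring == k), 2]
            sum_max[k] += z.max()
            sum_min[k] += z.min()
            n_frames[k] += 1
    with np.errstate(invalid="ignore"):
        mean_max = np.where(n_frames > 0, sum_max / np.maximum(n_frames, 1), np.nan)
        mean_min = np.where(n_frames > 0, sum_min / np.maximum(n_frames, 1), np.nan)
    radii = 0.5 * (edges[:-1] + edges[1:])
    return RadialEnvelope(radii, mean_max, mean_min, n_frames, ring_width, code)


def compute_diagnostics(
    frames: Sequence[MembraneFrame],
    bin_size: float = 2.0,
    z_bin: float = 1.0,
    window: tuple[float, float] | None = None,
) -> MembraneDiagnostics:
    """Thickness map, membrane area series and z mass profiles.

    Thickness is the outer-leaflet height map minus the inner-leaflet one,
    bin by bin, defined only where both leaflets have samples.  The area is
    simply box_x * box_y per frame.  Mass profiles histogram the
    phosphodiester and hydroxy headgroup beads along z and are scaled so
    each profile's maximum is one.
    """
    frames = select_window(frames, window)
    outer = compute_height_map(frames, OUTER, bin_size)
    inner = compute_height_map(frames, INNER, bin_size)
    thickness = outer.mean_z - inner.mean_z

    area = pd.DataFrame(
        {
            "time": [f.time for f in frames],
            "area": [float(f.box[0] * f.box[1]) for f in frames],
        }
    )

    z_all = np.concatenate([f.positions[:, 2] for f in frames])
    chol = np.concatenate([f.types == CHOLESTEROL for f in frames])
    zmax = np.abs(z_all).max() + z_bin
    edges = np.arange(-zmax, zmax + z_bin, z_bin)
    centers = 0.5 * (edges[:-1] + edges[1:])
    rows = []
    for label, sel in (("phosphate", ~chol), ("hydroxy", chol)):
        hist, _ = np.histogram(z_all[sel], bins=edges)
        peak = hist.max() if hist.max() > 0 else 1
        rows.append(
            pd.DataFrame(
                {"z": centers, "species": label, "density": hist / peak}
            )
        )
    profiles = pd.concat(rows, ignore_index=True)
    return MembraneDiagnostics(thickness, outer.x_edges, outer.y_edges, area, profiles)
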