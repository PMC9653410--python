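"""Dimer orientation angles, Boltzmann-inverted landscapes and minima.

The orientation of a C2-symmetric dimer is the angle of the vector from
protomer-A centroid to protomer-B centroid, projected on the membrane
plane, measured counterclockwise from +x (viewed from +z) and mapped to
[0, 360).  Because the dimer is two-fold symmetric, theta and theta + 180
are physically equivalent; the folded angle theta mod 180 carries that
label and both are first-class outputs.

The free-energy landscape over (theta1, theta2) is the Boltzmann inversion
G = -kBT ln(P / P_max) of the periodic occupancy histogram, so min G = 0 on
visited bins and unvisited bins stay masked.  Minima are detected with a
persistence criterion on the periodic grid: a basin counts as a distinct
minimum only if the saddle that merges it into a deeper basin lies at
least ``depth_threshold`` kBT above its bottom, which makes the number of
reported minima reproducible rather than smoothing-dependent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .frames import MembraneFrame


@dataclass
class OrientationSeries:
    times: np.ndarray                       # us
    theta: dict[str, np.ndarray]            # dimer id -> degrees in [0, 360)

    @property
    def dimer_ids(self) -> list[str]:
        return list(self.theta)

    def folded(self, dimer_id: str) -> np.ndarray:
        """C2-equivalent angle label in [0, 180)."""
        return np.mod(self.theta[dimer_id], 180.0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for did, th in self.theta.items():
            rows.append(
                pd.DataFrame(
                    {
                        "time": self.times,
                        "dimer": did,
                        "theta": th,
                        "theta_folded": np.mod(th, 180.0),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass
class FreeEnergyLandscape:
    bin_width: float
    centers: np.ndarray            # (n,) degrees, shared by both axes
    counts: np.ndarray             # (n, n)
    probability: np.ndarray        # (n, n), sums to 1
    free_energy: np.ndarray        # (n, n) kBT, min 0; NaN where unvisited
    temperature: float = 310.0
    smoothing_deg: float = 0.0
    minima: list[dict] = field(default_factory=list)

    @property
    def mask(self) -> np.ndarray:
        return ~np.isnan(self.free_energy)

    def to_frame(self) -> pd.DataFrame:
        t1, t2 = np.meshgrid(self.centers, self.centers, indexing="ij")
        return pd.DataFrame(
            {
                "theta1": t1.ravel(),
                "theta2": t2.ravel(),
                "count": self.counts.ravel().astype(int),
                "free_energy": self.free_energy.ravel(),
            }
        )


# ---------------------------------------------------------------------------
# Angle operator
# ---------------------------------------------------------------------------

def compute_orientation(frame: MembraneFrame, dimer_id: str) -> tuple[float, float]:
    """Orientation angle of one dimer: ``(theta, theta mod 180)`` in degrees.

    Exactly equivariant: rigidly rotating all beads about z by phi shifts
    theta by phi (mod 360).
    """
    dimer = frame.get_dimer(dimer_id)
    if dimer is None:
        raise ValueError(f"dimer {dimer_id!r} not present in frame")
    a, b = dimer.protomer_centroids()
    d = b[:2] - a[:2]
    if np.hypot(*d) < 1e-9:
        raise ValueError(f"protomer centroids of {dimer_id!r} coincide in xy")
    theta = float(np.degrees(np.arctan2(d[1], d[0]))) % 360.0
    return theta, theta % 180.0


def orientation_series(
    frames: Sequence[MembraneFrame], dimer_ids: Sequence[str] | None = None
) -> OrientationSeries:
    frames = list(frames)
    if dimer_ids is None:
        dimer_ids = [d.dimer_id for d in frames[0].dimers]
    times = np.array([f.time for f in frames])
    theta = {
        did: np.array([compute_orientation(f, did)[0] for f in frames])
        for did in dimer_ids
    }
    return OrientationSeries(times, theta)


def series_from_angles(
    theta1: np.ndarray,
    theta2: np.ndarray,
    times: np.ndarray | None = None,
    ids: tuple[str, str] = ("D1", "D2"),
) -> OrientationSeries:
    """Wrap raw angle arrays (e.g. from the rotating-dimer sampler)."""
    theta1 = np.mod(np.asarray(theta1, dtype=float), 360.0)
    theta2 = np.mod(np.asarray(theta2, dtype=float), 360.0)
    if times is None:
        times = np.arange(len(theta1), dtype=float)
    return OrientationSeries(np.asarray(times, dtype=float),
                             {ids[0]: theta1, ids[1]: theta2})


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

def build_landscape(
    series: OrientationSeries,
    bin_width: float = 5.0,
    window: tuple[float, float] | None = None,
    temperature: float = 310.0,
    smoothing_deg: float = 0.0,
    dimer_pair: tuple[str, str] | None = None,
) -> FreeEnergyLandscape:
    """Boltzmann inversion of the periodic (theta1, theta2) histogram.

    ``bin_width`` must divide 360.  Optional periodic Gaussian smoothing
    (width in degrees) is applied to the probability before inversion and
    recorded in the result; it is off by default so minima counts stay
    reproducible.
    """
    if abs(360.0 / bin_width - round(360.0 / bin_width)) > 1e-9:
        raise ValueError("bin_width must divide 360 degrees")
    ids = list(dimer_pair) if dimer_pair else series.dimer_ids[:2]
    if len(ids) < 2:
        raise ValueError("landscape needs two dimers")
    t1, t2 = series.theta[ids[0]], series.theta[ids[1]]
    if window is not None:
        sel = (series.times >= window[0]) & (series.times <= window[1])
        if not sel.any():
            raise ValueError("empty time window")
        t1, t2 = t1[sel], t2[sel]
    n = int(round(360.0 / bin_width))
    edges = np.linspace(0.0, 360.0, n + 1)
    counts, _, _ = np.histogram2d(np.mod(t1, 360.0), np.mod(t2, 360.0), bins=(edges, edges))
    if (counts > 0).sum() <= 1:
        warnings.warn("all samples fall in one bin; landscape is degenerate",
                      stacklevel=2)
    prob = counts / counts.sum()
    if smoothing_deg > 0:
        prob = gaussian_filter(prob, sigma=smoothing_deg / bin_width, mode="wrap")
        prob /= prob.sum()
    with np.errstate(divide="ignore"):
        g = -np.log(prob / prob.max())
    g[prob <= 0] = np.nan
    centers = 0.5 * (edges[:-1] + edges[1:])
    return FreeEnergyLandscape(
        bin_width=bin_width,
        centers=centers,
        counts=counts,
        probability=prob,
        free_energy=g,
        temperature=temperature,
        smoothing_deg=smoothing_deg,
    )


def detect_minima(
    landscape: FreeEnergyLandscape, depth_threshold: float = 1.0
) -> list[dict]:
    """Persistent local minima of the periodic, masked free-energy grid.

    Cells are processed in ascending free energy with a union-find over the
    8-connected periodic neighborhood.  A new component born at a cell is a
    candidate minimum; when two components meet, the shallower one dies at
    the meeting level and its persistence is (death - birth).  Minima whose
    persistence reaches ``depth_threshold`` (kBT) are returned, deepest
    first, as dicts with theta1, theta2, free_energy, persistence.
    Unvisited bins are impassable, and minima closer than one bin merge
    automatically.
    """
    g = landscape.free_energy
    n = g.shape[0]
    defined = landscape.mask
    if defined.sum() < 1:
        return []
    flat = np.flatnonzero(defined.ravel())
    order = flat[np.argsort(g.ravel()[flat], kind="stable")]

    parent = {}
    birth = {}
    birth_cell = {}
    persistence = {}

    def find(r):
        while parent[r] != r:
            parent[r] = parent[parent[r]]
            r = parent[r]
        return r

    processed = np.zeros(n * n, bool)
    gv = g.ravel()
    for cell in order:
        i, j = divmod(cell, n)
        neigh_roots = set()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                nb = ((i + di) % n) * n + (j + dj) % n
                if processed[nb]:
                    neigh_roots.add(find(nb))
        if not neigh_roots:
            parent[cell] = cell
            birth[cell] = gv[cell]
            birth_cell[cell] = cell
        else:
            roots = sorted(neigh_roots, key=lambda r: birth[r])
            survivor = roots[0]
            for r in roots[1:]:
                persistence[r] = gv[cell] - birth[r]
                parent[r] = survivor
            parent[cell] = survivor
        processed[cell] = True

    # components never merged persist to the top of the landscape; the global
    # basin's depth is likewise top - bottom, so a threshold above the deepest
    # basin reports no minima at all
    top = np.nanmax(gv[flat])
    for r in list(parent):
        if parent[r] == r and r not in persistence:
            persistence[r] = top - birth[r]

    minima = []
    for r, pers in persistence.items():
        if r in birth and pers >= depth_threshold:
            ci, cj = divmod(birth_cell[r], n)
            minima.append(
                {
                    "theta1": float(landscape.centers[ci]),
                    "theta2": float(landscape.centers[cj]),
                    "free_energy": float(birth[r]),
                    "persistence": float(pers),
                }
            )
    minima.sort(key=lambda m: m["free_energy"])
    landscape.minima = minima
    return minima


# ---------------------------------------------------------------------------
# 1-D histogram
# ---------------------------------------------------------------------------

def orientation_histogram(
    series: OrientationSeries,
    dimer_id: str | None = None,
    fold: bool = False,
    bin_width: float = 5.0,
):
    """Periodic 1-D histogram of theta (or the folded angle).

    Returns ``(counts, centers, mode_deg)`` where ``mode_deg`` is the
    center of the most populated bin.
    """
    if dimer_id is None:
        dimer_id = series.dimer_ids[0]
    period = 180.0 if fold else 360.0
    th = series.folded(dimer_id) if fold else series.theta[dimer_id]
    if len(th) == 0:
        raise ValueError("empty orientation series")
    n = int(round(period / bin_width))
    edges = np.linspace(0.0, period, n + 1)
    counts, _ = np.histogram(np.mod(th, period), bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts, centers, float(centers[np.argmax(counts)])
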