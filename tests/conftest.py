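"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from memfluct.frames import INNER, OUTER, DimerRecord, MembraneFrame


def make_flat_frame(
    n_side=16,
    box=(128.0, 128.0, 120.0),
    offset=20.0,
    types=None,
    time=0.0,
    dimers=(),
):
    """Perfectly flat bilayer on a regular lattice, both leaflets."""
    box = np.asarray(box, dtype=float)
    dx, dy = box[0] / n_side, box[1] / n_side
    ix, iy = np.meshgrid(np.arange(n_side), np.arange(n_side), indexing="ij")
    xy = np.column_stack([(ix.ravel() + 0.5) * dx, (iy.ravel() + 0.5) * dy])
    n = len(xy)
    pos = np.vstack(
        [
            np.column_stack([xy, np.full(n, offset)]),
            np.column_stack([xy, np.full(n, -offset)]),
        ]
    )
    if types is None:
        types = np.array(["POPC"] * (2 * n), dtype="U8")
    leaflet = np.concatenate([np.full(n, OUTER), np.full(n, INNER)]).astype(np.int8)
    return MembraneFrame(
        time=time,
        box=box.copy(),
        positions=pos,
        types=np.asarray(types, dtype="U8"),
        leaflet=leaflet,
        dimers=list(dimers),
    )


def single_bead_dimer(center, box_z_span=20.0, dimer_id="D1"):
    """Minimal dimer: two one-bead protomers 10 A apart along x at z=0."""
    cx, cy = center
    beads = np.array(
        [[cx - 5.0, cy, 0.0], [cx + 5.0, cy, 0.0]]
    )
    return DimerRecord(dimer_id, beads, np.array([0, 1]))


def brute_force_contacts(frame, dimer_id, cutoff):
    """Independent all-pairs contact count with explicit minimum-image loops."""
    d = frame.get_dimer(dimer_id)
    counts = {}
    for i in range(frame.n_lipids):
        best = np.inf
        for b in d.beads:
            delta = frame.positions[i] - b
            for ax in range(3):
                L = frame.box[ax]
                delta[ax] -= L * round(delta[ax] / L)
            best = min(best, float(np.sqrt((delta**2).sum())))
        if best <= cutoff:
            key = (str(frame.types[i]), int(frame.leaflet[i]))
            counts[key] = counts.get(key, 0) + 1
    return counts


def brute_force_dft_power(fields, area):
    """O(N^4) per-mode intensity oracle: A * |sum h e^{-i q.r} / N|^2."""
    n_frames, nx, ny = fields.shape
    power = np.zeros((nx, ny))
    jx = np.arange(nx)
    jy = np.arange(ny)
    for kx in range(nx):
        for ky in range(ny):
            ph = np.exp(
                -2j * np.pi * (kx * jx[:, None] / nx + ky * jy[None, :] / ny)
            )
            coef = np.tensordot(fields, ph, axes=([1, 2], [0, 1])) / (nx * ny)
            power[kx, ky] = area * np.mean(np.abs(coef) ** 2)
    return power


def boltzmann_oracle(potential, bin_width, subsamples=6):
    """Numeric Boltzmann integral of the angular potential per landscape bin."""
    n = int(round(360.0 / bin_width))
    off = (np.arange(subsamples) + 0.5) / subsamples * bin_width
    prob = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            t1, t2 = np.meshgrid(i * bin_width + off, j * bin_width + off, indexing="ij")
            prob[i, j] = np.exp(-potential.value(t1, t2)).mean()
    prob /= prob.sum()
    return -np.log(prob / prob.max())


@pytest.fixture
def flat_frames():
    return [make_flat_frame(time=0.01 * i) for i in range(5)]
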