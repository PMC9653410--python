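"""Synthetic coarse-grained membrane generator with known ground truth.

Every downstream stage of the package (height maps, depletion-enrichment
indices, fluctuation-spectrum bending-modulus fits, orientation landscapes)
can be verified against this module because the generator *plants* the
quantity the analysis is supposed to recover:

* thermal undulations drawn mode-by-mode from the Helfrich-Canham
  equipartition spectrum ``<|h(q)|^2> = kBT / (A (K q^4 + sigma q^2))``,
  so the bending modulus K is known exactly;
* C2-symmetric elevation/depression fields around protein footprints
  (a parametric stand-in for the deformation pattern a membrane protein
  dimer imprints on the surrounding lipids — the real pattern is not
  parameterized anywhere, so this template is an explicit invention);
* controlled local enrichment of chosen lipid types around a footprint,
  planted so the expected depletion-enrichment index equals a target;
* rotating-dimer angle dynamics sampled by Metropolis Monte Carlo from a
  prescribed periodic angular potential.

Frames are statistically independent equilibrium draws, not time-correlated
dynamics: equilibrium spectrum and occupancy estimation does not need
dynamics, and independence sharpens convergence of every estimator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .frames import (
    CHOLESTEROL,
    INNER,
    OUTER,
    DimerRecord,
    MembraneFrame,
    minimum_image,
    nearest_bead_distance,
    wrap_positions,
)

#: Study membrane composition (molar fractions): POPC:POPE:POPG:POPS:POPI:
#: DPSM:CHOL = 27:13:4:17:10:12:17, emulating the HEK-cell plasma membrane.
DEFAULT_COMPOSITION: dict[str, float] = {
    "POPC": 0.27,
    "POPE": 0.13,
    "POPG": 0.04,
    "POPS": 0.17,
    "POPI": 0.10,
    "DPSM": 0.12,
    "CHOL": 0.17,
}


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Parameters of an undulating synthetic bilayer.

    ``bending_modulus`` is in kBT units and ``surface_tension`` in kBT/A^2,
    so the per-mode variance ``kBT / (A (K q^4 + sigma q^2))`` is evaluated
    with kBT = 1 and carries units of A^2 directly.
    """

    box_x: float = 256.0
    box_y: float = 256.0
    lipids_per_leaflet: int = 1024
    composition: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION)
    )
    bending_modulus: float = 20.0      # K, kBT
    surface_tension: float = 0.0       # sigma, kBT / A^2
    temperature: float = 310.0         # K (metadata; spectrum is in kBT units)
    n_frames: int = 100
    seed: int = 0
    leaflet_offset: float = 20.0       # half-thickness, A
    box_z: float = 120.0
    max_mode: int | None = None        # largest Fourier index per axis; auto if None
    frame_interval: float = 0.01       # time stamp spacing, us

    def __post_init__(self) -> None:
        if self.box_x <= 0 or self.box_y <= 0:
            raise ValueError("box lengths must be positive")
        if self.bending_modulus <= 0:
            raise ValueError("bending modulus K must be > 0")
        if self.surface_tension < 0:
            raise ValueError("surface tension must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.lipids_per_leaflet < 4:
            raise ValueError("need at least 4 lipids per leaflet")
        total = float(sum(self.composition.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"composition fractions must sum to 1 (got {total!r})"
            )

    @property
    def area(self) -> float:
        return self.box_x * self.box_y

    def lattice_shape(self) -> tuple[int, int]:
        """Near-square lattice (nx, ny) holding ``lipids_per_leaflet`` sites."""
        aspect = self.box_x / self.box_y
        nx = max(2, int(round(math.sqrt(self.lipids_per_leaflet * aspect))))
        ny = max(2, int(math.ceil(self.lipids_per_leaflet / nx)))
        return nx, ny


@dataclass
class DeformationTemplate:
    """Parametric C2-symmetric elevation/depression pattern.

    The field added to the outer leaflet around a footprint at polar
    coordinates (r, phi) relative to the footprint center is::

        A * cos(m * (phi - theta)) * exp(-(r - r0)^2 / (2 w^2))
          * exp(-max(0, r - r0) / decay_length)

    with ``m = angular_order`` (2 for a two-fold symmetric dimer).  The
    inner leaflet receives the same field with opposite sign.  Negative
    amplitude means the depression lobe leads.
    """

    amplitude: float = 5.0         # A_def, Angstrom
    angular_order: int = 2
    radial_center: float = 25.0    # r0, Angstrom
    radial_width: float = 10.0     # w, Angstrom
    decay_length: float = 30.0     # Angstrom

    def __post_init__(self) -> None:
        if self.angular_order < 2 or self.angular_order % 2:
            raise ValueError("angular_order must be even and >= 2")
        if self.radial_width <= 0 or self.decay_length <= 0:
            raise ValueError("radial_width and decay_length must be positive")


@dataclass
class FootprintSpec:
    """Placement of a (placeholder) protein dimer in the membrane plane."""

    center_xy: tuple[float, float]
    orientation: float = 0.0           # theta, degrees in [0, 360)
    footprint_radius: float = 25.0     # A; lipids inside are excluded
    enrichment: Mapping[str, float] = field(default_factory=dict)
    dimer_id: str = "D1"
    protomer_separation: float | None = None   # default: footprint_radius

    def __post_init__(self) -> None:
        if self.footprint_radius <= 0:
            raise ValueError("footprint_radius must be > 0")
        self.orientation = float(self.orientation) % 360.0
        for lipid, idx in self.enrichment.items():
            if not np.isfinite(idx) or idx < 0:
                raise ValueError(f"enrichment target for {lipid} must be finite and >= 0")


@dataclass
class AngularPotential:
    """Periodic potential U(theta1, theta2) in kBT on a square grid.

    ``energies[i, j]`` is the energy at grid centers
    ``theta1 = i * 360/n``, ``theta2 = j * 360/n``; values between centers
    are obtained by periodic bilinear interpolation.
    """

    energies: np.ndarray            # (n, n) kBT
    step_deg: float = 20.0          # Metropolis proposal width

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.ndim != 2 or self.energies.shape[0] != self.energies.shape[1]:
            raise ValueError("energies must be a square 2-D grid")
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("energies must be finite everywhere")

    @property
    def n_grid(self) -> int:
        return self.energies.shape[0]

    def value(self, theta1, theta2):
        """Bilinear periodic interpolation; accepts scalars or arrays."""
        n = self.n_grid
        x = np.asarray(theta1, dtype=float) / 360.0 * n
        y = np.asarray(theta2, dtype=float) / 360.0 * n
        i0 = np.floor(x).astype(int)
        j0 = np.floor(y).astype(int)
        fx = x - i0
        fy = y - j0
        i0 %= n
        j0 %= n
        i1 = (i0 + 1) % n
        j1 = (j0 + 1) % n
        e = self.energies
        return (
            e[i0, j0] * (1 - fx) * (1 - fy)
            + e[i1, j0] * fx * (1 - fy)
            + e[i0, j1] * (1 - fx) * fy
            + e[i1, j1] * fx * fy
        )

    @classmethod
    def flat(cls, n: int = 36, **kw) -> "AngularPotential":
        return cls(np.zeros((n, n)), **kw)

    @classmethod
    def from_wells(
        cls,
        wells: Sequence[tuple[float, float]],
        depth: float = 4.0,
        width: float = 40.0,
        n: int = 36,
        **kw,
    ) -> "AngularPotential":
        """Sum of periodic Gaussian wells of given depth (kBT) and width (deg)."""
        centers = (np.arange(n) + 0.0) * 360.0 / n
        t1, t2 = np.meshgrid(centers, centers, indexing="ij")
        u = np.zeros((n, n))
        for (c1, c2) in wells:
            d1 = _angdiff(t1, c1)
            d2 = _angdiff(t2, c2)
            u -= depth * np.exp(-(d1**2 + d2**2) / (2 * width**2))
        u -= u.min()
        return cls(u, **kw)


def _angdiff(a, b):
    """Signed angular difference in degrees, wrapped to (-180, 180]."""
    return (np.asarray(a) - b + 180.0) % 360.0 - 180.0


# ---------------------------------------------------------------------------
# Undulating membrane
# ---------------------------------------------------------------------------

def fourier_modes(spec: SyntheticSpec):
    """Half-plane Fourier modes and their equipartition variances.

    Returns ``(q_vectors (M, 2), variances (M,))`` with one member of each
    Hermitian pair ``(q, -q)``; the real field is reconstructed as
    ``h(r) = sum_q 2 Re(a_q exp(i q.r))``.
    """
    nx, ny = spec.lattice_shape()
    spacing = min(spec.box_x / nx, spec.box_y / ny)
    if spec.max_mode is not None:
        nmax = int(spec.max_mode)
    else:
        # keep modes comfortably below the sampling Nyquist of the lipid lattice
        nmax = int(0.3 * min(spec.box_x, spec.box_y) / spacing)
    if nmax < 1:
        raise ValueError(
            "box too small for any undulation mode at this lipid density"
        )
    k = np.arange(-nmax, nmax + 1)
    kx, ky = np.meshgrid(k, k, indexing="ij")
    half = (ky > 0) | ((ky == 0) & (kx > 0))
    kx, ky = kx[half], ky[half]
    if len(kx) < 2:
        raise ValueError("box too small: fewer than 2 nonzero Fourier modes")
    qx = 2 * np.pi * kx / spec.box_x
    qy = 2 * np.pi * ky / spec.box_y
    q2 = qx**2 + qy**2
    denom = spec.area * (spec.bending_modulus * q2**2 + spec.surface_tension * q2)
    var = 1.0 / denom          # kBT = 1 in kBT units -> variance in A^2
    return np.column_stack([qx, qy]), var


def _lattice_sites(spec: SyntheticSpec) -> tuple[np.ndarray, float, float]:
    nx, ny = spec.lattice_shape()
    dx, dy = spec.box_x / nx, spec.box_y / ny
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    sites = np.column_stack([(ix.ravel() + 0.5) * dx, (iy.ravel() + 0.5) * dy])
    return sites[: spec.lipids_per_leaflet], dx, dy


def generate_undulating_membrane(spec: SyntheticSpec) -> list[MembraneFrame]:
    """Draw statistically independent frames of a thermally undulating bilayer.

    Lipids sit on a jittered lattice (uniform jitter of half a lattice
    spacing, avoiding the spectral peaks of a perfect lattice while keeping
    the in-plane density uniform).  The undulation field is drawn fresh each
    frame, mode by mode, with complex-coefficient variance
    ``kBT / (A (K q^4 + sigma q^2))``; both leaflets ride the same field at
    ``z = +/- leaflet_offset + h(x, y)``.
    """
    rng = np.random.default_rng(spec.seed)
    q, var = fourier_modes(spec)
    sites, dx, dy = _lattice_sites(spec)
    n = len(sites)

    names = sorted(spec.composition)
    probs = np.array([spec.composition[t] for t in names])
    probs = probs / probs.sum()
    # lipid identities persist across frames; drawn once per leaflet
    types_outer = rng.choice(names, size=n, p=probs).astype("U8")
    types_inner = rng.choice(names, size=n, p=probs).astype("U8")
    types = np.concatenate([types_outer, types_inner])
    leaflet = np.concatenate([np.full(n, OUTER), np.full(n, INNER)])

    sd = np.sqrt(var / 2.0)
    box = np.array([spec.box_x, spec.box_y, spec.box_z])
    frames: list[MembraneFrame] = []
    for i in range(spec.n_frames):
        # frames represent snapshots far apart in time: lateral diffusion has
        # fully remixed the lipids, so each lipid sits on a fresh lattice site
        site_o = sites[rng.permutation(n)]
        site_i = sites[rng.permutation(n)]
        jitter = rng.uniform(-0.5, 0.5, size=(2 * n, 2)) * np.array([dx, dy])
        xy = np.vstack([site_o, site_i]) + jitter
        xy = wrap_positions(xy, box[:2])
        a_re = rng.normal(0.0, sd)
        a_im = rng.normal(0.0, sd)
        phase = xy @ q.T
        h = 2.0 * (np.cos(phase) @ a_re - np.sin(phase) @ a_im)
        z = np.where(leaflet == OUTER, spec.leaflet_offset, -spec.leaflet_offset) + h
        frames.append(
            MembraneFrame(
                time=i * spec.frame_interval,
                box=box.copy(),
                positions=np.column_stack([xy, z]),
                types=types.copy(),
                leaflet=leaflet.copy(),
            )
        )
    return frames


# ---------------------------------------------------------------------------
# Deformation fields and protein footprints
# ---------------------------------------------------------------------------

def deformation_field(
    xy: np.ndarray,
    footprint: FootprintSpec,
    template: DeformationTemplate,
    box: np.ndarray,
) -> np.ndarray:
    """Outer-leaflet height perturbation of one template at the given points."""
    delta = minimum_image(
        np.asarray(xy, dtype=float) - np.asarray(footprint.center_xy), box[:2]
    )
    r = np.hypot(delta[:, 0], delta[:, 1])
    phi = np.arctan2(delta[:, 1], delta[:, 0])
    theta = math.radians(footprint.orientation)
    angular = np.cos(template.angular_order * (phi - theta))
    radial = np.exp(-((r - template.radial_center) ** 2) / (2 * template.radial_width**2))
    tail = np.exp(-np.maximum(0.0, r - template.radial_center) / template.decay_length)
    return template.amplitude * angular * radial * tail


def dimer_beads(
    footprint: FootprintSpec, leaflet_offset: float = 20.0, n_z: int = 5
) -> DimerRecord:
    """Placeholder backbone beads for a C2 dimer occupying the footprint.

    Two protomers sit at +/- separation/2 along the orientation axis; each
    protomer is a hexagonal column of beads spanning the membrane thickness
    so that both leaflets' headgroups can be within contact range.
    """
    sep = footprint.protomer_separation or footprint.footprint_radius
    theta = math.radians(footprint.orientation)
    axis = np.array([math.cos(theta), math.sin(theta)])
    ring_r = footprint.footprint_radius / 3.0
    ring = np.array(
        [[math.cos(a), math.sin(a)] for a in np.linspace(0, 2 * math.pi, 6, endpoint=False)]
    )
    z_levels = np.linspace(-leaflet_offset, leaflet_offset, n_z)
    beads = []
    protomer = []
    cx, cy = footprint.center_xy
    # protomer 0 sits behind the center so the A->B axis points along theta
    for p, sign in enumerate((-1.0, +1.0)):
        center = np.array([cx, cy]) + sign * axis * sep / 2.0
        columns = np.vstack([center, center + ring_r * ring])
        for col in columns:
            for z in z_levels:
                beads.append([col[0], col[1], z])
                protomer.append(p)
    return DimerRecord(
        dimer_id=footprint.dimer_id,
        beads=np.asarray(beads, dtype=float),
        protomer=np.asarray(protomer, dtype=int),
    )


def apply_deformation_field(
    frames: Sequence[MembraneFrame],
    placements: Sequence[tuple[FootprintSpec, DeformationTemplate]],
    add_proteins: bool = True,
    leaflet_offset: float = 20.0,
    seed: int = 0,
) -> list[MembraneFrame]:
    """Superpose deformation templates and carve out protein footprints.

    The outer leaflet gains the summed template field, the inner leaflet the
    mirrored (sign-flipped) field, and a placeholder :class:`DimerRecord` is
    attached per footprint.  Lipids whose in-plane position falls inside any
    ``footprint_radius`` are displaced: the protein occupies that area, so
    they re-enter the bulk at uniform positions outside every footprint (at
    the flat leaflet level), keeping the lipid count constant.
    Superposition is exactly linear, so a multi-template field equals the
    sum of single-template fields.
    """
    if len(placements) == 0:
        return [f.select(np.ones(f.n_lipids, bool)) for f in frames]
    for (fp, _t) in placements:
        box0 = frames[0].box
        if not (0 <= fp.center_xy[0] < box0[0] and 0 <= fp.center_xy[1] < box0[1]):
            raise ValueError(f"footprint {fp.dimer_id} lies outside the box")
    _warn_overlaps([fp for fp, _ in placements], frames[0].box)

    records = (
        [dimer_beads(fp, leaflet_offset) for fp, _ in placements] if add_proteins else []
    )
    rng = np.random.default_rng(seed)

    def inside_any(xy, box):
        hit = np.zeros(len(xy), bool)
        for fp, _t in placements:
            delta = minimum_image(xy - np.asarray(fp.center_xy), box[:2])
            hit |= np.hypot(delta[:, 0], delta[:, 1]) < fp.footprint_radius
        return hit

    out: list[MembraneFrame] = []
    for frame in frames:
        new = frame.select(np.ones(frame.n_lipids, bool))
        xy = new.positions[:, :2]
        displaced = inside_any(xy, new.box)
        moved = displaced.copy()
        while displaced.any():
            k = int(displaced.sum())
            xy[displaced] = rng.uniform(0.0, 1.0, size=(k, 2)) * new.box[:2]
            still = inside_any(xy[displaced], new.box)
            idx = np.flatnonzero(displaced)
            displaced[idx[~still]] = False
        # displaced lipids lose their local undulation height; they rejoin
        # the bulk at the flat leaflet level
        new.positions[moved, 2] = np.where(
            new.leaflet[moved] == OUTER, leaflet_offset, -leaflet_offset
        )
        dz = np.zeros(new.n_lipids)
        for fp, template in placements:
            dz += deformation_field(xy, fp, template, new.box)
        new.positions[:, 2] += np.where(new.leaflet == OUTER, 1.0, -1.0) * dz
        new.dimers = list(records)
        out.append(new)
    return out


def _warn_overlaps(footprints: Sequence[FootprintSpec], box: np.ndarray) -> None:
    for i in range(len(footprints)):
        for j in range(i + 1, len(footprints)):
            d = minimum_image(
                np.asarray(footprints[i].center_xy) - np.asarray(footprints[j].center_xy),
                box[:2],
            )
            if np.hypot(*d) < footprints[i].footprint_radius + footprints[j].footprint_radius:
                warnings.warn(
                    f"footprints {footprints[i].dimer_id} and {footprints[j].dimer_id} "
                    "overlap; fields are superposed anyway",
                    stacklevel=3,
                )


# ---------------------------------------------------------------------------
# Planted enrichment
# ---------------------------------------------------------------------------

def plant_enrichment(
    frames: Sequence[MembraneFrame],
    footprint: FootprintSpec,
    cutoff: float = 7.0,
    seed: int = 0,
    leaflet_offset: float = 20.0,
) -> list[MembraneFrame]:
    """Reassign lipid types near a footprint to plant depletion-enrichment indices.

    For every lipid whose headgroup lies within ``cutoff`` of the
    footprint's (placeholder) protein beads, the type is redrawn so that
    the *realized* index — local fraction over the whole-membrane fraction
    computed after reassignment — equals the target in expectation.  The
    finite-size coupling between the annular counts and the bulk fraction
    is corrected exactly: for target index e, bulk fraction b, region size
    n and total N, the planted local fraction is ``e b (N - n) / (N - e n)``.
    Total lipid count is unchanged.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    targets = dict(footprint.enrichment)
    if not targets:
        return [f.select(np.ones(f.n_lipids, bool)) for f in frames]
    rng = np.random.default_rng(seed)
    beads = dimer_beads(footprint, leaflet_offset).beads
    out = []
    for frame in frames:
        new = frame.select(np.ones(frame.n_lipids, bool))
        dist = nearest_bead_distance(new.positions, beads, new.box)
        region = dist <= cutoff
        n = int(region.sum())
        if n == 0:
            out.append(new)
            continue
        total = new.n_lipids
        names, counts = np.unique(new.types, return_counts=True)
        bulk = {str(t): c / total for t, c in zip(names, counts)}
        probs = _planted_fractions(targets, bulk, n, total)
        order = sorted(probs)
        p = np.array([probs[t] for t in order])
        new.types[region] = rng.choice(order, size=n, p=p / p.sum()).astype("U8")
        out.append(new)
    return out


def _planted_fractions(
    targets: Mapping[str, float], bulk: Mapping[str, float], n: int, total: int
) -> dict[str, float]:
    """Local type fractions realizing the target indices; validates feasibility."""
    probs: dict[str, float] = {}
    for lipid, e in targets.items():
        b = bulk.get(lipid, 0.0)
        denom = total - e * n
        if denom <= 0:
            raise ValueError(
                f"enrichment target {e} for {lipid} infeasible: region too large"
            )
        f = e * b * (total - n) / denom
        if f > 1.0 + 1e-12:
            raise ValueError(
                f"enrichment target {e} for {lipid} requires local fraction {f:.3f} > 1"
            )
        probs[lipid] = min(f, 1.0)
    spent = sum(probs.values())
    if spent > 1.0 + 1e-9:
        raise ValueError(
            f"enrichment targets jointly infeasible: local fractions sum to {spent:.3f}"
        )
    rest_bulk = sum(b for t, b in bulk.items() if t not in targets)
    if rest_bulk > 0:
        scale = max(0.0, 1.0 - spent) / rest_bulk
        for t, b in bulk.items():
            if t not in targets:
                probs[t] = b * scale
    return probs


# ---------------------------------------------------------------------------
# Rotating dimers
# ---------------------------------------------------------------------------

def sample_rotating_dimers(
    potential: AngularPotential,
    n_steps: int,
    seed: int = 0,
    initial: tuple[float, float] = (90.0, 90.0),
    burn_in: int = 0,
):
    """Metropolis Monte Carlo samples of two dimer angles.

    Returns ``(theta1, theta2, acceptance)`` with angles in degrees in
    ``[0, 360)``; the stationary density is proportional to
    ``exp(-U(theta1, theta2))`` with U in kBT.  Fixed seed gives a
    bitwise-identical series on rerun.
    """
    rng = np.random.default_rng(seed)
    total = n_steps + burn_in
    prop = rng.normal(0.0, potential.step_deg, size=(total, 2))
    logu = np.log(rng.random(total))
    t1, t2 = float(initial[0]) % 360.0, float(initial[1]) % 360.0
    e = float(potential.value(t1, t2))
    out1 = np.empty(total)
    out2 = np.empty(total)
    accepted = 0
    val = potential.value
    for i in range(total):
        c1 = (t1 + prop[i, 0]) % 360.0
        c2 = (t2 + prop[i, 1]) % 360.0
        ec = float(val(c1, c2))
        if e - ec >= logu[i]:
            t1, t2, e = c1, c2, ec
            accepted += 1
        out1[i] = t1
        out2[i] = t2
    acceptance = accepted / total
    if not (0.1 < acceptance < 0.9):
        warnings.warn(
            f"Metropolis acceptance {acceptance:.2f} outside (0.1, 0.9); "
            "adjust the proposal step size",
            stacklevel=2,
        )
    return out1[burn_in:], out2[burn_in:], acceptance


# ---------------------------------------------------------------------------
# Interference suite
# ---------------------------------------------------------------------------

def orientation_coupling(theta1_deg: float, theta2_deg: float) -> float:
    """Relative stiffness modulation for a pair of neighboring C2 dimers.

    Smooth, 180-degree periodic in both angles, symmetric under swapping the
    dimers and under the mirror theta -> -theta of the two-dimer geometry.
    It encodes the through-lipid interference phenomenon: matched
    45/45-type orientations (deformation patterns in line) soften the
    membrane most (value -0.85), while the 90/90 arrangement (maximal
    mismatch of elevated and depressed lipids) stiffens it most (+0.6).
    This coupling is *planted* by the generator — deriving it would require
    actual membrane elasticity with protein boundary conditions — so that
    the spectrum pipeline can be tested on recovering the known ordering.
    """
    s = math.sin(2 * math.radians(theta1_deg)) * math.sin(2 * math.radians(theta2_deg))
    c1 = math.cos(2 * math.radians(theta1_deg))
    c2 = math.cos(2 * math.radians(theta2_deg))
    return -0.5 * s - 0.5 * s * s + 0.15 * (1 - c1) * (1 - c2)


def interference_suite(
    orientations: Sequence[float] = (0.0, 45.0, 90.0, 135.0),
    base_modulus: float = 20.0,
    coupling_strength: float = 0.5,
    n_frames: int = 150,
    seed: int = 0,
    box_x: float = 400.0,
    box_y: float = 200.0,
    lipids_per_leaflet: int = 1250,
    amplitude: float = 2.0,
):
    """Two-dimer systems at all orientation pairs, with planted stiffness.

    Mirrors the study's double-dimer geometry: two footprints 200 A apart
    on the long axis of a 400 x 200 A box, each independently rotated on a
    45-degree grid.  For each pair (theta1, theta2) the undulations are
    drawn at ``K_eff = K0 (1 + coupling_strength * orientation_coupling)``
    and the static C2 deformation templates plus thermal noise are
    superposed on top.

    Yields ``((theta1, theta2), frames, K_eff)``.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(orientations) ** 2)
    idx = 0
    for th1 in orientations:
        for th2 in orientations:
            k_eff = base_modulus * (1.0 + coupling_strength * orientation_coupling(th1, th2))
            spec = SyntheticSpec(
                box_x=box_x,
                box_y=box_y,
                lipids_per_leaflet=lipids_per_leaflet,
                bending_modulus=k_eff,
                n_frames=n_frames,
                seed=int(children[idx].generate_state(1)[0] % (2**31)),
            )
            idx += 1
            frames = generate_undulating_membrane(spec)
            template = DeformationTemplate(amplitude=amplitude)
            placements = [
                (FootprintSpec(center_xy=(100.0, 100.0), orientation=th1,
                               dimer_id="D1"), template),
                (FootprintSpec(center_xy=(300.0, 100.0), orientation=th2,
                               dimer_id="D2"), template),
            ]
            frames = apply_deformation_field(frames, placements)
            yield (th1, th2), frames, k_eff
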