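"""Bending-modulus estimation from membrane height-fluctuation spectra.

Helfrich-Canham continuum elasticity relates the equilibrium undulation
spectrum of a quasi-flat bilayer to its bending modulus K and surface
tension sigma::

    <|h(q)|^2> = kBT / (K q^4 + sigma q^2)

The pipeline here mirrors the classic fluctuation analysis: phosphate-bead
z fluctuations are gridded over the membrane plane (lipids within an
exclusion shell of any protein are dropped first), Fourier transformed per
frame, the per-mode intensities frame-averaged and radially shell-averaged,
and the low-q free-undulation branch fitted with a fixed slope of -4 in
log-log space.  The y-intercept of that line is ln(kBT/K), giving K; the
high-q protrusion branch is fitted with fixed slope -2 and reported as a
proxy only.  The crossover between the two regimes is chosen by scanning
candidate split points and minimizing the summed squared residual of the
piecewise model, which makes the visually-identified regime boundary
deterministic and testable.

Intensity convention: per-mode intensity is ``A * |FFT(h)/N|^2`` (box area
times the squared normalized DFT coefficient), so a planted sine of
amplitude a carries ``a^2 A / 4`` at its mode, Parseval reads
``sum I / A = spatial variance``, and the Helfrich-Canham relation holds
with no extra box factor.  With K expressed in kBT the model is simply
``I(q) = 1 / (K q^4 + sigma q^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.constants import k as BOLTZMANN_J

from .frames import MembraneFrame, nearest_dimer_distance, select_window

MIN_SHELLS_PER_BRANCH = 4


@dataclass
class HeightFieldStack:
    """Per-frame midplane-fluctuation fields on a regular grid."""

    fields: np.ndarray          # (F, nx, ny), zero-mean per frame
    box_x: float
    box_y: float
    dx: float
    dy: float
    occupancy: float            # mean populated-bin fraction
    exclusion_radius: float = 0.0


@dataclass
class FluctuationSpectrum:
    q: np.ndarray               # shell wavenumbers, 1/A, ascending
    intensity: np.ndarray       # shell-mean per-mode intensity, A^4
    mode_counts: np.ndarray
    area: float
    grid_bin: tuple[float, float]
    exclusion_radius: float = 0.0
    q_modes: np.ndarray | None = None          # per-mode q (diagnostics/tests)
    intensity_modes: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"q": self.q, "intensity": self.intensity, "modes": self.mode_counts}
        )

    @classmethod
    def from_model(
        cls, q: np.ndarray, bending_modulus: float, surface_tension: float = 0.0
    ) -> "FluctuationSpectrum":
        """Noise-free spectrum evaluated from the closed-form model (kBT units)."""
        q = np.asarray(q, dtype=float)
        intensity = helfrich_intensity(q, bending_modulus, surface_tension)
        return cls(q, intensity, np.ones_like(q, dtype=int), area=np.nan,
                   grid_bin=(np.nan, np.nan))


def helfrich_intensity(q, bending_modulus: float, surface_tension: float = 0.0):
    """``1 / (K q^4 + sigma q^2)`` with K in kBT and sigma in kBT/A^2."""
    q = np.asarray(q, dtype=float)
    return 1.0 / (bending_modulus * q**4 + surface_tension * q**2)


@dataclass
class BendingFit:
    bending_modulus_kbt: float
    bending_modulus_joule: float
    crossover_q: float
    intercept_undulation: float
    intercept_protrusion: float          # NaN when no protrusion branch
    rss_undulation: float
    rss_protrusion: float
    n_undulation_shells: int
    temperature: float
    scaled: float | None = None

    def to_row(self) -> dict:
        return {
            "K_kbt": self.bending_modulus_kbt,
            "K_joule": self.bending_modulus_joule,
            "q_crossover": self.crossover_q,
            "intercept_q4": self.intercept_undulation,
            "intercept_q2": self.intercept_protrusion,
            "rss_q4": self.rss_undulation,
            "rss_q2": self.rss_protrusion,
            "n_shells_q4": self.n_undulation_shells,
            "temperature": self.temperature,
            "scaled_K": self.scaled,
        }


# ---------------------------------------------------------------------------
# Height field
# ---------------------------------------------------------------------------

def build_height_field(
    frames: Sequence[MembraneFrame],
    exclusion_radius: float = 0.0,
    grid_bin: float = 1.0,
    leaflet_mode: str = "undulation",
    max_empty_fraction: float = 0.5,
    window: tuple[float, float] | None = None,
) -> HeightFieldStack:
    """Grid the phosphate-bead z fluctuations of every frame.

    Cholesterol and protein beads never enter the field; lipids within
    ``exclusion_radius`` (3-D nearest-bead distance) of any protein are
    dropped.  Per leaflet the fluctuation is z minus that leaflet's mean z;
    in the default ``"undulation"`` mode both leaflets are pooled as-is
    (a bending undulation displaces both leaflets together), while
    ``"peristaltic"`` flips the inner-leaflet sign to isolate thickness
    modes instead.  Empty or excluded bins take the field's zero level, so
    the grid stays regular for the FFT.
    """
    if grid_bin <= 0:
        raise ValueError("grid_bin must be positive")
    if leaflet_mode not in {"undulation", "peristaltic"}:
        raise ValueError("leaflet_mode must be 'undulation' or 'peristaltic'")
    frames = select_window(frames, window)
    box = frames[0].box
    nx = max(2, int(round(box[0] / grid_bin)))
    ny = max(2, int(round(box[1] / grid_bin)))
    dx, dy = box[0] / nx, box[1] / ny
    xe = np.linspace(0.0, box[0], nx + 1)
    ye = np.linspace(0.0, box[1], ny + 1)

    fields = np.empty((len(frames), nx, ny))
    occ = 0.0
    for i, f in enumerate(frames):
        keep = f.phosphate_mask()
        if exclusion_radius > 0 and f.dimers:
            keep &= nearest_dimer_distance(f) > exclusion_radius
        p = f.positions[keep]
        leaf = f.leaflet[keep]
        z = p[:, 2].astype(float).copy()
        for code in (1, -1):
            m = leaf == code
            if m.any():
                z[m] -= z[m].mean()
        if leaflet_mode == "peristaltic":
            z[leaf == -1] *= -1.0
        zsum, _, _ = np.histogram2d(p[:, 0], p[:, 1], bins=(xe, ye), weights=z)
        cnt, _, _ = np.histogram2d(p[:, 0], p[:, 1], bins=(xe, ye))
        pop = cnt > 0
        occ += pop.mean()
        field = np.zeros((nx, ny))
        field[pop] = zsum[pop] / cnt[pop]
        level = field[pop].mean() if pop.any() else 0.0
        field[~pop] = level
        fields[i] = field - field.mean()
    occ /= len(frames)
    if occ < (1.0 - max_empty_fraction):
        raise ValueError(
            f"height field too sparse for FFT: only {occ:.0%} of bins populated; "
            "use a coarser grid_bin"
        )
    return HeightFieldStack(fields, box[0], box[1], dx, dy, occ, exclusion_radius)


# ---------------------------------------------------------------------------
# Spectrum
# ---------------------------------------------------------------------------

def compute_spectrum(
    stack: HeightFieldStack,
    window_correction: bool = True,
    min_modes_per_shell: int = 3,
    shells_per_decade: int = 12,
    q_discard_fraction: float = 0.1,
    keep_modes: bool = True,
) -> FluctuationSpectrum:
    """Frame-averaged, radially shell-averaged fluctuation spectrum.

    Per frame the field is Fourier transformed; per-mode intensities
    ``A |FFT/N|^2`` are averaged over frames and then over logarithmically
    spaced q shells holding at least ``min_modes_per_shell`` modes each.
    The zero mode and the Nyquist-adjacent top ``q_discard_fraction`` of
    wavenumbers are discarded (standard spectral hygiene).  When
    ``window_correction`` is on, the attenuation from bin-averaging the
    field (a sinc^2 mass-assignment window) is deconvolved per mode.
    """
    f = stack.fields
    if f.ndim != 3 or len(f) < 1:
        raise ValueError("need a (frames, nx, ny) field stack with >= 1 frame")
    n_frames, nx, ny = f.shape
    area = stack.box_x * stack.box_y
    fhat = np.fft.fft2(f, axes=(1, 2)) / (nx * ny)
    power = area * np.mean(np.abs(fhat) ** 2, axis=0)

    qx = 2 * np.pi * np.fft.fftfreq(nx, d=stack.dx)
    qy = 2 * np.pi * np.fft.fftfreq(ny, d=stack.dy)
    qxg, qyg = np.meshgrid(qx, qy, indexing="ij")
    qg = np.hypot(qxg, qyg)

    if window_correction:
        wx = np.sinc(qxg * stack.dx / (2 * np.pi))
        wy = np.sinc(qyg * stack.dy / (2 * np.pi))
        power = power / (wx * wy) ** 2

    q_nyq = min(np.pi / stack.dx, np.pi / stack.dy)
    keep = (qg > 0) & (qg <= (1.0 - q_discard_fraction) * q_nyq)
    qs = qg[keep]
    ps = power[keep]
    order = np.argsort(qs)
    qs, ps = qs[order], ps[order]

    shell_q, shell_i, shell_n = _log_shells(qs, ps, min_modes_per_shell, shells_per_decade)
    return FluctuationSpectrum(
        q=shell_q,
        intensity=shell_i,
        mode_counts=shell_n,
        area=area,
        grid_bin=(stack.dx, stack.dy),
        exclusion_radius=stack.exclusion_radius,
        q_modes=qs if keep_modes else None,
        intensity_modes=ps if keep_modes else None,
    )


def _log_shells(qs, ps, min_modes: int, shells_per_decade: int):
    decades = np.log10(qs[-1] / qs[0]) if qs[-1] > qs[0] else 1.0
    n_edges = max(2, int(np.ceil(decades * shells_per_decade)) + 1)
    edges = np.geomspace(qs[0] * (1 - 1e-12), qs[-1] * (1 + 1e-12), n_edges)
    idx = np.searchsorted(edges, qs, side="right") - 1
    shell_q, shell_i, shell_n = [], [], []
    buf_q: list[float] = []
    buf_i: list[float] = []
    current = idx[0]
    for q, p, b in zip(qs, ps, idx):
        if b != current and len(buf_q) >= min_modes:
            shell_q.append(np.exp(np.mean(np.log(buf_q))))
            shell_i.append(np.mean(buf_i))
            shell_n.append(len(buf_q))
            buf_q, buf_i = [], []
        current = b
        buf_q.append(q)
        buf_i.append(p)
    if buf_q:
        if len(buf_q) >= min_modes or not shell_q:
            shell_q.append(np.exp(np.mean(np.log(buf_q))))
            shell_i.append(np.mean(buf_i))
            shell_n.append(len(buf_q))
        else:   # fold a short trailing shell into the previous one
            n_prev = shell_n[-1]
            total = n_prev + len(buf_q)
            shell_q[-1] = np.exp(
                (n_prev * np.log(shell_q[-1]) + np.sum(np.log(buf_q))) / total
            )
            shell_i[-1] = (n_prev * shell_i[-1] + np.sum(buf_i)) / total
            shell_n[-1] = total
    return np.array(shell_q), np.array(shell_i), np.array(shell_n, dtype=int)


def spectrum_parseval_sum(stack: HeightFieldStack) -> float:
    """``sum_q A<|h_q|^2> / A`` over all modes incl. q=0; equals the variance."""
    n_frames, nx, ny = stack.fields.shape
    fhat = np.fft.fft2(stack.fields, axes=(1, 2)) / (nx * ny)
    return float(np.mean(np.sum(np.abs(fhat) ** 2, axis=(1, 2))))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_bending_modulus(
    spectrum: FluctuationSpectrum,
    temperature: float = 310.0,
    min_shells: int = MIN_SHELLS_PER_BRANCH,
    crossover_buffer: float = 2.0,
) -> BendingFit:
    """Two-regime fixed-slope fit of the log-log spectrum.

    The free-undulation branch (low q) is fitted to a line of slope exactly
    -4 and the protrusion branch (high q) to slope exactly -2; the split is
    scanned over every shell boundary leaving at least ``min_shells`` on
    each side (or no protrusion branch at all) and the split with the
    smallest total squared residual wins.  Shells within a factor
    ``crossover_buffer`` of the located crossover are then excluded from
    the -4 intercept (when enough shells remain), because near the
    crossover both regimes contribute comparably and the undulation
    intercept would be biased upward; the reported intercept thus comes
    from the region where the protrusion effect is genuinely minimal.
    K in kBT is ``exp(-intercept)`` of the -4 line; in SI units,
    K = kB T / exp(intercept).
    """
    q = np.asarray(spectrum.q, dtype=float)
    intensity = np.asarray(spectrum.intensity, dtype=float)
    if len(q) < min_shells:
        raise ValueError(f"need at least {min_shells} q shells, got {len(q)}")
    if np.any(intensity <= 0):
        raise ValueError("spectrum intensities must be positive")
    x = np.log(q)
    y = np.log(intensity)
    if np.polyfit(x, y, 1)[0] > 0:
        raise ValueError("spectrum increases with q; nonphysical input")

    candidates = list(range(min_shells, len(q) - min_shells + 1)) + [len(q)]
    best = None
    for split in candidates:
        b4 = float(np.mean(y[:split] + 4 * x[:split]))
        r4 = float(np.sum((y[:split] - (b4 - 4 * x[:split])) ** 2))
        if split < len(q):
            b2 = float(np.mean(y[split:] + 2 * x[split:]))
            r2 = float(np.sum((y[split:] - (b2 - 2 * x[split:])) ** 2))
        else:
            b2, r2 = np.nan, 0.0
        total = r4 + r2
        if best is None or total < best[0]:
            best = (total, split, b4, r4, b2, r2)
    _, split, b4, r4, b2, r2 = best
    q_c = float(q[-1]) if split == len(q) else float(np.sqrt(q[split - 1] * q[split]))
    if split < len(q):
        clean = q[:split] <= q_c / crossover_buffer
        if clean.sum() >= min_shells:
            b4 = float(np.mean(y[:split][clean] + 4 * x[:split][clean]))
            r4 = float(
                np.sum((y[:split][clean] - (b4 - 4 * x[:split][clean])) ** 2)
            )
    k_kbt = float(np.exp(-b4))
    return BendingFit(
        bending_modulus_kbt=k_kbt,
        bending_modulus_joule=k_kbt * BOLTZMANN_J * temperature,
        crossover_q=q_c,
        intercept_undulation=b4,
        intercept_protrusion=b2,
        rss_undulation=r4,
        rss_protrusion=r2,
        n_undulation_shells=split,
        temperature=temperature,
    )


def membrane_spectrum(
    frames: Sequence[MembraneFrame],
    exclusion_radius: float = 0.0,
    grid_bin: float = 1.0,
    window: tuple[float, float] | None = None,
    **spectrum_kwargs,
) -> FluctuationSpectrum:
    """Convenience: height field plus spectrum in one call."""
    stack = build_height_field(
        frames, exclusion_radius=exclusion_radius, grid_bin=grid_bin, window=window
    )
    return compute_spectrum(stack, **spectrum_kwargs)


def scale_moduli(
    moduli: Mapping[str, float] | pd.DataFrame,
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Divide each bending modulus by the maximum of its group.

    ``moduli`` maps system name to K (or is a DataFrame with columns
    ``system`` and ``K_kbt``); ``groups`` optionally maps system name to a
    group label (one group by default).  Scaled values lie in (0, 1] and
    preserve the within-group ordering.
    """
    if isinstance(moduli, pd.DataFrame):
        systems = list(moduli["system"])
        values = list(moduli["K_kbt"].astype(float))
    else:
        systems = list(moduli)
        values = [float(moduli[s]) for s in systems]
    grp = [groups.get(s, "all") if groups else "all" for s in systems]
    df = pd.DataFrame({"system": systems, "group": grp, "K_kbt": values})
    df["scaled_K"] = df["K_kbt"] / df.groupby("group")["K_kbt"].transform("max")
    return df
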