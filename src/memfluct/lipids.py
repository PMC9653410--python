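"""Annular lipid counting and depletion-enrichment statistics.

A lipid is "near" a protein dimer when the 3-D minimum-image distance from
its headgroup bead (PO4, or the hydroxy bead for cholesterol) to the
nearest protein bead is at most the cutoff (default 7 A, a closed bound).
The depletion-enrichment index of a lipid type L is the ratio of its local
fraction in that annular shell to its whole-membrane (bulk) fraction:

    DE(L) = f_L,local / f_L,bulk

with f_L,local = <count of L within cutoff> / <total count within cutoff>
(ratio of time-averaged counts) and f_L,bulk the whole-membrane fraction
over both leaflets.  An index of 1 means no preference; POPI and
cholesterol around the prestin dimer are the canonical enriched cases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .frames import (
    LEAFLET_CODES,
    LEAFLET_NAMES,
    MembraneFrame,
    nearest_dimer_distance,
    select_window,
)

DEFAULT_CUTOFF = 7.0


@dataclass
class ContactSeries:
    """Per-frame lipid counts within the cutoff, by type and leaflet."""

    data: pd.DataFrame          # columns: time, type, leaflet, count
    cutoff: float
    dimer_id: str

    def totals(self) -> pd.DataFrame:
        return (
            self.data.groupby("time", as_index=False)["count"].sum()
        )


@dataclass
class DepletionEnrichmentTable:
    data: pd.DataFrame          # type, f_local, f_bulk, index, index_std, n_snapshots
    cutoff: float

    def index_of(self, lipid_type: str) -> float:
        row = self.data.loc[self.data["type"] == lipid_type, "index"]
        return float(row.iloc[0])

    def stderr_of(self, lipid_type: str) -> float:
        row = self.data.loc[self.data["type"] == lipid_type]
        return float(row["index_std"].iloc[0]) / np.sqrt(int(row["n_snapshots"].iloc[0]))


def count_contacts(
    frames: Sequence[MembraneFrame],
    dimer_id: str,
    cutoff: float = DEFAULT_CUTOFF,
    window: tuple[float, float] | None = None,
) -> ContactSeries:
    """Count lipids within ``cutoff`` of one dimer, per type and leaflet.

    Frames without the dimer contribute zero counts (empty selection).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    frames = select_window(frames, window)
    all_types = sorted({str(t) for f in frames for t in np.unique(f.types)})
    rows = []
    for f in frames:
        dist = nearest_dimer_distance(f, [dimer_id])
        near = dist <= cutoff
        for leaf in (1, -1):
            sel = near & (f.leaflet == leaf)
            types, counts = np.unique(f.types[sel], return_counts=True)
            got = {str(t): int(c) for t, c in zip(types, counts)}
            for t in all_types:
                rows.append(
                    {
                        "time": f.time,
                        "type": t,
                        "leaflet": LEAFLET_NAMES[leaf],
                        "count": got.get(t, 0),
                    }
                )
    return ContactSeries(pd.DataFrame(rows), cutoff, dimer_id)


def depletion_enrichment(
    frames: Sequence[MembraneFrame],
    cutoff: float = DEFAULT_CUTOFF,
    dimer_ids: Sequence[str] | None = None,
    window: tuple[float, float] | None = None,
) -> DepletionEnrichmentTable:
    """Depletion-enrichment index per lipid type.

    Lipids within ``cutoff`` of *any* of the listed dimers (all dimers by
    default) form the local shell.  Local fractions come from the ratio of
    time-averaged counts; bulk fractions use every lipid in the membrane,
    both leaflets, exactly as the printed definition states.  The quoted
    uncertainty is the standard deviation of the per-snapshot indices.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    frames = select_window(frames, window)
    all_types = sorted({str(t) for f in frames for t in np.unique(f.types)})
    t_index = {t: i for i, t in enumerate(all_types)}
    n_types = len(all_types)

    local = np.zeros((len(frames), n_types))
    bulk = np.zeros((len(frames), n_types))
    for i, f in enumerate(frames):
        dist = nearest_dimer_distance(f, dimer_ids)
        near = dist <= cutoff
        for t, c in zip(*np.unique(f.types[near], return_counts=True)):
            local[i, t_index[str(t)]] = c
        for t, c in zip(*np.unique(f.types, return_counts=True)):
            bulk[i, t_index[str(t)]] = c

    total_local = local.sum(axis=1)
    if total_local.sum() == 0:
        raise ValueError("no lipids within the cutoff in any frame")
    f_local = local.sum(axis=0) / total_local.sum()
    f_bulk = bulk.sum(axis=0) / bulk.sum()

    # per-snapshot indices, for the uncertainty estimate
    ok = total_local > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        snap_local = local[ok] / total_local[ok, None]
        snap_bulk = bulk[ok] / bulk[ok].sum(axis=1, keepdims=True)
        snap_index = snap_local / snap_bulk
    std = np.nanstd(snap_index, axis=0, ddof=1) if ok.sum() > 1 else np.zeros(n_types)

    table = pd.DataFrame(
        {
            "type": all_types,
            "f_local": f_local,
            "f_bulk": f_bulk,
            "index": np.where(f_bulk > 0, f_local / np.maximum(f_bulk, 1e-300), np.nan),
            "index_std": std,
            "n_snapshots": int(ok.sum()),
        }
    )
    return DepletionEnrichmentTable(table, cutoff)


def occupancy_heatmap(
    frames: Sequence[MembraneFrame],
    lipid_type: str,
    leaflet: int | str,
    bin_size: float = 2.0,
    window: tuple[float, float] | None = None,
):
    """Normalized 2-D occupancy histogram of one lipid type's headgroups.

    Returns ``(density, x_edges, y_edges)`` with the density summing to 1
    over the grid.
    """
    frames = select_window(frames, window)
    code = LEAFLET_CODES.get(leaflet, leaflet)
    box = frames[0].box
    xe = np.arange(0.0, box[0], bin_size)
    if xe[-1] < box[0]:
        xe = np.append(xe, box[0])
    ye = np.arange(0.0, box[1], bin_size)
    if ye[-1] < box[1]:
        ye = np.append(ye, box[1])
    grid = np.zeros((len(xe) - 1, len(ye) - 1))
    found = False
    for f in frames:
        m = (f.types == lipid_type) & f.leaflet_mask(code)
        if m.any():
            found = True
            p = f.positions[m]
            h, _, _ = np.histogram2d(p[:, 0], p[:, 1], bins=(xe, ye))
            grid += h
    if not found:
        raise ValueError(f"lipid type {lipid_type!r} absent from leaflet")
    return grid / grid.sum(), xe, ye
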