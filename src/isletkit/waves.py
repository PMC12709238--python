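"""Intercellular wave detection by space-time clustering of onset events.

Onset events (cell, onset time) are linked when both their inter-cell
distance and onset-time difference fall below thresholds; connected
components of the resulting event graph are the waves.  Initiator scores
measure how often a cell activates among the earliest members of the
waves it participates in.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .traces import BinaryActivity, top_sextile

DEFAULT_MIN_WAVE_SIZE = 5
DEFAULT_FIRST_FRACTION = 0.02
GRID_LINK_RADIUS_UM = 22.0


@dataclass
class WaveRecord:
    """One detected wave: member cells, activation times and ranks (1-based)."""

    id: int
    cells: np.ndarray
    times: np.ndarray
    ranks: np.ndarray

    @property
    def size(self) -> int:
        return len(self.cells)


@dataclass
class WaveCatalog:
    waves: list[WaveRecord]
    r_spatial_um: float
    r_temporal_s: float
    min_wave_size: int

    @property
    def n_waves(self) -> int:
        return len(self.waves)


@dataclass
class InitiatorScore:
    """Share of participated waves in which each cell was among the first."""

    score: np.ndarray
    initiator_flag: np.ndarray


def default_link_radius(positions: np.ndarray, mode: str = "scatter") -> float:
    """Spatial link radius: 1.5x median nearest-neighbour distance, or 22 um on the grid."""
    if mode == "grid":
        return GRID_LINK_RADIUS_UM
    tree = cKDTree(positions)
    d, _ = tree.query(positions, k=2)
    return 1.5 * float(np.median(d[:, 1]))


def detect_waves(ba: BinaryActivity, positions: np.ndarray,
                 r_spatial_um: float | None = None,
                 r_temporal_s: float = 2.0,
                 min_wave_size: int = DEFAULT_MIN_WAVE_SIZE,
                 mode: str = "scatter",
                 window: tuple[float, float] | None = None) -> WaveCatalog:
    """Cluster onset events into intercellular waves.

    Two events are linked iff their cells lie within ``r_spatial_um`` and
    their onsets differ by at most ``r_temporal_s``.  Components with at
    least ``min_wave_size`` events become waves; when a cell fires more
    than once inside one component only its earliest event is kept.
    Restricting to ``window`` keeps onsets with t0 <= t < t1.
    """
    if r_spatial_um is None:
        r_spatial_um = default_link_radius(positions, mode)
    if r_spatial_um <= 0 or r_temporal_s <= 0:
        raise ValueError("link radii must be positive")

    ev_cell, ev_time = [], []
    for i in range(ba.n_cells):
        for t in ba.onsets[i]:
            if window is None or (window[0] <= t < window[1]):
                ev_cell.append(i)
                ev_time.append(float(t))
    if not ev_cell:
        return WaveCatalog([], r_spatial_um, r_temporal_s, min_wave_size)
    ev_cell = np.array(ev_cell)
    ev_time = np.array(ev_time)
    m = len(ev_cell)

    tree = cKDTree(positions)
    near = tree.query_pairs(r_spatial_um, output_type="ndarray")  # cell pairs
    cell_events: dict[int, np.ndarray] = {
        c: np.flatnonzero(ev_cell == c) for c in np.unique(ev_cell)}

    rows, cols = [], []

    def _link(eis: np.ndarray, ejs: np.ndarray) -> None:
        dtm = np.abs(ev_time[eis][:, None] - ev_time[ejs][None, :])
        ii, jj = np.nonzero(dtm <= r_temporal_s)
        rows.extend(eis[ii])
        cols.extend(ejs[jj])

    for a, b in near:
        ea, eb = cell_events.get(a), cell_events.get(b)
        if ea is not None and eb is not None:
            _link(ea, eb)
    for c, eis in cell_events.items():  # same-cell repeat events also link
        if len(eis) > 1:
            _link(eis, eis)

    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, m))
    n_comp, comp = connected_components(adj.maximum(adj.T), directed=False)

    records: list[WaveRecord] = []
    for cidx in range(n_comp):
        members = np.flatnonzero(comp == cidx)
        if len(members) < min_wave_size:
            continue
        # earliest event per cell
        best: dict[int, int] = {}
        for e in members:
            c = int(ev_cell[e])
            if c not in best or ev_time[e] < ev_time[best[c]]:
                best[c] = e
        evs = np.array(sorted(best.values(), key=lambda e: (ev_time[e], ev_cell[e])))
        records.append(WaveRecord(
            id=len(records),
            cells=ev_cell[evs],
            times=ev_time[evs],
            ranks=np.arange(1, len(evs) + 1),
        ))
    records.sort(key=lambda r: r.times[0])
    for i, r in enumerate(records):
        r.id = i
    return WaveCatalog(records, r_spatial_um, r_temporal_s, min_wave_size)


def initiator_scores(wc: WaveCatalog, n_cells: int,
                     first_fraction: float = DEFAULT_FIRST_FRACTION) -> InitiatorScore:
    """Score cells by how often they activate among the first in a wave.

    Per wave, the "first" set is the earliest ``ceil(first_fraction * size)``
    activations (at least one cell).  score = waves-in-first-set /
    waves-participated (0 when a cell joined no wave); the top ceil(N/6)
    scores are flagged, ties broken by cell index.
    """
    if not 0 < first_fraction <= 0.5:
        raise ValueError("first_fraction must lie in (0, 0.5]")
    first = np.zeros(n_cells)
    part = np.zeros(n_cells)
    for w in wc.waves:
        k = max(1, math.ceil(first_fraction * w.size))
        part[w.cells] += 1
        first[w.cells[:k]] += 1
    if wc.n_waves == 0:
        warnings.warn("empty wave catalog: all initiator scores are zero",
                      stacklevel=2)
        return InitiatorScore(score=np.zeros(n_cells),
                              initiator_flag=np.zeros(n_cells, dtype=bool))
    score = np.divide(first, part, out=np.zeros(n_cells), where=part > 0)
    return InitiatorScore(score=score, initiator_flag=top_sextile(score))
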