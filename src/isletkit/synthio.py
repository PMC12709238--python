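"""Synthetic islet generator and trace-set disk I/O.

Builds islets with known ground truth: spatially contiguous modules of
cells sharing intrinsic excitability, glucose-step response delays that
cluster by module, and a sustained phase of intercellular activity waves
seeded at high-excitability initiator cells and propagated over a
nearest-neighbour coupling graph.  Fluorescence is the pulse-kernel
convolution of the ground-truth binary activity plus drift and noise.

All randomness flows through one ``numpy.random.Generator`` seeded from
``IsletConfig.seed``; draws are consumed in a fixed documented order so
identical configs yield bit-identical output.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .traces import TraceSet

GRID_SPACING_UM = 15.0  # sub-region mesh edge length
MIN_SPACING_UM = 10.0   # dart-throwing exclusion radius in scatter mode
N_NEIGHBORS = 6         # coupling-graph neighbours (gap-junction analogue)
KERNEL_RISE_S = 0.2     # pulse-kernel rise time constant
KERNEL_DECAY_S = 0.35   # pulse-kernel decay time constant
EXCIT_JITTER = 0.04     # sd of per-cell excitability around the module mean
BOUNDARY_SLOWDOWN = 4.0  # conduction slow-down across module boundaries


class InvalidConfigError(ValueError):
    """Islet configuration is internally inconsistent."""


@dataclass
class IsletConfig:
    """Parameters of one synthetic islet.

    ``osc_duration_s`` is a (mean, sd) pair: the mean sets the length of
    the activation-phase transient; the sd jitters individual sustained-
    phase oscillation durations.
    """

    n_cells: int = 100
    field_shape: tuple[float, float] | None = None  # ellipse semi-axes, um
    mode: str = "scatter"                            # "scatter" | "grid"
    n_modules: int = 7
    sampling_hz: float = 10.0
    duration_s: float = 360.0
    stim_onset_s: float = 60.0
    wave_rate_hz: float = 0.25
    p_global_wave: float = 0.3
    conduction_speed_um_s: float = 40.0
    response_delay_spread_s: float = 3.0
    osc_duration_s: tuple[float, float] = (8.0, 0.3)
    noise_sd: float = 0.1
    drift_amp: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 12:
            raise InvalidConfigError("n_cells must be >= 12")
        if self.field_shape is None:
            # constant density (ellipse aspect 9:7): ~200 um^2 per cell in
            # scatter mode, ~300 um^2 per 15 um grid point in grid mode
            area = (300.0 if self.mode == "grid" else 200.0) * self.n_cells
            b = math.sqrt(area * 7.0 / (9.0 * math.pi))
            self.field_shape = (9.0 * b / 7.0, b)
        if self.sampling_hz <= 0:
            raise InvalidConfigError("sampling_hz must be positive")
        if self.n_modules < 1:
            raise InvalidConfigError("n_modules must be >= 1")
        if not 0 <= self.p_global_wave <= 1:
            raise InvalidConfigError("p_global_wave must lie in [0, 1]")
        if self.mode not in ("scatter", "grid"):
            raise InvalidConfigError(f"unknown mode {self.mode!r}")
        if self.stim_onset_s >= self.duration_s:
            raise InvalidConfigError("stim_onset_s must precede duration_s")


@dataclass
class GroundTruth:
    """Generator-side truth used to validate the analysis stages.

    ``intrinsic_active_time`` is the realized active fraction of the
    ground-truth binary matrix over the sustained window; ``wave_log``
    holds per-wave ``(cell, activation time)`` pairs sorted by time.
    """

    module_label: np.ndarray
    intrinsic_active_time: np.ndarray
    intrinsic_response_time: np.ndarray
    initiator_flag: np.ndarray
    wave_log: list[dict] = field(default_factory=list)
    binary: np.ndarray | None = None
    sustained_window: tuple[float, float] = (0.0, 0.0)


def _scatter_positions(rng: np.random.Generator, n: int,
                       semi_axes: tuple[float, float]) -> np.ndarray:
    """Dart-throwing (Poisson-disk) sample inside an ellipse."""
    a, b = semi_axes
    pts: list[np.ndarray] = []
    attempts = 0
    max_attempts = 20000 * n
    while len(pts) < n:
        attempts += 1
        if attempts > max_attempts:
            raise InvalidConfigError(
                f"cannot place {n} cells with {MIN_SPACING_UM} um spacing "
                f"inside ellipse {semi_axes}")
        p = rng.uniform(-1, 1, 2) * (a, b)
        if (p[0] / a) ** 2 + (p[1] / b) ** 2 > 1:
            continue
        if pts and np.min(np.hypot(*(np.array(pts) - p).T)) < MIN_SPACING_UM:
            continue
        pts.append(p)
    return np.array(pts)


def _grid_positions(n: int, semi_axes: tuple[float, float]) -> np.ndarray:
    a, b = semi_axes
    nx = int(a // GRID_SPACING_UM)
    ny = int(b // GRID_SPACING_UM)
    xs = np.arange(-nx, nx + 1) * GRID_SPACING_UM
    ys = np.arange(-ny, ny + 1) * GRID_SPACING_UM
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = (pts[:, 0] / a) ** 2 + (pts[:, 1] / b) ** 2 <= 1
    pts = pts[inside]
    if n > len(pts):
        raise InvalidConfigError(
            f"grid mode: {n} cells requested but only {len(pts)} grid points "
            f"fit inside ellipse {semi_axes}")
    # deterministic: keep the n points closest to the centre
    order = np.lexsort((pts[:, 1], pts[:, 0], np.hypot(pts[:, 0], pts[:, 1])))
    return pts[order[:n]]


def knn_graph(positions: np.ndarray, k: int = N_NEIGHBORS) -> csr_matrix:
    """Symmetrized k-nearest-neighbour graph with Euclidean edge weights."""
    n = len(positions)
    k = min(k, n - 1)
    tree = cKDTree(positions)
    dist, idx = tree.query(positions, k=k + 1)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    w = dist[:, 1:].ravel()
    g = csr_matrix((w, (rows, cols)), shape=(n, n))
    return g.maximum(g.T)


def generate_islet(config: IsletConfig) -> tuple[TraceSet, GroundTruth]:
    """Generate one synthetic islet and its ground truth.

    RNG draw order: positions, module seed cells, module excitability means,
    per-cell excitability jitter, module delay means, per-cell delay jitter,
    wave count, wave start times, per-wave type/seed, per-event duration
    jitter, drift phase, noise.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells

    # --- geometry and modules -------------------------------------------------
    if cfg.mode == "scatter":
        positions = _scatter_positions(rng, n, cfg.field_shape)
    else:
        positions = _grid_positions(n, cfg.field_shape)
    module_seeds = rng.choice(n, size=cfg.n_modules, replace=False)
    d2seed = np.linalg.norm(positions[:, None, :] - positions[module_seeds][None],
                            axis=2)
    module_label = np.argmin(d2seed, axis=1)

    # --- intrinsic parameters -------------------------------------------------
    module_excit = rng.uniform(0.25, 0.65, cfg.n_modules)
    excit = np.clip(module_excit[module_label] + rng.normal(0, EXCIT_JITTER, n),
                    0.05, 0.9)
    module_delay = rng.uniform(5.0, 25.0, cfg.n_modules)
    delays = np.clip(module_delay[module_label]
                     + rng.normal(0, cfg.response_delay_spread_s, n), 1.0, None)

    k_init = math.ceil(n / 6)
    order = np.lexsort((np.arange(n), -excit))
    initiator = np.zeros(n, dtype=bool)
    initiator[order[:k_init]] = True

    # --- time base ------------------------------------------------------------
    fs = cfg.sampling_hz
    n_frames = int(round(cfg.duration_s * fs))
    time_s = np.arange(n_frames) / fs
    dt = 1.0 / fs
    osc_mean, osc_sd = cfg.osc_duration_s
    transient_s = max(osc_mean, 3 * dt)
    sustained_t0 = cfg.stim_onset_s + float(delays.max()) + transient_s + 2.0
    sustained_t1 = cfg.duration_s
    if sustained_t0 >= sustained_t1 - 10.0:
        raise InvalidConfigError("duration too short for a sustained phase")

    binary = np.zeros((n_frames, n), dtype=np.int8)

    # --- activation phase: one transient per cell at its response delay -------
    resp_t = cfg.stim_onset_s + delays
    for i in range(n):
        s = int(round(resp_t[i] * fs))
        e = min(int(round((resp_t[i] + transient_s) * fs)), n_frames)
        binary[s:e, i] = 1

    # --- sustained phase: waves over the coupling graph -----------------------
    # inter-module edges conduct more slowly (weaker coupling at boundaries),
    # so travelling waves reach each module with a distinct delay signature
    graph = knn_graph(positions)
    gi, gj = graph.nonzero()
    cross = module_label[gi] != module_label[gj]
    graph = graph.tolil()
    graph[gi[cross], gj[cross]] *= BOUNDARY_SLOWDOWN
    graph = graph.tocsr()
    n_waves = rng.poisson(cfg.wave_rate_hz * cfg.duration_s)
    starts = np.sort(rng.uniform(sustained_t0, sustained_t1 - 2 * osc_mean,
                                 n_waves)) if n_waves else np.empty(0)
    init_idx = np.flatnonzero(initiator)
    wave_log: list[dict] = []
    events: list[list[tuple[int, float]]] = []
    for w in range(n_waves):
        is_global = rng.random() < cfg.p_global_wave
        seed_cell = int(rng.choice(init_idx))
        members = (np.arange(n) if is_global
                   else np.flatnonzero(module_label == module_label[seed_cell]))
        sub = graph[np.ix_(members, members)]
        src = int(np.flatnonzero(members == seed_cell)[0])
        hop = dijkstra(sub, indices=src)
        reach = np.isfinite(hop)
        t_act = starts[w] + hop[reach] / cfg.conduction_speed_um_s
        cells = members[reach]
        order = np.argsort(t_act, kind="stable")
        wave_log.append({
            "id": w,
            "global": bool(is_global),
            "seed": seed_cell,
            "cells": cells[order].tolist(),
            "times": t_act[order].tolist(),
        })
        events.append(list(zip(cells[order].tolist(), t_act[order].tolist())))

    # per-cell wave participation -> event duration hits the excitability target
    win_s = sustained_t1 - sustained_t0
    n_part = np.zeros(n, dtype=int)
    for ev in events:
        for c, _ in ev:
            n_part[c] += 1
    target_dur = np.where(n_part > 0, excit * win_s / np.maximum(n_part, 1), 0.0)
    min_event_s = max(0.5, 2 * dt)  # below ~5 frames events evade detection
    for ev in events:
        for c, t in ev:
            d = max(min_event_s, target_dur[c] + rng.normal(0, osc_sd))
            s = int(round(t * fs))
            e = min(int(round((t + d) * fs)), n_frames)
            if s < n_frames:
                binary[s:e, c] = 1

    # --- fluorescence ---------------------------------------------------------
    if fs >= 2.0:
        kt = np.arange(0, int(round(5.0 * fs))) * dt
        kernel = (1 - np.exp(-kt / KERNEL_RISE_S)) * np.exp(-kt / KERNEL_DECAY_S)
        kernel /= kernel.sum()  # unit gain: sustained activity -> plateau of 1
    else:
        kernel = np.array([1.0])  # slow sampling cannot resolve kinetics
    fluo = np.empty((n_frames, n))
    for i in range(n):
        fluo[:, i] = np.convolve(binary[:, i], kernel)[:n_frames]
    phase = rng.uniform(0, 2 * np.pi)
    drift = cfg.drift_amp * (np.sin(2 * np.pi * time_s / cfg.duration_s + phase)
                             + time_s / cfg.duration_s)
    fluo += drift[:, None]
    if cfg.noise_sd > 0:
        fluo += rng.normal(0, cfg.noise_sd, fluo.shape)

    in_win = (time_s >= sustained_t0) & (time_s < sustained_t1)
    realized_active = binary[in_win].mean(axis=0)

    ts = TraceSet(values=fluo, time_s=time_s, positions=positions,
                  sampling_hz=fs, stim_onset_s=cfg.stim_onset_s, mode=cfg.mode)
    gt = GroundTruth(module_label=module_label,
                     intrinsic_active_time=realized_active,
                     intrinsic_response_time=delays,
                     initiator_flag=initiator,
                     wave_log=wave_log,
                     binary=binary,
                     sustained_window=(sustained_t0, sustained_t1))
    return ts, gt


# --------------------------------------------------------------------------
# disk formats: traces.csv, coords.csv, meta.json (+ truth.json)
# --------------------------------------------------------------------------

class TraceParseError(ValueError):
    """Malformed trace/coordinate file; message names the offending row/column."""


def _fmt(x: float) -> str:
    return repr(float(x))


def write_traceset(ts: TraceSet, path: str | Path) -> None:
    """Write ``traces.csv``, ``coords.csv`` and ``meta.json`` under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cols = [f"cell_{i:03d}" for i in range(ts.n_cells)]
    with open(path / "traces.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t"] + cols)
        for k in range(ts.n_frames):
            w.writerow([_fmt(ts.time_s[k])] + [_fmt(v) for v in ts.values[k]])
    with open(path / "coords.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cell", "x_um", "y_um"])
        for i in range(ts.n_cells):
            w.writerow([cols[i], _fmt(ts.positions[i, 0]), _fmt(ts.positions[i, 1])])
    meta = {"sampling_hz": ts.sampling_hz, "stim_onset_s": ts.stim_onset_s,
            "mode": ts.mode}
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def _parse_float(tok: str, row: int, col: str) -> float:
    tok = tok.strip()
    if not tok:
        raise TraceParseError(f"missing value at row {row}, column {col!r}")
    try:
        return float(tok)
    except ValueError:
        raise TraceParseError(
            f"non-numeric value {tok!r} at row {row}, column {col!r}") from None


def read_traceset(path: str | Path) -> TraceSet:
    """Read a trace set written by :func:`write_traceset` (round-trip exact)."""
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    with open(path / "traces.csv", newline="") as fh:
        r = csv.reader(fh)
        header = next(r, None)
        if not header or header[0] != "t":
            raise TraceParseError("traces.csv: header must start with 't'")
        cells = header[1:]
        times, rows = [], []
        for k, row in enumerate(r, start=1):
            if len(row) != len(header):
                raise TraceParseError(
                    f"traces.csv: row {k} has {len(row)} fields, expected {len(header)}")
            times.append(_parse_float(row[0], k, "t"))
            rows.append([_parse_float(tok, k, cells[j])
                         for j, tok in enumerate(row[1:])])
    with open(path / "coords.csv", newline="") as fh:
        r = csv.reader(fh)
        header = next(r, None)
        if header != ["cell", "x_um", "y_um"]:
            raise TraceParseError("coords.csv: expected header cell,x_um,y_um")
        coords = {}
        for k, row in enumerate(r, start=1):
            if len(row) != 3:
                raise TraceParseError(f"coords.csv: row {k} is ragged")
            coords[row[0]] = (_parse_float(row[1], k, "x_um"),
                              _parse_float(row[2], k, "y_um"))
    try:
        positions = np.array([coords[c] for c in cells])
    except KeyError as exc:
        raise TraceParseError(f"coords.csv: missing coordinates for cell {exc}") from None
    return TraceSet(values=np.array(rows), time_s=np.array(times),
                    positions=positions, sampling_hz=float(meta["sampling_hz"]),
                    stim_onset_s=float(meta["stim_onset_s"]),
                    mode=meta.get("mode", "scatter"))


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    payload = {
        "module_label": gt.module_label.tolist(),
        "intrinsic_active_time": gt.intrinsic_active_time.tolist(),
        "intrinsic_response_time": gt.intrinsic_response_time.tolist(),
        "initiator_flag": gt.initiator_flag.astype(int).tolist(),
        "wave_log": gt.wave_log,
        "sustained_window": list(gt.sustained_window),
    }
    (path / "truth.json").write_text(json.dumps(payload))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads((Path(path) / "truth.json").read_text())
    return GroundTruth(
        module_label=np.array(payload["module_label"]),
        intrinsic_active_time=np.array(payload["intrinsic_active_time"]),
        intrinsic_response_time=np.array(payload["intrinsic_response_time"]),
        initiator_flag=np.array(payload["initiator_flag"], dtype=bool),
        wave_log=payload["wave_log"],
        sustained_window=tuple(payload["sustained_window"]),
    )
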