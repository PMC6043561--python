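"""Simulation orchestration: the MCS loop, event logging and run outputs.

One iteration of the loop is one second of physical time: a full Metropolis
sweep, one field update, then cell-cycle bookkeeping (division clocks,
mitotic-rounding onsets). Tumor-cell centroids, division events and cluster
metrics are logged periodically; a run directory always receives the exact
resolved configuration and seed, and identical (config, seed) reproduce
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time as _walltime
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import cycle as cycle_mod
from . import field as field_mod
from . import tracks as tracks_mod
from ._kernels import T_CORE
from .config import SimConfig
from .init_lattice import gen_initial_lattice
from .lattice import CellTable, Lattice, monte_carlo_step, total_hamiltonian

log = logging.getLogger("senoclust")


@dataclass
class SimResult:
    config: SimConfig
    lattice: Lattice
    cells: CellTable
    tracks: pd.DataFrame
    events: pd.DataFrame
    metrics: pd.DataFrame
    out_dir: Optional[Path]
    field: Optional[field_mod.ScalarField] = None
    n_mcs_run: int = 0

    def mature_intervals(self) -> np.ndarray:
        """Inter-division intervals from cohorts whose clocks started at
        least ``interval_maturity`` seconds before the run ended — complete
        observations, free of end-of-run censoring bias."""
        ev = self.events.dropna(subset=["interval"])
        horizon = self.n_mcs_run - self.config.run.interval_maturity
        born = ev["time"] - ev["interval"]
        return ev.loc[born <= horizon, "interval"].to_numpy()

    @property
    def cluster(self) -> Optional[tracks_mod.ClusterMetrics]:
        try:
            return tracks_mod.cluster_metrics(self.lattice, self.cells)
        except ValueError:
            return None


def _log_tracks(rows, lattice, cells, t):
    for tid in cells.tumor_ids:
        if lattice.volumes[tid] <= 0:
            continue
        c = lattice.centroid(tid)
        rows.append((int(tid), float(t), c[0], c[1], c[2]))


def run_simulation(config: SimConfig, out_dir=None) -> SimResult:
    """Run the configured scenario; write tracks/events/metrics (and the
    resolved config) to ``out_dir`` when given."""
    rng = np.random.default_rng(config.run.seed)
    params = config.energy.to_params()
    cyc = config.cycle.to_params()
    lattice, cells = gen_initial_lattice(config.init.to_init(config.grid))

    has_core = len(cells.ids_of_type("core")) > 0
    fld = None
    if config.field.enabled and has_core:
        fld = config.field.to_field(lattice.shape, lattice.spacing)
        field_mod.equilibrate(fld, lattice, cells, config.field.burn_in)

    # asynchronous initial population: each tumor cell starts at a uniform
    # random phase of a freshly drawn cycle
    for tid in cells.tumor_ids:
        cells.next_division_time[tid] = rng.uniform() * cycle_mod.draw_cycle_length(cyc, rng)

    track_rows = []
    event_rows = []
    metric_rows = []
    _log_tracks(track_rows, lattice, cells, 0.0)

    clock_starts: list = []  # birth times of division-started cycle clocks
    t0_wall = _walltime.time()
    t_end = config.run.n_mcs
    for t in range(1, config.run.n_mcs + 1):
        stats = monte_carlo_step(
            lattice, cells, params, field=fld, rng=rng, time=float(t), cycle=cyc
        )
        if fld is not None:
            field_mod.step_field(fld, lattice, cells, n_seconds=1.0)

        # divisions due this second
        due = np.nonzero(cells.next_division_time[: cells.n_ids] <= t)[0]
        for tid in due:
            interval = (
                float(t) - float(cells.birth_time[tid])
                if cells.born_by_division[tid]
                else np.nan
            )
            gen = int(cells.generation[tid])
            try:
                kept, new = cycle_mod.divide_cell(
                    lattice, cells, int(tid), rng, time=float(t), cycle=cyc
                )
            except cycle_mod.DivisionDeferred:
                cells.next_division_time[tid] = t + 1.0
                continue
            cen = lattice.centroid(kept)
            event_rows.append(
                {
                    "time": float(t),
                    "parent_id": int(tid),
                    "daughter_id": int(new),
                    "generation": gen + 1,
                    "interval": interval,
                    "x": cen[0],
                    "y": cen[1],
                    "z": cen[2],
                }
            )
            clock_starts.append(float(t))
            clock_starts.append(float(t))  # both daughters start fresh clocks

        if config.run.track_every and t % config.run.track_every == 0:
            _log_tracks(track_rows, lattice, cells, float(t))
        if config.run.metrics_every and t % config.run.metrics_every == 0:
            row = {
                "time": float(t),
                "n_tumor": int(len(cells.tumor_ids)),
                "acceptance_rate": stats["acceptance_rate"],
                "energy": total_hamiltonian(
                    lattice, cells, params, time=float(t), cycle=cyc
                ),
            }
            if has_core:
                cm = tracks_mod.cluster_metrics(lattice, cells)
                row.update(
                    n_cells_on_core=cm.n_cells_on_core,
                    max_stack_height=cm.max_stack_height,
                    cluster_formed=cm.cluster_formed,
                )
            metric_rows.append(row)
        if t % 1000 == 0:
            log.info(
                "t=%d s  cells=%d  acc=%.3f  wall=%.1fs",
                t,
                len(cells.tumor_ids),
                stats["acceptance_rate"],
                _walltime.time() - t0_wall,
            )
        if config.run.stop_after_intervals is not None:
            # count cycle clocks old enough that their completion (and hence
            # their interval) is certain to have been observed by now
            matured = np.searchsorted(clock_starts, t - config.run.interval_maturity)
            if matured >= config.run.stop_after_intervals:
                t_end = t
                break

    tracks = pd.DataFrame(track_rows, columns=tracks_mod.TRACK_COLUMNS)
    events = pd.DataFrame(
        event_rows,
        columns=["time", "parent_id", "daughter_id", "generation", "interval", "x", "y", "z"],
    )
    metrics = pd.DataFrame(metric_rows)

    result = SimResult(
        config=config,
        lattice=lattice,
        cells=cells,
        tracks=tracks,
        events=events,
        metrics=metrics,
        out_dir=None,
        field=fld,
        n_mcs_run=int(t_end),
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_dir / "config.yaml")
        tracks_mod.write_tracks(tracks, out_dir / "tracks.csv")
        events.to_csv(out_dir / "events.csv", index=False)
        metrics.to_csv(out_dir / "metrics.csv", index=False)
        summary = {
            "seed": config.run.seed,
            "n_mcs_run": int(t_end),
            "n_tumor_cells": int(len(cells.tumor_ids)),
            "n_division_events": int(len(events)),
        }
        if has_core:
            cm = tracks_mod.cluster_metrics(lattice, cells)
            core_id = int(cells.ids_of_type("core")[0])
            summary.update(
                cluster_formed=bool(cm.cluster_formed),
                n_cells_on_core=int(cm.n_cells_on_core),
                max_stack_height=int(cm.max_stack_height),
                core_centroid=[float(v) for v in lattice.centroid(core_id)],
            )
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        if config.run.snapshot_every:
            save_snapshot(lattice, cells, out_dir / "final_snapshot", fld)
        result.out_dir = out_dir
    return result


def save_snapshot(lattice: Lattice, cells: CellTable, prefix, fld=None):
    """Write the labelled grid as a z-stack TIFF plus a JSON sidecar mapping
    cell id -> type/generation (and the field as a float stack if given)."""
    import tifffile

    prefix = Path(prefix)
    stack = np.moveaxis(lattice.grid, 2, 0)  # pages = z slices
    tifffile.imwrite(str(prefix) + "_labels.tif", stack.astype(np.int32))
    if fld is not None:
        tifffile.imwrite(
            str(prefix) + "_field.tif", np.moveaxis(fld.omega, 2, 0).astype(np.float32)
        )
    sidecar = {
        str(cid): {
            "type": cells.record(cid).type,
            "generation": int(cells.generation[cid]),
        }
        for cid in range(1, cells.n_ids)
    }
    with open(str(prefix) + "_cells.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def analyze(
    tracks,
    center=None,
    heading_step: Optional[float] = None,
    dims=("x", "y"),
    out_dir=None,
) -> dict:
    """Run the full motility report on a track table (path or DataFrame):
    ensemble MSD + anomalous exponent, heading autocorrelation + two-tiered
    exponential fit, and (given a center) the mean radial approach speed."""
    if not isinstance(tracks, pd.DataFrame):
        tracks = tracks_mod.read_tracks(tracks)
    if tracks.empty:
        raise ValueError("track table is empty")
    msd = tracks_mod.compute_msd(tracks, dims=dims)
    alpha, alpha_se = tracks_mod.fit_msd_exponent(msd)
    pc = tracks_mod.direction_autocorr(tracks, heading_step=heading_step, dims=dims)
    fit = tracks_mod.fit_two_exponential(pc)
    report = {
        "n_tracks": int(msd.n_tracks),
        "msd": {"alpha": alpha, "alpha_se": alpha_se},
        "persistence": {
            "A": fit.A,
            "tau": fit.tau,
            "B": fit.B,
            "tau0": fit.tau0,
            "residual_norm": fit.residual_norm,
            "ok": fit.ok,
        },
    }
    if center is not None:
        report["radial_velocity"] = tracks_mod.radial_velocity(tracks, center)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"lag": msd.lags, "msd": msd.msd, "sd": msd.sd}).to_csv(
            out_dir / "msd.csv", index=False
        )
        pd.DataFrame({"lag": pc.lags, "cos_theta": pc.values, "sd": pc.sd}).to_csv(
            out_dir / "persistence.csv", index=False
        )
        with open(out_dir / "fits.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
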