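"""Hydration-shell counting, bridging-water detection, residence statistics.

The first hydration shell is taken as all waters whose oxygen lies within
0.5 nm (5 Å) of any solute atom; a bridging water is one whose oxygen is
simultaneously within 0.35 nm of two specific protein atoms (in the
progesterone-receptor case, the tryptophan-755 side-chain nitrogen NE1 and
the valine-912 backbone nitrogen N). A residence interval is one maximal run
of consecutive frames in which a tracked water satisfies the site criterion;
runs separated by at most ``gap_tolerance`` absent frames can be merged,
because frame striding fragments genuine residences.

Boundary rule used everywhere: a distance exactly equal to the cutoff counts
as inside (≤).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .geometry import TimeSeries, minimum_image_displacement
from .structio import SelectionMask, Trajectory

__all__ = [
    "SolvationConfig", "ResidenceInterval", "hydration_count_series",
    "block_average", "bridging_water_events", "residence_summary",
]


@dataclass
class SolvationConfig:
    """Cutoffs and options for solvation analyses.

    shell_cutoff: first-hydration-shell radius, nm (default 0.5 = 5 Å).
    bridge_cutoff: both-site bridging-water radius, nm (default 0.35).
    gap_tolerance: frames of absence bridged inside one residence interval.
    use_pbc: apply minimum-image distances when frames carry a box.
    neighbor_method: "cell" (cell lists) or "brute" (all pairs); both give
        identical results, cell lists are just faster for many waters.
    """

    shell_cutoff: float = 0.5
    bridge_cutoff: float = 0.35
    gap_tolerance: int = 0
    use_pbc: bool = False
    neighbor_method: str = "cell"

    def __post_init__(self) -> None:
        if self.shell_cutoff <= 0 or self.bridge_cutoff <= 0:
            raise ConfigurationError("cutoffs must be positive")
        if self.gap_tolerance < 0:
            raise ConfigurationError("gap_tolerance must be >= 0")
        if self.neighbor_method not in ("cell", "brute"):
            raise ConfigurationError(
                f"unknown neighbor_method {self.neighbor_method!r}"
            )


@dataclass(frozen=True)
class ResidenceInterval:
    """One continuous occupancy episode of a tracked water at a site.

    Times in ps; ``duration`` already includes one frame spacing, so a
    single-frame visit in a 2 ps-spaced trajectory lasts 2 ps.
    """

    water_id: tuple[str, int]   # (chain, resid) of the water residue
    start_time: float
    end_time: float
    site: str
    duration: float

    def __post_init__(self) -> None:
        if self.end_time < self.start_time:
            raise ConfigurationError("interval end_time precedes start_time")


# ---------------------------------------------------------------------------
# Neighbor searches
# ---------------------------------------------------------------------------

def _pair_displacements(a: np.ndarray, b: np.ndarray, box: np.ndarray | None):
    delta = a[:, None, :] - b[None, :, :]
    if box is not None:
        delta = minimum_image_displacement(delta, box)
    return delta


def _within_cutoff_brute(
    solute: np.ndarray, waters: np.ndarray, cutoff: float, box: np.ndarray | None
) -> np.ndarray:
    """Boolean per water: within cutoff of any solute atom (all-pairs)."""
    delta = _pair_displacements(solute, waters, box)
    d2 = np.einsum("ijk,ijk->ij", delta, delta)
    return (d2 <= cutoff * cutoff).any(axis=0)


def _within_cutoff_cell(
    solute: np.ndarray, waters: np.ndarray, cutoff: float, box: np.ndarray | None
) -> np.ndarray:
    """Cell-list variant of :func:`_within_cutoff_brute`; identical output.

    Waters are binned into cells no smaller than the cutoff; each solute atom
    only tests waters in its 27 surrounding cells. Falls back to brute force
    when the periodic box is too small for three cells per dimension.
    """
    if waters.shape[0] == 0:
        return np.zeros(0, dtype=bool)
    if box is not None:
        lengths = np.diag(np.asarray(box, dtype=float))
        if not np.allclose(box, np.diag(lengths)):
            raise ConfigurationError("cell lists support orthorhombic boxes only")
        ncells = np.maximum((lengths // cutoff).astype(int), 1)
        if ncells.min() < 3:
            return _within_cutoff_brute(solute, waters, cutoff, box)
        cell_size = lengths / ncells
        wkeys = np.floor(np.mod(waters, lengths) / cell_size).astype(int)
        wkeys = np.minimum(wkeys, ncells - 1)
        skeys = np.floor(np.mod(solute, lengths) / cell_size).astype(int)
        skeys = np.minimum(skeys, ncells - 1)
    else:
        cell_size = np.full(3, cutoff)
        origin = waters.min(axis=0)
        wkeys = np.floor((waters - origin) / cell_size).astype(int)
        skeys = np.floor((solute - origin) / cell_size).astype(int)
        ncells = None
    buckets: dict[tuple[int, int, int], list[int]] = {}
    for i, key in enumerate(map(tuple, wkeys)):
        buckets.setdefault(key, []).append(i)
    inside = np.zeros(waters.shape[0], dtype=bool)
    offsets = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
               for dz in (-1, 0, 1)]
    c2 = cutoff * cutoff
    for s_xyz, key in zip(solute, skeys):
        candidates: list[int] = []
        for off in offsets:
            nk = key + np.array(off)
            if ncells is not None:
                nk = np.mod(nk, ncells)
            candidates.extend(buckets.get(tuple(nk), ()))
        if not candidates:
            continue
        cand = np.array(candidates)
        cand = cand[~inside[cand]]
        if cand.size == 0:
            continue
        delta = waters[cand] - s_xyz
        if box is not None:
            delta = minimum_image_displacement(delta, box)
        d2 = np.einsum("ij,ij->i", delta, delta)
        inside[cand[d2 <= c2]] = True
    return inside


def waters_in_shell(
    solute: np.ndarray, waters: np.ndarray, cutoff: float,
    box: np.ndarray | None = None, method: str = "cell",
) -> np.ndarray:
    """Boolean mask over waters within ``cutoff`` of any solute atom."""
    fn = _within_cutoff_cell if method == "cell" else _within_cutoff_brute
    return fn(np.asarray(solute, float), np.asarray(waters, float), cutoff, box)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def hydration_count_series(
    traj: Trajectory,
    solute_mask: SelectionMask,
    water_mask: SelectionMask,
    cfg: SolvationConfig | None = None,
) -> TimeSeries:
    """Per-frame count of first-shell waters.

    ``water_mask`` should select one oxygen per water molecule (the oxygen is
    the distance proxy). Masks must be disjoint and non-empty.
    """
    cfg = cfg or SolvationConfig()
    if len(solute_mask) == 0:
        raise ConfigurationError("solute mask must be non-empty")
    if len(water_mask) == 0:
        return TimeSeries(traj.times, np.zeros(traj.n_frames),
                          label="hydration_count", units="count")
    if set(solute_mask.indices) & set(water_mask.indices):
        raise ConfigurationError("solute and water masks overlap")
    counts = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        box = frame.box if cfg.use_pbc else None
        if cfg.use_pbc and frame.box is None:
            raise ConfigurationError("use_pbc requested but frame has no box")
        inside = waters_in_shell(
            frame.coordinates[solute_mask.array],
            frame.coordinates[water_mask.array],
            cfg.shell_cutoff, box, cfg.neighbor_method,
        )
        counts[i] = inside.sum()
    return TimeSeries(traj.times, counts, label="hydration_count", units="count")


def block_average(series: TimeSeries, block: int, strict: bool = False) -> TimeSeries:
    """Non-overlapping block averages of a time series.

    Each block of ``block`` consecutive points emits (mean time, mean value).
    A trailing partial block is emitted and flagged in ``meta``; with
    ``strict`` a block larger than the series is an error.
    """
    if block < 1:
        raise ConfigurationError(f"block must be >= 1, got {block}")
    n = len(series)
    if strict and block > n:
        raise ConfigurationError(f"block {block} larger than series of {n} points")
    times, values = [], []
    partial = False
    for start in range(0, n, block):
        t = series.times[start:start + block]
        v = series.values[start:start + block]
        if t.size < block:
            partial = True
        times.append(t.mean())
        values.append(v.mean())
    return TimeSeries(
        np.array(times), np.array(values),
        label=f"{series.label}_block{block}", units=series.units,
        meta={**series.meta, "block": block, "partial_final_block": partial},
    )


def _runs_from_bool(present: np.ndarray, gap_tolerance: int) -> list[tuple[int, int]]:
    """Maximal index runs of True, merging gaps of at most gap_tolerance False."""
    idx = np.flatnonzero(present)
    if idx.size == 0:
        return []
    runs: list[tuple[int, int]] = []
    start = prev = int(idx[0])
    for i in idx[1:]:
        i = int(i)
        if i - prev - 1 <= gap_tolerance:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    return runs


def bridging_water_events(
    traj: Trajectory,
    site_a: SelectionMask,
    site_b: SelectionMask,
    water_mask: SelectionMask,
    cfg: SolvationConfig | None = None,
    site_label: str = "bridge",
) -> list[ResidenceInterval]:
    """Residence intervals of waters bridging two single protein atoms.

    A water (tracked by the chain and residue number of its oxygen) occupies
    the bridge when its oxygen is within ``bridge_cutoff`` of BOTH site
    atoms. Runs of consecutive occupied frames become intervals; runs
    separated by at most ``gap_tolerance`` unoccupied frames are merged.
    """
    cfg = cfg or SolvationConfig()
    if len(site_a) != 1 or len(site_b) != 1:
        raise ConfigurationError("bridge site masks must each contain exactly one atom")
    if len(water_mask) == 0:
        return []
    times = traj.times
    dt = traj.frame_spacing()
    ia, ib = site_a.indices[0], site_b.indices[0]
    widx = water_mask.array
    c2 = cfg.bridge_cutoff**2
    present = np.zeros((traj.n_frames, len(widx)), dtype=bool)
    for f, frame in enumerate(traj.frames):
        w = frame.coordinates[widx]
        da = w - frame.coordinates[ia]
        db = w - frame.coordinates[ib]
        if cfg.use_pbc:
            if frame.box is None:
                raise ConfigurationError("use_pbc requested but frame has no box")
            da = minimum_image_displacement(da, frame.box)
            db = minimum_image_displacement(db, frame.box)
        present[f] = (np.einsum("ij,ij->i", da, da) <= c2) & (
            np.einsum("ij,ij->i", db, db) <= c2
        )
    intervals: list[ResidenceInterval] = []
    for col, atom_index in enumerate(widx):
        atom = traj.topology.atoms[atom_index]
        for start, end in _runs_from_bool(present[:, col], cfg.gap_tolerance):
            intervals.append(ResidenceInterval(
                water_id=(atom.chain, atom.resid),
                start_time=float(times[start]), end_time=float(times[end]),
                site=site_label,
                duration=float(times[end] - times[start] + dt),
            ))
    intervals.sort(key=lambda iv: (iv.start_time, iv.water_id))
    return intervals


def residence_summary(intervals: list[ResidenceInterval]) -> dict:
    """Count, mean and max residence durations in ps (mean/max None if empty)."""
    if not intervals:
        return {"count": 0, "mean_ps": None, "max_ps": None}
    durations = np.array([iv.duration for iv in intervals])
    return {
        "count": len(intervals),
        "mean_ps": float(durations.mean()),
        "max_ps": float(durations.max()),
    }


def intervals_to_csv(intervals: list[ResidenceInterval], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [{"water_chain": iv.water_id[0], "water_resid": iv.water_id[1],
          "site": iv.site, "start_ps": iv.start_time, "end_ps": iv.end_time,
          "duration_ps": iv.duration} for iv in intervals]
    ).to_csv(path, index=False)
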