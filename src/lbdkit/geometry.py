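"""Superposition and RMSD-family metrics.

The central quantity of the state analysis is the two-reference ΔRMSD: a
frame's Cα RMSD to the "closed" (agonistic, helix 12 packed on the pocket)
reference minus its RMSD to the "open" (antagonistic) reference. Frames that
resemble the closed state therefore score negative, and the closed-state
criterion used throughout is ΔRMSD ≤ −0.1 nm.

All RMSDs are Kabsch-optimal: the mobile structure is rigidly superposed on
the reference by the rotation that minimises the weighted squared deviation
before the deviation is measured. Superposition (fit) masks and measurement
masks can differ — the default for regional RMSDs is a global Cα fit with a
regional measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, DegenerateGeometryError, InsufficientDataError
from .structio import Frame, SelectionMask, Topology, Trajectory

__all__ = [
    "TimeSeries", "ReferencePair", "kabsch_superpose", "superpose_coordinates",
    "rmsd", "rmsd_series", "delta_rmsd_series", "rmsf", "residue_rmsf",
    "distance_series", "minimum_image_displacement", "iterative_mean_structure",
]


# ---------------------------------------------------------------------------
# Time series container
# ---------------------------------------------------------------------------

@dataclass
class TimeSeries:
    """A labelled scalar time series (times in ps)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    units: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ConfigurationError("times and values must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) < 0):
            raise ConfigurationError("times must be non-decreasing")

    def __len__(self) -> int:
        return self.times.size

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"time_ps": self.times, "value": self.values,
             "label": self.label, "units": self.units}
        ).to_csv(path, index=False)


@dataclass
class ReferencePair:
    """Open and closed reference structures with a shared atom correspondence.

    ``mask_open[i]``, ``mask_closed[i]`` and ``mask_traj[i]`` address the same
    physical atom in the open reference, closed reference, and analysed
    trajectory respectively.
    """

    open_topology: Topology
    open_frame: Frame
    closed_topology: Topology
    closed_frame: Frame
    mask_open: SelectionMask
    mask_closed: SelectionMask
    mask_traj: SelectionMask

    def __post_init__(self) -> None:
        lengths = {len(self.mask_open), len(self.mask_closed), len(self.mask_traj)}
        if len(lengths) != 1:
            raise ConfigurationError("reference masks must have identical lengths")
        if lengths.pop() < 3:
            raise ConfigurationError("reference masks need at least 3 atoms")

    @property
    def open_coords(self) -> np.ndarray:
        return self.open_frame.coordinates[self.mask_open.array]

    @property
    def closed_coords(self) -> np.ndarray:
        return self.closed_frame.coordinates[self.mask_closed.array]

    def reference_separation(self) -> float:
        """Kabsch RMSD between the two references over their masks, nm."""
        return kabsch_superpose(self.closed_coords, self.open_coords)[2]


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def _check_nondegenerate(coords: np.ndarray, what: str) -> None:
    if coords.shape[0] < 3:
        raise DegenerateGeometryError(
            f"{what}: need at least 3 correspondence points, got {coords.shape[0]}"
        )
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-10 * max(s[0], 1e-30):
        raise DegenerateGeometryError(f"{what}: points are collinear or coincident")


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best matches ``reference`` in the
    (weighted) least-squares sense; the rotation is proper (det = +1) and the
    RMSD is in the coordinate units (nm).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ConfigurationError(
            f"coordinate sets differ in shape: {mobile.shape} vs {reference.shape}"
        )
    _check_nondegenerate(mobile, "mobile")
    _check_nondegenerate(reference, "reference")
    n = mobile.shape[0]
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ConfigurationError("weights must be non-negative with positive sum")
        w = w / w.sum()
    cm = w @ mobile
    cr = w @ reference
    p = mobile - cm
    q = reference - cr
    cov = (p * w[:, None]).T @ q
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = cr - rotation @ cm
    diff = p @ rotation.T - q
    msd = float(np.sum(w * np.einsum("ij,ij->i", diff, diff)))
    return rotation, translation, float(np.sqrt(max(msd, 0.0)))


def superpose_coordinates(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """Return ``mobile`` rigidly superposed onto ``reference``."""
    rot, trans, _ = kabsch_superpose(mobile, reference, weights)
    return mobile @ rot.T + trans


def rmsd(
    a: np.ndarray, b: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Kabsch-optimal RMSD between two coordinate sets, nm."""
    return kabsch_superpose(a, b, weights)[2]


# ---------------------------------------------------------------------------
# Series over trajectories
# ---------------------------------------------------------------------------

def rmsd_series(
    traj: Trajectory,
    ref: Frame,
    mask: SelectionMask,
    ref_mask: SelectionMask | None = None,
    *,
    fit_mask: SelectionMask | None = None,
    fit_ref_mask: SelectionMask | None = None,
    weights: np.ndarray | None = None,
    label: str = "rmsd",
) -> TimeSeries:
    """Per-frame Kabsch RMSD of a trajectory against a reference frame.

    By default the fit (superposition) atoms and the measured atoms coincide.
    Passing ``fit_mask``/``fit_ref_mask`` superposes globally on those atoms
    and measures the RMSD on ``mask`` without refitting — the convention used
    for regional RMSDs after a whole-domain Cα alignment.
    """
    ref_mask = ref_mask if ref_mask is not None else mask
    if len(ref_mask) != len(mask):
        raise ConfigurationError("mask and ref_mask must have equal lengths")
    refit = fit_mask is None
    if (fit_mask is None) != (fit_ref_mask is None):
        raise ConfigurationError("fit_mask and fit_ref_mask must be given together")
    ref_meas = ref.coordinates[ref_mask.array]
    values = np.empty(traj.n_frames)
    if refit:
        for i, frame in enumerate(traj.frames):
            values[i] = kabsch_superpose(
                frame.coordinates[mask.array], ref_meas, weights
            )[2]
    else:
        ref_fit = ref.coordinates[fit_ref_mask.array]
        for i, frame in enumerate(traj.frames):
            rot, trans, _ = kabsch_superpose(
                frame.coordinates[fit_mask.array], ref_fit, weights
            )
            moved = frame.coordinates[mask.array] @ rot.T + trans
            diff = moved - ref_meas
            values[i] = np.sqrt(np.mean(np.einsum("ij,ij->i", diff, diff)))
    return TimeSeries(traj.times, values, label=label, units="nm")


def delta_rmsd_series(traj: Trajectory, refs: ReferencePair) -> TimeSeries:
    """Two-reference ΔRMSD per frame: RMSD to closed minus RMSD to open, nm.

    Negative values mean closed-like; a frame identical to the closed
    reference scores exactly minus the open-closed reference RMSD.
    """
    to_closed = rmsd_series(
        traj, refs.closed_frame, refs.mask_traj, refs.mask_closed, label="rmsd_closed"
    )
    to_open = rmsd_series(
        traj, refs.open_frame, refs.mask_traj, refs.mask_open, label="rmsd_open"
    )
    return TimeSeries(
        traj.times, to_closed.values - to_open.values,
        label="delta_rmsd", units="nm",
        meta={"convention": "closed_minus_open"},
    )


def iterative_mean_structure(
    traj: Trajectory,
    mask: SelectionMask,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Converged mean structure and the superposed mask coordinates.

    Frames are superposed on a running mean until the mean moves by less than
    ``tol`` nm RMS; returns ``(mean (m, 3), superposed (n_frames, m, 3))``.
    """
    if traj.n_frames < 2:
        raise InsufficientDataError("need at least 2 frames for a mean structure")
    coords = traj.coordinate_array()[:, mask.array]
    ref = coords[0]
    for _ in range(max_iter):
        fitted = np.stack([superpose_coordinates(c, ref) for c in coords])
        mean = fitted.mean(axis=0)
        shift = np.sqrt(np.mean(np.sum((mean - ref) ** 2, axis=1)))
        ref = mean
        if shift < tol:
            break
    return ref, np.stack([superpose_coordinates(c, ref) for c in coords])


def rmsf(
    traj: Trajectory,
    mask: SelectionMask,
    superpose: bool = True,
    tol: float = 1e-6,
) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the mean structure, nm.

    With ``superpose`` (default) frames are first aligned on the iteratively
    converged mean of the selected atoms; without it, raw coordinates are
    used (appropriate for pre-aligned or synthetic data).
    """
    if traj.n_frames < 2:
        raise InsufficientDataError("RMSF needs at least 2 frames")
    if superpose:
        mean, fitted = iterative_mean_structure(traj, mask, tol=tol)
    else:
        fitted = traj.coordinate_array()[:, mask.array]
        mean = fitted.mean(axis=0)
    dev = fitted - mean
    return np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))


def residue_rmsf(traj: Trajectory, superpose: bool = True):
    """Per-residue RMSF table (chain, resid, rmsf_nm) using each residue's Cα."""
    import pandas as pd

    from .structio import select

    ca = select(traj.topology, "alphacarbon")
    if len(ca) == 0:
        raise InsufficientDataError("no alpha-carbon atoms in topology")
    values = rmsf(traj, ca, superpose=superpose)
    atoms = [traj.topology.atoms[i] for i in ca.indices]
    return pd.DataFrame(
        {"chain": [a.chain for a in atoms], "resid": [a.resid for a in atoms],
         "rmsf_nm": values}
    )


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def minimum_image_displacement(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    Only orthorhombic (diagonal) boxes are supported; triclinic boxes raise a
    configuration error.
    """
    box = np.asarray(box, dtype=float)
    if not np.allclose(box, np.diag(np.diag(box))):
        raise ConfigurationError("minimum image supports orthorhombic boxes only")
    lengths = np.diag(box)
    if np.any(lengths <= 0):
        raise ConfigurationError("box lengths must be positive")
    return delta - lengths * np.round(delta / lengths)


def distance_series(
    traj: Trajectory,
    mask_a: SelectionMask,
    mask_b: SelectionMask,
    use_pbc: bool = False,
    mass_weighted: bool = False,
    label: str = "distance",
) -> TimeSeries:
    """Per-frame distance between two atoms or group centroids, nm.

    Groups are reduced to unweighted centroids unless ``mass_weighted``.
    With ``use_pbc`` the minimum-image distance is taken (requires a box on
    every frame). PBC defaults to off: protein-internal distances assume the
    molecule is whole.
    """
    if len(mask_a) == 0 or len(mask_b) == 0:
        raise ConfigurationError("distance selections must be non-empty")
    masses = traj.topology.masses
    wa = masses[mask_a.array] if mass_weighted else np.ones(len(mask_a))
    wb = masses[mask_b.array] if mass_weighted else np.ones(len(mask_b))
    wa = wa / wa.sum()
    wb = wb / wb.sum()
    values = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        ca = wa @ frame.coordinates[mask_a.array]
        cb = wb @ frame.coordinates[mask_b.array]
        delta = ca - cb
        if use_pbc:
            if frame.box is None:
                raise ConfigurationError("use_pbc requested but frame has no box")
            delta = minimum_image_displacement(delta, frame.box)
        values[i] = np.linalg.norm(delta)
    return TimeSeries(traj.times, values, label=label, units="nm")
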