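"""Synthetic inputs with exact ground truth for every analysis stage.

The generator emulates, at toy scale, the structure of a ligand-binding-
domain simulation study: a Cα-resolution four-helix bundle with an "open"
and a "closed" reference conformation differing by a rigid swing of the
terminal helix (the helix-12 stand-in), staged open→closed transition
trajectories with Gaussian positional noise, scripted solvent particles with
known shell membership and bridging intervals, planted hydrogen-bond
geometries at known occupancy, and Gaussian ensembles with a prescribed
mass-weighted covariance spectrum for entropy validation.

Every generator is a pure function of its spec and seed. Ground-truth tables
are returned alongside the data so downstream analyses can be scored without
re-deriving any geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import GenerationError
from .geometry import ReferencePair, kabsch_superpose
from .solvation import ResidenceInterval, _runs_from_bool
from .structio import AtomRecord, Frame, Topology, Trajectory, select

__all__ = [
    "SyntheticSpec", "WaterEvent", "TransitionTruth", "SolventTruth",
    "make_references", "make_transition_trajectory", "make_gaussian_ensemble",
    "plant_solvent", "make_hbond_trajectory", "default_water_schedule",
]

#: First author residue number of the toy bundle; chosen so the two bridge
#: pseudo-atoms land on residues 755 (Trp NE1 stand-in) and 756 (Val backbone
#: N stand-in), echoing the real receptor's numbering.
RESID_START = 711

#: Closed-state threshold on ΔRMSD, nm (negative = closed-like).
CLOSED_THRESHOLD = -0.1


@dataclass(frozen=True)
class WaterEvent:
    """One scripted membership episode of a water particle.

    kind: 'shell' (inside the first shell, well within the cutoff),
    'shell_boundary' (exactly at the shell cutoff), or 'bridge' (at the
    midpoint of the two bridge-site atoms, hence within the bridge cutoff of
    both). Frames outside every event place the water far from the solute.
    """

    water: int
    start: int
    end: int   # inclusive
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("shell", "shell_boundary", "bridge"):
            raise GenerationError(f"unknown water event kind {self.kind!r}")
        if self.end < self.start or self.start < 0:
            raise GenerationError("water event frame range invalid")


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    Defaults give a 60-residue four-helix bundle whose open and closed
    references differ by 0.6 nm Cα RMSD, 1000 frames spaced 100 ps with
    0.02 nm per-coordinate Gaussian noise, and a three-stage transition
    schedule (fast core formation, fast helix-12 docking, slow loop
    adjustment: frames 0-30, 30-50, 50-999).
    """

    n_residues: int = 60
    state_separation: float = 0.6     # nm, Cα RMSD open vs closed
    noise_sigma: float = 0.02         # nm, per-coordinate Gaussian noise
    stage_schedule: list[tuple[int, int, float]] | None = None
    n_frames: int = 1000
    frame_spacing_ps: float = 100.0
    n_waters: int = 0
    water_schedule: list[WaterEvent] | None = None
    shell_cutoff: float = 0.5         # nm, used for boundary placements
    bridge_cutoff: float = 0.35
    hbond_occupancy: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 8 or self.n_residues % 4:
            raise GenerationError("n_residues must be a multiple of 4, >= 8")
        if self.state_separation < 0 or self.noise_sigma < 0:
            raise GenerationError("state_separation and noise_sigma must be >= 0")
        if self.n_frames < 1 or self.frame_spacing_ps <= 0:
            raise GenerationError("need n_frames >= 1 and positive frame spacing")
        if self.water_schedule:
            for ev in self.water_schedule:
                if ev.end >= self.n_frames:
                    raise GenerationError(
                        f"water event for water {ev.water} ends at frame {ev.end}, "
                        f"beyond the {self.n_frames}-frame trajectory"
                    )
                if ev.water >= max(self.n_waters, 0):
                    raise GenerationError(
                        f"water event references water {ev.water} but only "
                        f"{self.n_waters} waters exist"
                    )

    def resolved_stage_schedule(self) -> list[tuple[int, int, float]]:
        """The staged transition plan; defaults mirror the fast/fast/slow pattern."""
        if self.stage_schedule is not None:
            return list(self.stage_schedule)
        n = self.n_frames
        s1 = max(1, round(0.03 * n))
        s2 = max(s1 + 1, round(0.05 * n))
        return [(0, s1, 0.55), (s1, s2, 0.85), (s2, n - 1, 1.0)]


# ---------------------------------------------------------------------------
# References
# ---------------------------------------------------------------------------

def _helix_bundle_ca(n_residues: int) -> np.ndarray:
    """Cα coordinates (nm) of an ideal four-helix bundle."""
    per = n_residues // 4
    offsets = [(0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (1.0, 1.0)]
    coords = []
    for h, (ox, oy) in enumerate(offsets):
        direction = 1.0 if h % 2 == 0 else -1.0
        for j in range(per):
            theta = math.radians(100.0 * j)
            coords.append((
                ox + 0.23 * math.cos(theta),
                oy + 0.23 * math.sin(theta),
                direction * 0.15 * j - (0.0 if direction > 0 else -0.15 * (per - 1)),
            ))
    return np.array(coords)


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def _build_topology(spec: SyntheticSpec, n_waters: int = 0) -> tuple[Topology, dict]:
    """Topology of the toy bundle: one Cα per residue plus the two bridge
    pseudo-atoms (Trp NE1 on the last static residue, Val backbone N on the
    first mobile residue), optionally followed by water oxygens."""
    per = spec.n_residues // 4
    trp_resid = RESID_START + 3 * per - 1
    val_resid = trp_resid + 1
    atoms: list[AtomRecord] = []
    serial = 1
    layout = {"trp_resid": trp_resid, "val_resid": val_resid,
              "mobile_first_index": None, "ne1_index": None, "n_index": None,
              "water_indices": []}
    ca_indices = []
    for i in range(spec.n_residues):
        resid = RESID_START + i
        resname = "TRP" if resid == trp_resid else ("VAL" if resid == val_resid else "ALA")
        atoms.append(AtomRecord(serial, "CA", resname, resid, "A", "C", 12.011))
        ca_indices.append(len(atoms) - 1)
        serial += 1
        if resid == trp_resid:
            layout["ne1_index"] = len(atoms)
            atoms.append(AtomRecord(serial, "NE1", "TRP", resid, "A", "N", 14.007))
            serial += 1
        elif resid == val_resid:
            layout["mobile_first_index"] = len(atoms) - 1
            layout["n_index"] = len(atoms)
            atoms.append(AtomRecord(serial, "N", "VAL", resid, "A", "N", 14.007))
            serial += 1
    for w in range(n_waters):
        layout["water_indices"].append(len(atoms))
        atoms.append(AtomRecord(serial, "O", "SOL", w + 1, "W", "O", 15.999))
        serial += 1
    layout["ca_indices"] = ca_indices
    return Topology(atoms), layout


def _place_pseudo_atoms(coords: np.ndarray, layout: dict, top: Topology) -> None:
    """Put NE1 and the Val N on the midline between their residues' Cαs,
    0.3 nm apart, so a midpoint water bridges them in every state."""
    ca_by_resid = {top.atoms[i].resid: i for i in layout["ca_indices"]}
    ca_trp = coords[ca_by_resid[layout["trp_resid"]]]
    ca_val = coords[ca_by_resid[layout["val_resid"]]]
    u = ca_val - ca_trp
    norm = np.linalg.norm(u)
    u = u / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
    mid = 0.5 * (ca_trp + ca_val)
    coords[layout["ne1_index"]] = mid - 0.15 * u
    coords[layout["n_index"]] = mid + 0.15 * u


def make_references(spec: SyntheticSpec | None = None) -> ReferencePair:
    """Open and closed toy references with exact Cα RMSD ``state_separation``.

    The closed structure rotates the terminal helix about a hinge through its
    first Cα, is Kabsch-aligned back onto the open structure, and the
    displacement field is then scaled so the Cα RMSD equals the requested
    separation exactly. Because the closed structure is optimally aligned to
    the open one, linear interpolations between them have exactly linear
    RMSDs to both endpoints — the property the ΔRMSD contract tests rely on.
    """
    spec = spec or SyntheticSpec()
    top, layout = _build_topology(spec)
    per = spec.n_residues // 4
    ca = _helix_bundle_ca(spec.n_residues)
    open_coords = np.zeros((top.n_atoms, 3))
    for k, idx in enumerate(layout["ca_indices"]):
        open_coords[idx] = ca[k]
    _place_pseudo_atoms(open_coords, layout, top)

    ca_mask = select(top, "alphacarbon")
    if spec.state_separation == 0:
        closed_coords = open_coords.copy()
    else:
        mobile_atoms = [i for i in layout["ca_indices"][3 * per:]]
        mobile_atoms.append(layout["n_index"])
        hinge = open_coords[layout["ca_indices"][3 * per]].copy()
        closed_coords = None
        for angle_deg in (30, 60, 90, 120, 150, 179):
            cand = open_coords.copy()
            rot = _rotation_about_axis(np.array([1.0, 0.0, 0.0]),
                                       math.radians(angle_deg))
            cand[mobile_atoms] = (cand[mobile_atoms] - hinge) @ rot.T + hinge
            _place_pseudo_atoms(cand, layout, top)
            # Align closed onto open over Cα, then scale the displacement
            # field to the exact target separation (shrink only, which keeps
            # the alignment optimal along the whole interpolation path).
            r, t, _ = kabsch_superpose(cand[ca_mask.array], open_coords[ca_mask.array])
            aligned = cand @ r.T + t
            dev = aligned[ca_mask.array] - open_coords[ca_mask.array]
            d0 = float(np.sqrt(np.mean(np.sum(dev**2, axis=1))))
            if d0 >= spec.state_separation:
                s = spec.state_separation / d0
                closed_coords = open_coords + s * (aligned - open_coords)
                break
        if closed_coords is None:
            raise GenerationError(
                f"cannot reach state separation {spec.state_separation} nm "
                "with the toy geometry"
            )

    open_frame = Frame(open_coords, time=0.0)
    closed_frame = Frame(closed_coords, time=0.0)
    return ReferencePair(
        open_topology=top, open_frame=open_frame,
        closed_topology=top, closed_frame=closed_frame,
        mask_open=ca_mask, mask_closed=ca_mask, mask_traj=ca_mask,
    )


# ---------------------------------------------------------------------------
# Transition trajectories
# ---------------------------------------------------------------------------

@dataclass
class TransitionTruth:
    """Ground truth of a staged transition trajectory."""

    state_fraction: np.ndarray     # per-frame closed-state fraction f
    noise_free_delta: np.ndarray   # ΔRMSD of the noise-free interpolation, nm
    threshold: float               # closed criterion used, nm
    crossing_frame: int | None     # first noise-free frame with ΔRMSD <= threshold
    seed: int


def _stage_fractions(schedule: list[tuple[int, int, float]], n_frames: int) -> np.ndarray:
    f = np.zeros(n_frames)
    prev_target = 0.0
    for start, end, target in schedule:
        if not (0 <= start <= end < n_frames):
            raise GenerationError(f"stage ({start}, {end}) outside frame range")
        span = max(end - start, 1)
        for t in range(start, end + 1):
            f[t] = prev_target + (target - prev_target) * (t - start) / span
        if end + 1 < n_frames:
            f[end + 1:] = target
        prev_target = target
    return np.clip(f, 0.0, 1.0)


def make_transition_trajectory(
    spec: SyntheticSpec | None = None,
    refs: ReferencePair | None = None,
    crossing_frame: int | None = None,
    threshold: float = CLOSED_THRESHOLD,
) -> tuple[Trajectory, ReferencePair, TransitionTruth]:
    """Staged open→closed trajectory with Gaussian noise and exact truth.

    Frames interpolate the references following the spec's stage schedule.
    With ``crossing_frame`` the schedule is replaced by a linear ramp whose
    noise-free ΔRMSD crosses ``threshold`` exactly at that frame (the
    standard acceptance scenario plants the crossing at frame 400 of 1000).
    """
    spec = spec or SyntheticSpec()
    refs = refs or make_references(spec)
    n = spec.n_frames
    d_sep = spec.state_separation
    if crossing_frame is not None:
        if d_sep <= 0 or not (-d_sep < threshold < d_sep):
            raise GenerationError(
                "threshold must lie strictly between -separation and +separation"
            )
        if not (0 < crossing_frame < n):
            raise GenerationError("crossing_frame must lie inside the trajectory")
        f_star = (1.0 - threshold / d_sep) / 2.0
        # put the continuous crossing half a frame early, so the requested
        # frame is the first one at or below the threshold with a clear margin
        ramp_end = (crossing_frame - 0.5) / f_star
        f = np.minimum(np.arange(n) / ramp_end, 1.0)
    else:
        f = _stage_fractions(spec.resolved_stage_schedule(), n)

    open_all = refs.open_frame.coordinates
    delta_all = refs.closed_frame.coordinates - open_all
    rng = np.random.default_rng(spec.seed)
    times = np.arange(n) * spec.frame_spacing_ps
    frames = []
    for t in range(n):
        coords = open_all + f[t] * delta_all
        if spec.noise_sigma > 0:
            coords = coords + rng.normal(0.0, spec.noise_sigma, coords.shape)
        frames.append(Frame(coords, time=times[t]))
    traj = Trajectory(refs.open_topology, frames)

    noise_free_delta = (1.0 - 2.0 * f) * d_sep
    below = np.flatnonzero(noise_free_delta <= threshold)
    crossing = int(below[0]) if below.size else None
    truth = TransitionTruth(
        state_fraction=f, noise_free_delta=noise_free_delta,
        threshold=threshold, crossing_frame=crossing, seed=spec.seed,
    )
    return traj, refs, truth


# ---------------------------------------------------------------------------
# Gaussian ensembles for entropy validation
# ---------------------------------------------------------------------------

def make_gaussian_ensemble(
    eigenvalues: np.ndarray,
    masses: np.ndarray,
    n_frames: int = 20000,
    temperature: float = 300.0,
    seed: int = 0,
) -> tuple[Trajectory, dict]:
    """Sample a mean-zero Gaussian ensemble with a prescribed spectrum.

    ``eigenvalues`` (nm² amu, length 3m) prescribe the mass-weighted
    covariance spectrum; coordinate j of atom a is drawn independently with
    variance λ_j / m_a, so the mass-weighted covariance is diagonal with the
    prescribed eigenvalues. Returns the trajectory and the closed-form
    quasi-harmonic and Schlitter entropies of the prescribed spectrum.
    No rigid-body motion is added, so entropy estimation on these ensembles
    should use ``superpose=False``.
    """
    from .ensembles import harmonic_mode_entropy

    eigenvalues = np.asarray(eigenvalues, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if np.any(eigenvalues <= 0) or np.any(masses <= 0):
        raise GenerationError("eigenvalues and masses must be positive")
    m = masses.size
    if eigenvalues.size != 3 * m:
        raise GenerationError(
            f"need 3 x {m} = {3 * m} eigenvalues, got {eigenvalues.size}"
        )
    atoms = [
        AtomRecord(i + 1, "CA", "ALA", i + 1, "A", "C", float(masses[i]))
        for i in range(m)
    ]
    top = Topology(atoms)
    sigma = np.sqrt(eigenvalues / np.repeat(masses, 3))
    rng = np.random.default_rng(seed)
    samples = rng.normal(0.0, 1.0, (n_frames, 3 * m)) * sigma
    frames = [
        Frame(samples[i].reshape(m, 3), time=float(i)) for i in range(n_frames)
    ]
    closed_form = {
        "quasiharmonic": harmonic_mode_entropy(
            eigenvalues, temperature, "quasiharmonic").total,
        "schlitter": harmonic_mode_entropy(
            eigenvalues, temperature, "schlitter").total,
    }
    return Trajectory(top, frames), closed_form


# ---------------------------------------------------------------------------
# Scripted solvent
# ---------------------------------------------------------------------------

@dataclass
class SolventTruth:
    """Planted solvent ground truth."""

    shell_counts: np.ndarray                 # per-frame first-shell count
    bridge_intervals: list[ResidenceInterval]
    schedule: list[WaterEvent]


def default_water_schedule(n_frames: int, n_waters: int) -> list[WaterEvent]:
    """A simple scripted solvent plan: water 0 bridges for ~30% of the run,
    the rest visit the shell in staggered episodes."""
    events = []
    if n_waters >= 1 and n_frames >= 5:
        events.append(WaterEvent(0, n_frames // 10, (n_frames * 2) // 5, "bridge"))
    for w in range(1, n_waters):
        start = (w * 7) % max(n_frames - 3, 1)
        end = min(start + 2 + (w % 5), n_frames - 1)
        events.append(WaterEvent(w, start, end, "shell"))
    return events


def plant_solvent(
    traj: Trajectory,
    spec: SyntheticSpec,
) -> tuple[Trajectory, SolventTruth]:
    """Append scripted water oxygens to a toy-bundle trajectory.

    Each water follows its :class:`WaterEvent` schedule: during 'bridge'
    episodes it sits at the midpoint of the two bridge-site atoms, during
    'shell' episodes 0.3 nm outside a surface Cα, during 'shell_boundary'
    episodes exactly at the shell cutoff, and otherwise far from the solute.
    Returns the extended trajectory and the exact per-frame truth.
    """
    if spec.n_waters <= 0:
        raise GenerationError("spec.n_waters must be positive to plant solvent")
    schedule = (spec.water_schedule if spec.water_schedule is not None
                else default_water_schedule(spec.n_frames, spec.n_waters))
    if len(traj) != spec.n_frames:
        raise GenerationError(
            f"trajectory has {len(traj)} frames but spec says {spec.n_frames}"
        )
    old_top = traj.topology
    ne1_candidates = [i for i, a in enumerate(old_top.atoms) if a.name == "NE1"]
    n_candidates = [i for i, a in enumerate(old_top.atoms)
                    if a.name == "N" and a.resname == "VAL"]
    if len(ne1_candidates) != 1 or len(n_candidates) != 1:
        raise GenerationError(
            "trajectory lacks the two bridge-site pseudo-atoms (TRP NE1, VAL N)"
        )
    site_a, site_b = ne1_candidates[0], n_candidates[0]

    # Rebuild the topology with water oxygens appended.
    serial0 = max(a.serial for a in old_top.atoms)
    waters = [
        AtomRecord(serial0 + w + 1, "O", "SOL", w + 1, "W", "O", 15.999)
        for w in range(spec.n_waters)
    ]
    new_top = Topology(list(old_top.atoms) + waters)

    solute_xyz0 = traj.frames[0].coordinates
    centroid = solute_xyz0.mean(axis=0)
    anchor_idx = 0  # first Cα of the bundle as the shell anchor
    # Per-frame per-water kind (None outside every event)
    kind_grid: list[list[str | None]] = [
        [None] * spec.n_frames for _ in range(spec.n_waters)
    ]
    for ev in schedule:
        for t in range(ev.start, ev.end + 1):
            kind_grid[ev.water][t] = ev.kind

    far_base = solute_xyz0.max(axis=0) + 5.0
    new_frames = []
    for t, frame in enumerate(traj.frames):
        solute = frame.coordinates
        anchor = solute[anchor_idx]
        u = anchor - solute.mean(axis=0)
        u = u / np.linalg.norm(u)
        wpos = np.empty((spec.n_waters, 3))
        for w in range(spec.n_waters):
            kind = kind_grid[w][t]
            if kind is None:
                wpos[w] = far_base + np.array([5.0 + 2.0 * w, 0.0, 0.0])
            elif kind == "bridge":
                wpos[w] = 0.5 * (solute[site_a] + solute[site_b])
            elif kind == "shell":
                wpos[w] = anchor + 0.3 * u
            else:
                # shell_boundary: at the cutoff, biased inward by one part in
                # 1e12 so the inclusive (≤) rule holds under float rounding
                wpos[w] = anchor + spec.shell_cutoff * (1.0 - 1e-12) * u
            if kind in ("shell", "shell_boundary"):
                da = np.linalg.norm(wpos[w] - solute[site_a])
                db = np.linalg.norm(wpos[w] - solute[site_b])
                if da <= spec.bridge_cutoff and db <= spec.bridge_cutoff:
                    raise GenerationError(
                        f"shell placement of water {w} at frame {t} would "
                        "accidentally bridge the two sites"
                    )
        new_frames.append(Frame(np.vstack([solute, wpos]),
                                box=frame.box, time=frame.time))
    new_traj = Trajectory(new_top, new_frames)

    shell_counts = np.array([
        sum(kind_grid[w][t] is not None for w in range(spec.n_waters))
        for t in range(spec.n_frames)
    ], dtype=float)
    dt = new_traj.frame_spacing()
    times = new_traj.times
    intervals: list[ResidenceInterval] = []
    for w in range(spec.n_waters):
        bridging = np.array([kind_grid[w][t] == "bridge"
                             for t in range(spec.n_frames)])
        for start, end in _runs_from_bool(bridging, 0):
            intervals.append(ResidenceInterval(
                water_id=("W", w + 1), start_time=float(times[start]),
                end_time=float(times[end]), site="bridge",
                duration=float(times[end] - times[start] + dt),
            ))
    intervals.sort(key=lambda iv: (iv.start_time, iv.water_id))
    return new_traj, SolventTruth(shell_counts, intervals, list(schedule))


# ---------------------------------------------------------------------------
# Planted hydrogen bonds
# ---------------------------------------------------------------------------

def make_hbond_trajectory(
    occupancy: float = 0.5,
    n_frames: int = 100,
    frame_spacing_ps: float = 2.0,
) -> tuple[Trajectory, float]:
    """A three-atom donor/hydrogen/acceptor system with planted occupancy.

    The first ``round(occupancy * n_frames)`` frames hold a textbook
    hydrogen-bond geometry (D-A 0.28 nm, angle 180°); the rest move the
    acceptor to 0.60 nm. Returns the trajectory and the exact planted
    fraction (which may differ from ``occupancy`` by rounding).
    """
    if not 0.0 <= occupancy <= 1.0:
        raise GenerationError("occupancy must be in [0, 1]")
    atoms = [
        AtomRecord(1, "ND", "ASN", 1, "A", "N", 14.007),
        AtomRecord(2, "HD", "ASN", 1, "A", "H", 1.008),
        AtomRecord(3, "OA", "GLN", 2, "A", "O", 15.999),
    ]
    top = Topology(atoms)
    k = round(occupancy * n_frames)
    on = np.array([[0.0, 0.0, 0.0], [0.10, 0.0, 0.0], [0.28, 0.0, 0.0]])
    off = np.array([[0.0, 0.0, 0.0], [0.10, 0.0, 0.0], [0.60, 0.0, 0.0]])
    frames = [
        Frame((on if t < k else off).copy(), time=t * frame_spacing_ps)
        for t in range(n_frames)
    ]
    return Trajectory(top, frames), k / n_frames
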