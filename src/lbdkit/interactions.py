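"""Hydrogen bonds, salt bridges, charge centers and screened Coulomb energies.

Hydrogen-bond criterion: donor-acceptor distance ≤ 0.35 nm and, when an
explicit hydrogen is given, donor-H-acceptor angle ≥ 120°. These are
standard-practice geometric defaults.

The electrostatic model is a dielectric-screened point-charge interaction
with ε = 80 (bulk water), intended for fully solvent-exposed residues. The
default form is the physical Coulomb potential E = k_C q1 q2 / (ε d); an
``as_printed_1_over_d2`` form with d² in the denominator is also available
for fidelity with a published variant of the formula, and is flagged as
non-standard in output metadata because 1/d² is dimensionally a force law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, SelectionError
from .geometry import TimeSeries, minimum_image_displacement
from .structio import Frame, SelectionMask, Topology, Trajectory

__all__ = [
    "HBondSpec", "ChargeCenter", "CoulombSpec", "COULOMB_KC",
    "hbond_present", "hbond_occupancy", "charge_center_position",
    "coulomb_energy", "salt_bridge_series", "charge_center_distance_series",
]

#: Coulomb constant in kJ mol^-1 nm e^-2: e^2 N_A / (4 pi eps0), about 138.935458
#: (the value MD packages use), derived here from CODATA constants.
from scipy.constants import N_A as _NA, e as _E, epsilon_0 as _EPS0

COULOMB_KC = _E**2 * _NA / (4.0 * np.pi * _EPS0) * 1e6

#: Side-chain point used to represent each charged residue type:
#: a single atom, or a pair whose midpoint is taken (carboxylate oxygens).
CHARGED_SIDECHAIN_POINT = {
    "LYS": ("NZ",),
    "ARG": ("CZ",),
    "GLU": ("OE1", "OE2"),
    "ASP": ("OD1", "OD2"),
    "HIS": ("ND1", "NE2"),
}

#: Atoms entering salt-bridge N-O minimum distances.
BASIC_NITROGENS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2")}
ACIDIC_OXYGENS = {"GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2")}


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass
class HBondSpec:
    """Geometric hydrogen-bond criterion between three single-atom masks."""

    donor: SelectionMask
    acceptor: SelectionMask
    hydrogen: SelectionMask | None = None
    d_cutoff: float = 0.35      # nm, donor-acceptor
    angle_cutoff: float = 120.0  # degrees, donor-H-acceptor minimum

    def __post_init__(self) -> None:
        if self.d_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ConfigurationError("hydrogen-bond cutoffs must be positive")
        for name, mask in (("donor", self.donor), ("acceptor", self.acceptor),
                           ("hydrogen", self.hydrogen)):
            if mask is not None and len(mask) != 1:
                raise ConfigurationError(f"{name} mask must contain exactly one atom")


def hbond_present(frame: Frame, spec: HBondSpec) -> bool:
    """True iff the donor-acceptor distance and (optionally) the
    donor-H-acceptor angle satisfy the criterion in this frame."""
    coords = frame.coordinates
    n = coords.shape[0]
    for mask in (spec.donor, spec.acceptor, spec.hydrogen):
        if mask is not None and mask.indices[0] >= n:
            raise SelectionError(
                f"hydrogen-bond atom index {mask.indices[0]} out of range"
            )
    d_pos = coords[spec.donor.indices[0]]
    a_pos = coords[spec.acceptor.indices[0]]
    if np.linalg.norm(d_pos - a_pos) > spec.d_cutoff:
        return False
    if spec.hydrogen is None:
        return True
    h_pos = coords[spec.hydrogen.indices[0]]
    v1 = d_pos - h_pos
    v2 = a_pos - h_pos
    denom = np.linalg.norm(v1) * np.linalg.norm(v2)
    if denom == 0.0:
        return False
    cosang = np.clip(np.dot(v1, v2) / denom, -1.0, 1.0)
    angle = np.degrees(np.arccos(cosang))
    return bool(angle >= spec.angle_cutoff)


def hbond_occupancy(traj: Trajectory, spec: HBondSpec) -> float:
    """Fraction of frames in which the hydrogen bond is present, in [0, 1]."""
    if traj.n_frames == 0:
        raise ConfigurationError("occupancy needs at least one frame")
    hits = sum(hbond_present(frame, spec) for frame in traj.frames)
    return hits / traj.n_frames


# ---------------------------------------------------------------------------
# Charge centers
# ---------------------------------------------------------------------------

@dataclass
class ChargeCenter:
    """A cluster of charged residues reduced to one representative point.

    Atom rule ``sidechain_charged`` uses the charged side-chain point of each
    member residue (Lys NZ; Arg CZ; Glu/Asp carboxylate-oxygen midpoint);
    ``alphacarbon`` uses each member's Cα. The center position is the
    unweighted centroid of the member points. ``charge`` is the net charge
    in units of e.

    Two literature presets exist for the progesterone-receptor LBD surface:
    the helix-12 N-terminal acidic patch (E904/E907/E911, net −3) and the
    helix-3 C-terminal basic patch (K733/R740, net +2).
    """

    members: list[tuple[str, int]]
    charge: float
    atom_rule: str = "sidechain_charged"
    label: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ConfigurationError("charge center needs at least one member residue")
        if self.atom_rule not in ("sidechain_charged", "alphacarbon"):
            raise ConfigurationError(f"unknown atom rule {self.atom_rule!r}")


def h12nt_center(chain: str = "A") -> ChargeCenter:
    """Helix-12 N-terminal negative charge center preset (E904, E907, E911)."""
    return ChargeCenter([(chain, 904), (chain, 907), (chain, 911)],
                        charge=-3.0, label="H12NT")


def h3ct_center(chain: str = "A") -> ChargeCenter:
    """Helix-3 C-terminal positive charge center preset (K733, R740)."""
    return ChargeCenter([(chain, 733), (chain, 740)], charge=+2.0, label="H3CT")


def basic_patch_methods_preset(chain: str = "A") -> ChargeCenter:
    """Alternative basic-patch preset (K731, K734, K740) from the methods-level
    residue list; the default preset is :func:`h3ct_center`."""
    return ChargeCenter([(chain, 731), (chain, 734), (chain, 740)],
                        charge=+3.0, label="H3CT_alt")


def _residue_point(top: Topology, frame: Frame, chain: str, resid: int,
                   rule: str) -> np.ndarray:
    if rule == "alphacarbon":
        idx = top.find_atom(chain, resid, "CA")
        return frame.coordinates[idx]
    resname = top.atoms[top.atom_indices(chain, resid)[0]].resname
    names = CHARGED_SIDECHAIN_POINT.get(resname)
    if names is None:
        raise SelectionError(
            f"residue {resname} (chain={chain!r}, resid={resid}) has no "
            "charged side-chain point"
        )
    missing = []
    points = []
    for name in names:
        try:
            points.append(frame.coordinates[top.find_atom(chain, resid, name)])
        except SelectionError:
            missing.append(name)
    if missing:
        raise SelectionError(
            f"residue (chain={chain!r}, resid={resid}) missing atoms: "
            + ", ".join(missing)
        )
    return np.mean(points, axis=0)


def charge_center_position(
    frame: Frame, top: Topology, center: ChargeCenter
) -> np.ndarray:
    """Unweighted centroid of the center's member points in this frame, nm."""
    points = [
        _residue_point(top, frame, chain, resid, center.atom_rule)
        for chain, resid in center.members
    ]
    return np.mean(points, axis=0)


def charge_center_distance_series(
    traj: Trajectory, center_a: ChargeCenter, center_b: ChargeCenter,
    use_pbc: bool = False,
) -> TimeSeries:
    """Per-frame distance between two charge-center centroids, nm."""
    values = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        pa = charge_center_position(frame, traj.topology, center_a)
        pb = charge_center_position(frame, traj.topology, center_b)
        delta = pa - pb
        if use_pbc:
            if frame.box is None:
                raise ConfigurationError("use_pbc requested but frame has no box")
            delta = minimum_image_displacement(delta, frame.box)
        values[i] = np.linalg.norm(delta)
    label = f"{center_a.label or 'A'}-{center_b.label or 'B'}_distance"
    return TimeSeries(traj.times, values, label=label, units="nm")


# ---------------------------------------------------------------------------
# Coulomb energies
# ---------------------------------------------------------------------------

@dataclass
class CoulombSpec:
    """Dielectric-screened point-charge interaction.

    ``coulomb_1_over_d`` is the physical potential k_C q1 q2 / (ε d);
    ``as_printed_1_over_d2`` divides by d² instead and is flagged
    non-standard in metadata.
    """

    epsilon: float = 80.0
    form: str = "coulomb_1_over_d"

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be positive")
        if self.form not in ("coulomb_1_over_d", "as_printed_1_over_d2"):
            raise ConfigurationError(f"unknown Coulomb form {self.form!r}")

    @property
    def metadata(self) -> dict:
        return {
            "form": self.form,
            "epsilon": self.epsilon,
            "standard": self.form == "coulomb_1_over_d",
        }


def coulomb_energy(
    q1: float, q2: float, d: float, spec: CoulombSpec | None = None
) -> float:
    """Screened electrostatic energy of two point charges, kJ mol⁻¹.

    Charges in e, distance in nm.
    """
    spec = spec or CoulombSpec()
    if d <= 0:
        raise ConfigurationError(f"distance must be positive, got {d}")
    denom = d if spec.form == "coulomb_1_over_d" else d * d
    return COULOMB_KC * q1 * q2 / (spec.epsilon * denom)


def coulomb_energy_series(
    distances: TimeSeries, q1: float, q2: float, spec: CoulombSpec | None = None
) -> TimeSeries:
    spec = spec or CoulombSpec()
    values = np.array([coulomb_energy(q1, q2, d, spec) for d in distances.values])
    return TimeSeries(
        distances.times, values, label=f"{distances.label}_energy",
        units="kJ/mol", meta={**distances.meta, **spec.metadata, "q1": q1, "q2": q2},
    )


# ---------------------------------------------------------------------------
# Salt bridges
# ---------------------------------------------------------------------------

def _charged_group_atoms(top: Topology, chain: str, resid: int) -> tuple[str, list[int]]:
    """(polarity, atom indices) of a residue's charged group."""
    indices = top.atom_indices(chain, resid)
    resname = top.atoms[indices[0]].resname
    if resname in BASIC_NITROGENS:
        names, polarity = BASIC_NITROGENS[resname], "basic"
    elif resname in ACIDIC_OXYGENS:
        names, polarity = ACIDIC_OXYGENS[resname], "acidic"
    else:
        raise SelectionError(
            f"residue {resname} (chain={chain!r}, resid={resid}) has no charged group"
        )
    found = [i for i in indices if top.atoms[i].name in names]
    if not found:
        raise SelectionError(
            f"residue (chain={chain!r}, resid={resid}) lacks charged-group atoms "
            + ", ".join(names)
        )
    return polarity, found


def salt_bridge_series(
    traj: Trajectory,
    res_a: tuple[str, int],
    res_b: tuple[str, int],
    contact_cutoff: float = 0.4,
) -> TimeSeries:
    """Per-frame minimum N-O distance between two charged side chains, nm.

    One residue must be basic (Lys/Arg/His nitrogens) and the other acidic
    (Glu/Asp carboxylate oxygens). The contact flag (distance ≤ 0.4 nm by
    default) is stored in ``meta['contact']``.
    """
    pol_a, idx_a = _charged_group_atoms(traj.topology, *res_a)
    pol_b, idx_b = _charged_group_atoms(traj.topology, *res_b)
    if {pol_a, pol_b} != {"basic", "acidic"}:
        raise SelectionError(
            f"salt bridge needs one basic and one acidic residue, got "
            f"{pol_a} and {pol_b}"
        )
    values = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        a = frame.coordinates[idx_a]
        b = frame.coordinates[idx_b]
        delta = a[:, None, :] - b[None, :, :]
        values[i] = np.sqrt(np.einsum("ijk,ijk->ij", delta, delta).min())
    return TimeSeries(
        traj.times, values, label=f"saltbridge_{res_a[1]}_{res_b[1]}", units="nm",
        meta={"contact_cutoff": contact_cutoff,
              "contact": (values <= contact_cutoff).tolist()},
    )


def occupancy_table(traj: Trajectory, specs: dict[str, HBondSpec]):
    """Occupancies for a named set of hydrogen bonds as a DataFrame."""
    import pandas as pd

    rows = []
    for name, spec in specs.items():
        rows.append({"bond": name, "occupancy": hbond_occupancy(traj, spec)})
    return pd.DataFrame(rows)
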