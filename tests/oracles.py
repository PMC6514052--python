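"""Independent reference implementations used only to check lbdkit.

These deliberately take different algorithmic routes from the package:
quaternion (Horn) RMSD instead of SVD Kabsch, a list-based greedy clustering
instead of the boolean-matrix one, nested-loop distance features, and a
from-scratch harmonic mode sum for the entropy closed form.
"""

from __future__ import annotations

import numpy as np


def quaternion_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Minimum RMSD over proper rotations via Horn's quaternion method."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    n = p.shape[0]
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    m = pc.T @ qc
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam_max = np.linalg.eigvalsh(key)[-1]
    e0 = np.sum(pc * pc) + np.sum(qc * qc)
    return float(np.sqrt(max(e0 - 2.0 * lam_max, 0.0) / n))


def quaternion_rmsd_matrix(coords: np.ndarray) -> np.ndarray:
    n = coords.shape[0]
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = quaternion_rmsd(coords[i], coords[j])
    return mat


def greedy_cluster_reference(rmsd_matrix: np.ndarray, cutoff: float):
    """List-based reference of the gromos greedy clustering.

    Neighbour rule inclusive (<= cutoff); the medoid is the frame with the
    most remaining neighbours, ties to the lowest frame index.
    """
    n = rmsd_matrix.shape[0]
    remaining = list(range(n))
    assignment = [-1] * n
    medoids, sizes = [], []
    cid = 0
    while remaining:
        best, best_count = None, -1
        for i in remaining:
            count = sum(
                1 for j in remaining if j != i and rmsd_matrix[i, j] <= cutoff
            )
            if count > best_count:  # strict >, so the lowest index wins ties
                best, best_count = i, count
        members = [best] + [
            j for j in remaining if j != best and rmsd_matrix[best, j] <= cutoff
        ]
        for j in members:
            assignment[j] = cid
        medoids.append(best)
        sizes.append(len(members))
        remaining = [j for j in remaining if j not in members]
        cid += 1
    return np.array(assignment), np.array(medoids), np.array(sizes)


def nested_loop_distance_features(coords: np.ndarray) -> np.ndarray:
    """Upper-triangle pairwise distances, one row per frame, nested loops."""
    n_frames, m, _ = coords.shape
    rows = []
    for f in range(n_frames):
        row = []
        for i in range(m):
            for j in range(i + 1, m):
                row.append(float(np.linalg.norm(coords[f, i] - coords[f, j])))
        rows.append(row)
    return np.array(rows)


# Closed-form quantum harmonic oscillator entropy, written independently of
# the package (scipy constants, explicit per-mode loop).
def harmonic_entropy_closed_form(
    eigenvalues_nm2_amu, temperature: float, method: str = "quasiharmonic"
) -> float:
    from scipy.constants import Boltzmann, R, atomic_mass, hbar

    total = 0.0
    kt = Boltzmann * temperature
    for lam in np.asarray(eigenvalues_nm2_amu, float):
        lam_si = lam * 1e-18 * atomic_mass
        if lam_si <= 0:
            continue
        omega = np.sqrt(kt / lam_si)
        if method == "quasiharmonic":
            x = hbar * omega / kt
            total += R * (x / (np.exp(x) - 1.0) - np.log(1.0 - np.exp(-x)))
        else:
            total += 0.5 * R * np.log(1.0 + kt * np.e**2 * lam_si / hbar**2)
    return total


def coulomb_energy_from_constants(q1: float, q2: float, d_nm: float,
                                  epsilon: float) -> float:
    """Screened Coulomb energy in kJ/mol straight from CODATA constants."""
    from scipy.constants import N_A, e, epsilon_0

    d_m = d_nm * 1e-9
    energy_j_per_mol = (q1 * e) * (q2 * e) * N_A / (
        4.0 * np.pi * epsilon_0 * epsilon * d_m
    )
    return energy_j_per_mol / 1000.0


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR with sign fixing."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
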