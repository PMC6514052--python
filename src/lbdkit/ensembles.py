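"""Essential dynamics, configurational entropy, and conformational clustering.

Three ensemble-level views of a trajectory:

* PCA on Cα-Cα distance matrices (rotation/translation invariant by
  construction) or on superposed Cartesian coordinates (yields per-atom mode
  vectors for essential-dynamics visualisation).
* Quasi-harmonic configurational entropy from the eigenvalue spectrum of the
  mass-weighted Cartesian covariance, with the Schlitter upper-bound variant
  computed from the same spectrum.
* gromos clustering: greedily seed clusters from the frame with the most
  RMSD neighbours within a cutoff, remove it and its neighbours, repeat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InsufficientDataError
from .geometry import iterative_mean_structure, kabsch_superpose
from .structio import SelectionMask, Trajectory

__all__ = [
    "PCAResult", "EntropyResult", "ClusterResult",
    "distance_feature_matrix", "pca", "cartesian_pca",
    "quasiharmonic_entropy", "harmonic_mode_entropy", "gromos_cluster",
]

# Physical constants (SI unless noted)
KB = 1.380649e-23          # Boltzmann, J/K
HBAR = 1.054571817e-34     # reduced Planck, J s
GAS_R = 8.314462618        # molar gas constant, J mol-1 K-1
AMU = 1.66053906660e-27    # kg
NM2AMU_TO_SI = 1e-18 * AMU  # nm^2 amu -> m^2 kg

#: Covariance eigenvalues below this (nm^2 amu) are treated as rigid-body
#: remnants and discarded from the mode sum.
RIGID_BODY_TOL = 1e-8


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    mean: np.ndarray               # feature-space mean
    eigenvalues: np.ndarray        # full descending spectrum, feature units^2
    eigenvectors: np.ndarray       # (n_components, n_features), orthonormal
    projections: np.ndarray        # (n_frames, n_components)
    feature_kind: str              # "distance-matrix" | "cartesian"

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        k = self.eigenvectors.shape[0]
        if total <= 0:
            return np.zeros(k)
        return self.eigenvalues[:k] / total


def distance_feature_matrix(
    traj: Trajectory, mask: SelectionMask, stride: int = 1
) -> np.ndarray:
    """Pairwise-distance features: one row per strided frame.

    Columns are the upper-triangle (i < j, row-major) distances between the
    selected atoms, in nm — m(m-1)/2 of them. Because interatomic distances
    are invariant under rigid transforms, PCA on these features needs no
    prior superposition.
    """
    if stride <= 0:
        raise ConfigurationError(f"stride must be positive, got {stride}")
    m = len(mask)
    if m < 2:
        raise ConfigurationError("distance features need a mask of at least 2 atoms")
    iu = np.triu_indices(m, k=1)
    coords = traj.coordinate_array()[::stride, mask.array]
    diff = coords[:, :, None, :] - coords[:, None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=-1))
    return dist[:, iu[0], iu[1]]


def _fix_component_signs(eigenvectors: np.ndarray) -> np.ndarray:
    """Deterministic sign: the largest-magnitude loading of each PC is positive."""
    out = eigenvectors.copy()
    for i, vec in enumerate(out):
        j = int(np.argmax(np.abs(vec)))
        if vec[j] < 0:
            out[i] = -vec
    return out


def pca(features: np.ndarray, n_components: int = 2) -> PCAResult:
    """Principal component analysis as a covariance eigendecomposition.

    Features are column-mean-centred; components are sorted by descending
    eigenvalue (variance, with the 1/(n-1) convention) and carry a
    deterministic sign. The stored projections are the centred data's scores
    on the retained components.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise InsufficientDataError("PCA needs a 2-D feature matrix with >= 2 rows")
    n, p = x.shape
    mean = x.mean(axis=0)
    xc = x - mean
    # Thin SVD of the centred data: eigenvalues of the covariance are s^2/(n-1).
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    k = min(n_components, vt.shape[0])
    eigenvectors = _fix_component_signs(vt[:k])
    projections = xc @ eigenvectors.T
    return PCAResult(mean, eigenvalues, eigenvectors, projections, "distance-matrix")


def cartesian_pca(
    traj: Trajectory, mask: SelectionMask, n_components: int = 2
) -> PCAResult:
    """PCA on superposed Cartesian coordinates (essential dynamics).

    Frames are first superposed on their converged mean structure; each
    eigenvector reshapes to (m, 3) so the per-atom mode amplitude is the norm
    of that atom's 3-vector (see :func:`atom_mode_amplitudes`).
    """
    _, fitted = iterative_mean_structure(traj, mask)
    flat = fitted.reshape(fitted.shape[0], -1)
    result = pca(flat, n_components=n_components)
    result.feature_kind = "cartesian"
    return result


def atom_mode_amplitudes(result: PCAResult, component: int = 0) -> np.ndarray:
    """Per-atom amplitude of one Cartesian PCA mode (norm of each 3-vector)."""
    if result.feature_kind != "cartesian":
        raise ConfigurationError("per-atom amplitudes require cartesian PCA")
    vec = result.eigenvectors[component].reshape(-1, 3)
    return np.linalg.norm(vec, axis=1)


# ---------------------------------------------------------------------------
# Quasi-harmonic configurational entropy
# ---------------------------------------------------------------------------

@dataclass
class EntropyResult:
    total: float                   # J mol-1 K-1
    mode_frequencies: np.ndarray   # rad/s, retained modes
    eigenvalues: np.ndarray        # mass-weighted covariance spectrum, nm^2 amu
    n_modes_discarded: int
    method: str                    # "quasiharmonic" | "schlitter"
    temperature: float             # K

    def to_dict(self) -> dict:
        return {
            "total_J_per_mol_K": self.total,
            "method": self.method,
            "temperature_K": self.temperature,
            "n_modes_discarded": self.n_modes_discarded,
            "eigenvalues_nm2_amu": self.eigenvalues.tolist(),
            "mode_frequencies_rad_per_s": self.mode_frequencies.tolist(),
        }


def harmonic_mode_entropy(
    eigenvalues_nm2_amu: np.ndarray,
    temperature: float,
    method: str = "quasiharmonic",
    rigid_tol: float = RIGID_BODY_TOL,
) -> EntropyResult:
    """Entropy of a harmonic mode spectrum.

    Each eigenvalue λ of the mass-weighted covariance defines a quantum
    harmonic oscillator of frequency ω = sqrt(kB T / λ); the quasi-harmonic
    entropy is the sum of the oscillator entropies

        S = R Σ_i [ x_i / (exp(x_i) − 1) − ln(1 − exp(−x_i)) ],  x_i = ħω_i/kB T.

    The Schlitter variant, an upper bound computed from the same spectrum, is

        S = (R/2) Σ_i ln(1 + kB T e² λ_i / ħ²).

    Eigenvalues below ``rigid_tol`` (nm² amu) are discarded as rigid-body or
    numerically null modes.
    """
    if temperature <= 0:
        raise ConfigurationError(f"temperature must be positive, got {temperature}")
    if method not in ("quasiharmonic", "schlitter"):
        raise ConfigurationError(f"unknown entropy method {method!r}")
    lam = np.sort(np.asarray(eigenvalues_nm2_amu, dtype=float))[::-1]
    keep = lam >= rigid_tol
    n_discarded = int((~keep).sum())
    lam_kept = lam[keep]
    lam_si = lam_kept * NM2AMU_TO_SI
    kt = KB * temperature
    if lam_kept.size == 0:
        omega = np.array([])
        total = 0.0
    else:
        omega = np.sqrt(kt / lam_si)
        if method == "quasiharmonic":
            x = HBAR * omega / kt
            total = float(GAS_R * np.sum(x / np.expm1(x) - np.log1p(-np.exp(-x))))
        else:
            total = float(0.5 * GAS_R * np.sum(
                np.log1p(kt * np.e**2 * lam_si / HBAR**2)
            ))
    return EntropyResult(
        total=max(total, 0.0), mode_frequencies=omega, eigenvalues=lam,
        n_modes_discarded=n_discarded, method=method, temperature=temperature,
    )


def quasiharmonic_entropy(
    traj: Trajectory,
    mask: SelectionMask,
    temperature: float = 300.0,
    method: str = "quasiharmonic",
    superpose: bool = True,
    rigid_tol: float = RIGID_BODY_TOL,
) -> EntropyResult:
    """Configurational entropy of the selected atoms, J mol⁻¹ K⁻¹.

    Builds the mass-weighted covariance of the Cartesian coordinates and
    feeds its spectrum to :func:`harmonic_mode_entropy`. With ``superpose``
    (default) frames are first aligned on their converged mean structure to
    remove overall translation/rotation; disable it for ensembles generated
    without rigid-body motion, where alignment would perturb the spectrum.
    Fewer than 3m + 1 frames leaves the covariance rank-deficient (a warning,
    not an error).
    """
    import warnings

    if traj.n_frames < 2:
        raise InsufficientDataError("entropy needs at least 2 frames")
    if temperature <= 0:
        raise ConfigurationError(f"temperature must be positive, got {temperature}")
    if superpose:
        _, fitted = iterative_mean_structure(traj, mask)
    else:
        fitted = traj.coordinate_array()[:, mask.array]
    n, m, _ = fitted.shape
    if n < 3 * m + 1:
        warnings.warn(
            f"only {n} frames for {3 * m} degrees of freedom; "
            "the covariance is rank-deficient", stacklevel=2
        )
    masses = traj.topology.masses[mask.array]
    sqrt_m = np.sqrt(np.repeat(masses, 3))
    x = fitted.reshape(n, 3 * m)
    xc = (x - x.mean(axis=0)) * sqrt_m
    cov = xc.T @ xc / (n - 1)
    eigenvalues = np.linalg.eigvalsh(cov)
    return harmonic_mode_entropy(eigenvalues, temperature, method, rigid_tol)


# ---------------------------------------------------------------------------
# gromos clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    assignment: np.ndarray   # per-frame cluster id (0-based, formation order)
    medoids: np.ndarray      # representative frame index per cluster
    sizes: np.ndarray        # cluster sizes, non-increasing

    @property
    def n_clusters(self) -> int:
        return len(self.medoids)


def pairwise_rmsd_matrix(traj: Trajectory, mask: SelectionMask) -> np.ndarray:
    """Symmetric matrix of Kabsch RMSDs between all frame pairs, nm."""
    coords = traj.coordinate_array()[:, mask.array]
    n = coords.shape[0]
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = kabsch_superpose(coords[i], coords[j])[2]
    return mat


def gromos_cluster(
    traj: Trajectory,
    mask: SelectionMask,
    cutoff: float = 0.2,
    rmsd_matrix: np.ndarray | None = None,
) -> ClusterResult:
    """gromos conformational clustering at an RMSD cutoff (default 0.2 nm).

    Repeatedly: count each remaining frame's neighbours within the cutoff
    (inclusive, ≤), take the frame with the most as the next medoid (ties
    broken by the lowest frame index), assign it and its neighbours to a new
    cluster, remove them, and continue until no frames remain. Cluster sizes
    are non-increasing by construction.
    """
    if cutoff <= 0:
        raise ConfigurationError(f"cutoff must be positive, got {cutoff}")
    n = traj.n_frames
    if n == 0:
        raise InsufficientDataError("cannot cluster an empty trajectory")
    mat = pairwise_rmsd_matrix(traj, mask) if rmsd_matrix is None else rmsd_matrix
    neighbor = (mat <= cutoff)
    np.fill_diagonal(neighbor, False)
    remaining = np.ones(n, dtype=bool)
    assignment = np.full(n, -1, dtype=int)
    medoids: list[int] = []
    sizes: list[int] = []
    cluster_id = 0
    while remaining.any():
        counts = np.where(remaining, neighbor[:, remaining].sum(axis=1), -1)
        medoid = int(np.argmax(counts))  # argmax returns the lowest tied index
        members = remaining & neighbor[medoid]
        members[medoid] = True
        assignment[members] = cluster_id
        medoids.append(medoid)
        sizes.append(int(members.sum()))
        remaining &= ~members
        cluster_id += 1
    return ClusterResult(
        assignment=assignment, medoids=np.array(medoids, dtype=int),
        sizes=np.array(sizes, dtype=int),
    )
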