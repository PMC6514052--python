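# lbdkit

Trajectory analysis of nuclear-receptor **ligand-binding-domain (LBD)
helix-12 dynamics** — the open/closed conformational switch that decides
whether a receptor such as the progesterone receptor presents an agonistic
(co-activator-binding) or antagonistic surface.

The package is aimed at people analysing molecular-dynamics ensembles of
LBD-like systems who want the standard analysis battery as tested, reusable
library code rather than one-off scripts:

* **Two-reference ΔRMSD state tracking.** For each frame,
  `ΔRMSD = RMSD(frame, closed) − RMSD(frame, open)` over Cα atoms, with
  Kabsch-optimal superposition for every RMSD. Closed-like frames score
  negative; the closed-state criterion is `ΔRMSD ≤ −0.1 nm`, the open
  criterion `≥ +0.1 nm`, and the band in between is labelled *semi-open*.
* **RMSF** about an iteratively converged mean structure, per residue via Cα.
* **Essential-dynamics PCA** on Cα–Cα distance matrices (rigid-transform
  invariant by construction) or on superposed Cartesian coordinates (giving
  per-atom mode vectors).
* **Quasi-harmonic configurational entropy.** From the eigenvalues λᵢ of the
  mass-weighted coordinate covariance, each mode is a quantum harmonic
  oscillator with ω_i = √(k_B T / λᵢ) and

  S = R Σᵢ [ xᵢ/(e^{xᵢ}−1) − ln(1−e^{−xᵢ}) ],  xᵢ = ħωᵢ/k_B T,

  with the Schlitter upper bound S ≤ (R/2) Σᵢ ln(1 + k_B T e² λᵢ/ħ²)
  available from the same spectrum.
* **gromos clustering**: greedy medoid clustering at an RMSD cutoff
  (default 0.2 nm), deterministic tie-breaks.
* **Solvation**: first-hydration-shell counts (waters within 5 Å of the
  solute, cell-list or brute-force neighbour search), block averages,
  bridging-water detection (a water oxygen within 0.35 nm of *both* of two
  protein atoms, e.g. Trp755 NE1 and Val912 backbone N) and residence-time
  statistics.
* **Interactions**: hydrogen-bond occupancy (0.35 nm / 120° criterion),
  salt-bridge minimum N–O distances, charge-center geometry, and
  dielectric-screened Coulomb energies E = k_C q₁q₂/(ε d) with ε = 80.
* **A synthetic-data generator** producing toy helix-bundle references,
  staged open→closed transition trajectories, scripted solvent and Gaussian
  ensembles — all with exact ground truth, so every analysis stage is
  testable end to end.

## Worked example

```python
import lbdkit as lk
from lbdkit.synthetic import SyntheticSpec, make_transition_trajectory

# A 1000-frame open→closed transition of a 60-residue toy LBD with 0.02 nm
# positional noise, built so the noise-free ΔRMSD crosses −0.1 nm at frame 400.
spec = SyntheticSpec(seed=7)
traj, refs, truth = make_transition_trajectory(spec, crossing_frame=400)

delta = lk.delta_rmsd_series(traj, refs)
onset = lk.detect_closed_onset(delta)
print(f"reference separation: {refs.reference_separation():.3f} nm")
print(f"dRMSD first/last frame: {delta.values[0]:+.3f} / {delta.values[-1]:+.3f} nm")
print(f"closed-state onset: frame {onset} (planted at {truth.crossing_frame})")
```

prints

```
reference separation: 0.600 nm
dRMSD first/last frame: +0.575 / -0.568 nm
closed-state onset: frame 399 (planted at 400)
```

The first frame sits at the open reference (+0.6 nm separation, slightly
reduced by noise inflation of the instantaneous RMSDs), the last at the
closed reference, and the detected onset is within a couple of frames of the
planted crossing — the per-frame ΔRMSD noise (~0.004 nm) against the ramp
slope makes the first threshold crossing land a few frames early.

The same battery runs from the shell:

```bash
lbdkit synth --out-dir bundle --n-frames 1000 --crossing-frame 400 --n-waters 8 --seed 7
lbdkit analyze --out-dir results --seed 7          # built-in synthetic config
lbdkit analyze --config my.yaml --trajectory traj.pdb \
    --open-ref 2ovh_A.pdb --closed-ref 1a28_A.pdb --out-dir results
```

`analyze` writes `report.json` plus CSV exports of every time series.

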