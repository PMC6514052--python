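"""Configuration-driven orchestration of the full analysis battery.

A single config document (YAML or dict) names the input — either a synthetic
bundle spec or real structure files — and the stages to run: ΔRMSD state
tracking, RMSF, regional RMSDs, PCA, clustering, entropy, hydration,
bridging waters, hydrogen bonds and charge-center electrostatics. The
report is a plain JSON-serialisable dict; identical config and seed produce
byte-identical reports (no timestamps enter the output).

State classification operationalises the literature's labels: a frame is
"closed" when ΔRMSD ≤ −0.1 nm (the published closed criterion), "open" when
ΔRMSD ≥ +0.1 nm (a symmetric choice — the open bound is not quantified in
the literature), and "semi-open" in between.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .errors import ConfigurationError
from .geometry import (
    ReferencePair, TimeSeries, delta_rmsd_series, residue_rmsf, rmsd_series,
)
from .structio import SelectionMask, Trajectory, read_pdb, select

logger = logging.getLogger("lbdkit")

KNOWN_STAGES = (
    "delta_rmsd", "rmsf", "region_rmsd", "pca", "clustering", "entropy",
    "hydration", "bridging", "hbonds", "charge_centers",
)


@dataclass
class StateThresholds:
    """ΔRMSD bands for open / semi-open / closed labels (nm)."""

    closed_max: float = -0.1
    open_min: float = 0.1

    def __post_init__(self) -> None:
        if self.closed_max >= self.open_min:
            raise ConfigurationError("closed_max must be below open_min")


def classify_states(delta_rmsd: TimeSeries, thr: StateThresholds | None = None):
    """Per-frame labels: closed (≤ closed_max), open (≥ open_min), else semi-open."""
    thr = thr or StateThresholds()
    v = delta_rmsd.values
    labels = np.where(v <= thr.closed_max, "closed",
                      np.where(v >= thr.open_min, "open", "semi-open"))
    return labels


def detect_closed_onset(delta_rmsd: TimeSeries,
                        thr: StateThresholds | None = None) -> int | None:
    """Index of the first frame classified closed, or None."""
    thr = thr or StateThresholds()
    below = np.flatnonzero(delta_rmsd.values <= thr.closed_max)
    return int(below[0]) if below.size else None


# ---------------------------------------------------------------------------
# Config handling
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """Full analysis battery on the default synthetic transition bundle."""
    return {
        "seed": 0,
        "input": {
            "synthetic": {
                "n_residues": 60, "state_separation": 0.6, "noise_sigma": 0.02,
                "n_frames": 1000, "frame_spacing_ps": 100.0, "n_waters": 8,
                "crossing_frame": 400,
            }
        },
        "stages": {
            "delta_rmsd": {"closed_max": -0.1, "open_min": 0.1},
            "rmsf": {},
            "region_rmsd": {"regions": [{"label": "helix12", "resid": [756, 770]}]},
            "pca": {"kind": "distance-matrix", "stride": 10, "n_components": 2},
            "clustering": {"cutoff": 0.2, "stride": 10},
            "entropy": {"temperature": 300.0, "method": "quasiharmonic"},
            "hydration": {"shell_cutoff": 0.5, "block": 50},
            "bridging": {"site_a": "name NE1", "site_b": "resid 756 and name N",
                         "bridge_cutoff": 0.35},
            "hbonds": [],
            "charge_centers": None,
        },
    }


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config {path} is not a mapping")
    return cfg


def _validate_config(config: dict) -> None:
    if "input" not in config:
        raise ConfigurationError("config needs an 'input' block")
    stages = config.get("stages", {})
    if not isinstance(stages, dict):
        raise ConfigurationError("'stages' must be a mapping")
    unknown = set(stages) - set(KNOWN_STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
    inp = config["input"]
    if "synthetic" not in inp and "trajectory" not in inp:
        raise ConfigurationError(
            "input must give either 'synthetic' parameters or file paths"
        )
    if "synthetic" not in inp:
        for key in ("trajectory", "open_ref", "closed_ref"):
            if key not in inp:
                raise ConfigurationError(f"file input requires '{key}'")


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def build_reference_pair(
    traj: Trajectory, open_traj: Trajectory, closed_traj: Trajectory,
) -> ReferencePair:
    """Match Cα atoms of the two references and the trajectory by (chain, resid)."""
    def ca_map(t: Trajectory) -> dict:
        mask = select(t.topology, "alphacarbon")
        return {
            (t.topology.atoms[i].chain, t.topology.atoms[i].resid): i
            for i in mask.indices
        }

    m_traj, m_open, m_closed = ca_map(traj), ca_map(open_traj), ca_map(closed_traj)
    common = [k for k in m_traj if k in m_open and k in m_closed]
    if len(common) < 3:
        raise ConfigurationError(
            "fewer than 3 Cα atoms shared between trajectory and references"
        )
    return ReferencePair(
        open_topology=open_traj.topology, open_frame=open_traj.frames[0],
        closed_topology=closed_traj.topology, closed_frame=closed_traj.frames[0],
        mask_open=SelectionMask(tuple(m_open[k] for k in common)),
        mask_closed=SelectionMask(tuple(m_closed[k] for k in common)),
        mask_traj=SelectionMask(tuple(m_traj[k] for k in common)),
    )


# ---------------------------------------------------------------------------
# Input resolution
# ---------------------------------------------------------------------------

def _resolve_input(config: dict, seed: int):
    from .synthetic import SyntheticSpec, make_transition_trajectory, plant_solvent

    inp = config["input"]
    truth = None
    if "synthetic" in inp:
        params = dict(inp["synthetic"])
        crossing = params.pop("crossing_frame", None)
        params["seed"] = seed
        spec = SyntheticSpec(**params)
        traj, refs, truth = make_transition_trajectory(
            spec, crossing_frame=crossing)
        if spec.n_waters > 0:
            traj, solvent_truth = plant_solvent(traj, spec)
            truth = {"transition": truth, "solvent": solvent_truth}
        else:
            truth = {"transition": truth, "solvent": None}
    else:
        traj = read_pdb(inp["trajectory"])
        open_traj = read_pdb(inp["open_ref"])
        closed_traj = read_pdb(inp["closed_ref"])
        refs = build_reference_pair(traj, open_traj, closed_traj)
    return traj, refs, truth


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _series_payload(ts: TimeSeries) -> dict:
    return {
        "times_ps": ts.times.tolist(), "values": ts.values.tolist(),
        "label": ts.label, "units": ts.units,
    }


def _stage_delta_rmsd(traj, refs, params) -> dict:
    thr = StateThresholds(
        closed_max=params.get("closed_max", -0.1),
        open_min=params.get("open_min", 0.1),
    )
    series = delta_rmsd_series(traj, refs)
    labels = classify_states(series, thr)
    unique, counts = np.unique(labels, return_counts=True)
    return {
        "series": _series_payload(series),
        "thresholds": {"closed_max": thr.closed_max, "open_min": thr.open_min},
        "labels": labels.tolist(),
        "state_counts": dict(zip(unique.tolist(), counts.tolist())),
        "closed_onset_frame": detect_closed_onset(series, thr),
        "semi_open_note": "the semi-open band is an operational definition; "
                          "only the closed bound is quantified in the literature",
    }


def _stage_rmsf(traj, refs, params) -> dict:
    table = residue_rmsf(traj, superpose=params.get("superpose", True))
    return {"per_residue": table.to_dict(orient="records")}


def _stage_region_rmsd(traj, refs, params) -> dict:
    out = {}
    top = traj.topology
    ca_all = refs.mask_traj
    for region in params.get("regions", []):
        lo, hi = region["resid"]
        sub = [i for i in ca_all.indices
               if lo <= top.atoms[i].resid <= hi]
        ref_sub = [r for i, r in zip(ca_all.indices, refs.mask_closed.indices)
                   if lo <= top.atoms[i].resid <= hi]
        series = rmsd_series(
            traj, refs.closed_frame,
            SelectionMask(tuple(sub)), SelectionMask(tuple(ref_sub)),
            fit_mask=ca_all, fit_ref_mask=refs.mask_closed,
            label=f"rmsd_{region['label']}",
        )
        out[region["label"]] = _series_payload(series)
    return out


def _stage_pca(traj, refs, params) -> dict:
    from .ensembles import cartesian_pca, distance_feature_matrix, pca

    kind = params.get("kind", "distance-matrix")
    n_components = params.get("n_components", 2)
    if kind == "distance-matrix":
        features = distance_feature_matrix(
            traj, refs.mask_traj, stride=params.get("stride", 1))
        result = pca(features, n_components=n_components)
    elif kind == "cartesian":
        result = cartesian_pca(traj, refs.mask_traj, n_components=n_components)
    else:
        raise ConfigurationError(f"unknown PCA kind {kind!r}")
    return {
        "kind": result.feature_kind,
        "eigenvalues": result.eigenvalues[:10].tolist(),
        "explained_variance_ratio": result.explained_variance_ratio.tolist(),
        "projections": result.projections.tolist(),
    }


def _stage_clustering(traj, refs, params) -> dict:
    from .ensembles import gromos_cluster

    stride = params.get("stride", 1)
    sub = Trajectory(traj.topology, traj.frames[::stride])
    result = gromos_cluster(sub, refs.mask_traj, cutoff=params.get("cutoff", 0.2))
    return {
        "stride": stride,
        "n_clusters": result.n_clusters,
        "sizes": result.sizes.tolist(),
        "medoid_frames": (result.medoids * stride).tolist(),
        "assignment": result.assignment.tolist(),
    }


def _stage_entropy(traj, refs, params) -> dict:
    from .ensembles import quasiharmonic_entropy

    result = quasiharmonic_entropy(
        traj, refs.mask_traj,
        temperature=params.get("temperature", 300.0),
        method=params.get("method", "quasiharmonic"),
        superpose=params.get("superpose", True),
    )
    payload = result.to_dict()
    payload["eigenvalues_nm2_amu"] = payload["eigenvalues_nm2_amu"][:20]
    payload["mode_frequencies_rad_per_s"] = payload["mode_frequencies_rad_per_s"][:20]
    return payload


def _water_masks(traj):
    top = traj.topology
    solute = select(top, "protein")
    water = select(top, "water")
    return solute, water


def _stage_hydration(traj, refs, params) -> dict:
    from .solvation import SolvationConfig, block_average, hydration_count_series

    solute, water = _water_masks(traj)
    if len(water) == 0:
        return {"skipped": "no waters in topology"}
    cfg = SolvationConfig(shell_cutoff=params.get("shell_cutoff", 0.5))
    series = hydration_count_series(traj, solute, water, cfg)
    block = params.get("block", 50)
    blocked = block_average(series, block)
    return {
        "series": _series_payload(series),
        "block_average": _series_payload(blocked),
        "block": block,
        "mean_count": float(series.values.mean()),
    }


def _stage_bridging(traj, refs, params) -> dict:
    from .solvation import (
        SolvationConfig, bridging_water_events, residence_summary,
    )

    solute, water = _water_masks(traj)
    if len(water) == 0:
        return {"skipped": "no waters in topology"}
    site_a = select(traj.topology, params["site_a"])
    site_b = select(traj.topology, params["site_b"])
    cfg = SolvationConfig(
        bridge_cutoff=params.get("bridge_cutoff", 0.35),
        gap_tolerance=params.get("gap_tolerance", 0),
    )
    intervals = bridging_water_events(traj, site_a, site_b, water, cfg)
    return {
        "intervals": [
            {"water_chain": iv.water_id[0], "water_resid": iv.water_id[1],
             "start_ps": iv.start_time, "end_ps": iv.end_time,
             "duration_ps": iv.duration}
            for iv in intervals
        ],
        "summary": residence_summary(intervals),
    }


def _stage_hbonds(traj, refs, params) -> dict:
    from .interactions import HBondSpec, hbond_occupancy

    out = []
    for bond in params or []:
        spec = HBondSpec(
            donor=select(traj.topology, bond["donor"]),
            acceptor=select(traj.topology, bond["acceptor"]),
            hydrogen=(select(traj.topology, bond["hydrogen"])
                      if bond.get("hydrogen") else None),
            d_cutoff=bond.get("d_cutoff", 0.35),
            angle_cutoff=bond.get("angle_cutoff", 120.0),
        )
        out.append({
            "name": bond.get("name", f"{bond['donor']}->{bond['acceptor']}"),
            "occupancy": hbond_occupancy(traj, spec),
        })
    return {"occupancies": out}


def _stage_charge_centers(traj, refs, params) -> dict:
    from .interactions import (
        ChargeCenter, CoulombSpec, charge_center_distance_series,
        coulomb_energy_series,
    )

    if not params:
        return {"skipped": "no charge centers configured"}
    def center_from(cfg: dict) -> ChargeCenter:
        return ChargeCenter(
            members=[tuple(m) for m in cfg["members"]],
            charge=cfg["charge"],
            atom_rule=cfg.get("atom_rule", "sidechain_charged"),
            label=cfg.get("label", ""),
        )

    ca = center_from(params["a"])
    cb = center_from(params["b"])
    spec = CoulombSpec(
        epsilon=params.get("epsilon", 80.0),
        form=params.get("form", "coulomb_1_over_d"),
    )
    distances = charge_center_distance_series(traj, ca, cb)
    energies = coulomb_energy_series(distances, ca.charge, cb.charge, spec)
    return {
        "distance": _series_payload(distances),
        "energy": _series_payload(energies),
        "coulomb": spec.metadata,
    }


_STAGE_FUNCS = {
    "delta_rmsd": _stage_delta_rmsd,
    "rmsf": _stage_rmsf,
    "region_rmsd": _stage_region_rmsd,
    "pca": _stage_pca,
    "clustering": _stage_clustering,
    "entropy": _stage_entropy,
    "hydration": _stage_hydration,
    "bridging": _stage_bridging,
    "hbonds": _stage_hbonds,
    "charge_centers": _stage_charge_centers,
}


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Run the configured stages and return the report dict.

    The config is validated before any computation; a failing stage raises
    an error naming the stage while earlier stage results stay in the report
    written so far (when ``out_dir`` is given, a partial ``report.json`` is
    still emitted for the completed stages).
    """
    _validate_config(config)
    seed = int(config.get("seed", 0))
    traj, refs, truth = _resolve_input(config, seed)
    logger.info("input resolved: %d frames, %d atoms", traj.n_frames,
                traj.topology.n_atoms)
    report: dict = {
        "provenance": {
            "config_hash": _config_hash(config),
            "seed": seed,
            "lbdkit_version": __version__,
            "numpy_version": np.__version__,
        },
    }
    if truth is not None and truth.get("transition") is not None:
        report["synthetic_truth"] = {
            "crossing_frame": truth["transition"].crossing_frame,
            "threshold_nm": truth["transition"].threshold,
        }
    stages = config.get("stages", {})
    try:
        for name in KNOWN_STAGES:
            if name not in stages or stages[name] is None:
                continue
            params = stages[name]
            logger.info("stage %s: %s", name, params)
            try:
                report[name] = _STAGE_FUNCS[name](traj, refs, params)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    finally:
        if out_dir is not None:
            write_report(report, out_dir)
    return report


def write_report(report: dict, out_dir: str | Path) -> Path:
    """Write report.json plus CSV exports of every series in the report."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    for stage, payload in report.items():
        if not isinstance(payload, dict):
            continue
        series = payload.get("series")
        if isinstance(series, dict) and "times_ps" in series:
            pd.DataFrame({
                "time_ps": series["times_ps"], "value": series["values"],
                "label": series["label"], "units": series["units"],
            }).to_csv(out / f"{stage}.csv", index=False)
    return path
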