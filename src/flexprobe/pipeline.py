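"""Config-driven orchestration of the full analysis.

A single TOML config describes the systems (replicate trajectory files and
their save interval), the residue classifiers, the occlusion reference set
and the hydrogen-bond list; the three report runners then produce the
table-shaped outputs: a ΔG report (one row per system × residue, mean ± SD
over replicates), a bond-formation chronology, and a per-reference-atom
occlusion table with per-frame counts.

Outputs are deterministic and byte-stable: floats are written at fixed
precision (ΔG and SD to 2 decimals, times to 1 decimal) and every file
carries a provenance block (config hash, package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .boltzmann import (
    aggregate_replicates,
    delta_g_bl,
    dg_open_from_dg_bl,
    populations,
)
from .conformational_states import (
    DihedralReference,
    classify_trajectory,
    rmsd_reference_from_frame,
)
from .hbond_chronology import (
    HBondSpec,
    Persistence,
    aggregate_chronologies,
    chronology_table,
)
from .occlusion import (
    fractional_occlusion,
    occluded_count_series,
    reference_set_from_residue,
)
from .structure_io import AtomSelection, Trajectory, read_pdb_models

__all__ = [
    "AnalysisConfig",
    "run_deltag_report",
    "run_chronology_report",
    "run_occlusion_report",
]

log = logging.getLogger("flexprobe")


@dataclass(frozen=True)
class AnalysisConfig:
    """A validated analysis configuration plus its provenance hash."""

    raw: dict
    config_hash: str
    base_dir: Path

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        data = path.read_bytes()
        raw = tomllib.loads(data.decode())
        cfg = cls(
            raw=raw,
            config_hash=hashlib.sha256(data).hexdigest()[:16],
            base_dir=path.parent,
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for system in self.raw.get("systems", []):
            for traj_path in system.get("trajectories", []):
                p = self.resolve(traj_path)
                if not p.exists():
                    raise FileNotFoundError(
                        f"system {system.get('label')!r}: trajectory {p} not found"
                    )
        for res in self.raw.get("residues", []):
            for key in ("open_ref", "closed_ref"):
                if key in res and not self.resolve(res[key]).exists():
                    raise FileNotFoundError(
                        f"residue {res.get('name')!r}: {key} file "
                        f"{self.resolve(res[key])} not found"
                    )

    def resolve(self, rel: str) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else self.base_dir / p

    @property
    def frame_interval_ns(self) -> float:
        return float(self.raw.get("global", {}).get("frame_interval_ns", 0.1))

    @property
    def temperature_K(self) -> float:
        return float(self.raw.get("global", {}).get("temperature_K", 300.0))

    def provenance(self) -> dict:
        return {"package": "flexprobe", "version": __version__, "config_hash": self.config_hash}


def _load_replicates(config: AnalysisConfig, system: dict) -> list[Trajectory]:
    interval = float(system.get("frame_interval_ns", config.frame_interval_ns))
    trajs = []
    for i, rel in enumerate(system["trajectories"], start=1):
        trajs.append(
            read_pdb_models(
                config.resolve(rel),
                frame_interval_ns=interval,
                replicate_id=f"r{i}",
                system_label=system["label"],
            )
        )
    return trajs


def _residue_classifier(config: AnalysisConfig, res: dict):
    mode = res.get("mode", "chi1")
    chain = res.get("chain", "A")
    resnum = int(res["residue_number"])
    if mode == "chi1":
        open_ref = DihedralReference(
            chain, resnum, float(res["open_chi1"]), "open", provenance="config"
        )
        closed_ref = DihedralReference(
            chain, resnum, float(res["closed_chi1"]), "closed", provenance="config"
        )
        return open_ref, closed_ref
    if mode == "rmsd":
        refs = []
        for key, state in (("open_ref", "open"), ("closed_ref", "closed")):
            ref_traj = read_pdb_models(config.resolve(res[key]), frame_interval_ns=1.0)
            refs.append(
                rmsd_reference_from_frame(
                    ref_traj.frames[0], chain, resnum, state, provenance=res[key]
                )
            )
        return tuple(refs)
    raise ValueError(f"unknown classifier mode {mode!r}")


def run_deltag_report(config: AnalysisConfig) -> pd.DataFrame:
    """ΔG_BL / ΔG_open per (system, residue): mean ± SD over replicates."""
    rows = []
    for system in config.raw.get("systems", []):
        log.info("deltag: system %s", system["label"])
        trajs = _load_replicates(config, system)
        for res in config.raw.get("residues", []):
            classifier = _residue_classifier(config, res)
            bl_state = res.get("bl_state", "open")
            ligand = res.get("ligand_convention", "PD-L1")
            ests = []
            for traj in trajs:
                series = classify_trajectory(traj, classifier)
                pop = populations(series, bl_state=bl_state)
                ests.append(delta_g_bl(pop, temperature_K=config.temperature_K))
            agg = aggregate_replicates(ests)
            agg_open = dg_open_from_dg_bl(agg, res["name"], ligand)
            rows.append(
                {
                    "system": system["label"],
                    "residue": res["name"],
                    "bl_state": bl_state,
                    "ligand_convention": ligand,
                    "dg_bl_mean_kbt": round(agg.dg_kbt, 2),
                    "dg_bl_sd_kbt": round(agg.sd_kbt, 2),
                    "dg_open_mean_kbt": round(agg_open.dg_kbt, 2),
                    "dg_open_sd_kbt": round(agg_open.sd_kbt, 2),
                    "n_replicates": agg.n_replicates,
                }
            )
    return pd.DataFrame(rows)


def _bond_spec(entry: dict) -> HBondSpec:
    return HBondSpec(
        donor=entry["donor"],
        acceptor=entry["acceptor"],
        hydrogen=entry.get("hydrogen"),
        distance_cutoff=float(entry.get("distance_cutoff", 3.5)),
        angle_cutoff=float(entry.get("angle_cutoff", 135.0)),
        label=entry.get("label", ""),
    )


def run_chronology_report(config: AnalysisConfig) -> pd.DataFrame:
    """Δt-after-reference-bond chronology, aggregated over replicates."""
    hb = config.raw.get("hbonds", {})
    if "reference" not in hb:
        raise ValueError("hbonds.reference bond must be defined")
    reference = _bond_spec(hb["reference"])
    bonds = [_bond_spec(b) for b in hb.get("bonds", [])]
    if not bonds:
        log.warning("chronology: empty bond list")
    persistence = Persistence(
        window_ns=float(hb.get("window_ns", 1.0)),
        min_occupancy=float(hb.get("min_occupancy", 0.8)),
    )
    rows = []
    for system in config.raw.get("systems", []):
        log.info("chronology: system %s", system["label"])
        trajs = _load_replicates(config, system)
        replicate_records = [
            chronology_table(t, bonds, reference, persistence) for t in trajs
        ]
        for row in aggregate_chronologies(replicate_records):
            rows.append(
                {
                    "system": system["label"],
                    "bond": row["bond"],
                    "dt_mean_ns": round(row["dt_mean_ns"], 1),
                    "dt_sd_ns": round(row["dt_sd_ns"], 1),
                    "n_formed": row["n_formed"],
                    "n_replicates": row["n_replicates"],
                }
            )
    return pd.DataFrame(rows)


def run_occlusion_report(
    config: AnalysisConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fractional occlusion per reference atom and per-frame overlap counts."""
    occ = config.raw.get("occlusion", {})
    if "reference_structure" not in occ:
        raise ValueError("occlusion.reference_structure must be defined")
    ref_traj = read_pdb_models(
        config.resolve(occ["reference_structure"]), frame_interval_ns=1.0
    )
    ref_set = reference_set_from_residue(
        ref_traj.frames[0],
        chain=occ.get("reference_chain", "A"),
        residue_number=int(occ["reference_residue"]),
        atom_class=occ.get("reference_atom_class", "sidechain-heavy"),
        source=occ["reference_structure"],
    )
    probe = AtomSelection(
        atom_class=occ.get("probe", "all-heavy"),
        chain=occ.get("probe_chain"),
    )
    frac_rows, count_rows = [], []
    for system in config.raw.get("systems", []):
        log.info("occlusion: system %s", system["label"])
        for traj in _load_replicates(config, system):
            profile = fractional_occlusion(traj, ref_set, probe)
            for label, fraction in profile.fractions.items():
                frac_rows.append(
                    {
                        "system": system["label"],
                        "replicate": traj.replicate_id,
                        "label": label,
                        "fraction": round(fraction, 4),
                        "n_frames": profile.n_frames,
                    }
                )
            counts = occluded_count_series(traj, ref_set, probe)
            for t, c in zip(traj.times_ns(), counts):
                count_rows.append(
                    {
                        "system": system["label"],
                        "replicate": traj.replicate_id,
                        "time_ns": round(float(t), 1),
                        "n_occluded": int(c),
                    }
                )
    return pd.DataFrame(frac_rows), pd.DataFrame(count_rows)


def write_report(
    df: pd.DataFrame, path: str | Path, config: AnalysisConfig
) -> None:
    """Write a CSV report with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    prov = config.provenance()
    header = f"# flexprobe {prov['version']} config_hash={prov['config_hash']}\n"
    path.write_text(header + df.to_csv(index=False))


def write_summary_json(payload: dict, path: str | Path, config: AnalysisConfig) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"provenance": config.provenance(), **payload}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
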