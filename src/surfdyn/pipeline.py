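"""End-to-end orchestration: equilibrate -> SASA detection -> DCCM -> PCA.

A :class:`RunConfig` (parsed from a flat TOML file) fully determines a run;
identical config + seed gives byte-identical report tables. Every
analysis threshold the protocols use (burial 20 %, delta 5 pp, SEM rule,
probe 1.4 A, 960 quadrature points) lives in the config with its standard
value as default, and every defaulted field is logged in the run manifest.

Outputs under the run directory use fixed names: ``rmsd_series.tsv``,
``windows.tsv``, ``interface.tsv``, ``allostery.tsv``, ``dccm.tsv``,
``pca_projections.tsv``, ``pca_contributions.tsv``, ``pc1_interp.pdb``,
``truth.tsv`` (synthetic runs) and ``manifest.txt``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .core import partition_complex, select
from .correlation import ca_mask, center_ensemble, dccm, interpolate_pc_extremes, pca
from .equilibration import (
    EquilibratedWindow,
    ReplicateEnsemble,
    detect_equilibrated_window,
    rmsd_series,
)
from .io import (
    read_multi_model_pdb,
    write_multi_model_pdb,
    write_table,
    write_xyz_table,
)
from .sasa import detect_allosteric, detect_interfacial
from .synthetic import (
    SyntheticSpec,
    max_sasa_table,
    simulate_bound_ensemble,
    simulate_unbound_ensemble,
    truth,
)
from .tables import DEFAULT_N_POINTS, DEFAULT_PROBE_RADIUS


@dataclass
class RunConfig:
    """Flat, auditable record of one pipeline run."""

    synthetic: dict[str, Any] | None = None
    unbound_paths: list[str] = field(default_factory=list)
    bound_paths: list[str] = field(default_factory=list)
    partner_chains: list[str] = field(default_factory=lambda: ["B"])
    burial_threshold: float = 20.0
    delta_min: float = 5.0
    sem_rule: bool = True
    probe_radius: float = DEFAULT_PROBE_RADIUS
    n_points: int = DEFAULT_N_POINTS
    stride: int = 1
    slope_tol: float = 0.02
    spread_tol: float = 1.5
    min_tail_fraction: float = 0.2
    explicit_windows: list[list[int]] | None = None
    pca_selection: str = "name CA"
    pca_fit_selection: str = ""
    output_dir: str = "surfdyn_run"
    seed: int = 0
    defaulted: list[str] = field(default_factory=list)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        flat: dict[str, Any] = {}
        for key, value in raw.items():
            if key == "synthetic":
                flat["synthetic"] = dict(value)
            elif isinstance(value, dict):  # allow [thresholds]-style sections
                for k2, v2 in value.items():
                    flat[k2] = v2
            else:
                flat[key] = value
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**flat)
        config.defaulted = sorted(known - set(flat) - {"defaulted"})
        return config


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _load_ensembles(config: RunConfig):
    """Returns (unbound, bound, max_table, truth_or_None)."""
    if config.synthetic is not None:
        spec_kwargs = dict(config.synthetic)
        spec_kwargs.setdefault("seed", config.seed)
        spec_kwargs = {
            k: (tuple(tuple(x) if isinstance(x, list) else x for x in v)
                if isinstance(v, list) else v)
            for k, v in spec_kwargs.items()
        }
        if "planted_allosteric" in spec_kwargs and isinstance(
            spec_kwargs["planted_allosteric"], dict
        ):
            spec_kwargs["planted_allosteric"] = {
                int(k): float(v)
                for k, v in spec_kwargs["planted_allosteric"].items()
            }
        spec = SyntheticSpec(**spec_kwargs)
        return (
            simulate_unbound_ensemble(spec),
            simulate_bound_ensemble(spec),
            max_sasa_table(spec),
            truth(spec),
        )
    if not config.unbound_paths or not config.bound_paths:
        raise ValueError(
            "config must provide either a [synthetic] spec or both "
            "unbound_paths and bound_paths"
        )
    unbound = ReplicateEnsemble(
        [read_multi_model_pdb(p) for p in config.unbound_paths]
    )
    bound = ReplicateEnsemble([read_multi_model_pdb(p) for p in config.bound_paths])
    return unbound, bound, None, None


def _assign_windows(ensemble: ReplicateEnsemble, config: RunConfig,
                    log: list[str], label: str) -> pd.DataFrame:
    rows = []
    windows: list[EquilibratedWindow] = []
    for k, traj in enumerate(ensemble.trajectories):
        if config.explicit_windows is not None:
            start, end = config.explicit_windows[k]
            win = EquilibratedWindow(start, end, criterion_log="explicit")
        else:
            series = rmsd_series(traj, reference=0, mask=ca_mask(traj.system),
                                 label="rmsd_ca")
            win = detect_equilibrated_window(
                [series],
                min_tail_fraction=config.min_tail_fraction,
                slope_tol=config.slope_tol,
                spread_tol=config.spread_tol,
            )
            if not win.equilibrated:
                log.append(f"{label} replicate {k}: NOT equilibrated "
                           f"({win.criterion_log})")
        windows.append(win)
        rows.append(
            {
                "ensemble": label,
                "replicate": k,
                "start_frame": win.start_frame,
                "end_frame": win.end_frame,
                "start_ns": traj.times[win.start_frame],
                "end_ns": traj.times[win.end_frame - 1],
                "equilibrated": win.equilibrated,
            }
        )
    ensemble.windows = windows
    return pd.DataFrame(rows)


def run(config: RunConfig, output_dir: str | Path | None = None) -> Path:
    """Execute the full pipeline; returns the run directory.

    Stage order: load/simulate -> equilibrated windows -> interfacial SASA
    detection -> allosteric SASA detection -> DCCM -> PCA (+ extreme-
    structure interpolation along PC1). Any stage failure propagates with
    the stage recorded in the manifest.
    """
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_lines = [
        f"surfdyn {__version__}",
        f"seed: {config.seed}",
        "config: " + repr({
            f.name: getattr(config, f.name)
            for f in dataclasses.fields(config) if f.name != "defaulted"
        }),
        "defaulted fields: " + (", ".join(config.defaulted) or "(none)"),
    ]
    log: list[str] = []
    stage = "load"
    try:
        unbound, bound, max_table, planted = _load_ensembles(config)
        if max_table is None:
            log.append("max-SASA table: standard residue table (default)")
        if planted is not None:
            write_table(
                pd.DataFrame(
                    [
                        {"residue_key": k, "kind": "interfacial", "target_delta": ""}
                        for k in planted.interfacial
                    ]
                    + [
                        {"residue_key": k, "kind": "allosteric", "target_delta": d}
                        for k, d in planted.allosteric.items()
                    ]
                ),
                out / "truth.tsv",
            )

        stage = "equilibration"
        win_rows = []
        rmsd_rows = []
        for label, ens in (("unbound", unbound), ("bound", bound)):
            pre_set = ens.windows is not None and all(
                w is not None for w in ens.windows
            )
            if pre_set and config.explicit_windows is None:
                log.append(f"{label}: windows pre-set by generator (full range)")
                for k, (traj, win) in enumerate(zip(ens.trajectories, ens.windows)):
                    win_rows.append(
                        {"ensemble": label, "replicate": k,
                         "start_frame": win.start_frame,
                         "end_frame": win.end_frame,
                         "start_ns": traj.times[win.start_frame],
                         "end_ns": traj.times[win.end_frame - 1],
                         "equilibrated": win.equilibrated}
                    )
            else:
                win_rows.extend(
                    _assign_windows(ens, config, log, label).to_dict("records")
                )
            for k, traj in enumerate(ens.trajectories):
                series = rmsd_series(traj, 0, ca_mask(traj.system), "rmsd_ca")
                rmsd_rows.extend(
                    {"ensemble": label, "replicate": k, "time_ns": t, "rmsd_A": v}
                    for t, v in zip(series.times, series.values)
                )
        write_table(pd.DataFrame(win_rows), out / "windows.tsv")
        write_table(pd.DataFrame(rmsd_rows), out / "rmsd_series.tsv")

        stage = "sasa-interface"
        partition = partition_complex(bound.system, config.partner_chains)
        interface = detect_interfacial(
            bound, partition, config.delta_min, config.burial_threshold,
            config.sem_rule, config.stride, config.probe_radius,
            config.n_points, max_table,
        )
        write_table(interface, out / "interface.tsv")

        stage = "sasa-allostery"
        allostery = detect_allosteric(
            bound, unbound, partition, config.delta_min,
            config.burial_threshold, config.sem_rule, config.stride,
            config.probe_radius, config.n_points, max_table,
        )
        write_table(allostery, out / "allostery.tsv")

        stage = "dccm"
        mask = ca_mask(unbound.system)
        fit_mask = (
            select(unbound.system, config.pca_fit_selection)
            if config.pca_fit_selection else None
        )
        centered = center_ensemble(unbound, mask=mask, fit_mask=fit_mask)
        corr = dccm(centered)
        dccm_df = pd.DataFrame(corr.matrix, index=corr.labels, columns=corr.labels)
        dccm_df.insert(0, "residue_key", corr.labels)
        write_table(dccm_df, out / "dccm.tsv")

        stage = "pca"
        sel = select(unbound.system, config.pca_selection)
        centered_pca = center_ensemble(unbound, mask=sel, fit_mask=fit_mask)
        result = pca(centered_pca)
        proj = pd.DataFrame(
            result.projections[:, :10],
            columns=[f"PC{k+1}" for k in range(min(10, result.projections.shape[1]))],
        )
        proj.insert(0, "frame", np.arange(len(proj)))
        write_table(proj, out / "pca_projections.tsv")
        contrib = result.residue_contributions.iloc[:, :10].copy()
        contrib.insert(0, "residue_key", contrib.index)
        write_table(contrib.reset_index(drop=True), out / "pca_contributions.tsv")
        write_table(
            pd.DataFrame(
                {"component": [f"PC{k+1}" for k in range(len(result.variance_fraction))],
                 "variance_fraction": result.variance_fraction}
            ).head(20),
            out / "pca_variance.tsv",
        )
        write_multi_model_pdb(
            interpolate_pc_extremes(result, 0, 10), out / "pc1_interp.pdb"
        )
    except Exception as exc:
        manifest_lines.append(f"FAILED at stage {stage}: {exc}")
        (out / "manifest.txt").write_text("\n".join(manifest_lines) + "\n")
        raise
    manifest_lines.append("stages: all completed")
    manifest_lines.extend("log: " + entry for entry in log)
    for f in sorted(out.iterdir()):
        if f.name != "manifest.txt" and f.is_file():
            manifest_lines.append(f"sha256[{f.name}]: {_hash_file(f)}")
    (out / "manifest.txt").write_text("\n".join(manifest_lines) + "\n")
    return out


def export_ensemble(ensemble: ReplicateEnsemble, directory: str | Path,
                    prefix: str, dialect: str = "pdb") -> list[Path]:
    """Write each replicate as multi-model PDB or XYZ-table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, traj in enumerate(ensemble.trajectories):
        if dialect == "pdb":
            p = directory / f"{prefix}_rep{k}.pdb"
            write_multi_model_pdb(traj, p)
        elif dialect == "xyz":
            p = directory / f"{prefix}_rep{k}.xyz.tsv"
            write_xyz_table(traj, p)
        else:
            raise ValueError("dialect must be 'pdb' or 'xyz'")
        paths.append(p)
    return paths
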