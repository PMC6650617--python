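"""End-to-end analysis pipeline and report tables.

``run_pipeline`` drives contacts -> hydrogen bonds -> kinetics ->
energies -> LIE -> structural metrics over one system/trajectory and
collects everything in a :class:`ReportBundle` of data frames whose
column headers mirror the package's summary-table conventions. Outputs
are deterministic for a given configuration and seed; every table carries
the configuration hash and seed in the JSON run manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import contacts as _contacts
from . import energy as _energy
from . import kinetics as _kinetics
from . import lie as _lie
from . import metrics as _metrics
from .model_io import AnalysisConfig, MolecularSystem, Trajectory

__all__ = ["PipelineError", "ReportBundle", "run_pipeline"]

logger = logging.getLogger("surfbind.pipeline")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class ReportBundle:
    """All report tables of one pipeline run plus the run manifest."""

    contacts: pd.DataFrame
    hbonds: pd.DataFrame
    hbond_summary: pd.DataFrame
    kinetics: pd.DataFrame
    energy_summary: pd.DataFrame
    charges: pd.DataFrame
    waters: pd.DataFrame
    rmsd: pd.DataFrame
    rmsf: pd.DataFrame
    lie: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "contacts": self.contacts,
            "hbonds": self.hbonds,
            "hbond_summary": self.hbond_summary,
            "kinetics": self.kinetics,
            "energy_summary": self.energy_summary,
            "charges": self.charges,
            "waters": self.waters,
            "rmsd": self.rmsd,
            "rmsf": self.rmsf,
        }
        if self.lie is not None:
            out["lie"] = self.lie
        return out

    def write(self, outdir: str | Path) -> None:
        """Write every table as TSV plus the JSON manifest (byte-stable)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables().items():
            df.to_csv(
                outdir / f"{name}.tsv",
                sep="\t",
                index=False,
                float_format="%.6f",
                lineterminator="\n",
            )
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n"
        )


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: %.3f s", name, time.perf_counter() - t0)
            return result
        return wrapper
    return deco


@_stage("contacts")
def _contacts_table(frame, system, config) -> pd.DataFrame:
    rows = _contacts.binding_site_residues(frame, system, config.contact_cutoff)
    return pd.DataFrame(
        [
            {
                "Residue": c.residue_name,
                "Residue index": c.residue_index,
                "Chain": c.chain,
                "Closest ligand atom": c.ligand_atom,
                "Min. distance (A)": c.min_distance,
            }
            for c in rows
        ],
        columns=[
            "Residue",
            "Residue index",
            "Chain",
            "Closest ligand atom",
            "Min. distance (A)",
        ],
    )


@_stage("hbonds")
def _hbond_tables(frame, system, config) -> tuple[pd.DataFrame, pd.DataFrame]:
    prot = np.flatnonzero(system.group_mask("protein"))
    lig = np.flatnonzero(system.ligand_mask)
    bonds = _contacts.detect_hbonds(frame, system, config, prot, lig)
    names = system.names
    detail = pd.DataFrame(
        [
            {
                "Donor": names[b.donor],
                "Hydrogen": "" if b.hydrogen is None else names[b.hydrogen],
                "Acceptor": names[b.acceptor],
                "D-A distance (A)": b.distance,
                "H-D-A angle (deg)": np.nan if b.angle is None else b.angle,
                "Class": b.kind,
            }
            for b in bonds
        ],
        columns=[
            "Donor",
            "Hydrogen",
            "Acceptor",
            "D-A distance (A)",
            "H-D-A angle (deg)",
            "Class",
        ],
    )
    s = _contacts.hbond_summary(bonds)
    resid = system.residue_indices
    resnames = system.residue_names
    involved = sorted(
        {
            (int(resid[i]), str(resnames[i]))
            for b in bonds
            for i in (b.donor, b.acceptor)
            if system.groups[i] == "protein"
        }
    )
    summary = pd.DataFrame(
        [
            {
                "Interacting residues": "; ".join(
                    f"{name} {idx}" for idx, name in involved
                ),
                "No. of bifurcated HBs": s["n_bifurcated"],
                "No. of regular HBs": s["n_regular"],
                "Total no. of HBs": s["n_total"],
                "Avg. HB dist. (A)": s["avg_distance"],
            }
        ]
    )
    return detail, summary


@_stage("kinetics")
def _kinetics_table(trajectory, system, config) -> pd.DataFrame:
    prot = np.flatnonzero(system.group_mask("protein"))
    lig = np.flatnonzero(system.ligand_mask)
    rows = []
    direct = _contacts.hbond_series(trajectory, system, config, prot, lig)
    if direct.matrix.size:
        k = _kinetics.analyze_kinetics(direct, temperature=config.temperature)
        rows.append(("direct", k))
    if system.group_mask("water").any():
        bridged = _contacts.bridge_series(trajectory, system, config)
        if bridged.matrix.size:
            k = _kinetics.analyze_kinetics(
                bridged, temperature=config.temperature
            )
            rows.append(("water-mediated", k))
    return pd.DataFrame(
        [
            {
                "Bond class": label,
                "Lifetime (ps)": k.lifetime,
                "Relaxation time (ps)": k.relaxation_time,
                "Free energy (kJ/mol)": k.free_energy,
            }
            for label, k in rows
        ],
        columns=[
            "Bond class",
            "Lifetime (ps)",
            "Relaxation time (ps)",
            "Free energy (kJ/mol)",
        ],
    )


@_stage("energies")
def _energy_table(trajectory, system, config) -> pd.DataFrame:
    rows = []
    for label in ("ligand", "head", "alpha", "tail"):
        idx = _energy.resolve_group(system, label, config.include_ions)
        if idx.size == 0:
            continue
        series = _energy.energy_timeseries(
            trajectory, system, config, group_a=idx, group_b="surrounding"
        )
        rows.append(
            {
                "Group": label,
                "Mean Coulomb (kJ/mol)": series.mean_coulomb,
                "SEM Coulomb (kJ/mol)": series.sem_coulomb,
                "Mean LJ (kJ/mol)": series.mean_lj,
                "SEM LJ (kJ/mol)": series.sem_lj,
                "Scheme": series.scheme,
            }
        )
    return pd.DataFrame(rows)


@_stage("charges")
def _charges_table(system) -> pd.DataFrame:
    gc = _energy.group_charge_sums(system)
    return pd.DataFrame(
        [
            {
                "Head-group": gc.head,
                "alpha-group": gc.alpha,
                "alpha-group + alkyl tail": gc.tail_with_alpha,
                "Net charge": gc.net,
            }
        ]
    )


@_stage("waters")
def _waters_table(trajectory, system, config) -> pd.DataFrame:
    rows = {}
    for label in ("head", "tail"):
        if not system.group_mask(label).any():
            continue
        counts, avg = _contacts.waters_near_group(
            trajectory, label, 0.35, config.analysis_window, system
        )
        rows[f"Waters near {label}"] = counts
    df = pd.DataFrame(rows)
    df.insert(0, "Time (ps)", trajectory.times)
    return df


@_stage("metrics")
def _metrics_tables(trajectory, system) -> tuple[pd.DataFrame, pd.DataFrame]:
    try:
        sel = _metrics.select_atoms(system, names="backbone")
    except ValueError:
        sel = np.flatnonzero(system.group_mask("protein"))
    rmsd = _metrics.rmsd_series(trajectory, selection=sel)
    rmsd_df = pd.DataFrame(
        {"Time (ps)": trajectory.times, "Backbone RMSD (A)": rmsd}
    )
    rmsf = _metrics.rmsf_per_residue(trajectory, selection=sel)
    rmsf_df = rmsf.reset_index()
    rmsf_df.columns = ["Chain", "Residue index", "Residue", "RMSF (A)"]
    return rmsd_df, rmsf_df


@_stage("lie")
def _lie_table(lie_training, ligand_energies) -> pd.DataFrame | None:
    if lie_training is None and ligand_energies is None:
        return None
    model = (
        _lie.lie_calibrate(lie_training)
        if lie_training is not None
        else _lie.LIEModel()
    )
    rows = [
        {
            "beta": model.beta,
            "alpha": model.alpha,
            "gamma": model.gamma,
            "Training MAE (kJ/mol)": np.nan if model.mae is None else model.mae,
            "dG predicted (kJ/mol)": np.nan,
            "dG error (kJ/mol)": np.nan,
        }
    ]
    if ligand_energies is not None:
        res = _lie.lie_predict(ligand_energies, model)
        rows[0]["dG predicted (kJ/mol)"] = res.dg_predicted
        rows[0]["dG error (kJ/mol)"] = res.dg_error
    return pd.DataFrame(rows)


def run_pipeline(
    config: AnalysisConfig,
    system: MolecularSystem,
    trajectory: Trajectory,
    lie_training: pd.DataFrame | None = None,
    ligand_energies: "_lie.LigandEnergies | None" = None,
    outdir: str | Path | None = None,
) -> ReportBundle:
    """Run the full analysis over one system/trajectory.

    The classification tables (contacts, H-bond regular/bifurcated
    summary) are evaluated on frame 0, mirroring a docked-pose snapshot;
    kinetics and energies use the whole trajectory restricted to the
    configured analysis window. Identical config and seed give
    byte-identical outputs.
    """
    if config.analysis_window is not None:
        if not trajectory.window_mask(config.analysis_window).any():
            raise PipelineError(
                "stage 'validate' failed: analysis window excludes all frames"
            )
    frame0 = trajectory.frames[0]
    contacts_df = _contacts_table(frame0, system, config)
    hbonds_df, hbond_summary_df = _hbond_tables(frame0, system, config)
    kinetics_df = _kinetics_table(trajectory, system, config)
    energy_df = _energy_table(trajectory, system, config)
    charges_df = _charges_table(system)
    waters_df = _waters_table(trajectory, system, config)
    rmsd_df, rmsf_df = _metrics_tables(trajectory, system)
    lie_df = _lie_table(lie_training, ligand_energies)

    bundle = ReportBundle(
        contacts=contacts_df,
        hbonds=hbonds_df,
        hbond_summary=hbond_summary_df,
        kinetics=kinetics_df,
        energy_summary=energy_df,
        charges=charges_df,
        waters=waters_df,
        rmsd=rmsd_df,
        rmsf=rmsf_df,
        lie=lie_df,
        manifest={
            "config": config.to_dict(),
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "n_atoms": system.n_atoms,
            "n_frames": trajectory.n_frames,
        },
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle
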