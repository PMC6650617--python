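"""RMSD/RMSF on a jittered trajectory, and the full pipeline report.

Jitters a toy complex with 0.3 A Gaussian noise per axis, measures the
per-frame backbone-style RMSD and the per-residue RMSF (analytic truth
sigma*sqrt(3)), then runs the end-to-end pipeline and writes its TSV
report tables.
"""

import numpy as np

import surfbind as sb

system, frame = sb.gen_toy_complex(
    sb.ToyComplexSpec(n_protein=60, n_ligand=6, n_water=4, box=40.0, seed=5)
)
traj = sb.gen_jitter_trajectory(system, frame, sigma=0.3, n_frames=400, seed=5)

rmsd = sb.rmsd_series(traj, frame)
print(f"mean RMSD vs clean reference: {rmsd.mean():.3f} A "
      f"(analytic sigma*sqrt(3) = {0.3 * np.sqrt(3):.3f} A)")

rmsf = sb.rmsf_per_residue(traj)
print(f"mean per-residue RMSF       : {rmsf.mean():.3f} A (same truth; "
      "superposition absorbs a little)")

cfg = sb.AnalysisConfig(seed=5)
bundle = sb.run_pipeline(cfg, system, traj, outdir="scratch/report")
print("\npipeline tables written to scratch/report/:")
for name, df in bundle.tables().items():
    print(f"  {name:15s} {len(df):4d} rows")
print("config hash:", bundle.manifest["config_hash"])
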