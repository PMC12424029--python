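"""Generate a ground-truthed synthetic acquisition batch.

Writes ten mzML runs emulating a QC injection sequence — three tracked
compounds, a per-run mass-calibration drift, a PEG-like constant
background appearing mid-sequence — plus a manifest.json recording the
true drift parameters of every run.
"""

import numpy as np

from lcmsqc import BatchConfig, ContaminantSpec, generate_batch

rng = np.random.default_rng(0)
config = BatchConfig(
    n_runs=10,
    scans_per_run=50,
    ppm_offsets=rng.uniform(-25, 25, 10).round(2).tolist(),
    rt_shifts=rng.uniform(-0.1, 0.1, 10).round(3).tolist(),
    contaminants=[
        ContaminantSpec("peg_background", 415.2538, "constant", 800.0,
                        active_runs=[5, 6, 7, 8, 9]),
    ],
    noise_baseline=20.0,
    noise_centroids_per_scan=5,
    seed=0,
)
paths, manifest = generate_batch(config, "example_batch")

print(f"wrote {len(paths)} runs to example_batch/")
for run in manifest["runs"]:
    print(f"  {run['filename']}: true ppm offset {run['ppm_offset']:+.2f}, "
          f"true RT shift {run['rt_shift']:+.3f} min")
# Each line is the ground truth that the tracking example should recover:
# the calibration offset (ppm) and retention-time shift (min) of that run.
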