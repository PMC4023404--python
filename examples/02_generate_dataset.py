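"""Generate the synthetic experimental campaign.

Each design mimics one real measurement modality: population blots and mass
spectrometry (multiplicative assay noise, few replicates), and single-cell
imaging (per-cell amplitude jitter plus measurement noise, each trace
re-normalized to its own pre-stimulus frame).  A single master seed makes
the whole campaign reproducible byte for byte.
"""

import pathlib

from erkshuttle import fitted_designs, generate_all, load_theta_ref

theta, obs = load_theta_ref()
out = pathlib.Path("example_output/dataset")
out.mkdir(parents=True, exist_ok=True)

datasets = generate_all(theta, fitted_designs(), seed=2014, obs=obs)

print(f"{'experiment':<14}{'readouts':<28}{'rows':>6}")
for exp_id, ds in datasets.items():
    readouts = ",".join(sorted(ds.data["readout"].unique()))
    print(f"{exp_id:<14}{readouts:<28}{len(ds.data):>6}")
    ds.to_csv(out / f"{exp_id}.csv")

print(f"\nwrote {len(datasets)} CSV files (+ sidecar metadata) to {out}/")
print("re-running this script reproduces the files exactly.")
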