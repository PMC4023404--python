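"""Simulate the reference cell and read out what a microscope would see.

The model tracks MEK activation, two-site ERK phosphorylation, nuclear
shuttling and substrate binding in a two-compartment cell.  This script runs
a sustained growth-factor step, converts the state trajectory into the four
standard live-cell / biochemical readouts, and prints the kinetic features
that summarize the response.
"""

import numpy as np

from erkshuttle import load_theta_ref, observe, simulate, step_stimulus
from erkshuttle.observables import t_half

theta, obs = load_theta_ref()

grid = np.arange(0.0, 75.0 + 1e-9, 0.5)
traj = simulate(theta, step_stimulus(1.0, t_end=75.0), grid)
traces = observe(traj, obs)

print("sustained stimulus, reference parameters")
print("----------------------------------------")

# nuclear accumulation: peaks early, then relaxes toward a plateau
nucloc = traces["nucloc"]
i_peak = int(np.argmax(nucloc.values))
print(f"nucloc peak        {nucloc.values[i_peak]:.3f}-fold at "
      f"t = {grid[i_peak]:.1f} min")

# phospho-ERK (what a western blot integrates over the whole cell)
pp = traces["ppERK_blot"]
i_pp = int(np.argmax(pp.values))
adapt = pp.values[grid == 60.0][0] / pp.values[i_pp]
print(f"ppERK peak         t = {grid[i_pp]:.1f} min, "
      f"60-min/peak = {adapt:.3f}")

# nuclear substrate activity rises much more slowly than cytosolic
for name in ("ekar_cyt", "ekar_nuc"):
    tr = traces[name]
    target = 1.0 + 0.9 * (tr.value_at(60.0) - 1.0)
    idx = np.nonzero(tr.values >= target)[0]
    print(f"{name} t90        {grid[idx[0]]:.1f} min")

# decay speed after acute MEK inhibition depends on when you inhibit
from erkshuttle import mek_inhibition

for label, t_inh in (("late (46 min)", 46.0), ("early (10 min)", 10.0)):
    g = np.arange(0.0, t_inh + 25.0 + 1e-9, 0.25)
    tr = observe(simulate(theta, mek_inhibition(t_inh, t_end=g[-1]), g),
                 obs, readouts=("nucloc",))["nucloc"]
    th = t_half(tr, t_inh, baseline=1.0)
    print(f"nucloc t1/2 after {label} inhibition: {float(th):.2f} min")
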