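"""Substrate buffering: why nuclear activity is slow and persistent.

Nuclear anchoring substrates act as a kinetic buffer for active ERK.  The
dimensionless buffering strength B = (S_tot / phi) / K_m compares the
substrate pool to the Michaelis constant of the ERK-substrate interaction.
With B >> 1 in the nucleus, incoming active ERK is soaked up by free
substrate, so free nuclear activity rises slowly; after MEK inhibition the
bound pool keeps releasing active ERK, so activity decays slowly too --
*if* the inhibition comes early, while the buffer is still filling.

This script computes B for the reference cell, shows where ERK sits during
the response, and demonstrates the early-versus-late inhibition asymmetry
that the buffering produces.
"""

import numpy as np

from erkshuttle import (
    buffering_strengths,
    classify_mode,
    load_theta_ref,
    mek_inhibition,
    run_predictions,
    simulate,
    step_stimulus,
)
from erkshuttle.analysis import species_breakdown

theta, obs = load_theta_ref()

B_c, B_n = buffering_strengths(theta)
print(f"cytosolic buffering B_c = {B_c:.2f}")
print(f"nuclear   buffering B_n = {B_n:.2f}")
print(f"regime: {classify_mode(B_c, B_n)}-dominant buffering\n")

# where is ERK at the peak of the response?
grid = np.arange(0.0, 60.5, 0.5)
traj = simulate(theta, step_stimulus(1.0, t_end=60.0), grid)
df = species_breakdown(traj)
row = df.iloc[int(np.searchsorted(grid, 9.0))]
print("ERK partitioning at t = 9 min (fractions of total ERK):")
print(f"  cytosolic free {row['c'] + row['cp'] + row['cpp']:.3f}   "
      f"cytosolic bound {row['cs']:.3f}")
print(f"  nuclear   free {row['n'] + row['np'] + row['npp']:.3f}   "
      f"nuclear   bound {row['ns']:.3f}\n")

# prediction: nuclear decay speed depends on when MEK is inhibited
summary = run_predictions(
    [(theta, obs)],
    protocols={"early (10 min)": mek_inhibition(10.0, t_end=35.0),
               "late (46 min)": mek_inhibition(46.0, t_end=71.0)},
    readouts=("nucloc",),
)
print("nucloc half-decay time after MEK inhibition:")
for (proto, _), stats in summary.t_half_stats.items():
    print(f"  {proto:<15} t1/2 = {stats['mean']:.2f} min")
print("\nearly inhibition decays several-fold more slowly: the partially "
      "filled\nnuclear buffer releases active ERK back into the free pool.")
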