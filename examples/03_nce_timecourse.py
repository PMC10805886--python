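"""Neuronal congruency effect (NCE) time courses for both unit roles.

The NCE is the congruent-minus-incongruent firing-rate difference per unit.
Distractor-role conditions (target outside the RF) show a persistent
negative NCE from ~90 ms after cue onset; target-role conditions show the
U-shaped pattern: positive immediately after the cue, negative 300-750 ms,
positive again later.  Stars mark 50 ms windows (stepped 10 ms) where the
across-unit signed-rank test rejects zero at p < 0.05.
"""

import numpy as np

from ncelab import SynthConfig, generate_session, nce_series

session = generate_session(SynthConfig(n_units=60), seed=2)

for role in ("distractor", "target"):
    ser = nce_series(session.units, session.trials, role=role, rule="both",
                     width=100.0)
    c = ser.bin_centers
    print(f"\nNCE, {role}-role conditions (n = {len(ser.unit_ids)} units)")
    for lo, hi in ((0, 200), (300, 750), (750, 1200)):
        sel = (c >= lo) & (c < hi)
        mean = np.nanmean(ser.pop_mean[sel])
        starred = 100 * np.mean(ser.stars[sel])
        print(f"  {lo:4d}-{hi:4d} ms: mean {mean:+6.2f} sp/s, "
              f"{starred:3.0f}% of bins significant")
print("\nDistractor role: persistently negative after ~90 ms."
      "\nTarget role: positive / negative / positive (the U shape).")
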