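"""Per-modality adaptive cosine schedules.

Coordinates (nu=2.5) keep their signal longest, bond types (nu=1.5) decay
faster, atom types (nu=1.0, the standard cosine schedule) fastest.  The
printed columns are the cumulative signal-retention coefficient alpha-bar;
the last column is the truncated-SNR loss weight used in training.
"""

import numpy as np

from poligen import NoiseSchedule

sched = NoiseSchedule(T=500)
print(f"{'t':>5} {'coords':>10} {'bonds':>10} {'atoms':>10} {'w_s(t)':>8}")
for t in (0, 50, 125, 250, 375, 450, 500):
    row = [sched.alpha_bar(t, m)
           for m in ("coords", "bond_types", "atom_types")]
    w = sched.snr_weight(max(t, 1))
    print(f"{t:>5} {row[0]:>10.4f} {row[1]:>10.4f} {row[2]:>10.4f} {w:>8.3f}")

# alpha-bar starts at ~1 (clean data), reaches the clamp floor at t=T (pure
# noise); at every step the coordinate column is the largest of the three.
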