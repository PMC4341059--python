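"""The three error processes, shown as single staged events on peptide GKEGK.

The true read of GK*EGK* (labeled lysines at positions 2 and 5) is "xKxxK".
A dye failure deletes a drop; a failed Edman cycle delays later drops; a
photobleach moves a drop to an earlier cycle (an apparent upstream residue).
"""

import numpy as np

from fluorosim import (
    ErrorParams,
    Peptide,
    apply_edman_dilation,
    apply_photobleaching,
    dilation_pmf,
    encode_ideal,
    halflife_to_decay_constant,
    label_positions,
    simulate_batch,
)

pep = Peptide("GKEGK", "demo", anchor_index=None)
print("true read:", encode_ideal(pep, "K", 5).pattern(5))

labels = label_positions(pep, "K")

# (a) dye failure on the first lysine: the drop at cycle 2 vanishes
survivors = labels[1:]
removal = apply_edman_dilation(survivors, 1.0, None, np.random.default_rng(0))
read = apply_photobleaching(removal, 0.0, 5, np.random.default_rng(0))
print("dye failure at K2:       ", read.pattern(5))

# (b) photobleach of the K5 dye during imaging cycle 3: drop moves to cycle 3
class Scripted:
    def __init__(self, values): self.values = list(values)
    def exponential(self, scale): return self.values.pop(0)

removal = apply_edman_dilation(labels, 1.0, None, np.random.default_rng(0))
read = apply_photobleaching(removal, halflife_to_decay_constant(20), 5,
                            Scripted([10.0, 2.5]))
print("photobleach of K5 at c3: ", read.pattern(5))

# (c) Edman inefficiency dilates inter-label intervals: an interval of d
# residues takes d+e cycles with negative-binomial probability
print("\nP(interval d=2 takes 2+e cycles) at 90% Edman efficiency:")
for e in range(4):
    print(f"  e={e}: {dilation_pmf(2, e, 0.9):.4f}")

# all three at once, sampled
params = ErrorParams(0.2, 0.9, halflife_to_decay_constant(20))
counts = simulate_batch(pep, "K", params, 6, 10_000, np.random.default_rng(1))
print("\nmost frequent observed reads (u=0.2, p=0.9, half-life 20, 10k copies):")
for read, count in sorted(counts.items(), key=lambda kv: -kv[1])[:5]:
    print(f"  {read.to_string():14s} {count / 100:5.1f}%")
print("Only a fraction of copies reproduce the true read — attribution must")
print("therefore be statistical, which is what the trie provides.")
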