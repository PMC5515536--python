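"""Event-level QC of simulated reads: stays, skips, currents, model shift.

Simulates device-style event tables with known stay/skip probabilities and
Gaussian current noise, then recomputes the per-read QC statistics and the
per-k-mer shift of observed currents against the pore model.
"""

import numpy as np

from squiggleid import compute_qc, current_summary, model_shift, synthesize_pore_model
from squiggleid.fixtures import simulate_read_events
from squiggleid.simulate import random_genome

model = synthesize_pore_model(k=5, seed=7)
genome = random_genome(20_000, seed=31)

reads = [
    simulate_read_events(
        genome[i * 1500 : i * 1500 + 1500], model, seed=40 + i,
        stay_prob=0.3, skip_prob=0.1, noise_sd=1.5, read_id=f"read_{i}",
    )
    for i in range(10)
]

for read in reads[:3]:
    qc = compute_qc(read)
    print(f"{qc.read_id}: {qc.n_events} events, {qc.bases_called} bases, "
          f"{qc.stays_per_base:.3f} stays/base, {qc.skips_per_base:.3f} skips/base, "
          f"median current {qc.median_current:.1f} pA, noise {qc.median_noise:.2f} pA")

_, cohort_median = current_summary(reads)
table, shift = model_shift(reads, model)
print(f"cohort median current: {cohort_median:.2f} pA")
print(f"global mean shift vs pore model: {shift:+.3f} pA over {len(table)} k-mers")

# With stay probability 0.3 (geometric continuation) and 10% skips the
# expected rates are ~0.386 stays/base and ~0.100 skips/base; the mean shift
# should be ~0 pA because event currents are centred on the model levels.
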