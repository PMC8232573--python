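"""Karyotype and FISH detection of small clones, emulated.

Karyotyping scores 20 cultured metaphases and needs >= 2 abnormal ones;
FISH scores 200 interphase nuclei against probe-specific positivity
cutoffs (7% single-locus / break-apart, 2.3% dual-fusion). This prints
empirical detection rates across clonal fractions.
"""

import numpy as np

from panelcnv import emulate_fish, emulate_karyotype

rng = np.random.default_rng(11)
print(f"{'f':>5} {'karyotype':>10} {'FISH s.l.':>10} {'FISH d.f.':>10}")
for f in (0.02, 0.05, 0.10, 0.20, 0.50):
    k = np.mean([emulate_karyotype(f, rng=rng)[2] for _ in range(2000)])
    sl = np.mean([emulate_fish(f, rng=rng)[1] for _ in range(2000)])
    df = np.mean([emulate_fish(f, probe_type="dual_fusion", rng=rng)[1]
                  for _ in range(2000)])
    print(f"{f:5.2f} {k:10.2f} {sl:10.2f} {df:10.2f}")

print("\nKaryotyping reaches useful sensitivity around a ~10% clone "
      "(with the 1.3x culture growth bias), single-locus FISH near its 7% "
      "cutoff, and dual-fusion probes already at ~2-3% - all far below "
      "the ~50% clonality a read-depth caller needs at the 2.5/1.5 "
      "cutoffs.")
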