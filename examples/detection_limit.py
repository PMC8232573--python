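"""Clonal-fraction detection limit of the read-depth caller.

Runs a scaled-down replicate experiment: a single-copy whole-chromosome
gain spiked at clonal fractions 1.0 and 0.3 into a 2000-region panel at
~300x coverage. The 2.5/1.5 copy-number cutoffs translate into a ~50%
clonality floor for single-copy events (CN = 2 +/- f).
"""

from panelcnv.experiments import detection_limit_experiment

res = detection_limit_experiment(n_replicates=10, seed=7)
print(f"replicates: {res.n_replicates}")
print(f"f = 1.0  ->  called in {res.called_rate_clonal:.0%} "
      f"(mean CN {res.mean_cn_clonal:.2f})")
print(f"f = 0.3  ->  called in {res.called_rate_subclonal:.0%} "
      f"(mean CN {res.mean_cn_subclonal:.2f})")
print("\nThe clonal trisomy sits at CN ~3.0, comfortably above the 2.5 "
      "cutoff; the 30% clone sits at CN ~2.3 and is invisible to the "
      "caller, which is why minor-clone trisomies are found only by "
      "cytogenetics.")
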