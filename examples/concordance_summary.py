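"""Summarise the packaged cohort study's NGS-vs-cytogenetics concordance.

Loads the discordant-alteration tables and aggregate counts shipped with
the package (a published 138-patient myeloid-neoplasm cohort), rebuilds
the methodology tally and prints shares, chromosome frequencies and the
dominant discordant alterations.
"""

from panelcnv.concordance import (
    below_fish_cutoff,
    chromosome_frequencies,
    count_by_alteration,
    load_study_aggregates,
    load_study_records,
    study_tally,
    tally_shares,
)

tally = study_tally()
both, cyto_only, ngs_only = tally_shares(tally)
print(f"{tally.total} recurrent alterations: "
      f"{tally.n_both} by both techniques ({both}%), "
      f"{tally.n_cyto_only} cytogenetics-only ({cyto_only}%), "
      f"{tally.n_ngs_only} NGS-only ({ngs_only}%)")

agg = load_study_aggregates()
freqs = chromosome_frequencies(agg["chromosome_counts"],
                               agg["n_alterations_total"])
print("\nmost involved chromosomes:")
for chrom, (n, pct) in sorted(freqs.items(), key=lambda kv: -kv[1][0]):
    print(f"  {chrom}: {n}/{agg['n_alterations_total']} ({pct:.0f}%)")

cyto, ngs = load_study_records()
print(f"\ncytogenetics-only trisomy 8: {count_by_alteration(cyto, 'Trisomy 8')}"
      f" of {len(cyto)} | NGS-only del(12p): "
      f"{count_by_alteration(ngs, 'del(12p)')} of {len(ngs)}")

low = below_fish_cutoff(cyto, 10)
print(f"cytogenetics-only alterations with uncultured FISH < 10%: "
      f"{sorted(r.patient for r in low)}")
print("\nThose low-FISH cases are small clones: a 30% trisomy clone gives a "
      "bulk CN of 2.3, under the 2.5 duplication cutoff, so read depth "
      "cannot call it while a karyotype can still see 2+ abnormal metaphases.")
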