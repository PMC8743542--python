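"""Analyse a small synthetic cohort and print the cross-genome statistics.

The paper-style cohort jitters genome length, TIR extent, island size and
parS count per genome; `summarize_cohort` aggregates means and ranges the
way the per-cohort tables in comparative-genomics papers do.  Five genomes
keep this example quick; the acceptance script runs the full 20.
"""

from linarch.architecture import summarize_cohort
from linarch.pipeline import RunConfig, analyze_replicon
from linarch.synthetic import generate_cohort

summaries = []
for rec, truth in generate_cohort(5, seed=7):
    rep = analyze_replicon(rec, RunConfig())
    s = rep.summary
    summaries.append(s)
    print(f"{s.replicon_id}: {s.length:,} bp, TIR {s.tir_perfect:,} bp, "
          f"telomeres {s.telomere_left}/{s.telomere_right}, "
          f"{s.pars.n_sites} parS ({s.pars.pct_right:.0f}% right)")

cohort = summarize_cohort(summaries)
print(f"\ncohort of {cohort.n_chromosomes} chromosomes — means (min..max):")
for key in ("length", "tir_perfect", "island_size", "island_location_pct",
            "n_pars", "pct_right", "pct_in_island"):
    lo, hi = cohort.ranges[key]
    print(f"  {key:22s} {cohort.means[key]:14,.2f}  ({lo:,.2f} .. {hi:,.2f})")
print("\nThe island sits near mid-chromosome and parS sites stay ~80% on "
      "the right replichore across every genome — the conserved bilateral "
      "architecture the pipeline quantifies.")
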