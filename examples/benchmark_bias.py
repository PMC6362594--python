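"""Quantify the copy-number bias with stratified recall curves (AURC).

Non-expressed genes cannot have a genuine fitness effect, so their
enrichment among the most depleted fold changes measures gene-independent
bias.  Stratifying them by copy-number ratio shows the bias concentrates in
focally amplified strata, and that the per-sample GP correction removes it
without disturbing essential-gene recall.
"""

from crispy import (
    FoldChangeTable,
    essential_recall,
    filter_low_plasmid,
    gene_level,
    log2_foldchange,
    ratio_stratum,
    run_sample,
    size_factor_normalize,
    stratified_aurc,
)
from crispy.simulate import SimulationConfig, simulate_dataset

cfg = SimulationConfig(seed=1)
genome, screen = simulate_dataset(cfg)
gt = screen.ground_truth

filtered = filter_low_plasmid(screen.counts)
norm = size_factor_normalize(filtered)
guide_fc = log2_foldchange(norm, screen.counts.plasmid_id)
fc = guide_fc.fc.mean(axis=1)
result = run_sample(fc, genome.library, genome.segments, sample=cfg.cell_line)

original = gene_level(FoldChangeTable("guide", guide_fc.fc), genome.library).fc.mean(axis=1)
corrected = result.gene_table.set_index("gene")["corrected_fc"].loc[original.index]

nonexpressed = set(gt.index[gt["nonexpressed"]])
strata = {g: ratio_stratum(r) for g, r in gt["ratio"].items()}

before = {r.stratum: r for r in stratified_aurc(original, strata, nonexpressed)}
after = {r.stratum: r for r in stratified_aurc(corrected, strata, nonexpressed)}

print("AURC of non-expressed genes by copy-number-ratio stratum")
print(f"{'stratum':>8} {'n':>5} {'before':>8} {'after':>8}")
for label in sorted(before):
    print(f"{label:>8} {before[label].n_genes:>5} "
          f"{before[label].aurc:>8.3f} {after[label].aurc:>8.3f}")

essentials = set(gt.index[gt["essential"]])
print(f"\nessential-gene AURC: {essential_recall(original, essentials):.3f} before, "
      f"{essential_recall(corrected, essentials):.3f} after")
print("0.5 = no enrichment; amplified strata collapse toward 0.5 after")
print("correction while the essential-gene recall is preserved.")
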