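"""Match structural-variant calls to copy-number segments by breakpoint proximity.

Confident tandem-duplication and deletion calls (assembly score required) are
matched to segments whose start and end agree within 10 kb.  Tandem
duplications should land on segments with copy-number ratio above 1 and
deletions below 1 — the genomic signature behind the ratio metric.
"""

from crispy import (
    chromosome_cn,
    filter_confident_svs,
    match_sv_to_segments,
    sv_class_comparison,
)
from crispy.simulate import SimulationConfig, simulate_genome

cfg = SimulationConfig(seed=1)
genome = simulate_genome(cfg)

confident = filter_confident_svs(genome.svs)
print(f"{len(genome.svs)} SV calls, {len(confident)} confident "
      f"tandem duplications / deletions (scored, correct type)")

matches = match_sv_to_segments(confident, genome.segments, tolerance_bp=10_000)
print(f"{len(matches)} SV-segment matches within 10 kb at both breakpoints")

all_segments = [s for lst in genome.segments.values() for s in lst]
chrom_cn = {c: chromosome_cn(all_segments, c) for c in genome.segments}
ratios = {
    f"{s.chrom}:{s.start}-{s.end}": s.copy_number / chrom_cn[s.chrom]
    for s in all_segments
}

summary = sv_class_comparison(matches, ratios)
for cls, stats in summary["classes"].items():
    print(f"{cls}: n = {stats['n']}, median copy-number ratio = "
          f"{stats['median_ratio']:.2f}")
test = summary["tests"]["ratio"]
print(f"Welch's t test (ratio, tandem dup vs deletion): "
      f"t = {test['t']:.2f}, p = {test['p']:.2e}")
print("tandem duplications sit above ratio 1, deletions below: breakpoint-")
print("matched segments confirm what the ratio metric encodes.")
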