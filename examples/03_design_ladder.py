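"""Run the full one-step stabilization workflow on a synthetic bundle.

Confidence masking, PSSM filtering, membrane-aware scoring, an 18-threshold
ladder of nested sequence spaces, and selection of the lowest-scoring
mutation combination in each space: designs run from conservative (d1, few
mutations) to promiscuous (d18, many).
"""

import memstab
from memstab import fixtures as fx

bundle = fx.make_helix_bundle(seed=1, plddt_dips=[(40, 48, 70.0)])
tolerated = {
    pos: "".join(a for a in "ASTVLIF" if a != bundle.sequence[pos - 1])[:2]
    for pos in (10, 35, 75, 102, 150, 188, 205)
}
aln, _ = fx.make_msa(bundle.sequence, n_rows=50, tolerated=tolerated, seed=1)

config = memstab.PipelineConfig(tm_ranges=fx.tm_ranges_for_bundle(7, 30), seed=1)
report = memstab.run_design_pipeline(bundle, aln, config)

print(f"{len(report.candidates)} stabilizing candidates survived all filters")
print("design  mutations  total_score")
for d in report.designs:
    print(f"{d.name:>6s}  {d.n_mutations:9d}  {d.total_score:11.3f}")
# Mutation counts grow monotonically down the ladder because the sequence
# spaces are nested: a looser energy threshold only ever adds options.
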