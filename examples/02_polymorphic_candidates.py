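"""Call candidate polymorphic SSRs across assemblies.

Simulates three related assemblies in which half of the planted repeats
shift length, then identifies loci whose repeat counts vary (SD > 0)
with flanks found in at least half of the query assemblies.
"""

from ssrcore import SimulationConfig, call_candidates, generate_assemblies

aset = generate_assemblies(
    SimulationConfig(
        n_unigenes=40, n_planted_ssrs=20, n_assemblies=3,
        repeat_shift_prob=0.5, flank_substitution_rate=0.01, seed=4,
    )
)
reference = aset.assemblies[aset.reference_id]
queries = {k: v for k, v in aset.assemblies.items() if k != aset.reference_id}

candidates = call_candidates(reference, queries)
truth_poly = {t.unigene_id for t in aset.truth if t.polymorphic}

print(f"planted loci: {len(aset.truth)}, truly polymorphic: {len(truth_poly)}")
print(f"candidates called: {len(candidates)}")
for cand in candidates[:6]:
    counts = ", ".join(
        f"{a}={'.' if c is None else c}" for a, c in cand.repeat_counts.items()
    )
    print(
        f"  {cand.annotationless_id} {cand.reference_locus.sequence_id} "
        f"({cand.reference_locus.motif})n  repeats: {counts}  "
        f"sd={cand.sd:.3f} miss={cand.miss_rate:.2f}"
    )
# Each candidate is a marker whose repeat number differs between
# assemblies: exactly the loci worth designing primers for, since the
# length difference is genotypable on a gel.
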