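"""Predict virus-host links by the three complementary methods.

A small cohort is generated with planted prophages, CRISPR spacers and
k-mer signatures; the integrated predictions are compared against the
planted truth.
"""

from collections import Counter

from cutovir.host_linking import link_all
from cutovir.synthetic_community import CohortConfig, generate_cohort

config = CohortConfig(n_hosts=6, n_viruses=10, n_prophage=3, n_spacer_viruses=3,
                      simulate_profiles=False)
cohort = generate_cohort(3, 3, config, seed=11)

links = link_all(cohort.viruses, cohort.hosts, seed=2)
predicted = {l.pair for l in links}
true = cohort.truth.link_pairs()
tp = predicted & true

print(f"predicted links: {len(predicted)}, planted links: {len(true)}")
print(f"precision {len(tp) / len(predicted):.2f}, recall {len(tp) / len(true):.2f}")
print("method support:", dict(Counter(m for l in links for m in l.methods)))
for link in links[:3]:
    print(f"  {link.virus_id} -> {link.host_id} via {link.methods}")
# Every planted pair should be recovered; prophages appear as
# shared_region hits, arrays as spacer hits, and the k-mer signature
# method covers all viruses emitted from a host's composition model.
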