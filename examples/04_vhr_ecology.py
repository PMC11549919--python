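"""Classify each cutotype's virus-host regime from VHR patterns.

Coverage is measured from simulated depth profiles (trimmed-mean with
breadth filtering, then depth normalization), virus-to-host abundance
ratios are computed per link and sample, and each group is classified
as Piggyback-the-Winner or Piggyback-the-Persistent/Loser.
"""

from cutovir.abundance import build_abundance_matrix, normalize_depth
from cutovir.ecology import classify_groups
from cutovir.host_linking import HostLink
from cutovir.synthetic_community import generate_cohort

cohort = generate_cohort(10, 10, seed=4)
matrix = build_abundance_matrix(cohort.profiles, cohort.read_counts)
norm = normalize_depth(matrix)  # depth_corrected mode

links = [HostLink(v, h, ("truth",)) for v, h in sorted(cohort.truth.link_pairs())]
calls = classify_groups(
    norm.values, links, cohort.truth.cutotype_of_sample, [h.id for h in cohort.hosts]
)

for g, call in calls.items():
    print(f"cutotype {g}: {call.model}")
    print(f"  winner {call.winner_taxon} at {call.winner_abundance:.0%} "
          f"host-relative abundance, mean VHR {call.winner_vhr:.2f}")
    print(f"  remaining hosts' median VHR {call.rare_host_median_vhr:.2f}")
# Cutotype 1: dominant winner with VHR < 1 (lysogeny on the winner,
# lysis on the rare) -> PtW.  Cutotype 2: no dominant host, prevalent
# hosts at VHR <= 1 -> PtP_or_PtL.
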