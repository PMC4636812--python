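"""Co-occupancy between two factors, by k-means clusters and by overlap.

The simulation plants 60 % co-binding between factors A and B; both
estimators should land near that value.
"""

from chipmeta.scenarios import run_tss_cobinding

res = run_tss_cobinding(seed=1)
print(f"reference sites (factor A peaks): {res.n_reference_sites}")
print(f"planted co-binding:               {res.planted_cobind_pct:.1f} %")
print(f"cluster-positivity estimate:      {res.cobind_cluster_pct:.1f} %")
print(f"interval-overlap estimate:        {res.cobind_overlap_pct:.1f} %")
print("the cluster estimate partitions A's sites by B's density profile; the "
      "overlap estimate requires a called B peak to intersect the A peak.")
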