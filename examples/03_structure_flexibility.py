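"""Backbone flexibility of germline-recovered positions.

Runs the full pipeline, then compares the circular phi/psi deviation of
columns that reverted to germline in multi-state design (per-column
bit-score > 1) against those that did not. The planted 20-degree jitter at
flexibility columns should make the recovered group visibly more mobile.
"""

import polyspec as ps

res = ps.run(ps.RunConfig(out_dir="example_run", synthetic={"seed": 1},
                          base_seed=100))

g = res.group_comparison
print(f"germline-recovered columns: {g.mean_recovered:.1f} +/- "
      f"{g.sem_recovered:.1f} deg (n={g.n_recovered})")
print(f"non-recovered columns:      {g.mean_other:.1f} +/- "
      f"{g.sem_other:.1f} deg (n={g.n_other})")
print(f"two-sample t-test p = {g.ttest.pvalue:.2g}")
print(f"all-beta-framework reference: {g.reference_mean:.1f} deg")
print()
print("interface occurrence bins (mean per-column germline bits):")
for b in res.occurrence_bins:
    mean = "empty" if b.mean is None else f"{b.mean:.2f}"
    print(f"  occurs {b.label:>3} times: n={len(b.columns):2d}  mean bit {mean}")

# Larger deviation in the recovered group supports the reading that
# germline residues at those positions maintain conformational flexibility;
# the bin means rise as a column sits in more complex interfaces.
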