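"""Energetic cost of forcing designed positions back to germline.

Where multi-state design chose the germline residue in fewer than 10% of
the 100 trajectories, the germline identity is forced and the per-state
energy change is tabulated. Costs above 0.7 REU in some state mark
positions where the design genuinely prefers its own solution; smaller
costs mean the germline residue is tolerated and the deviation reflects
near-degenerate alternatives.
"""

import polyspec as ps

res = ps.run(ps.RunConfig(out_dir="example_run", synthetic={"seed": 1},
                          base_seed=100))

print(f"{len(res.reversions)} candidate columns "
      f"(germline chosen in <10% of trajectories)")
for r in res.reversions:
    worst = max(r.delta_e_by_state.values())
    tag = "SIGNIFICANT" if r.significant else "tolerated"
    print(f"  column {r.column:2d}: designed {r.designed_modal_aa} vs germline "
          f"{r.germline_aa}; worst-state dE = {worst:+.2f} REU  [{tag}]")

mean, sd, n = res.tolerance_estimate
print(f"\nsignificance tolerance recomputed from the data: "
      f"{mean:.2f} +/- {sd:.2f} REU over {n} mutated positions "
      f"(fixed constant: 0.7 REU)")
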