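"""Generate a synthetic antibody/antigen ensemble with planted truth.

Builds the default bundle: eight toy antibody/antigen complexes sharing a
germline heavy-chain sequence, with a 4-to-20 somatic-mutation gradient,
per-state energy tables, beta-strand backbones and pseudo-atom antigens.
"""

import collections

import polyspec as ps

bundle = ps.generate(ps.GeneratorSpec(seed=1), out_dir="example_bundle")

print(f"germline:  {bundle.truth['germline']}")
print(f"designed columns ({len(bundle.designed_columns)}):",
      list(bundle.designed_columns))
print("position classes:",
      dict(collections.Counter(bundle.truth["classes"].values())))
for cid, seq in bundle.alignment.mature.items():
    muts = bundle.truth["mutated_columns"][cid]
    print(f"{cid}: {len(muts):2d} somatic mutations, "
          f"{len(bundle.truth['interface_columns'][cid])} interface sites")
print("files written to example_bundle/ (MSA, energy TSVs, PDBs, truth JSON)")

# The classes drive everything downstream: 'flex' columns are
# germline-optimal in every state (polyspecificity positions), 'spec'
# columns have a state-specific mature optimum, 'shared' columns penalize
# germline everywhere, 'neutral' columns tolerate several residues.
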