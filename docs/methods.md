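# Methods

`polyspec` reverses antibody affinity maturation in silico at desk scale.
Given an ensemble of antibody/antigen complexes whose heavy chains derive
from one germline V-gene, it asks which amino-acid sequence is optimal for
binding *all* antigens at once (multi-state design) versus each antigen
alone (single-state design), and quantifies how strongly each answer
resembles the germline versus the somatically mutated sequences. This note
records the model, its assumptions, the tunable parameters, and the design
choices made where the design was genuinely open.

## The design model

The unit of optimization is a sequence over the *designed positions*: the
alignment columns at which at least one mature sequence differs from the
germline reference. Alignment columns (1-based) are the canonical
coordinate system; per-structure residue numbering enters only through an
explicit column→(chain, residue) map supplied as input. Columns gapped in
any record, and columns conserved across all matures, are excluded — no
claim can be made about positions that never varied.

Energies come from a pluggable table contract rather than a physical
force field: each state (one complex) supplies `E(column, amino acid)` in
REU-like units on a common scale, with an optional 20×20 pairwise coupling
between column pairs. The *design fitness* of a sequence is the target
state's energy (single-state) or the unweighted sum over all states
(multi-state); the same sequence is threaded through every state via the
alignment correspondence. Summation is the natural reading of an
"energetic consensus" and is equivalent to the mean up to scale. Tables
may be synthetic (below) or exported from any external scorer; everything
downstream is agnostic to their origin. Cross-residue comparability of
energies is the table supplier's responsibility.

### Optimizer

Sequences are optimized by Metropolis simulated annealing over
single-position substitutions (uniform over the 19 alternatives), with a
geometric temperature schedule (5.0 → 0.05 REU, 30 rungs, 50·|columns|
proposals per rung; all knobs overridable), followed by a deterministic
greedy per-position quench until no single substitution improves the
fitness. The quench matters: at the final temperature, positions whose
best and second-best residues differ by a fraction of an REU would
otherwise end in a Boltzmann mixture rather than at the optimum. For
additive tables the quench lands exactly on the separable global optimum;
with pairwise couplings it lands on a local optimum of the
single-substitution neighborhood, which is why the coupled-landscape test
asserts only that the global optimum is the modal outcome. One design
experiment runs 100 independent trajectories (trajectory *i* seeded
`base_seed + i`, bit-reproducible), mirroring the noise-averaging role of
repeated design simulations.

`enumerate_exact` is the independent oracle: per-column argmin for
additive tables (any size), brute force up to 20^n ≤ 10^7 with couplings.
Ties break toward the lexicographically smaller sequence and are flagged.

## Recovery statistics

For each designed column the ensemble yields frequencies `p_i` of the 20
amino acids. Against a reference residue with frequency `p`, the
self-information is

    I = p · log2(20 · p)   [bits],

zero when the residue appears at the uniform background 1/20, and
log2(20) = 4.3219 bits when every trajectory selects it (I(0) := 0 by the
limit convention). A design's total bit-score against a reference
(germline, or one complex's mature sequence) sums the per-column bits; the
normalized score divides by log2(20) × n_columns so 1.0 means perfect
recovery. Negative self-information (reference below background) is
clamped to zero for scoring — bit-scores are treated as non-negative
evidence — while the raw value is emitted alongside in the per-column TSV.
The normalization denominator uses the exact log2(20), not the rounded
4.32.

Derived quantities:

* **Δbit-score** = normalized(mature) − normalized(germline); positive
  means the design leans toward the mature (monospecific) sequence.
* **Maturation correlation**: Pearson r/r² of Δbit-score against the
  mutation percentage (mutations / non-gap aligned columns × 100). The
  pipeline applies it to the single-state Δbit-scores, where in-silico
  maturation makes the expected slope positive; the function itself is
  direction-agnostic.
* **Significance**: Wilcoxon matched-pairs (exact for n ≤ 25 without
  zeros, normal approximation otherwise) for germline-vs-mature scores
  within a protocol; paired t for between-protocol comparisons. With
  fewer than 5 pairs the pipeline reports the tests as unavailable rather
  than failing. Identical samples are flagged degenerate with p = 1. No
  multiple-testing correction is applied.
* Three fixed thresholds, all named constants: a column *contributes*
  recovery when its bit > 0, is *recovered* when bit > 1 (used for the
  flexibility grouping), and is a *reversion candidate* when the germline
  frequency is strictly below 10%.

## Structure measures

Backbone phi/psi follow the IUPAC convention; terminal residues, chain
breaks (C–N > 2.5 Å) and residues missing N/CA/C leave the affected
angles undefined rather than fabricated. Beta-framework membership uses a
Ramachandran-region rule — phi ∈ [−180°, −45°] and psi ∈ [45°, 180°] ∪
(−180°, −135°] — as a deliberate desk-scale stand-in for hydrogen-bond
based secondary structure; a per-residue override string is accepted for
users with an external assignment. Altlocs resolve to highest occupancy;
waters and heteroatom records are ignored.

Burial is a scalar neighbor count: for each residue center (Cβ, Cα for
glycine) the sum over all other centers of a weight that is 1 at or below
3.3 Å, 0 at or beyond 11.1 Å, and cosine-smooth between. The cited
falloff bounds are adopted because the original publication of the method
gives them; the orientation-weighted "neighbor vector" variant is out of
scope since every threshold used here is a scalar count. Interface
membership is the bound-minus-unbound change: the unbound antibody is the
same coordinates with antigen chains deleted (no repacking), and a
residue is an interacting residue iff its neighbor count drops by
strictly more than 1.0. Interface *occurrence* of a column is the number
of complexes classifying it as interacting; per-column germline bits are
binned by occurrence {0, 1, 2–4, ≥5} with mean ± SD per bin (empty bins
stay empty).

Per-column backbone variability across the ensemble is the circular
(directional) standard deviation sqrt(−2 ln R) of phi and of psi, averaged
into one combined number per column. The circular form is used because
arithmetic SD is wrong at the ±180° wrap ({179°, −179°} must give ≈1°,
not ≈253°); an arithmetic flag exists for comparison. Whether phi and psi
should be pooled per residue or per angle was open; the per-residue mean
of the two SDs is used. With the beta filter on, a column counts only if
labeled beta in a strict majority of its structures (ties → excluded).
Columns present in fewer than two structures are dropped. The
recovered-vs-other comparison groups columns by germline bit strictly
above/below 1 (exactly 1 → excluded), reports mean ± SEM per group and a
two-sample t-test, plus a reference deviation over *all* beta framework
columns including conserved ones.

## Reversion energetics

Columns whose germline frequency in the multi-state ensemble is below 10%
are forced back to germline: per state, ΔE = mean over trajectories of
`E(column, germline) − E(column, trajectory residue)` — a direct table
difference, since the table contract has no repacking step. A column is
*significant* when ΔE exceeds 0.7 REU in at least one state; otherwise
the germline residue is "tolerated as well" and the design's deviation
reflects near-degenerate alternatives (evolutionary sequence bias). The
candidate rule's source phrasing ("not chosen in at least 10%") is
grammatically ambiguous; frequency < 10% ⇒ candidate is implemented, and
the alternative reading is noted here. The 0.7 REU constant can be
recomputed from the data as the mean |E(germline) − E(mature)| over
somatically mutated (state, column) pairs, for comparison against the
fixed value.

## Synthetic study conditions

The generator emulates a germline test set end to end; its defaults are
the package's study conditions and are not tuned per experiment:

| parameter | default | meaning |
|---|---|---|
| n_columns / n_states | 40 / 8 | V-gene columns; complexes per germline group |
| n_flex / n_spec / n_shared / n_neutral | 10 / 15 / 2 / 5 | designed-position classes (32 designed columns) |
| g_flex | 2.0 REU | germline margin at flexibility columns, every state |
| g_spec | 1.0 REU | germline penalty in a mutated state at specificity columns |
| g_other | 3.0 REU | floor for disfavored residues |
| shared_penalty | 1.5 REU | germline penalty at shared columns, every state |
| sigma_e | 0.1 REU | noise inside neutral tolerated sets (clipped ±0.3) |
| mutations_min..max | 4..20 | somatic-mutation gradient across states |
| sigma_flex / sigma_rigid | 20° / 5° | phi/psi jitter at flex / other columns |
| antigen_distance | 5.0 Å | pseudo-atom offset from a site's Cβ |

*Flexibility* (flex) columns have the germline residue as each state's
energy optimum — the polyspecificity signal multi-state design should
recover. *Specificity* (spec) columns give each mutated state its own
mature optimum (germline second at g_spec), so single-state design
recovers maturation while the multi-state sum still prefers germline. A
small *shared* subset penalizes germline in every state — positions where
the design solution genuinely beats germline (the significant reversions).
*Neutral* columns hold a small tolerated set within a fraction of an REU,
yielding reversion candidates whose cost stays below 0.7 REU. The
maturation gradient allocates each state's budget ≈70% to spec columns,
the rest to flex and neutral with class coverage enforced (every designed
column mutates somewhere); the more-mature half of the states carries the
shared mutations. Energies are additive by default so the exhaustive
oracle applies globally; a pairwise-coupling option exists to stress the
optimizer.

Structures are ideal-geometry backbones built from internal coordinates
(NeRF; N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, ω = 180°) around ideal
beta (φ = −120°, ψ = 130°) with per-column Gaussian jitter, plus
idealized Cβ atoms. Generated sequences avoid glycine so every residue
carries a Cβ center; glycine handling (Cα fallback) is exercised with
hand-built models in the tests. The antigen is a pseudo-residue chain of
Cβ-like atoms: two atoms per interface site, ~5 Å outward of the site's
Cβ, giving the site a Δneighbor of ≈1.8 while flanking residues stay well
under the 1.0 threshold. Interface sites are drawn from germline-optimal
columns, pairwise ≥5 columns apart, with no neutral/shared column within
±2 — under backbone jitter the falloff of one site can still implicate a
residue two positions away, and this placement guarantees such spillover
only ever lands on another high-recovery (or undesigned) column. The
truth record asserts that every planted site is detected; occasional
extra detections in a site's ±2 periphery are part of the contract, not
an error. The shared/neutral block is placed as one contiguous run of
designed columns (a loop-like segment) to keep long germline-optimal
stretches available for sites.

### What the generator does and does not emulate

It reproduces the *statistical* structure of the real analysis — a
germline-consensus signal across states, state-specific maturation, a
maturation gradient, interface-linked recovery, flexibility-linked
recovery, and tolerated-alternative reversions — with planted effect
sizes large enough that directional outcomes are stable across seeds. It
does not produce immunoglobulin folds, side chains beyond Cβ, realistic
packing densities (extended toy strands bury far fewer neighbors than a
folded domain, so absolute burial values are not comparable), or a
physical energy function. With additive tables the fitness landscape is
separable, so the 100 trajectories typically coincide exactly and
per-column bits sit at 0 or 4.32; profile spread comparable to a rugged
physical scorer appears only with pairwise couplings. Passing tests
therefore demonstrate the correctness and direction of the *analysis
machinery*, not the physical claims about real antibodies.

## Problem sizes and numerics

The default experiment (8 states, 32 designed columns, 100 trajectories,
1 multi-state + 8 single-state designs) runs in a few seconds; the
acceptance script's oracle study uses 20 random tasks of 2–10 columns and
3–10 states, and the seed-sweep tests use 20 generator seeds — sizes
chosen so the whole suite stays interactive on one core. Angles are kept
in (−180°, 180°]; the circular SD of numerically identical angles can
come out at ~1e-7 degrees rather than exactly zero (float resultant
length marginally below 1). Bit-exact reproducibility holds for fixed
seeds: all randomness flows from one base seed per experiment.

## Known limitations

* The unbound-state neighbor counts reuse bound coordinates; induced-fit
  changes upon unbinding are invisible by construction.
* The beta assignment is a Ramachandran box, not hydrogen-bond topology;
  isolated extended residues can be labeled beta.
* The annealer's move set is single-substitution; strongly coupled tables
  can trap it in local optima (documented behavior, tested).
* Table energies have no notion of side-chain conformation, so "forcing"
  germline is a lookup, not a re-design; this is faithful to the table
  contract but weaker than a physical reversion experiment.
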