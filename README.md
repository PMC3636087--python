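# polyspec

Multi-state antibody sequence design and germline-recovery analysis on
pluggable energy tables.

## The problem

Germline-encoded antibodies are polyspecific: one inherited heavy-chain
V-gene sequence must bind many unrelated antigens, and somatic
hypermutation later trades that breadth for affinity to a single target.
`polyspec` studies this trade-off in reverse, by computational design over
an ensemble of antibody/antigen complex structures that share a germline
V-gene. Designing one sequence that minimizes energy across **all**
complexes at once (multi-state design, MSD) should recover
germline-like residues; designing against **each** complex alone
(single-state design, SSD) should recover the mature, somatically
mutated residues. The package is aimed at structural bioinformaticians
who want to run and dissect this style of analysis at desk scale:
energies come from a per-state table contract (exportable from any
scorer) rather than a full-atom force field, and a synthetic-ensemble
generator with planted ground truth makes every stage testable without
external data.

## The statistics at the core

For each designed alignment column, 100 independent design trajectories
yield amino-acid frequencies `p_i`. Recovery of a reference residue with
frequency `p` is scored by its Shannon self-information relative to the
uniform background `p_b = 1/20`:

    I = p · log2(20 p)    [bits],  I = 0 at p = 1/20,  I → log2(20) ≈ 4.32 at p = 1

Summed over designed columns and divided by `log2(20) · n_columns`, this
gives a normalized bit-score in [0, 1] against the germline or a mature
reference, and Δbit = normalized(mature) − normalized(germline) measures
the design's proclivity (positive → mature/monospecific, negative →
germline/polyspecific). Around this sit: a simulated-annealing optimizer
with an exhaustive oracle; Cβ neighbor-count burial with a strict
Δneighbor > 1.0 bound-vs-unbound interface rule; circular phi/psi
standard deviations comparing germline-recovered (bit > 1) versus
non-recovered positions; interface-occurrence binning {0, 1, 2–4, ≥5};
and forced germline-reversion energetics with a 0.7 REU significance
tolerance and a <10% candidate rule. See `docs/methods.md` for the full
model.

## Worked example

`examples/` holds one short script per capability. Generating the default
synthetic ensemble (8 complexes sharing a germline, 4–20 planted somatic
mutations) and designing against it:

```bash
python examples/02_design_and_recovery.py
```

```
multi-state vs germline: normalized bit-score 0.813 (1.0 = every trajectory germline)
mab01: multi-state Δbit = -0.125 (germline preferred), single-state Δbit = +0.063 (mature preferred)
mab02: multi-state Δbit = -0.188 (germline preferred), single-state Δbit = +0.094 (mature preferred)
mab03: multi-state Δbit = -0.219 (germline preferred), single-state Δbit = +0.125 (mature preferred)
```

Multi-state design reverts toward germline (negative Δbit, more strongly
the more mutated the antibody), single-state design matures (positive
Δbit) — the maturation process run forward and backward in silico.
`examples/03_structure_flexibility.py` adds the structural side:

```
germline-recovered columns: 9.4 +/- 1.4 deg (n=24)
non-recovered columns:      4.6 +/- 0.3 deg (n=6)
...
  occurs   0 times: n=24  mean bit 3.24
  occurs >=5 times: n= 3  mean bit 4.32
```

Positions that reverted to germline carry larger backbone phi/psi
spread (they are the flexibility positions), and germline recovery rises
with how often a column sits in the antigen interface.
`examples/04_reversion_energetics.py` closes the loop: among columns
where the design avoided germline, only those with a planted >0.7 REU
penalty are flagged significant; the rest tolerate germline within a
fraction of an REU.

The same workflow is available from the shell via the `polyspec` CLI
(`simulate`, `design`, `recover`, `structstats`, `revert`, `run`) driven
by a YAML config; `polyspec run --config cfg.yaml` writes TSV reports and
a JSON summary whose numbers are recomputable from the stage outputs.

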