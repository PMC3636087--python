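"""Shared constants: the amino-acid alphabet and the fixed analysis thresholds.

Every threshold that the analysis pins (interface Δneighbor, recovery bit
cutoffs, reversion candidacy, reversion significance) lives here as a named
constant so the pipeline surfaces a single overridable value for each.
"""

from __future__ import annotations

import math

#: Canonical one-letter amino-acid alphabet, alphabetical order. Index into
#: energy tables and profiles is the position in this string.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_AA = len(AMINO_ACIDS)

GAP = "-"

#: Background probability of each amino acid for the self-information score.
BACKGROUND_P = 1.0 / N_AA

#: Perfect per-column bit-score, log2(20) = 4.3219...; the normalization
#: denominator uses the exact value, not the rounded 4.32.
LOG2_20 = math.log2(N_AA)

#: Bound-minus-unbound neighbor-count change above which (strictly) a
#: position counts as an interacting/interface residue.
INTERFACE_DELTA_THRESHOLD = 1.0

#: Per-column bit-score above which a position counts as "recovered" to the
#: reference sequence (used for the flexibility group comparison).
RECOVERED_BIT_THRESHOLD = 1.0

#: Per-column bit-score above which a position "contributes" recovery signal.
CONTRIBUTES_BIT_THRESHOLD = 0.0

#: Germline frequency below which (strictly) a designed position becomes a
#: candidate for forced germline reversion.
REVERSION_CANDIDATE_FREQ = 0.10

#: Energy penalty (REU-like units) above which (strictly) a forced germline
#: reversion counts as significantly destabilizing.
REVERSION_SIGNIFICANCE_REU = 0.7

#: Neighbor-count falloff bounds in Angstrom: full weight at or below the
#: inner cutoff, zero at or beyond the outer cutoff, cosine-smooth between.
NEIGHBOR_INNER_A = 3.3
NEIGHBOR_OUTER_A = 11.1

#: Maximum bonded C(i)-N(i+1) distance in Angstrom; beyond this the chain is
#: treated as broken and dihedrals across the break are undefined.
PEPTIDE_BOND_MAX_A = 2.5
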