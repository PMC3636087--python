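"""Sequence-recovery statistics for design ensembles.

The central statistic is the Shannon self-information of the reference amino
acid among the design trajectories: per designed column, with ``p`` the
frequency of the reference residue over the ensemble and a uniform
background of 1/20, ``I = p * log2(20 p)`` in bits. ``I`` is 0 when the
residue appears at background frequency, and approaches log2(20) = 4.3219
bits when every trajectory selects it. A design's total bit-score against a
reference (germline or mature) sums the per-column bits; the normalized
score divides by ``log2(20) * n_columns`` so a perfect recovery is 1.

Negative self-information (reference frequency below 5%) is clamped to 0
for scoring, treating bit-scores as non-negative evidence; the raw value is
kept alongside for transparency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import AA_INDEX, AMINO_ACIDS, LOG2_20, N_AA
from .design import DesignEnsemble


class RecoveryError(ValueError):
    pass


@dataclass(frozen=True)
class PositionProfile:
    column: int
    frequencies: np.ndarray  # length 20, sums to 1
    n: int

    def p(self, aa: str) -> float:
        return float(self.frequencies[AA_INDEX[aa]])


@dataclass(frozen=True)
class RecoveryScore:
    reference: str  # "germline" or "mature:<complex>"
    columns: tuple[int, ...]
    per_column_raw: tuple[float, ...]
    per_column_bit: tuple[float, ...]  # clamped at 0
    skipped_columns: tuple[int, ...]  # reference gaps

    @property
    def total(self) -> float:
        return float(sum(self.per_column_bit))

    @property
    def normalized(self) -> float:
        n = len(self.columns)
        return self.total / (LOG2_20 * n) if n else 0.0

    def bit_at(self, column: int) -> float:
        return self.per_column_bit[self.columns.index(column)]


@dataclass(frozen=True)
class DeltaBitScore:
    complex_id: str
    value: float  # normalized(mature) - normalized(germline)


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    pvalue: float
    n: int
    r2: float | None = None
    degenerate: bool = False


@dataclass(frozen=True)
class OccurrenceBin:
    label: str
    lo: int
    hi: int  # inclusive; use a large sentinel for open-ended
    columns: tuple[int, ...]
    mean: float | None
    sd: float | None


def profile(ensemble: DesignEnsemble) -> list[PositionProfile]:
    """Per-column amino-acid frequencies over the trajectories."""
    if ensemble.n < 1:
        raise RecoveryError("empty ensemble")
    mat = np.array([[AA_INDEX[a] for a in seq] for seq in ensemble.sequences])
    out = []
    for i, col in enumerate(ensemble.columns):
        counts = np.bincount(mat[:, i], minlength=N_AA)
        out.append(
            PositionProfile(column=col, frequencies=counts / ensemble.n, n=ensemble.n)
        )
    return out


def self_information(p: float) -> float:
    """``p * log2(20 p)`` in bits, with the limit convention I(0) = 0.

    Raw (unclamped): values are negative for 0 < p < 0.05.
    """
    if not 0.0 <= p <= 1.0:
        raise RecoveryError(f"probability {p} outside [0, 1]")
    if p == 0.0:
        return 0.0
    return p * math.log2(N_AA * p)


def recovery(
    profiles: Sequence[PositionProfile], reference: str, label: str
) -> RecoveryScore:
    """Bit-score of an ensemble against a reference sequence.

    ``reference`` covers the designed columns in profile order; gap
    characters skip the column and shrink the normalization denominator.
    """
    if len(reference) != len(profiles):
        raise RecoveryError(
            f"reference length {len(reference)} != {len(profiles)} profiles"
        )
    cols, raws, bits, skipped = [], [], [], []
    for prof, aa in zip(profiles, reference):
        if aa == "-":
            skipped.append(prof.column)
            continue
        if aa not in AA_INDEX:
            raise RecoveryError(f"nonstandard reference residue {aa!r}")
        raw = self_information(prof.p(aa))
        cols.append(prof.column)
        raws.append(raw)
        bits.append(max(0.0, raw))
    return RecoveryScore(
        reference=label,
        columns=tuple(cols),
        per_column_raw=tuple(raws),
        per_column_bit=tuple(bits),
        skipped_columns=tuple(skipped),
    )


def delta(mature: RecoveryScore, germline: RecoveryScore, complex_id: str) -> DeltaBitScore:
    """Δbit-score = normalized(mature) − normalized(germline); positive means
    the design leans toward the mature (monospecific) sequence."""
    return DeltaBitScore(complex_id=complex_id, value=mature.normalized - germline.normalized)


def maturation_correlation(
    deltas: Sequence[float], mutation_percentages: Sequence[float]
) -> TestResult:
    """Pearson correlation of Δbit-score against maturation (mutation %)."""
    if len(deltas) != len(mutation_percentages):
        raise RecoveryError("deltas and mutation percentages must be paired")
    if len(deltas) < 3:
        raise RecoveryError("need at least 3 paired observations")
    x = np.asarray(mutation_percentages, float)
    y = np.asarray(deltas, float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise RecoveryError("zero variance; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return TestResult(name="pearson", statistic=float(r), pvalue=float(p),
                      n=len(x), r2=float(r * r))


DEFAULT_BINS = (("0", 0, 0), ("1", 1, 1), ("2-4", 2, 4), (">=5", 5, 10**9))


def bin_by_interface_occurrence(
    per_column_bits: Mapping[int, float],
    interface_columns_by_complex: Mapping[str, set[int]],
    bins: Sequence[tuple[str, int, int]] = DEFAULT_BINS,
) -> list[OccurrenceBin]:
    """Bin designed columns by how often they sit in a complex interface.

    Occurrence of a column = number of complexes classifying it as an
    interacting residue; bins report mean ± SD of the per-column bit-score
    (empty bins stay empty rather than zero).
    """
    occurrence = {
        col: sum(1 for cols in interface_columns_by_complex.values() if col in cols)
        for col in per_column_bits
    }
    out = []
    for label, lo, hi in bins:
        cols = tuple(sorted(c for c, o in occurrence.items() if lo <= o <= hi))
        vals = [per_column_bits[c] for c in cols]
        out.append(
            OccurrenceBin(
                label=label,
                lo=lo,
                hi=hi,
                columns=cols,
                mean=float(np.mean(vals)) if vals else None,
                sd=float(np.std(vals, ddof=1)) if len(vals) > 1 else None,
            )
        )
    return out


@dataclass(frozen=True)
class PairedTests:
    wilcoxon: TestResult
    paired_t: TestResult


def paired_tests(a: Sequence[float], b: Sequence[float]) -> PairedTests:
    """Wilcoxon matched-pairs signed-rank plus paired t on the same pairs.

    The Wilcoxon test is exact for n <= 25 (no ties/zeros), normal
    approximation above; identical samples are flagged degenerate with
    p = 1 rather than erroring.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise RecoveryError("paired samples must have equal length")
    n = len(a)
    diffs = a - b
    if np.all(diffs == 0):
        wil = TestResult("wilcoxon_matched_pairs", 0.0, 1.0, n, degenerate=True)
        t = TestResult("paired_t", 0.0, 1.0, n, degenerate=True)
        return PairedTests(wil, t)
    if n < 5:
        raise RecoveryError("Wilcoxon matched pairs needs n >= 5")
    method = "exact" if (n <= 25 and not np.any(diffs == 0)) else "approx"
    w = stats.wilcoxon(a, b, method=method)
    wil = TestResult("wilcoxon_matched_pairs", float(w.statistic), float(w.pvalue), n)
    tt = stats.ttest_rel(a, b)
    t = TestResult("paired_t", float(tt.statistic), float(tt.pvalue), n)
    return PairedTests(wilcoxon=wil, paired_t=t)


def logo_counts(profiles: Sequence[PositionProfile]) -> pd.DataFrame:
    """Counts matrix (columns x amino acids) usable by standard logo tools."""
    data = {
        aa: [round(p.frequencies[AA_INDEX[aa]] * p.n) for p in profiles]
        for aa in AMINO_ACIDS
    }
    return pd.DataFrame(data, index=[p.column for p in profiles])
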