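"""Per-position backbone variability across the complex ensemble.

Phi/psi angles live on a circle, so position-to-position spread is measured
with the circular (directional) standard deviation sqrt(-2 ln R), where R
is the mean resultant length; an arithmetic SD is available behind a flag
for comparison but mishandles the ±180° wrap. Per column the phi and psi
SDs are averaged into one combined deviation, computed over the structures
in which the column sits in the beta framework (majority rule across
structures when the beta filter is on).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .recovery import TestResult
from .structure import DihedralRecord

log = logging.getLogger(__name__)


class DeviationError(ValueError):
    pass


@dataclass(frozen=True)
class PhiPsiDeviation:
    column: int
    sd_phi: float
    sd_psi: float
    combined: float  # mean of sd_phi and sd_psi
    n_structures: int
    beta_only: bool


@dataclass(frozen=True)
class RecoveryGroupComparison:
    mean_recovered: float
    sem_recovered: float
    n_recovered: int
    mean_other: float
    sem_other: float
    n_other: int
    ttest: TestResult
    reference_mean: float | None
    reference_sem: float | None
    excluded_columns: tuple[int, ...]  # bit exactly at the threshold


def circular_sd(angles_deg: Sequence[float], method: str = "circular") -> float:
    """Standard deviation of angles in degrees.

    ``circular``: sqrt(-2 ln R) on the unit circle, immune to the ±180°
    wrap (e.g. {179°, −179°} → ≈1°, not ≈253°). ``arithmetic``: plain
    sample SD, provided for comparison only.
    """
    if len(angles_deg) < 2:
        raise DeviationError("need at least 2 angles")
    if method == "arithmetic":
        return float(np.std(angles_deg, ddof=1))
    if method != "circular":
        raise DeviationError(f"unknown method {method!r}")
    rad = np.radians(np.asarray(angles_deg, float))
    r = float(abs(np.mean(np.exp(1j * rad))))
    if r <= 0.0:
        return float("inf")
    r = min(r, 1.0)
    return math.degrees(math.sqrt(-2.0 * math.log(r)))


def position_deviation(
    dihedrals_by_complex: Mapping[str, Mapping[int, DihedralRecord]],
    beta_filter: bool = True,
    method: str = "circular",
) -> list[PhiPsiDeviation]:
    """Per-column phi/psi spread across complexes.

    ``dihedrals_by_complex[complex][column]`` holds the column-mapped
    dihedral record of each structure. Columns with both angles defined in
    fewer than two structures are excluded (logged). With the beta filter
    on, only columns labeled beta in a strict majority of their structures
    are kept (ties count as not beta).
    """
    columns = sorted({c for recs in dihedrals_by_complex.values() for c in recs})
    out = []
    for col in columns:
        recs = [
            recs[col]
            for recs in dihedrals_by_complex.values()
            if col in recs and recs[col].phi is not None and recs[col].psi is not None
        ]
        if len(recs) < 2:
            log.info("column %d present in <2 structures; excluded", col)
            continue
        if beta_filter:
            n_beta = sum(1 for r in recs if r.ss_label == "beta")
            if n_beta * 2 <= len(recs):
                continue
        sd_phi = circular_sd([r.phi for r in recs], method=method)
        sd_psi = circular_sd([r.psi for r in recs], method=method)
        out.append(
            PhiPsiDeviation(
                column=col,
                sd_phi=sd_phi,
                sd_psi=sd_psi,
                combined=0.5 * (sd_phi + sd_psi),
                n_structures=len(recs),
                beta_only=beta_filter,
            )
        )
    return out


def compare_recovery_groups(
    deviations: Mapping[int, float],
    per_column_bits: Mapping[int, float],
    reference_deviations: Sequence[float] | None = None,
    bit_threshold: float = 1.0,
) -> RecoveryGroupComparison:
    """Compare backbone spread of germline-recovered vs non-recovered columns.

    Columns split on per-column germline bit-score strictly above/below the
    threshold (exactly at it → excluded, logged); each group reports
    mean ± SEM and a two-sample t-test. ``reference_deviations`` is the
    all-framework baseline computed over every beta-framework column,
    designed or not.
    """
    recovered, other, excluded = [], [], []
    for col, dev in deviations.items():
        bit = per_column_bits.get(col)
        if bit is None:
            continue
        if bit > bit_threshold:
            recovered.append(dev)
        elif bit < bit_threshold:
            other.append(dev)
        else:
            excluded.append(col)
            log.info("column %d bit exactly at threshold; excluded", col)
    if len(recovered) < 2 or len(other) < 2:
        raise DeviationError(
            f"need >=2 columns per group; got {len(recovered)} recovered, "
            f"{len(other)} other"
        )
    if np.ptp(recovered + other) == 0:
        # no spread anywhere: no evidence of a difference
        class _Flat:
            statistic = 0.0
            pvalue = 1.0
        tt = _Flat()
    else:
        tt = stats.ttest_ind(recovered, other)
    ref_mean = ref_sem = None
    if reference_deviations is not None and len(reference_deviations) > 0:
        ref_mean = float(np.mean(reference_deviations))
        ref_sem = float(stats.sem(reference_deviations)) if len(reference_deviations) > 1 else 0.0
    return RecoveryGroupComparison(
        mean_recovered=float(np.mean(recovered)),
        sem_recovered=float(stats.sem(recovered)),
        n_recovered=len(recovered),
        mean_other=float(np.mean(other)),
        sem_other=float(stats.sem(other)),
        n_other=len(other),
        ttest=TestResult(
            name="students_t",
            statistic=float(tt.statistic),
            pvalue=float(tt.pvalue),
            n=len(recovered) + len(other),
        ),
        reference_mean=ref_mean,
        reference_sem=ref_sem,
        excluded_columns=tuple(excluded),
    )
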