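"""Energetics of forcing designed positions back to germline identity.

Where multi-state design avoids the germline amino acid (chosen in fewer
than 10% of trajectories), the germline identity is forced and the
per-state energy cost relative to the design solution is tabulated as a
direct table difference (no repacking exists under the table contract).
A cost strictly above 0.7 REU in at least one state marks the position as
one where the design solution is genuinely preferred; smaller costs mean
the germline residue is tolerated as well, i.e. the design's deviation
reflects near-degenerate alternatives rather than a real penalty.

The 0.7 REU constant can be recomputed from the data as the mean absolute
energy difference between germline and mature residues over the somatically
mutated positions (:func:`significance_tolerance`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .constants import (
    AA_INDEX,
    AMINO_ACIDS,
    REVERSION_CANDIDATE_FREQ,
    REVERSION_SIGNIFICANCE_REU,
)
from .design import DesignEnsemble, DesignTask, StateEnergyTable, seq_to_idx
from .recovery import profile


@dataclass(frozen=True)
class ReversionRecord:
    column: int
    designed_modal_aa: str
    germline_aa: str
    delta_e_by_state: Mapping[str, float]  # mean over trajectories, REU
    significant: bool  # max over states > REVERSION_SIGNIFICANCE_REU

    @property
    def max_delta_e(self) -> float:
        return max(self.delta_e_by_state.values())


def reversion_candidates(
    ensemble: DesignEnsemble,
    germline_designed: str,
    threshold: float = REVERSION_CANDIDATE_FREQ,
) -> list[int]:
    """Columns where the germline residue was chosen in < ``threshold`` of
    trajectories (strictly below; frequency exactly at 10% is excluded)."""
    if len(germline_designed) != len(ensemble.columns):
        raise ValueError("germline sequence must cover the designed columns")
    out = []
    for prof, aa in zip(profile(ensemble), germline_designed):
        if prof.p(aa) < threshold:
            out.append(prof.column)
    return out


def reversion_energies(
    task: DesignTask,
    ensemble: DesignEnsemble,
    candidates: Sequence[int],
    germline_designed: str,
    significance: float = REVERSION_SIGNIFICANCE_REU,
) -> list[ReversionRecord]:
    """ΔE of forcing germline at each candidate column, per state.

    ΔE(state) = mean over trajectories of
    ``E(column, germline aa) − E(column, trajectory aa)``; positive means
    the design solution is preferred over germline in that state.
    """
    bad = set(candidates) - set(ensemble.columns)
    if bad:
        raise ValueError(f"candidates {sorted(bad)} are not designed columns")
    col_pos = {c: i for i, c in enumerate(ensemble.columns)}
    germ_idx = seq_to_idx(germline_designed)
    traj = np.array([seq_to_idx(s) for s in ensemble.sequences])
    profs = {p.column: p for p in profile(ensemble)}
    out = []
    for col in candidates:
        i = col_pos[col]
        modal = AMINO_ACIDS[int(np.argmax(profs[col].frequencies))]
        des = {}
        for state in task.active_states:
            e_col = state.energies[i]
            de = float(np.mean(e_col[germ_idx[i]] - e_col[traj[:, i]]))
            des[state.state_id] = de
        out.append(
            ReversionRecord(
                column=col,
                designed_modal_aa=modal,
                germline_aa=germline_designed[i],
                delta_e_by_state=des,
                significant=max(des.values()) > significance,
            )
        )
    return out


def significance_tolerance(
    states: Sequence[StateEnergyTable],
    germline_designed: str,
    mature_designed: Mapping[str, str],
) -> tuple[float, float, int]:
    """Recompute the reversion-significance tolerance from the data.

    Over every (state, column) where the mature residue differs from
    germline, collect ``|E(germline) − E(mature)|`` and return
    (mean, SD, n). Comparable to the fixed 0.7 REU constant.
    """
    diffs = []
    for state in states:
        mat = mature_designed[state.state_id]
        for i, col in enumerate(state.columns):
            g, m = germline_designed[i], mat[i]
            if g != m:
                diffs.append(abs(state.energies[i, AA_INDEX[g]] - state.energies[i, AA_INDEX[m]]))
    if not diffs:
        return (0.0, 0.0, 0)
    sd = float(np.std(diffs, ddof=1)) if len(diffs) > 1 else 0.0
    return (float(np.mean(diffs)), sd, len(diffs))
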