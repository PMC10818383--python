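"""Personalized therapy-parameter identification from a class grid.

Given the class labels over (electrode position, current, muscle), the
electrode position and sub-motor therapy current are chosen by a nested
search applied per subject/measurement:

1. a position is eligible only if at least two class-1 (reflex) labels
   occur at a single current across the four muscles;
2. eligible positions are ranked by the largest number of class-1 labels at
   any one current;
3. ties broken by the smallest current difference between the onset of any
   leg response and the current carrying that maximum;
4. then by the lowest such current;
5. then by the largest total number of class-1 labels at the position;
   residual ties go to the most caudal position.

The therapy current is 90 % of the lowest current with a class-1 label at
the chosen position (sub-motor threshold); when no position passes rule 1
the current is reported as 0 mA. Agreement between EMG-derived (ground
truth) and ML-derived parameters is quantified as the exact-current,
within-±5 mA and position-match proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TherapyParams:
    """Selected parameters for one subject/measurement.

    ``position`` is None for single-position measurements (patients) or
    when no position qualifies; ``therapy_current`` is 0.0 when no current
    could be found (lack of class-1 events).
    """

    subject_id: str
    position: float | None
    therapy_current: float  # mA; 0 when none found
    first_reflex_current: float | None  # mA


def _valid(grid: pd.DataFrame) -> pd.DataFrame:
    if "valid" in grid.columns:
        return grid[grid["valid"]]
    return grid


def _position_rank_key(sub: pd.DataFrame, position) -> tuple | None:
    """Lexicographic ranking key of one position, None if rule 1 fails."""
    counts = (sub[sub.label == 1].groupby("current_ma").size())
    if counts.empty or counts.max() < 2:
        return None
    n1max = int(counts.max())
    candidate = float(counts[counts == n1max].index.min())
    responding = sub[sub.label > 0]
    onset = float(responding.current_ma.min())
    total_c1 = int((sub.label == 1).sum())
    # smaller is better on every component
    return (-n1max, candidate - onset, candidate, -total_c1, position)


def nested_position_current_search(grid: pd.DataFrame
                                   ) -> tuple[float, float] | None:
    """Apply the five-rule nested search to a labeled class grid.

    ``grid`` needs columns position, current_ma, muscle, label (and
    optionally valid). Returns (position, current carrying the rule-2
    maximum) or None when no position passes rule 1. Deterministic: equal
    grids give equal output.
    """
    if grid.empty:
        raise ValueError("empty class grid")
    g = _valid(grid)
    ranked = []
    for pos, sub in g.groupby("position"):
        key = _position_rank_key(sub, pos)
        if key is not None:
            ranked.append((key, pos))
    if not ranked:
        return None
    key, pos = min(ranked)
    return pos, float(key[2])


def first_reflex_current(grid: pd.DataFrame, position: float) -> float | None:
    """Smallest current with at least one class-1 label at ``position``."""
    g = _valid(grid)
    sub = g[(g.position == position) & (g.label == 1)]
    if sub.empty:
        return None
    return float(sub.current_ma.min())


def therapy_current(first_reflex: float) -> float:
    """Sub-motor therapy current: 90 % of the first-reflex intensity."""
    if first_reflex < 0:
        raise ValueError("current must be >= 0")
    return 0.9 * first_reflex


def extract_therapy_params(grid: pd.DataFrame, subject_id: str,
                           single_position: bool = False) -> TherapyParams:
    """Run the full parameter identification on one measurement's grid.

    For single-position measurements the position is not reported, but the
    rule-1 eligibility gate still applies before a current is returned.
    """
    found = nested_position_current_search(grid)
    if found is None:
        return TherapyParams(subject_id=subject_id, position=None,
                             therapy_current=0.0, first_reflex_current=None)
    pos, _ = found
    frc = first_reflex_current(grid, pos)
    return TherapyParams(
        subject_id=subject_id,
        position=None if single_position else pos,
        therapy_current=therapy_current(frc),
        first_reflex_current=frc,
    )


# ---------------------------------------------------------------------------
# agreement with the EMG ground truth
# ---------------------------------------------------------------------------

def compare_to_ground_truth(gt: TherapyParams, pred: TherapyParams,
                            margin: float = 5.0) -> dict:
    """One agreement row: EMG-derived vs ML-derived parameters.

    ``current_diff`` is ground truth minus prediction, so a negative value
    means the ML path chose a higher current. The margin comparison is
    inclusive (|diff| <= margin).
    """
    if gt.subject_id != pred.subject_id:
        raise ValueError("parameters come from different subjects")
    diff = gt.therapy_current - pred.therapy_current
    exact = bool(np.isclose(diff, 0.0))
    within = exact or bool(abs(diff) <= margin + 1e-12)
    row = {
        "subject_id": gt.subject_id,
        "current_diff_ma": diff,
        "exact_current_match": exact,
        "within_margin": within,
    }
    if gt.position is not None and pred.position is not None:
        row["position_match"] = bool(np.isclose(gt.position, pred.position))
    elif gt.position is not None or pred.position is not None:
        row["position_match"] = False
    else:
        row["position_match"] = None
    return row


def aggregate_agreement(rows: list[dict]) -> dict:
    """Proportions of exact, within-margin, position and combined matches."""
    if not rows:
        return {"n": 0}
    df = pd.DataFrame(rows)
    out = {
        "n": int(len(df)),
        "exact_current": float(df.exact_current_match.mean()),
        "within_margin": float(df.within_margin.mean()),
    }
    pos = df[df.position_match.notna()] if "position_match" in df else df.iloc[0:0]
    if len(pos):
        out["position"] = float(pos.position_match.mean())
        out["position_and_margin"] = float(
            (pos.position_match.astype(bool) & pos.within_margin).mean())
        out["position_and_exact"] = float(
            (pos.position_match.astype(bool) & pos.exact_current_match).mean())
        out["n_with_position"] = int(len(pos))
    return out
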