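"""Differential representation testing for alternative-splicing events.

Each event is tested for unequal representation between two sample groups
with a Pearson chi-square on a 2x2 group x present/absent table (presence
= read count >= presence_min in that sample).  Multiple testing is handled
with Storey-Tibshirani q-values; biomarkers are selected at q < 0.05.

An alternative read-count mode tests the event's group read totals against
the complement (all other events' reads in that group).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import CubicSpline

from .junctions import AnnotatedEvent

__all__ = [
    "GroupDesign",
    "read_design",
    "presence_table",
    "chi_square",
    "storey_qvalues",
    "test_events",
    "select_biomarkers",
]


@dataclass
class GroupDesign:
    """Assignment of samples to exactly two groups.

    Group order is the order of first appearance, so contingency-table
    rows are deterministic.
    """

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        groups = list(dict.fromkeys(self.assignments.values()))
        if len(groups) != 2:
            raise ValueError(f"design must have exactly 2 groups, got {groups}")
        if any(not g for g in groups):
            raise ValueError("group labels must be nonempty")
        for g in groups:
            n = sum(1 for v in self.assignments.values() if v == g)
            if n < 2:
                raise ValueError(f"group {g!r} has fewer than 2 samples")
        self.groups: tuple[str, str] = (groups[0], groups[1])

    @property
    def samples(self) -> list[str]:
        return list(self.assignments)

    def group_samples(self, group: str) -> list[str]:
        return [s for s, g in self.assignments.items() if g == group]

    def group_sizes(self) -> tuple[int, int]:
        return tuple(len(self.group_samples(g)) for g in self.groups)


def read_design(path) -> GroupDesign:
    """Read a two-column sample_id/group TSV (optional header)."""
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("sample_id", "sample"):
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected sample_id<TAB>group")
            assignments[fields[0]] = fields[1]
    return GroupDesign(assignments)


def presence_table(
    event: AnnotatedEvent | dict[str, int],
    design: GroupDesign,
    presence_min: int = 1,
) -> np.ndarray:
    """2x2 table: rows = design groups, columns = (present, absent)."""
    counts = event.counts if isinstance(event, AnnotatedEvent) else event
    missing = [s for s in design.samples if s not in counts]
    if missing:
        raise ValueError(f"samples missing from count matrix: {missing}")
    table = np.zeros((2, 2), dtype=int)
    for gi, group in enumerate(design.groups):
        members = design.group_samples(group)
        present = sum(1 for s in members if counts[s] >= presence_min)
        table[gi, 0] = present
        table[gi, 1] = len(members) - present
    return table


def chi_square(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df = 1.

    No continuity correction by default.  Degenerate tables (any zero
    marginal) return (0, 1) rather than erroring.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("negative cell count")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 0.0, 1.0
    stat, p, _, _ = sps.chi2_contingency(arr, correction=yates)
    return float(stat), float(p)


def storey_qvalues(
    pvals, pi0: float | None = None, min_m_for_pi0: int = 100
) -> np.ndarray:
    """Storey-Tibshirani q-values.

    pi0 is estimated on the lambda grid 0, 0.05, ..., 0.90 via a natural
    cubic spline through pi0(lambda) = #{p > lambda} / (m (1 - lambda)),
    evaluated at the largest lambda and clipped to (0, 1].  For small
    problems (m < ``min_m_for_pi0``) the estimate is unstable and pi0
    falls back to 1, making the procedure exactly Benjamini-Hochberg.

    q_(i) = min_{j >= i} pi0 * m * p_(j) / j, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a nonempty 1-d array")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if m < min_m_for_pi0:
            pi0 = 1.0
        else:
            lambdas = np.arange(0.0, 0.91, 0.05)
            pi0_lam = np.array(
                [(p > lam).mean() / (1.0 - lam) for lam in lambdas]
            )
            spline = CubicSpline(lambdas, pi0_lam, bc_type="natural")
            pi0 = float(spline(lambdas[-1]))
            pi0 = min(max(pi0, 1.0 / m), 1.0)
    if not 0 < pi0 <= 1:
        raise ValueError(f"pi0 must lie in (0, 1], got {pi0}")
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def test_events(
    events: list[AnnotatedEvent],
    design: GroupDesign,
    presence_min: int = 1,
    mode: str = "presence",
    yates: bool = False,
) -> pd.DataFrame:
    """Chi-square + q-value for every event; one row per event.

    mode="presence" (default) tests sample-level presence/absence;
    mode="counts" tests group read totals against the complement of all
    other events' reads.
    """
    if mode not in ("presence", "counts"):
        raise ValueError(f"unknown test mode {mode!r}")
    g1, g2 = design.groups
    rows = []
    if mode == "counts":
        group_totals = {
            g: sum(
                ev.counts.get(s, 0)
                for ev in events for s in design.group_samples(g)
            )
            for g in design.groups
        }
    for ev in events:
        if mode == "presence":
            table = presence_table(ev, design, presence_min)
        else:
            r1 = sum(ev.counts.get(s, 0) for s in design.group_samples(g1))
            r2 = sum(ev.counts.get(s, 0) for s in design.group_samples(g2))
            table = np.array(
                [[r1, group_totals[g1] - r1], [r2, group_totals[g2] - r2]]
            )
        stat, p = chi_square(table, yates=yates)
        rows.append(
            {
                "event_id": ev.event_id,
                "category": ev.category,
                "gene_id": ev.gene_id,
                "transcript_id": ev.transcript_id,
                f"present_{g1}": int(table[0, 0]),
                f"absent_{g1}": int(table[0, 1]),
                f"present_{g2}": int(table[1, 0]),
                f"absent_{g2}": int(table[1, 1]),
                "chi2": stat,
                "p": p,
            }
        )
    result = pd.DataFrame(rows)
    if not result.empty:
        result["q"] = storey_qvalues(result["p"].to_numpy())
    else:
        result["q"] = pd.Series(dtype=float)
    return result


def select_biomarkers(results: pd.DataFrame, q_max: float = 0.05) -> pd.DataFrame:
    """Events with q strictly below ``q_max``, sorted by (q, event_id)."""
    if results.empty:
        return results.copy()
    selected = results[results["q"] < q_max]
    return selected.sort_values(
        ["q", "event_id"], kind="stable"
    ).reset_index(drop=True)
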