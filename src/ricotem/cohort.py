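"""Group summaries, non-parametric comparison and cut-off evaluation.

Scores are summarized as median, quartiles and range; groups are compared
with a two-tailed Mann-Whitney U test (exact distribution for small
tie-free samples, normal approximation with tie correction otherwise); and
the screening performance of a Ricotem+ cut-off is evaluated against the
laboratory phenotype.

A note on vocabulary: among patients *flagged* at a cut-off, the proportion
with laboratory-confirmed VWD is a positive-predictive proportion, even
though screening write-ups sometimes call it "specificity". It is exposed
here as ``flagged_positive_proportion``; the conventional specificity
(non-VWD patients correctly not flagged) is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import InvalidInputError, MissingDataError
from .labs import classify_vwd, has_vwd
from .records import PatientRecord
from .scores import CutoffConfig, classify_responder

__all__ = [
    "GroupSummary",
    "MannWhitneyResult",
    "CutoffEvaluation",
    "summarize_group",
    "mann_whitney_u",
    "evaluate_cutoff",
    "flagged_ids",
    "plot_response",
]


@dataclass(frozen=True)
class GroupSummary:
    """Order statistics of one group's scores."""

    label: str
    n: int
    median: float
    q25: float
    q75: float
    min: float
    max: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def summarize_group(scores: Sequence[float], label: str = "") -> GroupSummary:
    """Median, 25th/75th percentile (linear interpolation) and range."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise InvalidInputError("cannot summarize an empty group")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("scores must be finite")
    q25, med, q75 = np.percentile(arr, [25, 50, 75])
    return GroupSummary(
        label=label,
        n=int(arr.size),
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        min=float(arr.min()),
        max=float(arr.max()),
    )


@dataclass(frozen=True)
class MannWhitneyResult:
    """U statistic of the first group, two-sided p and the path taken."""

    u: float
    p: float
    method: str  # "exact" or "asymptotic"


#: Largest combined sample size for which the exact U distribution is used.
EXACT_MAX_COMBINED_N = 20


def mann_whitney_u(
    group_a: Sequence[float], group_b: Sequence[float]
) -> MannWhitneyResult:
    """Two-tailed Mann-Whitney U test.

    Exact-distribution p when the combined sample size is at most
    ``EXACT_MAX_COMBINED_N`` and there are no ties; otherwise the normal
    approximation with tie and continuity correction. The result records
    which path was taken.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    if a.size + b.size <= EXACT_MAX_COMBINED_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return MannWhitneyResult(u=float(res.statistic), p=float(min(res.pvalue, 1.0)), method=method)


@dataclass(frozen=True)
class CutoffEvaluation:
    """Screening performance of one Ricotem+ cut-off.

    ``flagged_positive_proportion`` is the share of flagged patients with
    confirmed VWD (``None`` when nobody is flagged); ``sensitivity`` the
    share of VWD patients flagged (``None`` when the cohort has no VWD);
    ``specificity`` the share of non-VWD patients not flagged.
    """

    cutoff_pct: float
    n_flagged: int
    n_flagged_with_vwd: int
    flagged_positive_proportion: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _flags_and_truth(
    records: Iterable[PatientRecord],
    cutoff_pct: float,
    include_possible: bool,
    minus_cutoff_pct: float,
) -> Tuple[List[str], List[bool], List[bool]]:
    cfg = CutoffConfig(
        ricotem_minus_cutoff_pct=minus_cutoff_pct,
        ricotem_plus_cutoff_pct=cutoff_pct,
    )
    ids, flags, truths = [], [], []
    missing = []
    for rec in records:
        if rec.panel is None:
            missing.append(rec.patient_id)
            continue
        phenotype = rec.phenotype or classify_vwd(rec.lab)
        ids.append(rec.patient_id)
        flags.append(classify_responder(rec.panel, cfg) == "high")
        truths.append(has_vwd(phenotype, include_possible))
    if missing:
        raise MissingDataError(
            f"records missing Ricotem scores: {', '.join(missing)}"
        )
    return ids, flags, truths


def flagged_ids(
    records: Iterable[PatientRecord],
    cutoff_pct: float,
    minus_cutoff_pct: float = 25.0,
) -> List[str]:
    """Patient ids flagged (high responders) at a Ricotem+ cut-off."""
    ids, flags, _ = _flags_and_truth(records, cutoff_pct, False, minus_cutoff_pct)
    return [i for i, f in zip(ids, flags) if f]


def evaluate_cutoff(
    records: Iterable[PatientRecord],
    cutoff_pct: float,
    include_possible: bool = False,
    minus_cutoff_pct: float = 25.0,
) -> CutoffEvaluation:
    """Evaluate one Ricotem+ cut-off against the laboratory phenotype.

    A patient is flagged when the stepwise responder classification assigns
    ``high`` at the given cut-off. Lowering the cut-off can only grow the
    flagged set (monotone screening).
    """
    _, flags, truths = _flags_and_truth(
        records, cutoff_pct, include_possible, minus_cutoff_pct
    )
    flags_arr = np.asarray(flags, dtype=bool)
    truth_arr = np.asarray(truths, dtype=bool)
    n_flagged = int(flags_arr.sum())
    n_flagged_vwd = int((flags_arr & truth_arr).sum())
    n_vwd = int(truth_arr.sum())
    n_non_vwd = int((~truth_arr).sum())
    return CutoffEvaluation(
        cutoff_pct=cutoff_pct,
        n_flagged=n_flagged,
        n_flagged_with_vwd=n_flagged_vwd,
        flagged_positive_proportion=(n_flagged_vwd / n_flagged) if n_flagged else None,
        sensitivity=(n_flagged_vwd / n_vwd) if n_vwd else None,
        specificity=(int((~flags_arr & ~truth_arr).sum()) / n_non_vwd)
        if n_non_vwd
        else None,
    )


def plot_response(
    records: Sequence[PatientRecord],
    cutoffs_pct: Sequence[float] = (50.0, 35.0),
    path: Optional[str] = None,
):
    """Per-patient Ricotem+ values with horizontal cut-off lines.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ids, values = [], []
    for rec in records:
        if rec.panel is not None and rec.panel.ricotem_plus is not None:
            ids.append(rec.patient_id)
            values.append(rec.panel.ricotem_plus)
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(ids)), 4))
    ax.scatter(range(len(ids)), values, c="tab:gray", zorder=3)
    for c, color in zip(cutoffs_pct, ("black", "tab:orange", "tab:blue")):
        ax.axhline(c, color=color, lw=1.2, label=f"cut-off {c:g}%")
    ax.set_xticks(range(len(ids)))
    ax.set_xticklabels(ids, rotation=90, fontsize=7)
    ax.set_ylabel("Ricotem+ (%)")
    ax.set_xlabel("patient")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
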