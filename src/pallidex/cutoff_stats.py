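"""ROC curves, Youden cutoffs, the statistic-by-mode cutoff grid, screening.

A positive call is a score strictly above the cutoff.  Candidate cutoffs
are midpoints between adjacent distinct pooled scores plus -inf/+inf
sentinels; AUC uses the pair-counting (Mann–Whitney) formula with ties
credited 0.5; the Youden-optimal cutoff maximizes J = sensitivity +
specificity - 1, reporting the smallest optimal cutoff on ties (which
maximizes sensitivity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ContractError
from .gp_index import IndexSummary, summary_statistics

STATISTICS = ("median", "p60", "p70", "p80", "hodges_lehmann")
MODES = ("G", "L")


@dataclass
class ROCCurve:
    """ROC over candidate cutoffs, with AUC and the Youden-optimal point."""

    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_cutoff: float
    youden_j: float
    sensitivity_at_youden: float
    specificity_at_youden: float


def _as_scores(x) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64).ravel()
    if arr.size < 1:
        raise ContractError("each group needs at least one score")
    if not np.all(np.isfinite(arr)):
        raise ContractError("scores must be finite")
    return arr


def mann_whitney_auc(case_scores, control_scores) -> float:
    """AUC by rank-sum pair counting; tied pairs credited 0.5."""
    cases = _as_scores(case_scores)
    controls = _as_scores(control_scores)
    pooled = np.concatenate([cases, controls])
    ranks = rankdata(pooled)            # average ranks handle ties as 0.5
    r1 = ranks[: cases.size].sum()
    n1, n0 = cases.size, controls.size
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_curve(case_scores, control_scores) -> ROCCurve:
    """ROC with midpoint candidate cutoffs; positive = score > cutoff."""
    cases = _as_scores(case_scores)
    controls = _as_scores(control_scores)
    pooled = np.unique(np.concatenate([cases, controls]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0 if pooled.size > 1 else np.array([])
    cutoffs = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = np.array([(cases > c).mean() for c in cutoffs])
    spec = np.array([(controls <= c).mean() for c in cutoffs])
    auc = mann_whitney_auc(cases, controls)
    j = sens + spec - 1.0
    best = int(np.argmax(j))            # argmax returns the first (smallest cutoff)
    return ROCCurve(
        cutoffs=cutoffs, sensitivity=sens, specificity=spec, auc=auc,
        youden_cutoff=float(cutoffs[best]), youden_j=float(j[best]),
        sensitivity_at_youden=float(sens[best]),
        specificity_at_youden=float(spec[best]),
    )


@dataclass
class CutoffTable:
    """Five statistics x two normalization modes, one ROC row each."""

    table: pd.DataFrame
    best_statistic: str
    best_mode: str

    @property
    def best_row(self) -> pd.Series:
        m = (self.table["statistic"] == self.best_statistic) \
            & (self.table["mode"] == self.best_mode)
        return self.table[m].iloc[0]


def cutoff_table(case_summaries: dict[str, list[IndexSummary]],
                 control_summaries: dict[str, list[IndexSummary]]
                 ) -> CutoffTable:
    """Build the 10-row AUC/cutoff grid from per-subject summaries.

    ``case_summaries`` / ``control_summaries`` map mode ("G"/"L") to one
    :class:`IndexSummary` per subject.  The best row is the one with the
    highest AUC; exact AUC ties go to the row with the better achievable
    operating point (higher Youden J), then to the earlier row in canonical
    order (statistics within mode G first).
    """
    for mode in MODES:
        if mode not in case_summaries or mode not in control_summaries:
            raise ContractError(f"summaries for mode {mode!r} are required")
        if not case_summaries[mode] or not control_summaries[mode]:
            raise ContractError(f"empty group for mode {mode!r}")
    rows = []
    for mode in MODES:
        cases = [summary_statistics(s) for s in case_summaries[mode]]
        controls = [summary_statistics(s) for s in control_summaries[mode]]
        for stat in STATISTICS:
            roc = roc_curve([c[stat] for c in cases], [c[stat] for c in controls])
            rows.append({
                "statistic": stat, "mode": mode, "auc": roc.auc,
                "cutoff": roc.youden_cutoff,
                "specificity": roc.specificity_at_youden,
                "sensitivity": roc.sensitivity_at_youden,
                "youden_j": roc.youden_j,
            })
    table = pd.DataFrame(rows)
    order = sorted(table.index,
                   key=lambda i: (-table.loc[i, "auc"],
                                  -table.loc[i, "youden_j"], i))
    best = order[0]
    return CutoffTable(table, str(table.loc[best, "statistic"]),
                       str(table.loc[best, "mode"]))


@dataclass
class ScreeningSummary:
    n_flagged: int
    n_total: int
    percent_flagged: float
    flags: np.ndarray


def screen_cohort(indices, cutoff: float) -> ScreeningSummary:
    """Strict-exceedance screening; percent reported to one decimal."""
    idx = _as_scores(indices)
    flags = idx > cutoff
    n_flagged = int(flags.sum())
    percent = round(100.0 * n_flagged / idx.size, 1)
    return ScreeningSummary(n_flagged, int(idx.size), percent, flags)


def group_distributions(indices_by_group: dict[str, list[float] | np.ndarray]
                        ) -> pd.DataFrame:
    """Descriptive per-group summaries (n, mean, sd, quartiles)."""
    if not indices_by_group:
        raise ContractError("at least one group is required")
    rows = []
    for group, vals in indices_by_group.items():
        v = _as_scores(vals)
        rows.append({
            "group": group, "n": int(v.size), "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "q25": float(np.percentile(v, 25)),
            "median": float(np.percentile(v, 50)),
            "q75": float(np.percentile(v, 75)),
        })
    return pd.DataFrame(rows).set_index("group")


def ordering_check(indices_by_group: dict[str, list[float] | np.ndarray],
                   order: tuple[str, ...] = ("LC_HE", "LC_noHE", "HC", "dementia")
                   ) -> bool:
    """True when group means are strictly decreasing along ``order``."""
    means = [float(np.mean(np.asarray(indices_by_group[g], dtype=np.float64)))
             for g in order]
    return bool(all(a > b for a, b in zip(means, means[1:])))


def plot_roc(roc: ROCCurve, ax=None, label: str | None = None):
    """Simple ROC plot (1 - specificity vs sensitivity)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot((1 - roc.specificity)[::-1], roc.sensitivity[::-1],
            drawstyle="steps-post", label=label)
    ax.plot([0, 1], [0, 1], ls=":", c="gray")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    if label:
        ax.legend()
    return ax
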