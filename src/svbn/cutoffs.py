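"""ROC-AUC-driven selection of outcome dichotomization cutoffs.

For each candidate cutoff the target is dichotomized, the network structure
and parameters are relearned on the resulting discrete cohort, every subject
is scored with the exact conditional probability of the flagged state given
their other observed variables, and the ROC AUC of those scores against the
induced labels is computed.  The cutoff with the highest AUC wins; ties go
to the more balanced class split, then to the smaller cutoff.  Scoring uses
the same data the network was fit on (no held-out set), so the AUCs are
optimistic as estimates of out-of-sample discrimination — the procedure
selects a cutoff, it does not validate a classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import CohortTable, DiscreteCohort, ThresholdRule, apply_thresholds
from .inference import Evidence, query
from .model import BayesianNetwork, LearnerConfig, learn_network

__all__ = ["CutoffSearchResult", "CutoffError", "roc_auc", "score_subjects", "optimize_cutoff"]


class CutoffError(Exception):
    """Invalid cutoff-search input or a degenerate search outcome."""


@dataclass(frozen=True)
class CutoffSearchResult:
    """Grid of candidate cutoffs with per-cutoff AUC and the optimum."""

    target: str
    grid: tuple[float, ...]
    auc_by_cutoff: dict[float, float]
    optimal_cutoff: float
    optimal_auc: float
    skipped: tuple[tuple[float, str], ...] = field(default_factory=tuple)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability a random positive outscores a random negative, ties 1/2.

    Computed through the rank-sum (Mann-Whitney) identity, so it is exact,
    invariant under strictly increasing score transforms, and matches the
    normalized U statistic to machine precision.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise CutoffError("scores and labels must have equal length")
    pos = y.astype(bool)
    n1 = int(pos.sum())
    n0 = int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise CutoffError("labels must contain both classes; AUC undefined")
    from scipy.stats import rankdata

    ranks = rankdata(s)  # midranks handle ties
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def score_subjects(
    net: BayesianNetwork, cohort: DiscreteCohort, target: str
) -> np.ndarray:
    """Per-subject P(target = flagged | all other observed variables).

    The flagged state is the first state of the target's state set.  Exact
    inference; identical covariate rows receive identical scores (memoized).
    """
    if target not in net.structure.state_sets:
        raise CutoffError(f"target {target!r} is not a node of the network")
    others = [v for v in cohort.variables if v != target]
    for v in others:
        if v not in net.structure.state_sets:
            raise CutoffError(f"cohort column {v!r} is not a node of the network")
    for v in others:
        bad = set(cohort.data[v].unique()) - set(net.states(v))
        if bad:
            i = int(cohort.data[v].isin(bad).idxmax())
            raise CutoffError(
                f"subject {cohort.subject_ids[i]!r}: state "
                f"{cohort.data[v].iloc[i]!r} not in state set of {v!r}"
            )
    flagged = net.states(target)[0]

    if set(others) | {target} == set(net.nodes):
        # evidence covers every non-target node, so the posterior is a ratio
        # of full joints: P(t | rest) = joint(t, rest) / sum_t' joint(t', rest)
        # — exact, and vectorizable over all subjects at once
        codes = {
            v: cohort.data[v].map(
                {s: i for i, s in enumerate(net.states(v))}
            ).to_numpy()
            for v in others
        }
        n = cohort.n_subjects
        n_t = len(net.states(target))
        logj = np.zeros((n_t, n))
        for t_idx in range(n_t):
            codes_full = dict(codes)
            codes_full[target] = np.full(n, t_idx)
            for v in net.nodes:
                pars = net.structure.parent_tuple(v)
                row = np.zeros(n, dtype=np.int64)
                for p in pars:
                    row = row * len(net.states(p)) + codes_full[p]
                with np.errstate(divide="ignore"):
                    logj[t_idx] += np.log(net.cpts[v][row, codes_full[v]])
        m = logj.max(axis=0)
        w = np.exp(logj - m)
        return w[net.states(target).index(flagged)] / w.sum(axis=0)

    # net has nodes absent from the cohort: marginalize them by exact
    # variable elimination, memoizing identical covariate rows
    cache: dict[tuple[str, ...], float] = {}
    out = np.empty(cohort.n_subjects)
    rows = list(zip(*(cohort.data[v] for v in others))) if others else [()] * cohort.n_subjects
    for i, key in enumerate(rows):
        if key not in cache:
            ev = Evidence(dict(zip(others, key)))
            cache[key] = query(net, target, ev).distribution[flagged]
        out[i] = cache[key]
    return out


def optimize_cutoff(
    table: CohortTable,
    target: str,
    grid: Sequence[float],
    direction: str = "le",
    learner: LearnerConfig | None = None,
    *,
    min_class_size: int = 5,
    min_class_share: float = 0.05,
    flag_label: str = "true",
    complement_label: str = "false",
) -> CutoffSearchResult:
    """Grid search for the cutoff maximizing network-score ROC AUC.

    Every other analysis variable must already be binary.  For each viable
    candidate the structure AND parameters are relearned on the induced
    discrete cohort.  Candidates inducing a class smaller than
    ``max(min_class_size, ceil(min_class_share * n))`` are recorded in
    ``skipped``: AUC values computed against severely imbalanced label sets
    are not comparable across candidates (a handful of extreme-tail subjects
    forms an artificially pure positive class with near-perfect AUC), so
    extreme cutoffs must be excluded for the argmax to be meaningful.  Ties
    in the argmax are broken toward the more balanced split, then the
    smaller cutoff.
    """
    learner = learner or LearnerConfig()
    grid = [float(c) for c in grid]
    if not grid:
        raise CutoffError("candidate grid is empty")
    if not all(np.isfinite(grid)):
        raise CutoffError("grid contains non-finite values")
    if target not in table.kinds or table.kinds[target] != "continuous":
        raise CutoffError(f"target {target!r} must be a continuous column")
    values = table.data[target].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise CutoffError("target contains missing values; filter complete cases first")

    n = len(values)
    min_class = max(min_class_size, int(np.ceil(min_class_share * n)))
    aucs: dict[float, float] = {}
    skipped: list[tuple[float, str]] = []
    records: list[tuple[float, float, int]] = []  # (auc, balance, idx in grid)
    for idx, c in enumerate(grid):
        rule = ThresholdRule(target, c, direction, flag_label, complement_label)
        flags = rule.applies(values)
        n_flag = int(flags.sum())
        if min(n_flag, n - n_flag) < min_class:
            skipped.append((c, "degenerate class"))
            continue
        disc = apply_thresholds(table, [rule])
        net = learn_network(disc, learner)
        scores = score_subjects(net, disc, target)
        auc = roc_auc(scores, flags.astype(int))
        aucs[c] = auc
        balance = min(n_flag, n - n_flag) / n
        records.append((auc, balance, idx))
    if not records:
        raise CutoffError("every candidate cutoff was skipped")

    # argmax with deterministic tie-break: higher AUC, then more balanced
    # split, then smaller cutoff
    best = max(records, key=lambda r: (r[0], r[1], -grid[r[2]]))
    return CutoffSearchResult(
        target=target,
        grid=tuple(grid),
        auc_by_cutoff=aucs,
        optimal_cutoff=grid[best[2]],
        optimal_auc=best[0],
        skipped=tuple(skipped),
    )
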