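"""Relative-risk queries on fitted networks with bootstrap confidence intervals.

The relative risk of outcome A given risk variables B, C, ... is the
conditional-probability ratio

    RR = P(A = flagged | B = flagged, C = flagged, ...)
       / P(A = flagged | B = complement, C = complement, ...),

with every unlisted variable marginalized, never conditioned.  It is a
ratio of network queries, not a causal effect.  Uncertainty comes from the
percentile bootstrap: rows are resampled with replacement to the original
size, the network structure AND parameters are relearned on each replicate,
the RR is recomputed, and the 5th/95th percentiles of the surviving
replicate RRs form the interval (a 90% percentile interval; the default is
1000 replicates).  Replicates where an arm has probability zero are
discarded and counted rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import DiscreteCohort
from .inference import Evidence, InconsistentEvidenceError, query
from .model import BayesianNetwork, LearnerConfig, learn_network

__all__ = [
    "RiskScenario",
    "RiskEstimate",
    "RiskError",
    "relative_risk",
    "bootstrap_ci",
    "scenario_battery",
]


class RiskError(Exception):
    """Undefined relative risk or invalid scenario."""


@dataclass(frozen=True)
class RiskScenario:
    """Outcome (A, flagged state) against risk variables [(B, flagged), ...].

    The complement of each risk variable's flagged state is used for the
    denominator arm; each risk variable must therefore be binary.
    """

    outcome: str
    outcome_state: str
    risk_variables: tuple[tuple[str, str], ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.risk_variables:
            raise RiskError("at least one risk variable is required")
        names = [v for v, _ in self.risk_variables]
        if self.outcome in names:
            raise RiskError(f"outcome {self.outcome!r} is also a risk variable")
        if len(set(names)) != len(names):
            raise RiskError("duplicate risk variable")

    def describe(self) -> str:
        if self.label:
            return self.label
        rv = "+".join(f"{v}={s}" for v, s in self.risk_variables)
        return f"{self.outcome}={self.outcome_state} | {rv}"


@dataclass(frozen=True)
class RiskEstimate:
    """Point RR with percentile-bootstrap interval and bookkeeping."""

    scenario: RiskScenario
    rr: float
    ci_lo: float
    ci_hi: float
    n_boot: int
    n_failed: int
    seed: int


def _complement_state(net: BayesianNetwork, var: str, flagged: str) -> str:
    states = net.states(var)
    if flagged not in states:
        raise RiskError(f"state {flagged!r} not in state set of {var!r}")
    if len(states) != 2:
        raise RiskError(f"risk variable {var!r} is not binary")
    return states[0] if states[1] == flagged else states[1]


def relative_risk(net: BayesianNetwork, scenario: RiskScenario) -> float:
    """P(A flagged | all risk vars flagged) / P(A flagged | all complement)."""
    for name in (scenario.outcome, *(v for v, _ in scenario.risk_variables)):
        if name not in net.structure.state_sets:
            raise RiskError(f"variable {name!r} is not a node of the network")
    if scenario.outcome_state not in net.states(scenario.outcome):
        raise RiskError(
            f"state {scenario.outcome_state!r} not in state set of "
            f"{scenario.outcome!r}"
        )
    flagged_ev = Evidence({v: s for v, s in scenario.risk_variables})
    complement_ev = Evidence(
        {v: _complement_state(net, v, s) for v, s in scenario.risk_variables}
    )
    try:
        num = query(net, scenario.outcome, flagged_ev).distribution[
            scenario.outcome_state
        ]
    except InconsistentEvidenceError as e:
        raise RiskError(f"numerator arm inconsistent: {e}") from e
    try:
        den = query(net, scenario.outcome, complement_ev).distribution[
            scenario.outcome_state
        ]
    except InconsistentEvidenceError as e:
        raise RiskError(f"denominator arm inconsistent: {e}") from e
    if den == 0.0:
        raise RiskError("denominator arm has probability 0; RR undefined")
    return num / den


def _replicate_indices(seed: int, n_rows: int, n_boot: int) -> list[np.ndarray]:
    """Stream-stable resample indices: replicate r depends only on (seed, r),
    so extending n_boot never changes earlier replicates, and batteries can
    share one replicate stream across scenarios."""
    out = []
    for r in range(n_boot):
        rng = np.random.Generator(
            np.random.Philox(np.random.SeedSequence(seed, spawn_key=(r,)))
        )
        out.append(rng.integers(0, n_rows, size=n_rows))
    return out


def _resample(cohort: DiscreteCohort, idx: np.ndarray) -> DiscreteCohort:
    return DiscreteCohort(
        data=cohort.data.iloc[idx].reset_index(drop=True),
        state_sets=dict(cohort.state_sets),
        subject_ids=[f"R{i:06d}" for i in range(len(idx))],
    )


def bootstrap_ci(
    cohort: DiscreteCohort,
    scenario: RiskScenario,
    n_boot: int = 1000,
    seed: int = 0,
    learner: LearnerConfig | None = None,
    *,
    _full_net: BayesianNetwork | None = None,
    _indices: Sequence[np.ndarray] | None = None,
) -> RiskEstimate:
    """Point RR from the full-cohort network; CI from relearned replicates.

    Each replicate resamples rows with replacement to the original N and
    relearns structure and parameters before recomputing the RR.  ``ci_lo``
    and ``ci_hi`` are the 5th and 95th percentiles of the surviving
    replicate RRs.  Fully reproducible from ``seed``.
    """
    if n_boot < 1:
        raise RiskError("n_boot must be at least 1")
    learner = learner or LearnerConfig()
    net = _full_net if _full_net is not None else learn_network(cohort, learner)
    rr = relative_risk(net, scenario)
    indices = (
        list(_indices)
        if _indices is not None
        else _replicate_indices(seed, cohort.n_subjects, n_boot)
    )
    reps: list[float] = []
    n_failed = 0
    for idx in indices:
        try:
            boot = _resample(cohort, idx)
            boot_net = learn_network(boot, learner)
            reps.append(relative_risk(boot_net, scenario))
        except RiskError:
            n_failed += 1
    if not reps:
        raise RiskError("all bootstrap replicates failed")
    lo, hi = np.percentile(reps, [5.0, 95.0])
    return RiskEstimate(
        scenario=scenario,
        rr=float(rr),
        ci_lo=float(lo),
        ci_hi=float(hi),
        n_boot=n_boot,
        n_failed=n_failed,
        seed=seed,
    )


def scenario_battery(
    cohort: DiscreteCohort,
    scenarios: Sequence[RiskScenario],
    n_boot: int = 1000,
    seed: int = 0,
    learner: LearnerConfig | None = None,
) -> list[RiskEstimate | RiskError]:
    """One RiskEstimate per scenario against the same full-data network and a
    shared bootstrap replicate stream (identical resampled row indices for
    every scenario, so estimates are comparable).  A failing scenario yields
    a RiskError in its slot; the battery continues.
    """
    if not scenarios:
        raise RiskError("scenario list is empty")
    learner = learner or LearnerConfig()
    net = learn_network(cohort, learner)
    indices = _replicate_indices(seed, cohort.n_subjects, n_boot)
    # relearn each replicate net once and reuse it across scenarios
    boot_nets: list[BayesianNetwork] = [
        learn_network(_resample(cohort, idx), learner) for idx in indices
    ]
    out: list[RiskEstimate | RiskError] = []
    for k, scenario in enumerate(scenarios):
        try:
            rr = relative_risk(net, scenario)
            reps: list[float] = []
            n_failed = 0
            for bn in boot_nets:
                try:
                    reps.append(relative_risk(bn, scenario))
                except RiskError:
                    n_failed += 1
            if not reps:
                raise RiskError("all bootstrap replicates failed")
            lo, hi = np.percentile(reps, [5.0, 95.0])
            out.append(
                RiskEstimate(
                    scenario=scenario,
                    rr=float(rr),
                    ci_lo=float(lo),
                    ci_hi=float(hi),
                    n_boot=n_boot,
                    n_failed=n_failed,
                    seed=seed,
                )
            )
        except RiskError as e:
            out.append(RiskError(f"scenario {k}: {e}"))
    return out
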