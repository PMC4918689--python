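"""Group comparison and state-sequence analytics.

Two layers sit on top of the fitted per-subject models:

* the group-comparison protocol -- symmetrized model distances for every
  control-control and control-patient pair, compared per reference network
  with a two-sample t-test (a significant test flags a dynamic functional
  connectivity change in that network's interactions);
* descriptive analytics of transition matrices (loopback and reach
  probabilities) and decoded state sequences (state changes, distinct
  states, dwell durations, pattern occupancy, and a Kruskal-Wallis
  comparison of occupancy rates between groups).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .distance import derive_seed, directed_distance
from .phmm import ProductHMMModel, StateSequence, state_label

__all__ = [
    "DistanceSets",
    "GroupComparison",
    "StatePattern",
    "SequenceStats",
    "TransitionSummary",
    "pairwise_distance_sets",
    "compare_groups",
    "transition_summaries",
    "sequence_stats",
    "pattern_occupancy",
    "compare_occupancy",
]


@dataclass
class DistanceSets:
    """Pairwise symmetrized distances split by group composition.

    ``control_control`` and ``control_patient`` enter the t-test;
    ``patient_patient`` is computed for inspection only and excluded from
    the test.
    """

    rsn_label: str
    t_gen: int
    control_control: list[tuple[str, float]] = field(default_factory=list)
    control_patient: list[tuple[str, float]] = field(default_factory=list)
    patient_patient: list[tuple[str, float]] = field(default_factory=list)

    def values(self, which: str) -> np.ndarray:
        return np.array([d for _, d in getattr(self, which)], dtype=float)


@dataclass(frozen=True)
class GroupComparison:
    """t-test outcome for one reference network and one T_gen setting."""

    rsn_label: str
    t_gen: int
    t_stat: float
    p_value: float
    h: int
    alpha: float


@dataclass
class StatePattern:
    """A partial constraint on joint states: per channel +1, -1 or wildcard (0).

    Matches any joint state whose sub-states satisfy every non-wildcard
    constraint -- e.g. "correlated LFPN and anti-correlated RFPN, whatever
    the other networks".
    """

    constraints: np.ndarray

    def __post_init__(self) -> None:
        self.constraints = np.asarray(self.constraints, dtype=int)
        if not np.isin(self.constraints, (-1, 0, 1)).all():
            raise ValueError("constraints must be -1, 0 (wildcard) or +1")
        if not np.any(self.constraints != 0):
            raise ValueError("pattern needs at least one non-wildcard constraint")

    @classmethod
    def from_names(cls, channel_names: list[str],
                   **constraints: int) -> "StatePattern":
        """Build a pattern from channel names, e.g. ``from_names(names, LFPN=+1, RFPN=-1)``."""
        vec = np.zeros(len(channel_names), dtype=int)
        for name, value in constraints.items():
            try:
                vec[channel_names.index(name)] = value
            except ValueError:
                raise ValueError(f"unknown channel {name!r}") from None
        return cls(vec)


@dataclass
class SequenceStats:
    """Run-length summary of a decoded joint-state path."""

    n_state_changes: int
    n_distinct_states: int
    dwell_durations: list[tuple[int, int]]
    mean_dwell_seconds: float
    mean_dwell_windows: float


@dataclass
class TransitionSummary:
    """Loopback (diagonal) and reach (column-mean) probabilities, sorted descending."""

    loopback: list[tuple[int, str, float]]
    reach: list[tuple[int, str, float]]


# ---------------------------------------------------------------------------


def pairwise_distance_sets(models: dict[str, ProductHMMModel],
                           groups: dict[str, str],
                           t_gen: int, master_seed: int,
                           rsn_label: str = "") -> DistanceSets:
    """All pairwise symmetrized distances, split into c-c, c-p and p-p sets.

    Every subject in ``groups`` must have a fitted model for this reference
    network.  Per-pair generation seeds are derived from
    (master_seed, rsn_label, unordered pair ids, generating subject id), so
    the result is independent of subject enumeration order and exactly
    symmetric in each pair.
    """
    missing = sorted(set(groups) - set(models))
    if missing:
        raise KeyError(f"no fitted model for subject(s): {', '.join(missing)}")
    bad = {s: g for s, g in groups.items() if g not in ("control", "patient")}
    if bad:
        raise ValueError(f"group labels must be control/patient: {bad}")
    sets = DistanceSets(rsn_label=rsn_label, t_gen=t_gen)
    for s1, s2 in combinations(sorted(groups), 2):
        lo, hi = sorted((s1, s2))
        ds = []
        for gen_subject, other in ((s2, s1), (s1, s2)):
            seed = derive_seed(master_seed, rsn_label, lo, hi, gen_subject)
            ds.append(directed_distance(models[other], models[gen_subject],
                                        t_gen, seed))
        sym = (ds[0] + ds[1]) / 2.0
        pair_label = f"{s1}|{s2}"
        kinds = {groups[s1], groups[s2]}
        if kinds == {"control"}:
            sets.control_control.append((pair_label, sym))
        elif kinds == {"patient"}:
            sets.patient_patient.append((pair_label, sym))
        else:
            sets.control_patient.append((pair_label, sym))
    return sets


def compare_groups(sets: DistanceSets, alpha: float = 0.01,
                   welch: bool = False) -> GroupComparison:
    """Two-sided two-sample t-test between the c-c and c-p distance sets.

    Student's pooled-variance test by default (``welch=True`` switches to
    the unequal-variance form).  ``h = 1`` iff ``p < alpha``.
    """
    cc = sets.values("control_control")
    cp = sets.values("control_patient")
    if len(cc) < 2 or len(cp) < 2:
        raise ValueError("each distance set needs at least 2 values")
    t_stat, p = stats.ttest_ind(cc, cp, equal_var=not welch)
    return GroupComparison(rsn_label=sets.rsn_label, t_gen=sets.t_gen,
                           t_stat=float(t_stat), p_value=float(p),
                           h=int(p < alpha), alpha=alpha)


def transition_summaries(transmat: np.ndarray,
                         channel_names: list[str] | None = None
                         ) -> TransitionSummary:
    """Loopback (a_ii) and reach (mean over i of a_ij) probabilities.

    Loopback measures the temporal stability of each joint state; reach the
    mean one-step probability of entering it.  Both lists are sorted
    descending, ties broken by state index.
    """
    a = np.asarray(transmat, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(a < 0) or np.max(np.abs(a.sum(axis=1) - 1.0)) > 1e-8:
        raise ValueError("transition matrix must be row-stochastic")
    m = a.shape[0]
    k = int(np.log2(m))
    if 2 ** k != m:
        raise ValueError("transition matrix size must be a power of two")
    loop = np.diag(a)
    reach = a.mean(axis=0)

    def ranked(v: np.ndarray) -> list[tuple[int, str, float]]:
        order = np.lexsort((np.arange(m), -v))
        return [(int(i), state_label(int(i), channel_names, k=k), float(v[i]))
                for i in order]

    return TransitionSummary(loopback=ranked(loop), reach=ranked(reach))


def _joint_path(seq) -> np.ndarray:
    if isinstance(seq, StateSequence):
        return seq.joint
    return np.asarray(seq, dtype=int)


def sequence_stats(seq, tr_seconds: float) -> SequenceStats:
    """State changes, distinct states and dwell (run) durations of a path.

    Dwell durations are the run-length encoding of the joint path; the mean
    dwell is reported both in windows and in seconds (windows * TR).
    """
    path = _joint_path(seq)
    if path.ndim != 1 or len(path) < 1:
        raise ValueError("need a nonempty 1-D state path")
    change_points = np.flatnonzero(np.diff(path) != 0)
    starts = np.concatenate(([0], change_points + 1))
    ends = np.concatenate((change_points + 1, [len(path)]))
    dwell = [(int(path[s]), int(e - s)) for s, e in zip(starts, ends)]
    runs = np.array([r for _, r in dwell], dtype=float)
    return SequenceStats(
        n_state_changes=int(len(change_points)),
        n_distinct_states=int(len(np.unique(path))),
        dwell_durations=dwell,
        mean_dwell_windows=float(runs.mean()),
        mean_dwell_seconds=float(runs.mean() * tr_seconds),
    )


def pattern_occupancy(seq, pattern: StatePattern) -> float:
    """Fraction of windows whose sub-states satisfy every pattern constraint."""
    if isinstance(seq, StateSequence):
        per_channel = seq.per_channel
    else:
        per_channel = np.asarray(seq, dtype=int)
    if per_channel.ndim != 2:
        raise ValueError("need a (K, T) per-channel sub-state matrix")
    k = per_channel.shape[0]
    if len(pattern.constraints) != k:
        raise ValueError(
            f"pattern has {len(pattern.constraints)} channels, sequence has {k}")
    active = pattern.constraints != 0
    match = (per_channel[active] == pattern.constraints[active, None]).all(axis=0)
    return float(match.mean())


def compare_occupancy(rates_a, rates_b) -> tuple[float, float]:
    """Kruskal-Wallis rank test on per-subject occupancy rates of two groups.

    Returns (H statistic, p-value).  If every rate in both groups is the
    same constant the test is degenerate; (0.0, 1.0) is returned.
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(a, b)
    return float(h), float(p)
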