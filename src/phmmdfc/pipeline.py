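"""End-to-end protocol: correlate -> fit -> decode -> distances -> t-tests.

For every reference network n (the "one RSN vs. the others" strategy) and
every subject, the pipeline builds the correlation plot CC_n, initializes
and trains a product HMM on it (emissions fixed), decodes the state path,
computes all pairwise symmetrized model distances at each T_gen setting,
and t-tests the control-control against the control-patient distance set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .group import (DistanceSets, GroupComparison, compare_groups,
                    pairwise_distance_sets)
from .io import RunConfig
from .phmm import (FitResult, StateSequence, baum_welch_fit, init_parameters,
                   viterbi_decode)
from .windows import TimecourseSet, build_correlation_plot, build_taper

__all__ = ["SubjectModels", "RunResult", "fit_subject", "run_protocol"]

logger = logging.getLogger(__name__)


@dataclass
class SubjectModels:
    """Per-subject artifacts for one reference network."""

    subject_id: str
    group: str
    reference_label: str
    correlation_plot: object
    fit: FitResult
    decoded: StateSequence


@dataclass
class RunResult:
    """Everything the run-all protocol produces, keyed by reference network."""

    config: RunConfig
    subjects: dict[str, list[SubjectModels]] = field(default_factory=dict)
    distance_sets: list[DistanceSets] = field(default_factory=list)
    comparisons: list[GroupComparison] = field(default_factory=list)


def fit_subject(tc: TimecourseSet, reference_index: int,
                config: RunConfig) -> SubjectModels:
    """Correlation plot, initialized + EM-trained model, decoded path."""
    window = build_taper(config.rect_len, config.gauss_len, config.gauss_sigma)
    cp = build_correlation_plot(tc, reference_index, window, config.step)
    model0 = init_parameters(cp.values, channel_names=cp.channel_labels)
    fit = baum_welch_fit(model0, cp.values, max_iter=config.em_max_iter,
                         tol=config.em_tol)
    seq = viterbi_decode(fit.model, cp.values)
    return SubjectModels(subject_id=tc.subject_id, group=tc.group,
                         reference_label=cp.reference_label,
                         correlation_plot=cp, fit=fit, decoded=seq)


def run_protocol(cohort: list[TimecourseSet], config: RunConfig) -> RunResult:
    """Full group protocol over every reference network in the cohort.

    Results are independent of subject order: per-pair generation seeds
    derive from subject identities and the master seed only.
    """
    if not cohort:
        raise ValueError("empty cohort")
    labels = cohort[0].labels
    if any(tc.labels != labels for tc in cohort):
        raise ValueError("all subjects must share the same network labels")
    ids = [tc.subject_id for tc in cohort]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids in cohort")
    result = RunResult(config=config)
    groups = {tc.subject_id: tc.group for tc in cohort}
    for n, rsn in enumerate(labels):
        logger.info("reference network %s (%d/%d)", rsn, n + 1, len(labels))
        fitted = [fit_subject(tc, n, config) for tc in cohort]
        result.subjects[rsn] = fitted
        models = {sm.subject_id: sm.fit.model for sm in fitted}
        for t_gen in config.t_gen:
            sets = pairwise_distance_sets(models, groups, t_gen,
                                          config.master_seed, rsn_label=rsn)
            result.distance_sets.append(sets)
            result.comparisons.append(compare_groups(sets, alpha=config.alpha))
    return result
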