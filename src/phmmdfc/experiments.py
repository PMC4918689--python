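"""Reusable simulation experiments exercising the full protocol.

These functions define the package's standard synthetic studies -- each is
deterministic given a master seed and returns plain results, so the same
code backs the test suite, the examples and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distance import derive_seed
from .group import GroupComparison, compare_groups, pairwise_distance_sets
from .phmm import (ProductHMMModel, baum_welch_fit, generate_observations,
                   init_parameters, viterbi_decode)
from .synthetic import make_phmm, two_group_generator_models

__all__ = ["PowerReplicate", "power_replicate", "power_study",
           "transition_recovery", "decoding_accuracy"]


@dataclass(frozen=True)
class PowerReplicate:
    """Outcome of one end-to-end two-group comparison at one master seed."""

    comparison: GroupComparison
    n_control_pairs: int
    n_cross_pairs: int


def power_replicate(master_seed: int, k: int = 6, t: int = 103,
                    n_controls: int = 20, n_patients: int = 16,
                    t_gen: int = 150, alpha: float = 0.01,
                    em_max_iter: int = 50) -> PowerReplicate:
    """One full protocol run on a synthetic two-group cohort.

    Controls and patients are drawn from the built-in well-separated
    generator pair; each subject's product HMM is initialized from its own
    observations and EM-trained, then all pairwise symmetrized distances
    feed the two-sample t-test.
    """
    control_m, patient_m = two_group_generator_models(k)
    models: dict[str, ProductHMMModel] = {}
    groups: dict[str, str] = {}
    for i in range(n_controls + n_patients):
        group = "control" if i < n_controls else "patient"
        gen = control_m if group == "control" else patient_m
        sid = f"sub{i:03d}"
        obs, _ = generate_observations(gen, t, derive_seed(master_seed, "power", sid))
        fit = baum_welch_fit(init_parameters(obs), obs, max_iter=em_max_iter)
        models[sid] = fit.model
        groups[sid] = group
    sets = pairwise_distance_sets(models, groups, t_gen, master_seed,
                                  rsn_label="synthetic")
    comparison = compare_groups(sets, alpha=alpha)
    return PowerReplicate(comparison=comparison,
                          n_control_pairs=len(sets.control_control),
                          n_cross_pairs=len(sets.control_patient))


def power_study(master_seed: int, n_replicates: int = 20,
                **kwargs) -> list[PowerReplicate]:
    """Repeat :func:`power_replicate` over derived per-replicate seeds."""
    seeds = [int(s) for s in
             derive_seed(master_seed, "power-study").generate_state(n_replicates) >> 1]
    return [power_replicate(s, **kwargs) for s in seeds]


def transition_recovery(master_seed: int, k: int = 2, t: int = 2000,
                        stay: float = 0.9, mu: float = 0.5,
                        sigma: float = 0.1) -> float:
    """Max elementwise |A_hat - A| after EM on one generated sequence.

    A diagonal-dominant K-channel model with well-separated emissions is
    sampled for ``t`` steps; the model is re-fit from a data-driven
    initialization and the recovered transition matrix compared to truth.
    """
    truth = make_phmm(k, mu, -mu, sigma, stay)
    obs, _ = generate_observations(truth, t, derive_seed(master_seed, "recovery"))
    fit = baum_welch_fit(init_parameters(obs), obs)
    return float(np.max(np.abs(fit.model.transmat - truth.transmat)))


def decoding_accuracy(master_seed: int, k: int = 4, t: int = 500,
                      stay: float = 0.85, mu: float = 0.45,
                      sigma: float = 0.15) -> float:
    """Per-channel Viterbi accuracy on data generated from a known model.

    Emission separation here is |mu_{+1} - mu_{-1}| = 6 sigma with loopback
    ``stay``, the regime where decoding should be near-perfect.
    """
    truth = make_phmm(k, mu, -mu, sigma, stay)
    obs, hidden = generate_observations(truth, t,
                                        derive_seed(master_seed, "decoding"))
    decoded = viterbi_decode(truth, obs)
    return float((decoded.per_channel == hidden.per_channel).mean())
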