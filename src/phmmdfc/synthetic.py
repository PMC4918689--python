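"""Synthetic cohorts for the two entry points of the pipeline.

Real resting-state cohorts for this protocol are clinical and not
redistributable, so the package ships a generator that emulates their
structure at both stages:

* :func:`generate_timecourses` -- raw network time-courses with
  piecewise-stationary between-network correlation.  The timeline is cut
  into regimes of geometric duration (memoryless, matching the Markov
  assumption the product HMM will fit); within a regime the pairwise
  correlations are +/-rho according to a random sign pattern, with the
  sign probability of one designated pair differing between the control
  and patient groups (the built-in group effect).  Arbitrary sign patterns
  need not form a valid correlation matrix, so each target is repaired to
  the nearest positive-definite correlation matrix by eigenvalue clipping;
  the repair delta and post-repair targets are recorded in the truth
  sidecar.

* :func:`sample_correlation_plots` -- correlation-plot observations drawn
  directly from a known product HMM, with the hidden paths retained, for
  recovery and end-to-end power studies.

Defaults emulate the study conditions: N = 7 networks, 120 usable volumes
at TR = 3 s, 20 controls and 16 patients.  No hemodynamic-response or
scanner-noise realism is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .phmm import (EmissionParams, ProductHMMModel, StateSequence,
                   generate_observations)
from .windows import TimecourseSet

__all__ = [
    "GroupEffect",
    "SyntheticSpec",
    "DEFAULT_NETWORKS",
    "generate_timecourses",
    "generate_cohort",
    "sample_correlation_plots",
    "uniform_diag_transmat",
    "make_phmm",
    "two_group_generator_models",
]

DEFAULT_NETWORKS = ["DMN", "LFPN", "RFPN", "OPFN", "OPN", "MON", "BG"]


@dataclass(frozen=True)
class GroupEffect:
    """Which network pair's correlation-sign probability differs by group."""

    pair: tuple[int, int] = (1, 2)
    p_positive_control: float = 0.85
    p_positive_patient: float = 0.15


@dataclass
class SyntheticSpec:
    """Study-shaped generator settings.

    ``regime_mean_duration`` is the mean regime length in volumes (TR
    units); ``correlation_magnitude`` is the within-regime |correlation|
    target for constrained pairs; ``observation_noise_sd`` adds white
    measurement noise on top of the unit-variance network signals.
    """

    n_networks: int = 7
    n_volumes: int = 120
    tr_seconds: float = 3.0
    regime_mean_duration: float = 15.0
    correlation_magnitude: float = 0.6
    observation_noise_sd: float = 0.2
    n_controls: int = 20
    n_patients: int = 16
    baseline_p_positive: float = 0.5
    group_effect: GroupEffect | None = field(default_factory=GroupEffect)
    network_labels: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_networks < 2 or self.n_volumes < 2:
            raise ValueError("need at least 2 networks and 2 volumes")
        if not 0 < self.correlation_magnitude < 1:
            raise ValueError("correlation_magnitude must lie in (0, 1)")
        if min(self.tr_seconds, self.regime_mean_duration) <= 0 \
                or self.observation_noise_sd < 0:
            raise ValueError("durations must be positive, noise nonnegative")
        if self.network_labels is None:
            if self.n_networks == len(DEFAULT_NETWORKS):
                self.network_labels = list(DEFAULT_NETWORKS)
            else:
                self.network_labels = [f"RSN{i + 1}" for i in range(self.n_networks)]
        elif len(self.network_labels) != self.n_networks:
            raise ValueError("network_labels length must equal n_networks")

    @property
    def n_subjects(self) -> int:
        return self.n_controls + self.n_patients

    def group_of(self, subject_index: int) -> str:
        if not 0 <= subject_index < self.n_subjects:
            raise ValueError(f"subject_index {subject_index} out of range")
        return "control" if subject_index < self.n_controls else "patient"


def _nearest_pd_correlation(target: np.ndarray, eps: float = 1e-4) -> tuple[np.ndarray, float]:
    """Clip eigenvalues at ``eps`` and rescale to unit diagonal.

    Returns the repaired correlation matrix and the max absolute entrywise
    repair delta.
    """
    vals, vecs = np.linalg.eigh(target)
    repaired = (vecs * np.maximum(vals, eps)) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired, float(np.max(np.abs(repaired - target)))


def _sample_regime(rng: np.random.Generator, spec: SyntheticSpec, group: str,
                   max_retries: int = 20) -> tuple[np.ndarray, np.ndarray, float]:
    """Draw a sign pattern, repair it, and reject sign-flipping repairs."""
    n = spec.n_networks
    rho = spec.correlation_magnitude
    pairs = list(combinations(range(n), 2))
    for _ in range(max_retries):
        signs = np.eye(n)
        for (i, j) in pairs:
            p = spec.baseline_p_positive
            if spec.group_effect is not None \
                    and tuple(sorted((i, j))) == tuple(sorted(spec.group_effect.pair)):
                p = (spec.group_effect.p_positive_control if group == "control"
                     else spec.group_effect.p_positive_patient)
            s = 1.0 if rng.random() < p else -1.0
            signs[i, j] = signs[j, i] = s
        target = signs * rho
        np.fill_diagonal(target, 1.0)
        repaired, delta = _nearest_pd_correlation(target)
        off = ~np.eye(n, dtype=bool)
        # reject repairs that flip a requested sign or crush it below 10% of rho
        if np.all(np.sign(repaired[off]) == np.sign(target[off])) \
                and np.all(np.abs(repaired[off]) >= 0.1 * rho):
            return repaired, signs, delta
    raise RuntimeError(
        f"could not repair a feasible sign pattern in {max_retries} tries")


def generate_timecourses(spec: SyntheticSpec, subject_index: int) -> TimecourseSet:
    """One subject's (N, n_volumes) time-courses with regime structure.

    Deterministic given ``(spec.seed, subject_index)``.  The returned
    set's ``truth`` sidecar records, per regime, the start volume, length,
    requested sign pattern, repaired correlation matrix and repair delta.
    """
    group = spec.group_of(subject_index)
    rng = np.random.default_rng(
        np.random.SeedSequence((int(spec.seed), int(subject_index))))
    n, t_full = spec.n_networks, spec.n_volumes
    data = np.empty((n, t_full))
    regimes = []
    t = 0
    while t < t_full:
        length = min(int(rng.geometric(1.0 / spec.regime_mean_duration)), t_full - t)
        corr, signs, delta = _sample_regime(rng, spec, group)
        chol = np.linalg.cholesky(corr)
        z = rng.standard_normal((length, n)) @ chol.T
        data[:, t:t + length] = z.T
        regimes.append({"start": t, "length": length,
                        "requested_signs": signs.copy(),
                        "correlation": corr, "repair_delta": delta})
        t += length
    if spec.observation_noise_sd > 0:
        data += spec.observation_noise_sd * rng.standard_normal(data.shape)
    return TimecourseSet(
        subject_id=f"sub{subject_index:03d}",
        group=group,
        labels=list(spec.network_labels),
        data=data,
        tr_seconds=spec.tr_seconds,
        truth={"regimes": regimes, "seed": spec.seed,
               "subject_index": subject_index},
    )


def generate_cohort(spec: SyntheticSpec) -> list[TimecourseSet]:
    """All controls followed by all patients, each deterministic per subject."""
    return [generate_timecourses(spec, i) for i in range(spec.n_subjects)]


def sample_correlation_plots(model: ProductHMMModel, n_subjects: int, t: int,
                             seed: int) -> list[tuple[np.ndarray, StateSequence]]:
    """Draw ``n_subjects`` (K, t) observation matrices from a known model.

    Per-subject streams are spawned from ``seed``; the true hidden paths
    are returned alongside for recovery tests.
    """
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    return [generate_observations(model, t, child) for child in children]


# ---------------------------------------------------------------------------
# Convenience model builders for simulation studies


def uniform_diag_transmat(n_states: int, stay: float) -> np.ndarray:
    """Row-stochastic matrix with ``stay`` on the diagonal, rest uniform."""
    if not 0 < stay < 1:
        raise ValueError("stay probability must lie in (0, 1)")
    a = np.full((n_states, n_states), (1.0 - stay) / (n_states - 1))
    np.fill_diagonal(a, stay)
    return a


def make_phmm(k: int, mu_pos: float, mu_neg: float, sigma: float,
              stay: float, channel_names: list[str] | None = None
              ) -> ProductHMMModel:
    """Homogeneous product HMM: same emissions on every channel, uniform-
    off-diagonal transitions with a common loopback probability."""
    m = 2 ** k
    means = np.tile([mu_neg, mu_pos], (k, 1)).astype(float)
    stds = np.full((k, 2), float(sigma))
    return ProductHMMModel(k=k, startprob=np.full(m, 1.0 / m),
                           transmat=uniform_diag_transmat(m, stay),
                           emissions=EmissionParams(means, stds),
                           channel_names=channel_names or [])


def two_group_generator_models(k: int = 6) -> tuple[ProductHMMModel, ProductHMMModel]:
    """The built-in well-separated two-group scenario for power studies.

    Controls: sharp, stable correlation states (mu = +/-0.45, sigma = 0.15,
    loopback 0.85).  Patients: weaker, noisier, less stable states
    (mu = +/-0.20, sigma = 0.30, loopback 0.60).  The gap is large enough
    that fitted subject models separate cleanly in the distance metric.
    """
    names = DEFAULT_NETWORKS[:k] if k <= len(DEFAULT_NETWORKS) else None
    control = make_phmm(k, 0.45, -0.45, 0.15, 0.85, names)
    patient = make_phmm(k, 0.20, -0.20, 0.30, 0.60, names)
    return control, patient
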