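"""Plain-text readers and writers for every pipeline artifact.

All artifacts are delimited or structured text so runs are diffable:
time-courses as CSV with a YAML metadata sidecar, correlation plots and
decoded sequences as TSV, models as JSON (floats round-trip exactly via
Python's shortest-repr serialization), distance sets and group reports as
CSV/TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .phmm import ProductHMMModel, StateSequence
from .windows import CorrelationPlot, TimecourseSet
from .group import DistanceSets, GroupComparison

__all__ = [
    "RunConfig",
    "write_timecourses", "read_timecourses",
    "write_correlation_plot", "read_correlation_plot",
    "save_model", "load_model",
    "write_state_sequence", "read_state_sequence",
    "write_distance_sets", "read_distance_sets",
    "write_group_report",
]


# ---------------------------------------------------------------------------
# Time-courses: CSV (first column = network label) + YAML sidecar


def write_timecourses(tc: TimecourseSet, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(tc.data, index=pd.Index(tc.labels, name="network"))
    df.columns = [f"v{c:04d}" for c in range(tc.data.shape[1])]
    df.to_csv(path, float_format="%.17g")
    sidecar = {"subject_id": tc.subject_id, "group": tc.group,
               "tr_seconds": float(tc.tr_seconds)}
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))


def read_timecourses(path: str | Path) -> TimecourseSet:
    path = Path(path)
    df = pd.read_csv(path, index_col="network", float_precision="round_trip")
    meta_path = path.with_suffix(".yaml")
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {meta_path}")
    meta = yaml.safe_load(meta_path.read_text())
    return TimecourseSet(subject_id=str(meta["subject_id"]),
                         group=str(meta["group"]),
                         labels=[str(x) for x in df.index],
                         data=df.to_numpy(dtype=float),
                         tr_seconds=float(meta["tr_seconds"]))


# ---------------------------------------------------------------------------
# Correlation plots: TSV with a window-index column


def write_correlation_plot(cp: CorrelationPlot, path: str | Path) -> None:
    df = pd.DataFrame(cp.values.T, columns=cp.channel_labels)
    df.insert(0, "window", np.arange(cp.n_windows))
    header = (f"# reference={cp.reference_label} reference_index={cp.reference_index} "
              f"rect_len={cp.window.rect_len} gauss_len={cp.window.gauss_len} "
              f"gauss_sigma={cp.window.gauss_sigma:.17g} step={cp.step}\n")
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_correlation_plot(path: str | Path) -> CorrelationPlot:
    from .windows import build_taper

    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# reference="):
            raise ValueError(f"{path}: missing correlation-plot header line")
        meta = dict(item.split("=", 1) for item in header[2:].split())
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    window = build_taper(int(meta["rect_len"]), int(meta["gauss_len"]),
                         float(meta["gauss_sigma"]))
    channels = [c for c in df.columns if c != "window"]
    return CorrelationPlot(reference_index=int(meta["reference_index"]),
                           reference_label=meta["reference"],
                           channel_labels=channels,
                           values=df[channels].to_numpy(dtype=float).T,
                           window=window, step=int(meta["step"]))


# ---------------------------------------------------------------------------
# Models: JSON with declared bit order; exact float round-trip


def save_model(model: ProductHMMModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def load_model(path: str | Path) -> ProductHMMModel:
    return ProductHMMModel.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Decoded sequences: TSV (window, joint index, case-convention label, K sub-states)


def write_state_sequence(seq: StateSequence, path: str | Path) -> None:
    df = pd.DataFrame({"window": np.arange(len(seq)),
                       "state_index": seq.joint,
                       "label": seq.labels()})
    for k, name in enumerate(seq.channel_names):
        df[name] = seq.per_channel[k]
    with open(path, "w") as fh:
        fh.write(f"# log_prob={seq.log_prob:.17g}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_state_sequence(path: str | Path) -> StateSequence:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# log_prob="):
            raise ValueError(f"{path}: missing state-sequence header line")
        log_prob = float(header.split("=", 1)[1])
        df = pd.read_csv(fh, sep="\t")
    channel_names = [c for c in df.columns
                     if c not in ("window", "state_index", "label")]
    return StateSequence(joint=df["state_index"].to_numpy(dtype=int),
                         per_channel=df[channel_names].to_numpy(dtype=int).T,
                         log_prob=log_prob, channel_names=channel_names)


# ---------------------------------------------------------------------------
# Distance sets and group reports


def write_distance_sets(sets: DistanceSets, path: str | Path) -> None:
    rows = []
    for kind in ("control_control", "control_patient", "patient_patient"):
        for pair, d in getattr(sets, kind):
            rows.append({"rsn": sets.rsn_label, "t_gen": sets.t_gen,
                         "kind": kind, "pair": pair, "distance": d})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_distance_sets(path: str | Path) -> DistanceSets:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: empty distance table")
    sets = DistanceSets(rsn_label=str(df["rsn"].iloc[0]),
                        t_gen=int(df["t_gen"].iloc[0]))
    for _, row in df.iterrows():
        getattr(sets, row["kind"]).append((row["pair"], float(row["distance"])))
    return sets


def write_group_report(comparisons: list[GroupComparison], path: str | Path) -> None:
    """Report table: one row per T_gen of p-values across reference networks,
    plus the h decision row (1 iff p < alpha for every tested T_gen)."""
    rsns = list(dict.fromkeys(c.rsn_label for c in comparisons))
    t_gens = sorted({c.t_gen for c in comparisons})
    by_key = {(c.rsn_label, c.t_gen): c for c in comparisons}
    rows = []
    for tg in t_gens:
        rows.append({"row": str(tg),
                     **{r: f"{by_key[(r, tg)].p_value:.3g}" for r in rsns}})
    rows.append({"row": "h",
                 **{r: str(int(all(by_key[(r, tg)].h for tg in t_gens)))
                    for r in rsns}})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Validated settings for a full pipeline run (the run-all protocol)."""

    input_dir: str = ""
    output_dir: str = "phmm_out"
    rect_len: int = 15
    gauss_len: int = 4
    gauss_sigma: float = 1.0
    step: int = 1
    em_tol: float = 1e-4
    em_max_iter: int = 100
    t_gen: list[int] = field(default_factory=lambda: [150, 300])
    alpha: float = 0.01
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.rect_len < 1 or self.gauss_len < 1 or self.gauss_sigma <= 0 \
                or self.step < 1:
            raise ValueError("invalid window parameters")
        if self.em_tol <= 0 or self.em_max_iter < 1:
            raise ValueError("invalid EM settings")
        if not self.t_gen or any(t < 1 for t in self.t_gen):
            raise ValueError("t_gen entries must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        Path(path).write_text(yaml.safe_dump(d))
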