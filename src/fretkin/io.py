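"""Plain-text readers/writers for traces, idealized paths, models, configs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .hmm import HmmModel, IdealizedTrace
from .kinetics import SequenceCondition
from .simulate import StatePath, TimeTrace

__all__ = [
    "write_traces_csv",
    "read_traces_csv",
    "write_state_paths_csv",
    "write_idealized_csv",
    "read_idealized_csv",
    "write_model_json",
    "read_model_json",
    "read_condition_table",
    "load_config",
]

TRACE_COLUMNS = ["trace_id", "time_s", "donor", "acceptor"]


def write_traces_csv(traces: Sequence[TimeTrace], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "trace_id": tr.trace_id,
                "time_s": tr.times,
                "donor": tr.donor,
                "acceptor": tr.acceptor,
            }
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path) -> list[TimeTrace]:
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    traces = []
    for trace_id, g in df.groupby("trace_id", sort=True):
        g = g.sort_values("time_s")
        times = g["time_s"].to_numpy(float)
        frame_time = float(np.median(np.diff(times))) if len(times) > 1 else 0.1
        traces.append(
            TimeTrace(
                trace_id=str(trace_id),
                times=times,
                donor=g["donor"].to_numpy(float),
                acceptor=g["acceptor"].to_numpy(float),
                frame_time=frame_time,
            )
        )
    return traces


def write_state_paths_csv(traces: Sequence[TimeTrace], path) -> None:
    """Companion ground-truth table for simulated traces that carry one."""
    rows = []
    for tr in traces:
        if tr.ground_truth is None:
            continue
        for state, start, duration in tr.ground_truth.segments:
            rows.append(
                {
                    "trace_id": tr.trace_id,
                    "state": state,
                    "start_s": start,
                    "duration_s": duration,
                }
            )
    pd.DataFrame(rows, columns=["trace_id", "state", "start_s", "duration_s"]).to_csv(
        path, index=False
    )


def write_idealized_csv(ideals: Sequence[IdealizedTrace], path) -> None:
    rows = []
    for ideal in ideals:
        for state, start, duration, mean_e in ideal.segments:
            rows.append(
                {
                    "trace_id": ideal.trace_id,
                    "state": state,
                    "start_s": start,
                    "duration_s": duration,
                    "mean_e": mean_e,
                }
            )
    pd.DataFrame(
        rows, columns=["trace_id", "state", "start_s", "duration_s", "mean_e"]
    ).to_csv(path, index=False)


def read_idealized_csv(path, frame_time: float = float("nan")) -> list[IdealizedTrace]:
    df = pd.read_csv(path)
    ideals = []
    for trace_id, g in df.groupby("trace_id", sort=True):
        g = g.sort_values("start_s")
        segments = [
            (int(r.state), float(r.start_s), float(r.duration_s), float(r.mean_e))
            for r in g.itertuples()
        ]
        ideals.append(
            IdealizedTrace(
                trace_id=str(trace_id),
                segments=segments,
                log_prob=float("nan"),
                frame_time=frame_time,
            )
        )
    return ideals


def write_model_json(model: HmmModel, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2, sort_keys=True) + "\n")


def read_model_json(path) -> HmmModel:
    return HmmModel.from_dict(json.loads(Path(path).read_text()))


def read_condition_table(path) -> list[SequenceCondition]:
    """Condition CSV: columns label, reca_uM, atpase_rate."""
    df = pd.read_csv(path)
    return [
        SequenceCondition(
            label=str(r.label),
            atpase_rate=float(r.atpase_rate),
            reca_concentration=float(r.reca_uM),
        )
        for r in df.itertuples()
    ]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg
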