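"""Plain-text interchange for parameter sets, spike trains and traces."""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .patterns import SpikePattern, VoltageTrace
from .plasticity import PlasticityRuleParams

PathLike = Union[str, Path]


def rules_to_frame(rule_sets: Sequence[PlasticityRuleParams],
                   sse: Optional[np.ndarray] = None) -> pd.DataFrame:
    df = pd.DataFrame([p.as_dict() for p in rule_sets])
    if sse is not None:
        df.insert(0, "sse", np.asarray(sse))
    return df


def save_rules_csv(rule_sets: Sequence[PlasticityRuleParams], path: PathLike,
                   sse: Optional[np.ndarray] = None) -> None:
    rules_to_frame(rule_sets, sse).to_csv(path, index=False)


def load_rules_csv(path: PathLike) -> List[PlasticityRuleParams]:
    df = pd.read_csv(path)
    fields = [f for f in PlasticityRuleParams.__dataclass_fields__]
    out = []
    for _, row in df.iterrows():
        kwargs = {k: row[k] for k in fields if k in df.columns}
        out.append(PlasticityRuleParams(**kwargs))
    return out


def save_rules_json(rule_sets: Sequence[PlasticityRuleParams],
                    path: PathLike) -> None:
    Path(path).write_text(json.dumps([p.as_dict() for p in rule_sets],
                                     indent=1))


def load_rules_json(path: PathLike) -> List[PlasticityRuleParams]:
    return [PlasticityRuleParams(**d)
            for d in json.loads(Path(path).read_text())]


def save_spikes(pattern: SpikePattern, path: PathLike) -> None:
    """Two-column text (neuron_id, time_ms) plus an Up-interval sidecar."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# duration_ms {pattern.duration_ms} state {pattern.state}\n")
        for i, times in enumerate(pattern.spikes):
            for t in times:
                fh.write(f"{i}\t{t:.6f}\n")
    if len(pattern.up_intervals):
        side = path.with_suffix(path.suffix + ".up")
        np.savetxt(side, pattern.up_intervals, fmt="%.6f",
                   header="up_start_ms up_end_ms")


def load_spikes(path: PathLike) -> SpikePattern:
    path = Path(path)
    header = path.open().readline().split()
    duration_ms = float(header[2])
    state = header[4]
    data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        spikes = [np.empty(0)]
    else:
        n = int(data[:, 0].max()) + 1
        spikes = [np.sort(data[data[:, 0] == i, 1]) for i in range(n)]
    side = path.with_suffix(path.suffix + ".up")
    ups = np.loadtxt(side, ndmin=2) if side.exists() else np.empty((0, 2))
    return SpikePattern(spikes=spikes, duration_ms=duration_ms,
                        up_intervals=ups.reshape(-1, 2), state=state)


def save_trace(trace: VoltageTrace, path: PathLike) -> None:
    """Array container (.npz) with the step size recorded alongside."""
    np.savez_compressed(path, v=trace.v, dt=np.array([trace.dt]))


def load_trace(path: PathLike) -> VoltageTrace:
    with np.load(path) as data:
        return VoltageTrace(v=data["v"], dt=float(data["dt"][0]))


def curves_to_frame(curves, sse: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Heatmap-ready long-format table of change-versus-lag curves."""
    rows = []
    for i, curve in enumerate(curves):
        for lag, change in zip(curve.lags, curve.change):
            rows.append({"set_index": i, "lag_ms": lag, "change": change,
                         "sse": None if sse is None else float(sse[i])})
    return pd.DataFrame(rows)
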