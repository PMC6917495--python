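"""Plain-text I/O for trial sets and fit results.

Trial CSV dialect: one file per stimulus named after its label, header
``t_ms,rep1,rep2,...``, one row per time sample, with a JSON sidecar
(``<label>.json``) carrying dt, stimulus onset, group id and protocol
metadata. The round trip is lossless to well below 1e-9 mV.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import FitResult
from .metrics import StimulusTrials, TrialSet

__all__ = ["write_trials", "read_trials", "write_fit_results"]


def write_trials(ts: TrialSet, directory: str | Path) -> None:
    """Write every stimulus block of a TrialSet as CSV + JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for st in ts:
        n = st.traces.shape[1]
        t_ms = np.arange(n) * st.dt_ms
        cols = {"t_ms": t_ms}
        for i, row in enumerate(st.traces, start=1):
            cols[f"rep{i}"] = row
        pd.DataFrame(cols).to_csv(directory / f"{st.label}.csv",
                                  index=False, float_format="%.10g")
        sidecar = {
            "label": st.label,
            "dt_ms": st.dt_ms,
            "onset_ms": st.onset_ms,
            "group": st.group,
            "n_trials": st.n_trials,
            "meta": st.meta,
        }
        (directory / f"{st.label}.json").write_text(json.dumps(sidecar, indent=1))


def read_trials(directory: str | Path) -> TrialSet:
    """Read a directory written by :func:`write_trials`.

    Rejects malformed headers and ragged rows with the offending line
    number, and a missing JSON sidecar with the file name.
    """
    directory = Path(directory)
    ts = TrialSet()
    for csv_path in sorted(directory.glob("*.csv")):
        sidecar_path = csv_path.with_suffix(".json")
        if not sidecar_path.exists():
            raise FileNotFoundError(
                f"missing JSON sidecar for {csv_path.name}: expected {sidecar_path.name}")
        meta = json.loads(sidecar_path.read_text())
        with open(csv_path, newline="") as fh:
            header = fh.readline().strip().rstrip(",")
            names = header.split(",")
            if names[0] != "t_ms" or any(not n.startswith("rep") for n in names[1:]):
                raise ValueError(
                    f"{csv_path.name}: malformed header line 1: {header!r} "
                    "(expected 't_ms,rep1,rep2,...')")
            rows = []
            for lineno, line in enumerate(fh, start=2):
                line = line.strip()
                if not line:
                    continue
                fields = line.split(",")
                if len(fields) != len(names):
                    raise ValueError(
                        f"{csv_path.name}: line {lineno} has {len(fields)} "
                        f"fields, expected {len(names)}")
                try:
                    rows.append([float(f) for f in fields])
                except ValueError as exc:
                    raise ValueError(f"{csv_path.name}: line {lineno}: {exc}") from None
        data = np.asarray(rows)
        traces = data[:, 1:].T
        ts.add(StimulusTrials(
            traces=traces, dt_ms=float(meta["dt_ms"]),
            onset_ms=float(meta["onset_ms"]), label=meta["label"],
            group=meta.get("group", "default"), meta=meta.get("meta", {})))
    return ts


def write_fit_results(results: list[FitResult], path: str | Path,
                      config_echo: dict | None = None) -> None:
    """Write all restart results plus a config echo as one JSON file."""
    from .model import EIParams, EpEmParams  # avoid cycle at import time

    def params_obj(p) -> dict:
        if isinstance(p, (EIParams, EpEmParams)):
            return asdict(p)
        raise TypeError(f"cannot serialize params of type {type(p).__name__}")

    records = [{
        "variant": r.variant,
        "sse": r.sse,
        "start_index": r.start_index,
        "rng_seed": r.rng_seed,
        "converged": r.converged,
        "params": params_obj(r.params),
    } for r in results]
    obj = {"software": "t5model 0.1.0", "config": config_echo or {},
           "results": records}
    Path(path).write_text(json.dumps(obj, indent=1))
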