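"""Tabular serialization: long-format CSV for data and moments, JSON for results.

All artifacts are plain text and embed the seed, parameter vector and package
version where applicable, so that any output can be traced back to the exact
run that produced it.  Round trips are exact for integer counts and at least
1e-12-accurate for reals.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ValidationError
from .sample_moments import SampleMomentSeries
from .ssa import DataTensor

__all__ = ["write_data_tensor", "read_data_tensor",
           "write_sample_moments", "read_sample_moments",
           "write_fit_result", "write_chain", "write_report_json"]


def write_data_tensor(data: DataTensor, csv_path, sidecar_path=None):
    """Long-format CSV (replicate, time, species, count) + provenance JSON."""
    n, k, d = data.values.shape
    rep, t_idx, s_idx = np.meshgrid(np.arange(n), np.arange(k), np.arange(d),
                                    indexing="ij")
    df = pd.DataFrame({
        "replicate": rep.ravel(),
        "time": data.times[t_idx.ravel()],
        "species": np.asarray(data.observed_indices)[s_idx.ravel()],
        "count": data.values.ravel(),
    })
    df.to_csv(csv_path, index=False)
    if sidecar_path is not None:
        meta = dict(data.meta)
        meta.update({"version": __version__,
                     "observed_indices": list(data.observed_indices),
                     "times": [float(t) for t in data.times],
                     "n_replicates": int(n)})
        Path(sidecar_path).write_text(json.dumps(meta, indent=2))


def read_data_tensor(csv_path, sidecar_path=None):
    df = pd.read_csv(csv_path)
    required = {"replicate", "time", "species", "count"}
    if not required <= set(df.columns):
        raise ValidationError(f"data CSV must have columns {sorted(required)}")
    times = np.sort(df["time"].unique())
    species = sorted(df["species"].unique())
    reps = np.sort(df["replicate"].unique())
    values = np.empty((len(reps), len(times), len(species)), dtype=int)
    t_pos = {t: i for i, t in enumerate(times)}
    s_pos = {s: i for i, s in enumerate(species)}
    r_pos = {r: i for i, r in enumerate(reps)}
    values[df["replicate"].map(r_pos), df["time"].map(t_pos),
           df["species"].map(s_pos)] = df["count"]
    meta = {}
    if sidecar_path is not None and Path(sidecar_path).exists():
        meta = json.loads(Path(sidecar_path).read_text())
    return DataTensor(values, times, tuple(species), meta)


def write_sample_moments(sm: SampleMomentSeries, csv_path):
    """Tidy CSV: time, statistic, component_i, component_j, value."""
    rows = []
    comps = (list(sm.observed_indices) if sm.observed_indices
             else list(range(sm.d)))
    for k, t in enumerate(sm.times):
        for i, ci in enumerate(comps):
            rows.append((t, "mean", ci, "", sm.mean[k, i]))
        if sm.cov is not None:
            for i, ci in enumerate(comps):
                for j, cj in enumerate(comps):
                    if j < i:
                        continue
                    rows.append((t, "cov", ci, cj, sm.cov[k, i, j]))
    df = pd.DataFrame(rows, columns=["time", "statistic", "component_i",
                                     "component_j", "value"])
    df.attrs["n_replicates"] = sm.n_replicates
    df.to_csv(csv_path, index=False)
    return df


def read_sample_moments(csv_path, n_replicates):
    df = pd.read_csv(csv_path)
    times = np.sort(df["time"].unique())
    comps = sorted(df.loc[df["statistic"] == "mean", "component_i"].unique())
    k, d = len(times), len(comps)
    mean = np.zeros((k, d))
    t_pos = {t: i for i, t in enumerate(times)}
    c_pos = {c: i for i, c in enumerate(comps)}
    has_cov = (df["statistic"] == "cov").any()
    cov = np.zeros((k, d, d)) if has_cov else None
    for row in df.itertuples(index=False):
        ti = t_pos[row.time]
        ci = c_pos[row.component_i]
        if row.statistic == "mean":
            mean[ti, ci] = row.value
        elif row.statistic == "cov":
            cj = c_pos[int(float(row.component_j))]
            cov[ti, ci, cj] = row.value
            cov[ti, cj, ci] = row.value
        else:
            raise ValidationError(f"unknown statistic '{row.statistic}'")
    return SampleMomentSeries(times, 2 if has_cov else 1, mean, cov,
                              n_replicates, tuple(int(c) for c in comps))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_fit_result(fit, json_path, trace_csv_path=None, extra=None):
    payload = {
        "version": __version__,
        "c_hat": fit.c_hat.tolist(),
        "cost": fit.cost,
        "n_iterations": fit.n_iterations,
        "n_evaluations": fit.n_evaluations,
        "termination": fit.termination,
        "success": fit.success,
        "rel_errors": None if fit.rel_errors is None else fit.rel_errors.tolist(),
    }
    payload.update(_jsonable(extra or {}))
    Path(json_path).write_text(json.dumps(payload, indent=2))
    if trace_csv_path is not None:
        cols = {f"c{i+1}": fit.iterates[:, i] for i in range(fit.iterates.shape[1])}
        cols["cost"] = fit.cost_trace
        pd.DataFrame(cols).to_csv(trace_csv_path, index=False)


def write_chain(chain, csv_path, json_path=None, summary=None):
    cols = {f"c{i+1}": chain.samples[:, i] for i in range(chain.samples.shape[1])}
    cols["log_target"] = chain.log_target_trace
    pd.DataFrame(cols).to_csv(csv_path, index=False)
    if json_path is not None:
        payload = {
            "version": __version__,
            "seed": chain.seed,
            "burn_in": chain.burn_in,
            "acceptance_rate": chain.acceptance_rate,
            "proposal_sd": chain.proposal_sd.tolist(),
            "priors": [{"shape": p.shape, "rate": p.rate} for p in chain.priors],
        }
        if summary is not None:
            payload["summary"] = _jsonable(summary)
        Path(json_path).write_text(json.dumps(payload, indent=2))


def write_report_json(report_dict, json_path):
    payload = {"version": __version__}
    payload.update(_jsonable(report_dict))
    Path(json_path).write_text(json.dumps(payload, indent=2))
    return payload
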