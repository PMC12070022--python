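"""CSV / JSON serialization for every pipeline artefact.

Schemas
-------
events CSV   : participant_id,channel,start,end  (ISO-8601 with offset)
hourly CSV   : participant_id,timestamp,hour,<5 channel columns>,
               overall_available,gps_available — one row per hour; channel
               cells are the binary indicators, empty when the hour is
               overall-unavailable
clinical CSV : participant_id,group,age[,overall_availability,scores...]
model JSON   : {n_states, channels, pi, phi, beta, covariate, meta}
paths CSV    : participant_id,t,state,missing
dwell CSV    : participant_id,active_state,total_dwell_time,
               n_hours_observed,n_hours_missing
results CSV  : term,coef,se,stat,df,p,p_adj[,odds_ratio,ci_low,ci_high]

Numeric fields round-trip at 12 significant digits; malformed input raises
with the offending column or row named.
"""

from __future__ import annotations

import json
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .hmm import FitResult, HMMParameters
from .phenotype import DwellRecord, StatePath
from .preprocess import ACTIVITY_CHANNELS, EventLog, HourlySeries, PreprocessError

_OFFSET = "+00:00"  # synthetic data are generated in a single local zone


class IOError_(ValueError):
    pass


def _require(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise IOError_(f"{what}: missing required column(s) {missing}")


# -- events ------------------------------------------------------------------

def write_events_csv(logs: list[EventLog], path) -> None:
    frames = []
    for log in logs:
        df = log.records.copy()
        df.insert(0, "participant_id", log.participant_id)
        df["start"] = [t.isoformat() + _OFFSET for t in df["start"]]
        df["end"] = [t.isoformat() + _OFFSET for t in df["end"]]
        frames.append(df[["participant_id", "channel", "start", "end"]])
    pd.concat(frames).to_csv(path, index=False)


def read_events_csv(path) -> list[EventLog]:
    from .preprocess import parse_events

    df = pd.read_csv(path, dtype=str)
    _require(df, ["participant_id", "channel", "start", "end"], "events CSV")
    return parse_events(df)


# -- hourly series -----------------------------------------------------------

def write_hourly_csv(series_list: list[HourlySeries], path) -> None:
    rows = []
    for s in series_list:
        if s.binary is None:
            raise IOError_("hourly series must be binarized before writing")
        hods = s.hour_of_day
        for t, ts in enumerate(s.timestamps()):
            row = {
                "participant_id": s.participant_id,
                "timestamp": ts.isoformat() + _OFFSET,
                "hour": int(hods[t]),
            }
            for c, chan in enumerate(s.channels):
                row[chan] = (
                    int(s.binary[t, c]) if s.overall_available[t] else ""
                )
            row["overall_available"] = int(s.overall_available[t])
            row["gps_available"] = int(s.gps_available[t])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_hourly_csv(path) -> list[HourlySeries]:
    df = pd.read_csv(path)
    cols = ["participant_id", "timestamp", "hour", *ACTIVITY_CHANNELS,
            "overall_available", "gps_available"]
    _require(df, cols, "hourly CSV")
    if df.duplicated(subset=["participant_id", "timestamp"]).any():
        dup = df[df.duplicated(subset=["participant_id", "timestamp"])].iloc[0]
        raise IOError_(
            f"duplicated participant-hour row: {dup['participant_id']} {dup['timestamp']}"
        )
    out = []
    for pid, sub in df.groupby("participant_id", sort=True):
        sub = sub.reset_index(drop=True)
        start = datetime.fromisoformat(str(sub["timestamp"].iloc[0])).replace(tzinfo=None)
        avail = sub["overall_available"].to_numpy().astype(bool)
        binary = np.zeros((len(sub), len(ACTIVITY_CHANNELS)), dtype=np.int8)
        for c, chan in enumerate(ACTIVITY_CHANNELS):
            vals = pd.to_numeric(sub[chan], errors="coerce")
            binary[:, c] = np.where(avail, vals.fillna(0).astype(int), 0)
        out.append(
            HourlySeries(
                participant_id=str(pid),
                start=start,
                channels=ACTIVITY_CHANNELS,
                fractions=binary.astype(float),  # fractions are not stored
                overall_available=avail,
                gps_available=sub["gps_available"].to_numpy().astype(bool),
                binary=binary,
                threshold=None,
            )
        )
    return out


# -- model JSON --------------------------------------------------------------

def write_model_json(fit: FitResult, path) -> None:
    p = fit.params
    doc = {
        "n_states": p.n_states,
        "channels": list(p.channels) if p.channels else None,
        "pi": p.pi.tolist(),
        "phi": p.phi.tolist(),
        "beta": p.beta.tolist(),
        "covariate": p.covariate,
        "meta": {
            "seed": fit.seed,
            "loglik": fit.loglik,
            "bic": fit.bic,
            "n_iter": fit.n_iter,
            "n_obs_used": fit.n_obs_used,
            "converged": bool(fit.converged),
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_model_json(path) -> tuple[HMMParameters, dict]:
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("n_states", "pi", "phi", "beta", "covariate"):
        if key not in doc:
            raise IOError_(f"model JSON: missing key {key!r}")
    params = HMMParameters(
        pi=np.array(doc["pi"]),
        phi=np.array(doc["phi"]),
        beta=np.array(doc["beta"]),
        covariate=doc["covariate"],
        channels=tuple(doc["channels"]) if doc.get("channels") else None,
    )
    return params, doc.get("meta", {})


# -- paths / dwell / results -------------------------------------------------

def write_paths_csv(paths: list[StatePath], path) -> None:
    rows = []
    for p in paths:
        for t in range(p.T):
            rows.append(
                {
                    "participant_id": p.participant_id,
                    "t": t,
                    "state": int(p.states[t]),
                    "missing": int(p.missing_mask[t]),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_paths_csv(path) -> list[StatePath]:
    df = pd.read_csv(path)
    _require(df, ["participant_id", "t", "state", "missing"], "paths CSV")
    out = []
    for pid, sub in df.groupby("participant_id", sort=True):
        sub = sub.sort_values("t")
        out.append(
            StatePath(
                participant_id=str(pid),
                states=sub["state"].to_numpy(),
                missing_mask=sub["missing"].to_numpy().astype(bool),
            )
        )
    return out


def write_dwell_csv(records: list[DwellRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "active_state": r.active_state,
                "total_dwell_time": round(r.total_dwell_time, 10),
                "n_hours_observed": r.n_hours_observed,
                "n_hours_missing": r.n_hours_missing,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def read_dwell_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(
        df,
        ["participant_id", "active_state", "total_dwell_time",
         "n_hours_observed", "n_hours_missing"],
        "dwell CSV",
    )
    return df


def read_clinical_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["participant_id", "group", "age"], "clinical CSV")
    return df


def write_results_csv(result, path) -> None:
    result.table.to_csv(path, index=False, float_format="%.12g")
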