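"""Synthetic smartphone cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes: each
participant carries a latent socially active / inactive state evolving as an
hour-dependent Markov chain (a raised-cosine diurnal profile on the score of
transitioning into the active state, peaked mid-afternoon); binary channel
activity is emitted per hour from state-specific Bernoulli rates; active
hours are expanded into event intervals whose durations follow a
right-skewed zero-truncated Beta(1.5, 5) law, under which the 0% and 5%
activity thresholds agree on ~91% of active hours while a 10% threshold
diverges markedly; Wi-Fi scans and location fixes are emitted as Poisson
streams so availability can be computed from sampling frequency; and block
missingness removes whole hours of records at once.  Clinical groups shift
the into-active transition score (harder to enter the active state), which
lowers dwell time — the target phenotype.  Clinical scores are generated from
linear models on the *true* dwell time with the published coefficient values
as defaults, so the downstream regressions have a known truth to recover.

Every draw is reproducible from the master seed; ground truth (state paths,
true dwell times, generating coefficients) is returned alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .hmm import HMMParameters, N_HOURS, ObservationSequence
from .phenotype import StatePath
from .preprocess import ACTIVITY_CHANNELS, HOUR, EventLog, HourlySeries


class SimulationError(ValueError):
    pass


def diurnal_profile(low: float, high: float, peak_hour: float = 15.0) -> np.ndarray:
    """Smooth 24-value day/night profile: ``low`` at night, ``high`` at the
    mid-afternoon peak, raised-cosine in between."""
    h = np.arange(N_HOURS)
    w = 0.5 * (1.0 + np.cos(2 * np.pi * (h - peak_hour) / N_HOURS))
    return low + (high - low) * w


def default_hmm_parameters(enter_shift: float = 0.0) -> HMMParameters:
    """2-state generating model: state 1 socially inactive, state 2 active.

    ``enter_shift`` is added to the into-active transition score from both
    origins (group effects make entering the active state harder).
    """
    phi = np.array(
        [
            [0.05, 0.03, 0.01, 0.01, 0.15],  # inactive
            [0.55, 0.75, 0.10, 0.12, 0.95],  # active
        ]
    )
    beta = np.zeros((2, 2, N_HOURS))
    beta[0, 1] = diurnal_profile(-3.2, -0.6) + enter_shift
    beta[1, 1] = diurnal_profile(-0.8, 1.6) + enter_shift
    return HMMParameters(
        pi=np.array([0.74, 0.26]),
        phi=phi,
        beta=beta,
        covariate="hour_onehot24",
        channels=ACTIVITY_CHANNELS,
    )


@dataclass
class SimulationConfig:
    """Cohort-level generating conditions.

    Defaults reflect a 42-day collection window (plus a partial onboarding
    day that preprocessing trims), validation-set group proportions of the
    source cohort scaled to a desk-size study, and clinical-score
    coefficients set to the published point estimates where those exist.
    """

    n_per_group: dict = field(
        default_factory=lambda: {"HC": 40, "SZ": 6, "AD": 8, "SCC": 16}
    )
    days: int = 42
    start: datetime = field(default_factory=lambda: datetime(2019, 3, 4, 9, 0))
    group_enter_shift: dict = field(
        default_factory=lambda: {"HC": 0.0, "SZ": -0.1, "AD": -0.9, "SCC": -0.35}
    )
    subject_sd: float = 0.3  # per-participant random effect on the enter score
    # availability: per-participant target ~ Beta(a, b); missing hours arrive
    # in geometric blocks
    availability_beta: tuple[float, float] = (7.0, 1.0)
    block_mean_length: float = 12.0
    # active-hour activity fractions ~ Beta(a, b) (zero-truncated by design)
    fraction_beta: tuple[float, float] = (1.5, 5.0)
    wifi_rate: float = 6.0  # samples per hour
    location_rate: float = 1.5
    # age ranges per group; HC is a mixture matching both clinical age bands
    age_ranges: dict = field(
        default_factory=lambda: {
            "SZ": (18, 45),
            "AD": (50, 80),
            "SCC": (45, 80),
            "HC": ((18, 45), (45, 80), 0.4),  # (young band, old band, P(young))
        }
    )
    # SFS ~ b0 + b_dwell*dwell + b_age*age + group main + group:dwell + N(0, sd)
    sfs_coefficients: dict = field(
        default_factory=lambda: {
            "intercept": 100.0,
            "total_dwell_time": 0.1193,
            "age": 0.0269,
            "SZ": -20.5052,
            "AD": 4.4857,
            "SCC": 0.0,
            "SZ:total_dwell_time": 0.0401,
            "AD:total_dwell_time": -0.3201,
            "SCC:total_dwell_time": 0.0,
            "noise_sd": 10.0,
        }
    )
    loneliness_coefficients: dict = field(
        default_factory=lambda: {
            "intercept": 8.0,
            "total_dwell_time": -0.01,
            "age": 0.005,
            "noise_sd": 2.0,
        }
    )
    mmse_coefficients: dict = field(
        default_factory=lambda: {
            "intercept": 29.0,
            "total_dwell_time": 0.0,
            "age": -0.01,
            "AD": -5.0,
            "noise_sd": 1.2,
        }
    )
    panss_total_coefficients: dict = field(
        default_factory=lambda: {
            "intercept": 55.0,
            "total_dwell_time": -0.05,
            "noise_sd": 8.0,
        }
    )
    seed: int = 0


def simulate_sequences(
    params: HMMParameters,
    n_sequences: int,
    T: int,
    seed=None,
    start_hour: int = 0,
):
    """Exact draws from the HMM: (list of ObservationSequence, list of
    StatePath).  The workhorse for parameter-recovery benchmarks."""
    rng = np.random.default_rng(seed)
    A = params.transition_matrices()  # (P, N, N)
    N = params.n_states
    seqs, paths = [], []
    hours = (start_hour + np.arange(T)) % N_HOURS
    hidx = hours if params.covariate == "hour_onehot24" else np.zeros(T, dtype=int)
    for i in range(n_sequences):
        z = np.zeros(T, dtype=int)
        z[0] = rng.choice(N, p=params.pi)
        for t in range(1, T):
            z[t] = rng.choice(N, p=A[hidx[t], z[t - 1]])
        x = (rng.random((T, params.n_channels)) < params.phi[z]).astype(float)
        seqs.append(
            ObservationSequence(
                participant_id=f"sim{i:04d}",
                x=x,
                hour_of_day=hours,
                channels=params.channels,
            )
        )
        paths.append(
            StatePath(
                participant_id=f"sim{i:04d}",
                states=z + 1,
                missing_mask=np.zeros(T, dtype=bool),
            )
        )
    return seqs, paths


def sample_missing_mask(
    T: int, availability_target: float, block_mean_length: float, rng
) -> np.ndarray:
    """(T,) boolean mask, True = missing, built from geometric-length blocks.

    Blocks are dropped until the number of missing hours reaches
    round(T * (1 - target)); the final block is truncated so the realised
    availability lands within the +-2% band around the target.
    """
    if not (0.0 < availability_target <= 1.0):
        raise SimulationError("availability target must lie in (0, 1]")
    missing = np.zeros(T, dtype=bool)
    target_missing = int(round(T * (1.0 - availability_target)))
    p_geom = min(1.0, 1.0 / block_mean_length)
    while missing.sum() < target_missing:
        start = int(rng.integers(0, T))
        length = int(rng.geometric(p_geom))
        block = np.arange(start, min(start + length, T))
        new = block[~missing[block]]
        need = target_missing - int(missing.sum())
        missing[new[:need]] = True
    return missing


def inject_missingness(
    series: HourlySeries, availability_target: float, block_mean_length: float, seed=None
) -> tuple[HourlySeries, np.ndarray]:
    """Mark block-missing hours on an hourly series (availability masks set
    False, binary/fractions zeroed there).  Returns (series, mask)."""
    rng = np.random.default_rng(seed)
    mask = sample_missing_mask(series.T, availability_target, block_mean_length, rng)
    from dataclasses import replace

    out = replace(
        series,
        fractions=np.where(mask[:, None], 0.0, series.fractions),
        binary=None
        if series.binary is None
        else np.where(mask[:, None], 0, series.binary),
        overall_available=series.overall_available & ~mask,
        gps_available=series.gps_available & ~mask,
    )
    return out, mask


def _events_for_hour(rng, hour_start, x_row, frac_a, frac_b):
    """Expand one hour's binary channel activity into event intervals.

    Each active channel gets one interval of Beta-drawn length placed
    uniformly in the hour; overall phone usage is the union of the other
    channels' intervals plus its own (so it is always a superset).
    """
    rows = []
    union: list[tuple[float, float]] = []
    for c, chan in enumerate(ACTIVITY_CHANNELS[:-1]):
        if x_row[c] > 0:
            dur = float(rng.beta(frac_a, frac_b)) * 3600.0
            dur = max(dur, 1.0)
            off = float(rng.uniform(0.0, 3600.0 - dur))
            rows.append((chan, off, off + dur))
            union.append((off, off + dur))
    if x_row[-1] > 0:
        dur = float(rng.beta(frac_a, frac_b)) * 3600.0
        dur = max(dur, 1.0)
        off = float(rng.uniform(0.0, 3600.0 - dur))
        union.append((off, off + dur))
    if union:  # phone usage covers all in-phone activity
        union.sort()
        merged = [list(union[0])]
        for s, e in union[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            rows.append(("phone_usage", s, e))
    out = []
    for chan, s, e in rows:
        out.append(
            {
                "channel": chan,
                "start": hour_start + timedelta(seconds=s),
                "end": hour_start + timedelta(seconds=e),
            }
        )
    return out


def simulate_participant(
    config: SimulationConfig, group: str, participant_id: str, seed=None
) -> tuple[EventLog, StatePath, dict]:
    """One participant's event log plus ground truth.

    The latent path starts at the configured (non-midnight) install time; the
    truth dict records the post-first-midnight portion (what survives
    preprocessing): true states, the injected missingness mask, true dwell
    time over non-missing hours, and the realised availability.
    """
    if group not in config.group_enter_shift:
        raise SimulationError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    shift = config.group_enter_shift[group] + rng.normal(0.0, config.subject_sd)
    params = default_hmm_parameters(enter_shift=shift)
    A = params.transition_matrices()

    start = config.start
    first_midnight = start.replace(hour=0, minute=0) + timedelta(days=1)
    T_total = int((first_midnight - start) // HOUR) + config.days * 24
    hours = np.array([(start + t * HOUR).hour for t in range(T_total)])

    z = np.zeros(T_total, dtype=int)
    z[0] = rng.choice(2, p=params.pi)
    for t in range(1, T_total):
        z[t] = rng.choice(2, p=A[hours[t], z[t - 1]])
    x = (rng.random((T_total, len(ACTIVITY_CHANNELS))) < params.phi[z]).astype(float)

    availability = float(
        rng.beta(*config.availability_beta)
    )
    missing = sample_missing_mask(
        T_total, max(availability, 0.05), config.block_mean_length, rng
    )

    frac_a, frac_b = config.fraction_beta
    records = []
    for t in range(T_total):
        if missing[t]:
            continue
        hour_start = start + t * HOUR
        records.extend(_events_for_hour(rng, hour_start, x[t], frac_a, frac_b))
        for _ in range(rng.poisson(config.wifi_rate)):
            ts = hour_start + timedelta(seconds=float(rng.uniform(0, 3600)))
            records.append({"channel": "wifi_sample", "start": ts, "end": ts})
        for _ in range(rng.poisson(config.location_rate)):
            ts = hour_start + timedelta(seconds=float(rng.uniform(0, 3600)))
            records.append({"channel": "location_sample", "start": ts, "end": ts})
    if not records:
        raise SimulationError(f"participant {participant_id}: no data survived")
    log = EventLog(participant_id, pd.DataFrame(records))

    # truth restricted to the retained (post-first-midnight) portion
    keep = int((first_midnight - start) // HOUR)
    z_kept, miss_kept = z[keep:], missing[keep:]
    observed = ~miss_kept
    true_dwell = 100.0 * (z_kept[observed] == 1).sum() / max(observed.sum(), 1)
    truth = {
        "true_states": z_kept + 1,
        "missing_mask": miss_kept,
        "true_dwell": float(true_dwell),
        "availability": float(observed.mean()),
        "enter_shift": float(shift),
    }
    path = StatePath(participant_id, z_kept + 1, miss_kept)
    return log, path, truth


def _draw_age(rng, spec):
    if isinstance(spec[0], tuple):
        young, old, p_young = spec
        lo, hi = young if rng.random() < p_young else old
    else:
        lo, hi = spec
    return float(rng.uniform(lo, hi))


def simulate_cohort(config: SimulationConfig):
    """Full cohort: (logs, truths, cohort table, generating-truth sidecar).

    ``logs`` maps participant id -> EventLog; ``truths`` id -> truth dict;
    the cohort table carries group, age, realised availability, true dwell
    and clinical scores.  SFS-type scores follow the study's administration
    pattern (SFS and loneliness for HC/SZ/AD, MMSE for HC/AD, PANSS for SZ).
    """
    if not config.n_per_group:
        raise SimulationError("empty group list")
    root = np.random.default_rng(config.seed)
    logs, truths, rows = {}, {}, []
    for group in config.n_per_group:
        if group not in config.group_enter_shift:
            raise SimulationError(f"unknown group {group!r}")
    for group, n in config.n_per_group.items():
        for i in range(n):
            pid = f"{group}{i:03d}"
            pseed = int(root.integers(2**31 - 1))
            log, path, truth = simulate_participant(config, group, pid, pseed)
            logs[pid] = log
            truths[pid] = truth
            age = _draw_age(root, config.age_ranges[group])
            dwell = truth["true_dwell"]
            c = config.sfs_coefficients
            sfs = (
                c["intercept"]
                + c["total_dwell_time"] * dwell
                + c["age"] * age
                + c.get(group, 0.0)
                + c.get(f"{group}:total_dwell_time", 0.0) * dwell
                + root.normal(0.0, c["noise_sd"])
            )
            lc = config.loneliness_coefficients
            lone = (
                lc["intercept"]
                + lc["total_dwell_time"] * dwell
                + lc["age"] * age
                + root.normal(0.0, lc["noise_sd"])
            )
            mc = config.mmse_coefficients
            mmse = (
                mc["intercept"]
                + mc["total_dwell_time"] * dwell
                + mc["age"] * age
                + mc.get(group, 0.0)
                + root.normal(0.0, mc["noise_sd"])
            )
            pc = config.panss_total_coefficients
            panss = (
                pc["intercept"]
                + pc["total_dwell_time"] * dwell
                + root.normal(0.0, pc["noise_sd"])
            )
            rows.append(
                {
                    "participant_id": pid,
                    "group": group,
                    "age": age,
                    "overall_availability": truth["availability"],
                    "true_dwell": dwell,
                    "sfs": sfs if group in ("HC", "SZ", "AD") else np.nan,
                    "loneliness": lone if group in ("HC", "SZ", "AD") else np.nan,
                    "mmse": mmse if group in ("HC", "AD") else np.nan,
                    "panss_total": panss if group == "SZ" else np.nan,
                }
            )
    table = pd.DataFrame(rows)
    sidecar = {
        "seed": config.seed,
        "sfs_coefficients": dict(config.sfs_coefficients),
        "group_enter_shift": dict(config.group_enter_shift),
        "true_dwell": {r["participant_id"]: r["true_dwell"] for r in rows},
    }
    return logs, truths, table, sidecar


def simulate_group_labels(dwell, alpha: float, beta: float, seed=None) -> np.ndarray:
    """Binary labels with P(label=1) = logistic(alpha + beta * dwell) — the
    generator behind logistic-slope recovery checks."""
    rng = np.random.default_rng(seed)
    p = 1.0 / (1.0 + np.exp(-(alpha + beta * np.asarray(dwell, dtype=float))))
    return (rng.random(len(p)) < p).astype(int)
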