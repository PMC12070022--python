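"""Interpretation of fitted states and dwell-time phenotypes.

After fitting, states are interpreted through their emission probabilities:
the "socially active" state is the one most likely to show communication-app
activity (phone usage breaks ties).  The per-participant phenotype is the
total dwell time — the percentage of non-missing hours whose decoded state is
the socially active one (fractional occupancy).  Two decodings of the same
series (e.g. from a model trained on healthy controls vs one trained on the
clinical groups) are compared by accuracy / sensitivity / specificity after
matching states between the models by emission similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .hmm import HMMParameters, ModelError


class PhenotypeError(ValueError):
    pass


@dataclass
class StatePath:
    """Decoded hidden state sequence (1-based states) with its missingness mask."""

    participant_id: str
    states: np.ndarray  # (T,) int in 1..N
    missing_mask: np.ndarray  # (T,) bool, True where the hour was not observed

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.states.shape != self.missing_mask.shape:
            raise PhenotypeError("states and missing_mask lengths differ")

    @property
    def T(self) -> int:
        return self.states.shape[0]


@dataclass
class DwellRecord:
    participant_id: str
    active_state: int
    total_dwell_time: float  # percent of observed hours in the active state
    n_hours_observed: int
    n_hours_missing: int


@dataclass
class DecodingComparison:
    accuracy: float
    sensitivity: float | None  # None when the reference has no active hours
    specificity: float | None  # None when the reference has no inactive hours
    state_matching: tuple[int, ...]


def identify_active_state(
    params: HMMParameters,
    communication_channel: str = "communication",
    phone_channel: str = "phone_usage",
) -> int:
    """The socially active state (1-based): maximal communication-app
    emission probability, ties broken by maximal phone-usage emission."""
    channels = params.channels or ()
    try:
        c_comm = channels.index(communication_channel)
        c_phone = channels.index(phone_channel)
    except (ValueError, AttributeError) as exc:
        raise PhenotypeError(
            "params.channels must name the communication and phone-usage columns"
        ) from exc
    comm = params.phi[:, c_comm]
    best = np.flatnonzero(comm == comm.max())
    if len(best) > 1:
        phone = params.phi[best, c_phone]
        best = best[np.flatnonzero(phone == phone.max())]
    if len(best) > 1:
        raise PhenotypeError("states not distinguishable")
    return int(best[0]) + 1


def total_dwell_time(path: StatePath, active_state: int) -> DwellRecord:
    """Percentage of observed hours decoded as the active state.

    Missing hours are dropped before the percentage is formed, so the value
    reflects only the data that were actually collected.
    """
    observed = ~path.missing_mask
    n_obs = int(observed.sum())
    if n_obs == 0:
        raise PhenotypeError(f"no observed data for {path.participant_id!r}")
    n_active = int((path.states[observed] == active_state).sum())
    return DwellRecord(
        participant_id=path.participant_id,
        active_state=active_state,
        total_dwell_time=100.0 * n_active / n_obs,
        n_hours_observed=n_obs,
        n_hours_missing=int(path.missing_mask.sum()),
    )


def match_states(params_a: HMMParameters, params_b: HMMParameters) -> tuple[int, ...]:
    """Match states of model b onto model a by emission similarity.

    Returns the permutation ``perm`` (1-based) minimising the total L1
    distance between matched emission rows, with ``perm[i]`` the state of b
    corresponding to state ``i+1`` of a.  Exhaustive over the N! candidates
    (N <= 4 in practice).
    """
    if params_a.n_states != params_b.n_states:
        raise ModelError("models have different numbers of states")
    if params_a.n_channels != params_b.n_channels:
        raise ModelError("models have different channel sets")
    N = params_a.n_states
    best_perm, best_cost = None, np.inf
    for perm in permutations(range(N)):
        cost = sum(
            np.abs(params_a.phi[i] - params_b.phi[perm[i]]).sum() for i in range(N)
        )
        if cost < best_cost:
            best_perm, best_cost = perm, cost
    assert best_perm is not None
    return tuple(p + 1 for p in best_perm)


def apply_matching(path: StatePath, matching: tuple[int, ...]) -> StatePath:
    """Relabel a path decoded under model b into model a's state labels,
    given ``matching`` from :func:`match_states`(a, b)."""
    inverse = np.zeros(len(matching) + 1, dtype=int)
    for a_state, b_state in enumerate(matching, start=1):
        inverse[b_state] = a_state
    return StatePath(
        participant_id=path.participant_id,
        states=inverse[path.states],
        missing_mask=path.missing_mask,
    )


def compare_paths(
    reference: StatePath,
    test: StatePath,
    active_state: int,
    matching: tuple[int, ...] | None = None,
) -> DecodingComparison:
    """Accuracy / sensitivity / specificity of ``test`` against ``reference``.

    The test path is first relabelled through ``matching`` (identity when
    None).  Hours missing in either path are excluded.  Sensitivity is
    P(test = active | reference = active); an empty reference class makes the
    corresponding metric None rather than silently 1.
    """
    if reference.T != test.T:
        raise PhenotypeError("paths have different lengths")
    if matching is not None:
        test = apply_matching(test, matching)
        matching_out = matching
    else:
        matching_out = tuple(range(1, int(max(reference.states.max(), 1)) + 1))
    observed = ~(reference.missing_mask | test.missing_mask)
    if not observed.any():
        raise PhenotypeError("no jointly observed timepoints")
    ref = reference.states[observed]
    tst = test.states[observed]
    accuracy = float((ref == tst).mean())
    ref_active = ref == active_state
    tst_active = tst == active_state
    sensitivity = (
        float(tst_active[ref_active].mean()) if ref_active.any() else None
    )
    specificity = (
        float((~tst_active[~ref_active]).mean()) if (~ref_active).any() else None
    )
    return DecodingComparison(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        state_matching=matching_out,
    )
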