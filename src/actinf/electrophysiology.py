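"""Simulated neuronal observables derived from trial records.

Units are identified with the sufficient statistics of posterior beliefs:
the softmax readout ``s_bar`` plays the role of firing rate (rasters), its
rate of change ``nu_dot`` the role of depolarisation (simulated ERPs), the
policy precision ``gamma = 1/beta`` the role of dopamine, and the amount of
belief updating between probe and report the role of reaction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import softmax
from .hierarchy import HierarchicalTrialResult
from .inference import TrialRecord

__all__ = [
    "ERPWaveform", "MS_PER_ITERATION",
    "unit_raster", "simulate_erp", "simulate_dopamine", "reaction_time",
    "upper_nu_dot_timeline", "global_event_offsets",
    "phasic_probe_amplitude", "updates_per_iteration",
]

#: display convention mapping gradient iterations onto milliseconds: one
#: 16-iteration update block spans ~256 ms.
MS_PER_ITERATION = 16.0


@dataclass
class ERPWaveform:
    condition: str
    units: list
    values: np.ndarray          # mean nu_dot per iteration tick (nats/iteration)
    ms_per_tick: float = MS_PER_ITERATION
    lock: str = ""

    @property
    def times_ms(self):
        return np.arange(len(self.values)) * self.ms_per_tick


def _policy_averaged(arrs, q_pi):
    """Average a per-policy [n_pol, T, n] array over policies."""
    return np.tensordot(q_pi, arrs, axes=(0, 0))


def unit_raster(record: TrialRecord, units):
    """Matrix [unit x iteration] of Bayesian-model-averaged expectations
    ``s_bar`` for the requested units ((factor, state, time) triples)."""
    out = np.zeros((len(units), record.n_iterations))
    for it, (nus, q_pi) in enumerate(zip(record.nu_log, record.q_pi_iter)):
        for k, (f, s, tt) in enumerate(units):
            sb = softmax(nus[f], axis=-1)
            if not (0 <= s < sb.shape[2] and 0 <= tt < sb.shape[1]):
                raise KeyError(f"unknown unit (factor={f}, state={s}, time={tt})")
            out[k, it] = _policy_averaged(sb, q_pi)[tt, s]
    return out


def _nu_dot_series(record: TrialRecord, units):
    """Per-iteration policy-averaged nu_dot for the requested units."""
    out = np.zeros((len(units), record.n_iterations))
    for it, (nds, q_pi) in enumerate(zip(record.nu_dot_log, record.q_pi_iter)):
        for k, (f, s, tt) in enumerate(units):
            out[k, it] = _policy_averaged(nds[f], q_pi)[tt, s]
    return out


def updates_per_iteration(record: TrialRecord):
    """Number of individual belief updates (nu components) per gradient
    iteration at this level — the unit of simulated computational work."""
    if not record.nu_dot_log:
        return 0
    return int(sum(a.size for a in record.nu_dot_log[0]))


# ---------------------------------------------------------------------------
# hierarchical timelines
# ---------------------------------------------------------------------------

def upper_nu_dot_timeline(result: HierarchicalTrialResult, units):
    """Global-clock nu_dot of upper-level units across a hierarchical trial.

    The global clock concatenates, for every slow step, the lower epoch's
    gradient iterations followed by the upper level's own update block;
    upper units are silent (zero rate of change) while the lower level is
    updating.
    """
    sched = result.schedule
    total = sched.total_iterations
    series = np.zeros((len(units), total))
    upper_vals = _nu_dot_series(result.upper_record, units)
    for t2 in range(result.upper_record.steps_executed):
        start, stop = result.upper_record.step_window(t2)
        g0 = sched.global_offset(t2, within="upper")
        series[:, g0:g0 + (stop - start)] = upper_vals[:, start:stop]
    return series


def global_event_offsets(result: HierarchicalTrialResult):
    """Global iteration index at which each labelled epoch's sensory input
    arrives (the start of its lower-level epoch)."""
    out = {}
    for label, t2 in result.events.items():
        if t2 < len(result.schedule.lower_iters):
            out[label] = result.schedule.global_offset(t2, within="lower")
    return out


def simulate_erp(result, units, lock_event, window=None, condition=""):
    """Event-locked simulated ERP: mean over ``units`` of the rate of change
    of neuronal activity (the nu_dot terms), on the global iteration clock.

    ``lock_event`` is an epoch label (hierarchical results) or a global
    iteration index. ``window`` is the number of ticks from the lock
    (default: to the end of the trial)."""
    if isinstance(result, HierarchicalTrialResult):
        series = upper_nu_dot_timeline(result, units).mean(axis=0)
        events = global_event_offsets(result)
    else:
        series = _nu_dot_series(result, units).mean(axis=0)
        events = result.events
    if isinstance(lock_event, str):
        if lock_event not in events:
            raise KeyError(f"event {lock_event!r} absent from this record")
        lock = events[lock_event]
    else:
        lock = int(lock_event)
    if window is None:
        window = len(series) - lock
    vals = np.zeros(window)
    avail = series[lock:lock + window]
    vals[:len(avail)] = avail
    return ERPWaveform(condition=condition, units=list(units), values=vals,
                       lock=str(lock_event))


# ---------------------------------------------------------------------------
# dopamine and reaction time
# ---------------------------------------------------------------------------

def simulate_dopamine(record: TrialRecord):
    """Concatenated gamma = 1/beta trajectory over all precision-update
    iterations, plus its first difference (the phasic component).

    Returns (gamma, phasic, step_boundaries)."""
    gamma = np.concatenate([np.asarray(g, dtype=float)
                            for g in record.gamma_traj]) if record.gamma_traj \
        else np.zeros(0)
    phasic = np.diff(gamma, prepend=gamma[0]) if len(gamma) else gamma
    bounds, off = [], 0
    for g in record.gamma_traj:
        off += len(g)
        bounds.append(off)
    return gamma, phasic, bounds


def probe_gamma_response(result: HierarchicalTrialResult, probe_event="probe"):
    """Precision (dopamine) response locked to the probe-and-response
    complex (the probe step and the feedback step that follows).

    Returns a dict with
      ``peak_gamma``  — peak level of the gamma signal in the window (the
                        quantity whose attenuation tracks falling dopamine:
                        the whole signal scales with 1/beta);
      ``excursion``   — peak |gamma - pre-probe baseline| (the
                        baseline-subtracted phasic component; this vanishes
                        at very high precision, where posterior and prior
                        policy beliefs coincide);
      ``deflection``  — peak signed gamma elevation above the trial's tonic
                        level 1/beta_prior within the window.
    """
    t2 = result.events[probe_event]
    rec = result.upper_record
    if t2 >= rec.steps_executed:
        raise ValueError("probe step was not executed")
    baseline = rec.gamma_traj[t2 - 1][-1] if t2 > 0 else rec.gamma_traj[0][0]
    tonic = rec.gamma_traj[0][0]
    window = [g for traj in rec.gamma_traj[t2:t2 + 2] for g in traj]
    window = np.asarray(window, dtype=float)
    return dict(
        peak_gamma=float(window.max()),
        excursion=float(np.abs(window - baseline).max()),
        deflection=float(window.max() - tonic),
    )


def phasic_probe_amplitude(result: HierarchicalTrialResult, probe_event="probe"):
    """Baseline-subtracted phasic amplitude at the probe (see
    :func:`probe_gamma_response`)."""
    return probe_gamma_response(result, probe_event)["excursion"]


def reaction_time(result: HierarchicalTrialResult, probe_event="probe",
                  response_event=None):
    """Belief updates executed between probe onset and the report selection.

    Counts every individual update of a log-belief component (iterations
    weighted by the number of units they update, at both levels) — the
    deterministic proxy for the computational time the scheme spends on this
    trial segment. Returns (count, censored): ``censored`` is True when no
    report was emitted (the trial ended before the probe step completed).
    """
    t2 = result.events[probe_event]
    rec = result.upper_record
    if t2 >= rec.steps_executed or len(rec.actions) <= t2 - 1:
        return 0, True
    count = 0
    lower = result.lower_records[t2]
    count += lower.n_iterations * updates_per_iteration(lower)
    start, stop = rec.step_window(t2)
    count += (stop - start) * updates_per_iteration(rec)
    censored = len(rec.actions) < t2 + 1  # no action selected at the probe step
    return int(count), censored
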