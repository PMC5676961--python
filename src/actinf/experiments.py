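"""Scripted drivers for the five simulation studies.

Each driver runs seeded trials of the delay-period retrocue task (or the
orientation model), collects behavioural / electrophysiological summaries
into tidy tables, and derives the headline statistics (RT slope and R^2,
ERP window signs, fixation counts per precision level, belief decay and
stimulus shift per precision cell).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import transition_entropy
from .electrophysiology import (
    probe_gamma_response,
    reaction_time,
    simulate_erp,
)
from .hierarchy import HierarchicalConfig, run_hierarchical_trial
from .inference import InferenceConfig, run_level_trial
from .io_cli import seeded_stream
from .tasks import (
    PAIRS,
    SEQUENCE,
    DelayTaskProcess,
    TaskParams,
    TrialScript,
    build_delay_task,
    build_orientation_task,
    draw_trial_script,
    orientation_process,
    trial_events,
)

__all__ = [
    "ExperimentResult",
    "run_rt_experiment",
    "run_context_erp_experiment",
    "run_load_erp_experiment",
    "run_dopamine_sweep",
    "run_forgetting_grid",
]


@dataclass
class ExperimentResult:
    label: str
    tables: dict = field(default_factory=dict)   # name -> DataFrame
    stats: dict = field(default_factory=dict)
    seed: int = 0
    config: dict = field(default_factory=dict)

    @property
    def config_hash(self):
        payload = json.dumps(self.config, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def save(self, out_dir):
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{self.label}_{name}.csv", index=False)
        summary = dict(label=self.label, seed=self.seed,
                       config=self.config, config_hash=self.config_hash,
                       stats=_jsonable(self.stats))
        (out / f"{self.label}_summary.json").write_text(
            json.dumps(summary, indent=2, default=str))


def _jsonable(d):
    out = {}
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            out[k] = v.tolist()
        elif isinstance(v, (np.floating, np.integer)):
            out[k] = v.item()
        else:
            out[k] = v
    return out


def _default_hconfig(beta=1.0 / 64.0, mode="argmax"):
    """High policy precision, deterministic action selection: the regime of
    the paper's baseline simulations. Fast (saccade) level replans constant
    policies against the executed past; the slow (report) level owns full
    commit-at-step-k action sequences."""
    return HierarchicalConfig(
        lower=InferenceConfig(beta_prior=beta, action_mode=mode,
                              condition_past_on_executed=True),
        upper=InferenceConfig(beta_prior=beta, action_mode=mode,
                              condition_past_on_executed=False),
    )


def _run_trial(params, script, seed, stream, hconfig=None, model=None):
    model = model if model is not None else build_delay_task(params)
    hconfig = hconfig or _default_hconfig()
    proc = DelayTaskProcess(model, params, script,
                            seeded_stream(seed, f"{stream}:process"))
    agent_rng = seeded_stream(seed, f"{stream}:agent")
    return run_hierarchical_trial(model, proc, hconfig,
                                  agent_rng=agent_rng, events=trial_events())


# ---------------------------------------------------------------------------
# reaction times (set-size scaling)
# ---------------------------------------------------------------------------

def run_rt_experiment(n_per_condition=50, set_sizes=(3, 4, 5), seed=0,
                      hconfig=None):
    """Reaction-time scaling with the number of possible scenes.

    Per set size, runs ``n_per_condition`` trials in which the probe is a
    scene outside the remembered pair, measures the belief updating between
    probe onset and report, and fits RT against set size by least squares.
    """
    rows = []
    models = {}
    for n in set_sizes:
        params = TaskParams(n_total_scenes=n)
        models[n] = build_delay_task(params)
        probe = n - 1 if n == 3 else 3  # a scene outside the pair (s3 or s4/s5)
        for rep in range(n_per_condition):
            rng = seeded_stream(seed, f"rt:{n}:{rep}:script")
            script = draw_trial_script(params, rng, pair_idx=0, order=0,
                                       probe=probe)
            res = _run_trial(params, script, seed, f"rt:{n}:{rep}",
                             hconfig=hconfig, model=models[n])
            rt, censored = reaction_time(res)
            rows.append(dict(set_size=n, rep=rep, rt=rt, censored=censored,
                             fixations_probe=res.schedule.lower_steps[
                                 SEQUENCE.index("probe")]))
    df = pd.DataFrame(rows)
    ok = df[~df.censored]
    means = ok.groupby("set_size").rt.mean()
    stats = dict(mean_rt={int(k): float(v) for k, v in means.items()},
                 n_censored=int(df.censored.sum()))
    if len(set_sizes) > 1:
        x = np.array(sorted(means.index), dtype=float)
        y = np.array([means[k] for k in sorted(means.index)])
        slope, intercept = np.polyfit(x, y, 1)
        yhat = slope * x + intercept
        ss_res = float(((y - yhat) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        stats.update(slope=float(slope), intercept=float(intercept),
                     r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
                     monotone=bool(np.all(np.diff(y) > 0)))
    return ExperimentResult(label="rt", tables=dict(trials=df), stats=stats,
                            seed=seed,
                            config=dict(n_per_condition=n_per_condition,
                                        set_sizes=list(set_sizes)))


# ---------------------------------------------------------------------------
# simulated ERPs (context updating; load dependency)
# ---------------------------------------------------------------------------

def _probe_units(model):
    """Upper-level units representing the possible probes (belief about the
    probe identity at the end of the trial)."""
    lvl2 = model.levels[1]
    n = lvl2.state_dims[2]
    return [(2, s, lvl2.T - 1) for s in range(n)]


def _erp_trial(validity, seed, stream, hconfig=None):
    """One matched trial: pair (s1, s2), probe = cued first scene; only the
    believed retrocue validity differs between conditions."""
    params = TaskParams(n_total_scenes=3, retrocue_validity=validity)
    model = build_delay_task(params)
    script = TrialScript(pair_idx=0, order=0, probe=0, cue=0)
    res = _run_trial(params, script, seed, stream, hconfig=hconfig, model=model)
    return model, res


def run_context_erp_experiment(validities=(0.9, 0.5), seed=0, hconfig=None):
    """Context updating: retrocue-locked ERPs from the probe units under an
    informative (valid) versus uninformative retrocue.

    The window runs from retrocue onset to the end of the trial; its early
    half contains the retrocue updating, its late half the probe response.
    The valid-minus-invalid difference changes sign between the two: only a
    valid cue updates the context early, and the updated context spares
    belief updating later at the probe."""
    waves = {}
    rows = []
    for v in validities:
        model, res = _erp_trial(v, seed, f"context:{v}", hconfig)
        erp = simulate_erp(res, _probe_units(model), "retrocue",
                           condition=f"validity={v}")
        waves[v] = erp.values
        for i, val in enumerate(erp.values):
            rows.append(dict(validity=v, tick=i, ms=i * erp.ms_per_tick,
                             nu_dot=val))
    n = min(len(w) for w in waves.values())
    diff = waves[validities[0]][:n] - waves[validities[1]][:n]
    half = n // 2
    early, late = diff[:half], diff[half:]
    stats = dict(early_mean=float(early.mean()), late_mean=float(late.mean()),
                 early_sign=int(np.sign(early.mean())),
                 late_sign=int(np.sign(late.mean())),
                 sign_reversal=bool(np.sign(early.mean())
                                    * np.sign(late.mean()) < 0),
                 early_abs_mean=float(np.abs(early).mean()))
    df = pd.DataFrame(rows)
    dd = pd.DataFrame(dict(tick=np.arange(n), difference=diff))
    return ExperimentResult(label="context_erp",
                            tables=dict(waveforms=df, difference=dd),
                            stats=stats, seed=seed,
                            config=dict(validities=list(validities)))


def run_load_erp_experiment(validities=(0.9, 0.5), seed=0, hconfig=None,
                            threshold_frac=0.05):
    """Load dependency: probe-locked ERPs. An uninformative retrocue leaves
    the full memory load to be searched at probe time, producing a sustained
    difference from the valid condition that begins once the probe evidence
    reaches the higher level."""
    waves = {}
    rows = []
    for v in validities:
        model, res = _erp_trial(v, seed, f"load:{v}", hconfig)
        erp = simulate_erp(res, _probe_units(model), "probe",
                           condition=f"validity={v}")
        waves[v] = erp.values
        for i, val in enumerate(erp.values):
            rows.append(dict(validity=v, tick=i, ms=i * erp.ms_per_tick,
                             nu_dot=val))
    n = min(len(w) for w in waves.values())
    diff = waves[validities[0]][:n] - waves[validities[1]][:n]
    peak = np.abs(diff).max()
    thresh = threshold_frac * peak if peak > 0 else np.inf
    above = np.flatnonzero(np.abs(diff) > thresh)
    onset = int(above[0]) if len(above) else -1
    stats = dict(
        peak_abs_difference=float(peak),
        sustained=bool(len(above) > 0
                       and np.abs(diff[above[0]:]).mean() > 0.5 * thresh),
        onset_tick=onset,
        onset_ms=float(onset * 16.0) if onset >= 0 else float("nan"),
        mean_abs_difference=float(np.abs(diff).mean()),
    )
    df = pd.DataFrame(rows)
    dd = pd.DataFrame(dict(tick=np.arange(n), difference=diff))
    return ExperimentResult(label="load_erp",
                            tables=dict(waveforms=df, difference=dd),
                            stats=stats, seed=seed,
                            config=dict(validities=list(validities)))


# ---------------------------------------------------------------------------
# dopamine / precision sweep
# ---------------------------------------------------------------------------

def run_dopamine_sweep(betas=(1.0 / 64.0, 1.0, 4.0, 16.0), seed=0, n_reps=16):
    """Precision-lesion sweep: the same trials replayed with increasing prior
    inverse precision beta (decreasing dopamine). Action selection samples
    from the policy posterior; the generative-process stream (and the
    agent's sampling stream) are shared across beta rows, so rows differ
    only in beta.

    Reports fixations per scene epoch, saccades to the never-informative
    lower-left quadrant, and the probe-locked phasic precision response.
    """
    params = TaskParams(n_total_scenes=3)
    model = build_delay_task(params)
    scene_steps = [SEQUENCE.index("scene1"), SEQUENCE.index("scene2")]
    ll_quadrant = 2
    rows = []
    for rep in range(n_reps):
        script = draw_trial_script(
            params, seeded_stream(seed, f"da:script:{rep}"),
            pair_idx=0, order=0, probe=0)
        for beta in betas:
            hcfg = _default_hconfig(beta=beta, mode="sample")
            res = _run_trial(params, script, seed, f"da:{rep}",
                             hconfig=hcfg, model=model)
            fix = [res.schedule.lower_steps[t] for t in scene_steps
                   if t < len(res.schedule.lower_steps)]
            ll = sum(1 for t in scene_steps
                     if t < len(res.lower_records)
                     for a in res.lower_records[t].actions
                     if a[1] == ll_quadrant)
            try:
                resp = probe_gamma_response(res)
            except (KeyError, ValueError, IndexError):
                resp = dict(peak_gamma=float("nan"), excursion=float("nan"),
                            deflection=float("nan"))
            rows.append(dict(beta=beta, rep=rep,
                             fixations_per_scene=float(np.mean(fix)),
                             lower_left_saccades=int(ll),
                             probe_peak_gamma=resp["peak_gamma"],
                             phasic_excursion=resp["excursion"]))
    df = pd.DataFrame(rows)
    g = df.groupby("beta")
    mean_fix = g.fixations_per_scene.mean()
    mean_ll = g.lower_left_saccades.mean()
    mean_peak = g.probe_peak_gamma.mean()
    mean_exc = g.phasic_excursion.mean()
    betas_sorted = sorted(betas)
    stats = dict(
        betas=list(betas_sorted),
        mean_fixations=[float(mean_fix[b]) for b in betas_sorted],
        mean_lower_left=[float(mean_ll[b]) for b in betas_sorted],
        mean_probe_peak_gamma=[float(mean_peak[b]) for b in betas_sorted],
        mean_phasic_excursion=[float(mean_exc[b]) for b in betas_sorted],
        probe_signal_decreasing_in_beta=bool(
            np.all(np.diff([mean_peak[b] for b in betas_sorted]) < 0)),
        fixations_nondecreasing=bool(
            np.all(np.diff([mean_fix[b] for b in betas_sorted]) >= -1e-12)),
        lowest_beta_fixations=float(mean_fix[betas_sorted[0]]),
        lowest_beta_lower_left=float(mean_ll[betas_sorted[0]]),
        highest_beta_lower_left=float(mean_ll[betas_sorted[-1]]),
    )
    return ExperimentResult(label="dopamine", tables=dict(trials=df),
                            stats=stats, seed=seed,
                            config=dict(betas=list(betas), n_reps=n_reps))


# ---------------------------------------------------------------------------
# volatility / forgetting grid
# ---------------------------------------------------------------------------

def _orientation_trial(a_precision, b_precision, seed, stream,
                       present_stimulus=True, n_iter=16):
    level, sched = build_orientation_task(a_precision=a_precision,
                                          b_precision=b_precision)
    proc = orientation_process(level, sched,
                               seeded_stream(seed, f"{stream}:process"),
                               present_stimulus=present_stimulus)
    cfg = InferenceConfig(n_iter=n_iter, update_precision=False)
    rec = run_level_trial(level, proc, cfg)
    # filtering trajectory: belief about the current orientation at each step
    traj = np.stack([rec.bma_step[t][0][t] for t in range(rec.steps_executed)])
    return level, sched, rec, traj


def run_forgetting_grid(a_precisions=(2.0, 0.05), b_precisions=(8.0, 0.5),
                        seed=0, b_sweep=(16.0, 4.0, 1.0, 0.25)):
    """Volatility and observation noise in working memory maintenance.

    2x2 grid over likelihood (A) and transition (B) precision: per cell, the
    pre-stimulus decay of the maintained orientation belief and the shift of
    belief toward the stimulus orientation while it is presented. Also runs
    a B-precision sweep relating decay to transition-column entropy.
    """
    rows = []
    for ap in a_precisions:
        for bp in b_precisions:
            level, sched, rec, traj = _orientation_trial(ap, bp, seed,
                                                         f"forget:{ap}:{bp}")
            t_pre = min(sched["stim_steps"]) - 1
            decay = float(traj[0].max() - traj[t_pre].max())
            stim_bin = sched["stim_bin"]
            t_on = max(s for s in sched["stim_steps"] if s < traj.shape[0])
            shift = float(traj[t_on][stim_bin] - traj[t_pre][stim_bin])
            b_entropy = transition_entropy(level.B[0][:, stim_bin, 0])
            rows.append(dict(a_precision=ap, b_precision=bp,
                             b_column_entropy=b_entropy,
                             decay=decay, stimulus_shift=shift))
    df = pd.DataFrame(rows)

    sweep_rows = []
    for bp in b_sweep:
        level, sched, rec, traj = _orientation_trial(
            a_precisions[0], bp, seed, f"forget:sweep:{bp}",
            present_stimulus=False)
        t_pre = min(sched["stim_steps"]) - 1
        sweep_rows.append(dict(
            b_precision=bp,
            b_column_entropy=transition_entropy(level.B[0][:, 0, 0]),
            decay=float(traj[0].max() - traj[t_pre].max())))
    sweep = pd.DataFrame(sweep_rows).sort_values("b_column_entropy")

    hi_a, lo_a = max(a_precisions), min(a_precisions)
    hi_b, lo_b = max(b_precisions), min(b_precisions)
    pick = lambda ap, bp, col: float(
        df[(df.a_precision == ap) & (df.b_precision == bp)][col].iloc[0])
    stats = dict(
        decay_precise_B=pick(hi_a, hi_b, "decay"),
        decay_volatile_B=pick(hi_a, lo_b, "decay"),
        shift_precise_A=pick(hi_a, hi_b, "stimulus_shift"),
        shift_imprecise_A=pick(lo_a, hi_b, "stimulus_shift"),
        decay_monotone_in_entropy=bool(
            np.all(np.diff(sweep.decay.values) >= -1e-12)),
    )
    return ExperimentResult(label="forgetting",
                            tables=dict(grid=df, b_sweep=sweep),
                            stats=stats, seed=seed,
                            config=dict(a_precisions=list(a_precisions),
                                        b_precisions=list(b_precisions)))
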