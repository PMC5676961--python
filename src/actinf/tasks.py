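"""Concrete generative models: the two-level delay-period retrocue task and
the single-level orientation/volatility model.

Delay-period task
-----------------
A trial runs through seven slow (second-level) epochs: delay, two scenes,
a retrocue, another delay, the probe, and feedback. Each scene is a 2x2
arrangement of quadrants holding two images (bird / cat / seeds); the agent
foveates quadrants to work out which scene is displayed, must remember the
two scenes shown at the start, and finally reports whether the probe scene
was one of them. The retrocue indicates which of the two remembered scenes
is the more likely probe (validity 0.9 by default) while carrying no
information about whether the probe is in the remembered set at all.

Level 1 (fast): hidden states = displayed scene x fixation location; the
agent controls fixation through its B-matrix; outcomes are the image at the
foveated quadrant plus proprioceptive eye position. Level 2 (slow): hidden
states = scene pair, presentation order, probe identity, sequence position
(a deterministic counter) and the agent's report; outcomes are the scene
shown to level 1 (via the hierarchical link) and feedback, with preferences
favouring being correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import (
    GenerativeLevel,
    HierarchicalModel,
    Policy,
    constant_policies,
    make_banded_kernel,
    normalise,
)
from .inference import MDPProcess

__all__ = [
    "IMAGES", "QUADRANTS", "PAIRS", "SEQUENCE",
    "SceneSpec", "TaskParams", "TrialScript",
    "default_scenes", "validate_scenes", "build_delay_task",
    "draw_trial_script", "DelayTaskProcess", "trial_events", "monty_hall_marginal",
    "build_orientation_task", "orientation_process",
]

IMAGES = ["blank", "bird", "cat", "seeds", "cue1", "cue2"]
QUADRANTS = ["TL", "TR", "LL", "LR"]
PAIRS = [(0, 1), (0, 2), (1, 2)]  # scene-index pairs the trial can open with
SEQUENCE = ["delay", "scene1", "scene2", "retrocue", "delay2", "probe", "feedback"]

# Scene layouts. Verbal constraints honoured: every test scene places two
# images in two quadrants; among the first three scenes one is diagonal and
# two horizontal; the lower-left quadrant is blank (hence never informative)
# in every scene; the top-right quadrant distinguishes all of the first three
# scenes, and the lower-right identifies a scene only when seeds are there.
# Extra scenes (set sizes 4 and 5) reuse the same grammar and collide with
# the core scenes quadrant by quadrant, so larger hypothesis sets need more
# fixations to disambiguate.
_DEFAULT_LAYOUTS = [
    {"TL": "bird", "TR": "seeds"},            # scene 1 (horizontal)
    {"TL": "bird", "TR": "cat"},              # scene 2 (horizontal)
    {"TL": "cat", "LR": "seeds"},             # scene 3 (diagonal)
    {"TL": "cat", "TR": "seeds"},             # scene 4 (horizontal)
    {"TL": "cat", "LR": "bird"},              # scene 5 (diagonal)
]


@dataclass
class SceneSpec:
    """Quadrant -> image mapping per scene; omitted quadrants are blank."""

    scenes: list  # list of dict quadrant-name -> image-name

    def image_at(self, scene, quadrant):
        return self.scenes[scene].get(QUADRANTS[quadrant], "blank")


def default_scenes(n_total_scenes=3):
    if not 3 <= n_total_scenes <= 5:
        raise ValueError("the task supports 3, 4 or 5 possible scenes")
    return SceneSpec(scenes=[dict(s) for s in _DEFAULT_LAYOUTS[:n_total_scenes]])


def validate_scenes(spec: SceneSpec):
    """Check the scene-grammar invariants; returns a list of violations."""
    v = []
    for i, s in enumerate(spec.scenes):
        imgs = [im for im in s.values() if im != "blank"]
        if len(imgs) != 2:
            v.append(f"scene {i}: needs exactly two non-blank quadrants")
        for q, im in s.items():
            if q not in QUADRANTS or im not in IMAGES[:4]:
                v.append(f"scene {i}: unknown quadrant/image {q}={im}")
    def _orient(s):
        qs = sorted(q for q, im in s.items() if im != "blank")
        if qs in (["TL", "TR"], ["LL", "LR"]):
            return "horizontal"
        if qs in (["LR", "TL"], ["LL", "TR"]):
            return "diagonal"
        return "vertical"
    orients = [_orient(s) for s in spec.scenes[:3]]
    if orients.count("diagonal") != 1 or orients.count("horizontal") != 2:
        v.append("first three scenes: expected one diagonal and two horizontal")
    lls = {s.get("LL", "blank") for s in spec.scenes}
    if len(lls) != 1:
        v.append("lower-left quadrant must be identical across all scenes")
    return v


@dataclass
class TaskParams:
    retrocue_validity: float = 0.9      # the agent's believed cue validity
    n_total_scenes: int = 3
    steps_per_epoch: int = 4            # fixation budget per scene epoch
    feedback_correct: float = 3.0       # log-preference (nats)
    feedback_incorrect: float = -6.0
    sequence: tuple = tuple(SEQUENCE)

    def validate(self):
        if not 0.5 <= self.retrocue_validity <= 1.0:
            raise ValueError("retrocue_validity must lie in [0.5, 1]")
        if self.n_total_scenes not in (3, 4, 5):
            raise ValueError("n_total_scenes must be 3, 4 or 5")
        if self.steps_per_epoch < 2:
            raise ValueError("steps_per_epoch must allow at least one saccade")


# ---------------------------------------------------------------------------
# level builders
# ---------------------------------------------------------------------------

def _scene_values(n):
    """Level-1 scene-state labels: test scenes, blank display, two cues."""
    return [f"s{i+1}" for i in range(n)] + ["blank", "cue1", "cue2"]


def _build_level1(params: TaskParams, scenes: SceneSpec):
    n = params.n_total_scenes
    vals = _scene_values(n)
    nsv = len(vals)
    n_img, n_q = len(IMAGES), len(QUADRANTS)

    A_vis = np.zeros((n_img, nsv, n_q))
    for sv in range(nsv):
        for q in range(n_q):
            if sv < n:
                img = scenes.image_at(sv, q)
            elif sv == n:
                img = "blank"
            else:
                img = "cue1" if sv == n + 1 else "cue2"
            A_vis[IMAGES.index(img), sv, q] = 1.0
    A_prop = np.zeros((n_q, nsv, n_q))
    for q in range(n_q):
        A_prop[q, :, q] = 1.0

    B_scene = np.eye(nsv)[:, :, None]
    B_fix = np.zeros((n_q, n_q, n_q))
    for u in range(n_q):
        B_fix[u, :, u] = 1.0  # a saccade lands where it is aimed

    level = GenerativeLevel(
        A=[A_vis, A_prop],
        B=[B_scene, B_fix],
        C=[np.zeros(n_img), np.zeros(n_q)],
        D=[np.full(nsv, 1.0 / nsv), _delta(n_q, QUADRANTS.index("LL"))],
        policies=constant_policies(n_q, controllable_factor=1, n_factors=2),
        T=params.steps_per_epoch,
        state_labels=[vals, QUADRANTS],
        outcome_labels=[IMAGES, QUADRANTS],
        action_labels=[["none"], QUADRANTS],
        name="level1",
    )
    return level


def _delta(n, i):
    d = np.zeros(n)
    d[i] = 1.0
    return d


def _ordered_pair(pair_idx, order):
    a, b = PAIRS[pair_idx]
    return (a, b) if order == 0 else (b, a)


def _report_policies(nseq):
    """Slow-level policy set: withhold throughout, or commit to a report
    ("same"/"different") from step k onward and hold it. Policies own their
    whole action sequence, so a policy that would already have responded is
    ruled out by the feedback it failed to predict — the evidence stream that
    drives precision (dopamine) dynamics."""
    n_trans = nseq - 1
    pols = [Policy(actions=tuple((0, 0, 0, 0, 0) for _ in range(n_trans)))]
    for u in (1, 2):  # same, different
        for k in range(n_trans):
            acts = tuple((0, 0, 0, 0, u if t >= k else 0)
                         for t in range(n_trans))
            pols.append(Policy(actions=acts))
    return pols


def _build_level2(params: TaskParams):
    n = params.n_total_scenes
    vals = _scene_values(n)
    nsv = len(vals)
    dims = (len(PAIRS), 2, n, len(SEQUENCE), 3)  # pair, order, probe, seq, report
    v = params.retrocue_validity

    A_scene = np.zeros((nsv,) + dims)
    A_fb = np.zeros((3,) + dims)  # none, correct, incorrect
    for pi in range(dims[0]):
        for o in range(2):
            first, second = _ordered_pair(pi, o)
            for pr in range(n):
                for seq in range(len(SEQUENCE)):
                    label = SEQUENCE[seq]
                    if label == "scene1":
                        disp = {first: 1.0}
                    elif label == "scene2":
                        disp = {second: 1.0}
                    elif label == "retrocue":
                        if pr == first:
                            p1 = v
                        elif pr == second:
                            p1 = 1.0 - v
                        else:
                            p1 = 0.5
                        disp = {n + 1: p1, n + 2: 1.0 - p1}
                    elif label == "probe":
                        disp = {pr: 1.0}
                    else:
                        disp = {n: 1.0}  # blank display
                    for r in range(3):
                        for val, p in disp.items():
                            A_scene[val, pi, o, pr, seq, r] = p
                        if label == "feedback":
                            if r == 0:
                                fb = 0
                            elif (r == 1) == (pr in PAIRS[pi]):
                                fb = 1
                            else:
                                fb = 2
                        else:
                            fb = 0 if r == 0 else 2  # premature responses are wrong
                        A_fb[fb, pi, o, pr, seq, r] = 1.0

    B_pair = np.eye(dims[0])[:, :, None]
    B_order = np.eye(2)[:, :, None]
    B_probe = np.eye(n)[:, :, None]
    nseq = len(SEQUENCE)
    B_seq = np.zeros((nseq, nseq, 1))
    for s in range(nseq):
        B_seq[min(s + 1, nseq - 1), s, 0] = 1.0  # deterministic increment
    B_rep = np.zeros((3, 3, 3))
    for u in range(3):
        B_rep[u, :, u] = 1.0

    C_fb = np.array([0.0, params.feedback_correct, params.feedback_incorrect])
    level = GenerativeLevel(
        A=[A_scene, A_fb],
        B=[B_pair, B_order, B_probe, B_seq, B_rep],
        C=[np.zeros(nsv), C_fb],
        D=[np.full(dims[0], 1 / dims[0]), np.full(2, 0.5), np.full(n, 1.0 / n),
           _delta(nseq, 0), _delta(3, 0)],
        policies=_report_policies(nseq),
        T=nseq,
        state_labels=[[f"pair{a+1}{b+1}" for a, b in PAIRS], ["order12", "order21"],
                      vals[:n], list(SEQUENCE), ["withhold", "same", "different"]],
        outcome_labels=[vals, ["none", "correct", "incorrect"]],
        action_labels=[["none"]] * 4 + [["withhold", "same", "different"]],
        name="level2",
    )
    return level


def build_delay_task(params: TaskParams = None, scenes: SceneSpec = None):
    """Construct the full two-level delay-period retrocue model."""
    params = params or TaskParams()
    params.validate()
    scenes = scenes or default_scenes(params.n_total_scenes)
    if len(scenes.scenes) != params.n_total_scenes:
        raise ValueError(
            f"{len(scenes.scenes)} scene layouts for "
            f"n_total_scenes={params.n_total_scenes}")
    bad = validate_scenes(scenes)
    if bad:
        raise ValueError("; ".join(bad))
    lvl1 = _build_level1(params, scenes)
    lvl2 = _build_level2(params)
    link_init = lvl2.A_flat(0).copy()  # P(scene shown | slow states)
    link_policy = np.full((len(lvl1.policies), lvl2.n_joint),
                          1.0 / len(lvl1.policies))
    return HierarchicalModel(
        levels=[lvl1, lvl2],
        link_init=[link_init],
        link_policy=[link_policy],
        steps_per_epoch=params.steps_per_epoch,
        linked_factor=0,
    )


# ---------------------------------------------------------------------------
# the generative process (the true world)
# ---------------------------------------------------------------------------

@dataclass
class TrialScript:
    """The realised hidden course of one trial: which pair was shown in which
    order, the probe identity, and the cue that was actually displayed."""

    pair_idx: int
    order: int
    probe: int
    cue: int  # 0 -> cue1, 1 -> cue2


def draw_trial_script(params: TaskParams, rng, pair_idx=None, order=None,
                      probe=None, process_validity=None):
    """Sample (or fix) the trial realisation. The cue is drawn with the
    process validity: if the probe is in the pair, the cue points at its
    serial position with probability ``validity``; otherwise it is fair."""
    v = params.retrocue_validity if process_validity is None else process_validity
    if pair_idx is None:
        pair_idx = int(rng.integers(len(PAIRS)))
    if order is None:
        order = int(rng.integers(2))
    if probe is None:
        probe = int(rng.integers(params.n_total_scenes))
    first, second = _ordered_pair(pair_idx, order)
    if probe == first:
        p_cue1 = v
    elif probe == second:
        p_cue1 = 1.0 - v
    else:
        p_cue1 = 0.5
    cue = 0 if rng.random() < p_cue1 else 1
    return TrialScript(pair_idx=pair_idx, order=order, probe=probe, cue=cue)


class DelayTaskProcess:
    """Bundles the slow-level generative process with the factory that spawns
    the fast-level process for each epoch. All trial randomness lives in the
    TrialScript, so reruns with different agents see the same world."""

    def __init__(self, model: HierarchicalModel, params: TaskParams,
                 script: TrialScript, rng):
        self.model = model
        self.params = params
        self.script = script
        lvl2 = model.levels[1]
        # scripted display: the cue epoch shows exactly the scripted cue
        A_scene = lvl2.A[0].copy()
        n = params.n_total_scenes
        cue_seq = SEQUENCE.index("retrocue")
        A_scene[:, :, :, :, cue_seq, :] = 0.0
        A_scene[n + 1 + script.cue, :, :, :, cue_seq, :] = 1.0
        self._A_scene_proc = A_scene
        self.upper = MDPProcess(
            A=[A_scene, lvl2.A[1]], B=lvl2.B,
            init_states=[script.pair_idx, script.order, script.probe, 0, 0],
            rng=rng)

    def displayed_scene(self, upper_states):
        j = np.ravel_multi_index(tuple(upper_states),
                                 self.model.levels[1].state_dims)
        col = self._A_scene_proc.reshape(self._A_scene_proc.shape[0], -1)[:, j]
        return int(np.argmax(col))

    def lower_factory(self, upper_t, upper_states):
        lvl1 = self.model.levels[0]
        disp = self.displayed_scene(upper_states)
        return MDPProcess(
            A=lvl1.A, B=lvl1.B,
            init_states=[disp, QUADRANTS.index("LL")],
            rng=self.upper.rng)


def trial_events():
    """Upper-step indices of the loggable epochs."""
    return {label: i for i, label in enumerate(SEQUENCE)}


def monty_hall_marginal(model: HierarchicalModel, pair_belief):
    """Probability that the probe lies in the remembered pair, under the
    model's probe prior: sum_pair Q(pair) sum_{probe in pair} P(probe).

    With three possible scenes and a uniform probe prior this is 2/3 for any
    pair belief — the Monty Hall structure of the task."""
    lvl2 = model.levels[1]
    probe_prior = lvl2.D[2]
    pair_belief = np.asarray(pair_belief, dtype=float)
    if pair_belief.shape[0] != len(PAIRS):
        raise ValueError("pair belief must have one entry per pair")
    total = 0.0
    for pi, pair in enumerate(PAIRS):
        total += pair_belief[pi] * sum(probe_prior[m] for m in pair)
    return float(total)


# ---------------------------------------------------------------------------
# orientation / volatility model
# ---------------------------------------------------------------------------

def build_orientation_task(n_bins=20, a_precision=2.0, b_precision=8.0,
                           T=10, stim_steps=(3, 4), stim_bin=None,
                           init_bin=None, circular=True, init_precision=2.0):
    """Single-level model of a remembered bar orientation.

    Hidden states: orientation (``n_bins`` bins over the circle; transition
    kernel banded at ``b_precision`` — its column entropy is the believed
    volatility) and stimulus visibility. Outcomes: the observed orientation
    (likelihood banded at ``a_precision`` when visible — sensory
    signal-to-noise) or nothing when invisible. The initial prior peaks near
    pi radians; the stimulus process presents a bar near pi/2 radians during
    ``stim_steps``.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    stim_bin = n_bins // 4 if stim_bin is None else stim_bin       # ~ pi/2
    init_bin = n_bins // 2 if init_bin is None else init_bin       # ~ pi
    B_orient = make_banded_kernel(n_bins, b_precision, circular=circular)[:, :, None]
    B_vis = np.full((2, 2, 1), 0.5)  # the stimulus may (dis)appear at any time

    A = np.zeros((n_bins + 1, n_bins, 2))
    A[:n_bins, :, 1] = make_banded_kernel(n_bins, a_precision, circular=circular)
    A[n_bins, :, 0] = 1.0  # invisible -> "nothing seen"

    D_orient = make_banded_kernel(n_bins, init_precision, circular=circular)[:, init_bin]
    level = GenerativeLevel(
        A=[A],
        B=[B_orient, B_vis],
        C=[np.zeros(n_bins + 1)],
        D=[normalise(D_orient, axis=0), np.full(2, 0.5)],
        policies=[Policy(actions=((0, 0),))],
        T=T,
        state_labels=[[f"bin{i}" for i in range(n_bins)], ["invisible", "visible"]],
        outcome_labels=[[f"obs{i}" for i in range(n_bins)] + ["none"]],
        name="orientation",
    )
    sched = dict(stim_steps=tuple(stim_steps), stim_bin=stim_bin,
                 init_bin=init_bin, n_bins=n_bins)
    return level, sched


def orientation_process(level, sched, rng, T=None, present_stimulus=True,
                        deterministic_obs=True):
    """Generative process for the orientation trial: the bar is visible (at
    ``stim_bin``) during the scheduled steps, absent otherwise."""
    T = T if T is not None else level.T
    n_bins = sched["n_bins"]
    states, outs = [], []
    for t in range(T):
        vis = 1 if (present_stimulus and t in sched["stim_steps"]) else 0
        states.append((sched["stim_bin"], vis))
        if deterministic_obs:
            outs.append([sched["stim_bin"] if vis else n_bins])
        else:
            outs.append(None)
    return MDPProcess(A=level.A, B=level.B, init_states=states[0], rng=rng,
                      scripted_states=states, scripted_outcomes=outs)
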