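"""Synthetic multi-subject, multi-run cohort generator.

Emulates the structure of a resting-state epilepsy cohort at desk scale:
a group-level parcellation of K networks planted on a two-hemisphere vertex
graph; per-subject parcellations that deviate from the group at network
boundaries; hemispherically asymmetric language networks planted per
dominance group (left / bilateral / right); network-structured vertex and
ROI time series whose top-fraction binarized correlation profiles recover
the planted labels; and alternating stimulation/rest block runs.

Every quantity is reproducible from (config, seed); seeds are split with
``numpy.random.SeedSequence`` so each subject/run draws from an independent
stream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .graph import HEMI_L, HEMI_R, CorticalGraph
from .hrf import stim_regressor
from .vmf import sample_vmf  # noqa: F401  (re-exported: part of this module's surface)

def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


#: planted laterality-index moments per task-dominance group (mean, SD)
DOMINANCE_LI_PARAMS = {
    "left": (0.165, 0.106),
    "bilateral": (0.056, 0.074),
    "right": (0.023, 0.055),
}

#: default per-group counts for a 43-participant dominance-labeled cohort
DEFAULT_DOMINANCE_DESIGN = {"left": 15, "bilateral": 14, "right": 14}


@dataclass
class RunTimeSeries:
    subject_id: int
    session_id: int
    vertex_ts: np.ndarray    # (T, V)
    roi_ts: np.ndarray       # (T, R)
    tr_seconds: float = 2.0

    def __post_init__(self):
        self.vertex_ts = np.asarray(self.vertex_ts, dtype=float)
        self.roi_ts = np.asarray(self.roi_ts, dtype=float)
        if not (np.all(np.isfinite(self.vertex_ts)) and np.all(np.isfinite(self.roi_ts))):
            raise ValueError("time series must be finite")
        if self.vertex_ts.shape[0] != self.roi_ts.shape[0]:
            raise ValueError("vertex and ROI series must share T")
        if self.vertex_ts.shape[0] < 20:
            raise ValueError("runs must have at least 20 frames")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_frames(self) -> int:
        return self.vertex_ts.shape[0]


@dataclass
class StimulationDesign:
    block_onsets: np.ndarray      # frame indices
    block_durations: np.ndarray   # frame counts
    block_kinds: list             # per-block "stim" or "rest", alternating
    discard_frames: int = 4

    def __post_init__(self):
        self.block_onsets = np.asarray(self.block_onsets, dtype=int)
        self.block_durations = np.asarray(self.block_durations, dtype=int)
        n = len(self.block_onsets)
        if not (len(self.block_durations) == len(self.block_kinds) == n):
            raise ValueError("onsets, durations, kinds must align")
        ends = self.block_onsets + self.block_durations
        if np.any(self.block_onsets[1:] < ends[:-1]):
            raise ValueError("blocks must be ordered and non-overlapping")
        for a, b in zip(self.block_kinds, self.block_kinds[1:]):
            if a == b:
                raise ValueError("block kinds must alternate")
        if any(k not in ("stim", "rest") for k in self.block_kinds):
            raise ValueError("block kinds must be 'stim' or 'rest'")

    @property
    def n_frames(self) -> int:
        return int(self.block_onsets[-1] + self.block_durations[-1])


def make_alternating_design(n_blocks: int, frames_per_block: int = 15,
                            first: str = "rest", discard_frames: int = 4) -> StimulationDesign:
    """Alternating ~30 s stimulation/rest blocks (15 frames at TR = 2 s)."""
    kinds = [first if i % 2 == 0 else ("stim" if first == "rest" else "rest")
             for i in range(n_blocks)]
    onsets = np.arange(n_blocks) * frames_per_block
    durations = np.full(n_blocks, frames_per_block)
    return StimulationDesign(onsets, durations, kinds, discard_frames)


@dataclass
class CohortTruth:
    """Ground truth of a synthetic cohort: planted parcellations and LIs."""

    graph: CorticalGraph
    K: int
    R: int
    group_labels: np.ndarray                 # (V,) 0..K, 0 = masked
    mu_true: np.ndarray                      # (K, R) unit rows
    roi_parents: np.ndarray                  # (R,) parent network (1..K)
    language_ids: tuple                      # two labels: Language A, Language/Default B
    subject_labels: list = field(default_factory=list)   # per-subject (V,) arrays
    subject_mu: list = field(default_factory=list)       # per-subject (K, R)
    subject_leak_rho: list = field(default_factory=list)     # per-subject (K,)
    subject_leak_partner: list = field(default_factory=list)  # per-subject (K,)
    dominance: list = field(default_factory=list)        # per-subject group
    target_li: list = field(default_factory=list)        # planted LI draws
    achieved_li: list = field(default_factory=list)      # LI realized in labels
    li_flagged: list = field(default_factory=list)       # True if target unreachable
    generator_params: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_labels)


# --------------------------------------------------------------------------
# group truth

def sample_group_truth(graph: CorticalGraph, K: int, R: int,
                       min_angle: float = np.pi / 4, seed=0) -> CohortTruth:
    """Plant a group parcellation: K contiguous patches per hemisphere grown
    from random seeds, plus K orthogonal mean connectivity directions.

    The mean direction of network k is the unit-normalized indicator of the
    ROIs parented to k (round-robin assignment), which is exactly the
    direction its binarized connectivity profiles concentrate around under
    the shared-latent-signal time-series model below.  The directions are
    pairwise orthogonal, so any separation requirement up to pi/2 holds by
    construction; beyond that (or with K > R) no valid set exists.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if R < K:
        raise ValueError("need at least one ROI per network (R >= K)")
    if min_angle > np.pi / 2 + 1e-12:
        raise ValueError(
            f"min_angle {min_angle:.3f} infeasible for (K={K}, R={R}): "
            "pairwise separation beyond pi/2 is unattainable for K mutually "
            "separated directions here")
    rng = np.random.default_rng(seed)

    roi_parents = (np.arange(R) % K) + 1
    mu_true = np.zeros((K, R))
    for k in range(1, K + 1):
        members = roi_parents == k
        mu_true[k - 1, members] = 1.0 / np.sqrt(members.sum())

    labels = np.zeros(graph.n_vertices, dtype=np.int64)
    for hemi in (HEMI_L, HEMI_R):
        verts = graph.hemisphere_vertices(hemi)
        verts = verts[graph.cortex_mask[verts]]
        if len(verts) < 2 * K:
            raise ValueError("each hemisphere needs at least 2K analyzable vertices")
        seeds = rng.choice(verts, size=K, replace=False)
        labels[seeds] = np.arange(1, K + 1)
        frontier = list(seeds)
        vset = set(int(v) for v in verts)
        while frontier:
            i = int(rng.integers(len(frontier)))
            v = frontier.pop(i)
            for w in graph.neighbors(v):
                w = int(w)
                if w in vset and labels[w] == 0:
                    labels[w] = labels[v]
                    frontier.append(w)
    labels[~graph.cortex_mask] = 0

    return CohortTruth(
        graph=graph, K=K, R=R, group_labels=labels, mu_true=mu_true,
        roi_parents=roi_parents, language_ids=(1, 2),
        generator_params={"K": K, "R": R, "min_angle": float(min_angle),
                          "group_seed": seed if isinstance(seed, int) else str(seed)},
    )


# --------------------------------------------------------------------------
# subject labels with planted laterality

def _li_counts(labels: np.ndarray, graph: CorticalGraph, language_ids) -> tuple[int, int]:
    lang = np.isin(labels, list(language_ids))
    lh = int(np.sum(lang & (graph.hemisphere == HEMI_L)))
    rh = int(np.sum(lang & (graph.hemisphere == HEMI_R)))
    return lh, rh


def _li_value(lh: int, rh: int) -> float:
    return (lh - rh) / (lh + rh) if lh + rh else np.nan


def perturb_boundary_labels(graph: CorticalGraph, labels: np.ndarray,
                            deviation_rate: float, rng) -> np.ndarray:
    """Reassign boundary vertices to a neighboring network with probability
    ``deviation_rate`` — the individual-deviation model."""
    if not 0 <= deviation_rate < 0.5:
        raise ValueError("deviation_rate must lie in [0, 0.5)")
    out = labels.copy()
    if deviation_rate == 0:
        return out
    # boundary set computed on the group labels, flips applied simultaneously
    for v in range(graph.n_vertices):
        if labels[v] == 0:
            continue
        neigh = graph.neighbors(v)
        neigh = neigh[labels[neigh] != 0]
        other = neigh[labels[neigh] != labels[v]]
        if len(other) and rng.random() < deviation_rate:
            out[v] = labels[int(rng.choice(other))]
    return out


def _transfer_candidates(graph, labels, language_ids, hemi, direction, rng,
                         frozen_ids=()):
    """Vertices eligible to gain ('add') or shed ('remove') a language label
    in hemisphere ``hemi``; boundary-adjacent first to keep patches coherent.
    Vertices carrying a label in ``frozen_ids`` are never converted, and
    frozen labels are never used as recipients."""
    lang = list(language_ids)
    frozen = list(frozen_ids)
    in_hemi = graph.hemisphere == hemi
    is_lang = np.isin(labels, lang)
    is_frozen = np.isin(labels, frozen)
    if direction == "add":
        pool = np.flatnonzero(in_hemi & ~is_lang & ~is_frozen
                              & (labels != 0) & graph.cortex_mask)
    else:
        pool = np.flatnonzero(in_hemi & is_lang & graph.cortex_mask)
    boundary, interior = [], []
    for v in pool:
        neigh = graph.neighbors(v)
        nl = labels[neigh]
        if direction == "add":
            targets = nl[np.isin(nl, lang)]
        else:
            targets = nl[(~np.isin(nl, lang)) & (~np.isin(nl, frozen)) & (nl != 0)]
        (boundary if len(targets) else interior).append((int(v), targets))
    return boundary if boundary else interior


def _apply_transfer(graph, labels, language_ids, hemi, direction, rng,
                    frozen_ids=()) -> bool:
    cands = _transfer_candidates(graph, labels, language_ids, hemi, direction,
                                 rng, frozen_ids)
    if not cands:
        return False
    v, targets = cands[int(rng.integers(len(cands)))]
    if len(targets):
        labels[v] = int(rng.choice(targets))
    elif direction == "add":
        labels[v] = int(rng.choice(list(language_ids)))
    else:
        # donor = most common eligible non-language network in this hemisphere
        in_hemi = graph.hemisphere == hemi
        eligible = (in_hemi & ~np.isin(labels, list(language_ids))
                    & ~np.isin(labels, list(frozen_ids)) & (labels != 0))
        nonlang = labels[eligible]
        if not len(nonlang):
            return False
        labels[v] = int(np.bincount(nonlang).argmax())
    return True


def plant_laterality(graph: CorticalGraph, labels: np.ndarray, language_ids,
                     target_li: float, tol: float = 0.02, rng=None,
                     frozen_ids=()) -> tuple[np.ndarray, float, bool]:
    """Transfer vertices between the language networks and donor networks,
    one per step and per hemisphere, until no move brings the realized LI
    closer to ``target_li``.  Stopping only once within ``tol`` would leave a
    one-sided bias of up to ``tol`` toward the starting LI, so we always run
    to the closest reachable value and flag subjects that end outside ``tol``."""
    rng = np.random.default_rng(rng)
    labels = labels.copy()
    for _ in range(4 * graph.n_vertices):
        lh, rh = _li_counts(labels, graph, language_ids)
        li = _li_value(lh, rh)
        if not np.isfinite(li):
            return labels, li, True
        err = li - target_li
        # a single transfer changes LI by ~2/(lh+rh); closer than one step
        # means this is the closest reachable point
        if abs(err) < 1.0 / (lh + rh):
            return labels, li, abs(err) > tol
        if err < 0:   # need higher LI: grow language in LH or shrink in RH
            moves = [(HEMI_L, "add"), (HEMI_R, "remove")]
        else:
            moves = [(HEMI_R, "add"), (HEMI_L, "remove")]
        rng.shuffle(moves)
        moved = False
        for hemi, direction in moves:
            trial = labels.copy()
            if _apply_transfer(graph, trial, language_ids, hemi, direction,
                               rng, frozen_ids):
                nlh, nrh = _li_counts(trial, graph, language_ids)
                if abs(_li_value(nlh, nrh) - target_li) < abs(err):
                    labels = trial
                    moved = True
                    break
        if not moved:
            lh, rh = _li_counts(labels, graph, language_ids)
            li = _li_value(lh, rh)
            return labels, li, abs(li - target_li) > tol
    lh, rh = _li_counts(labels, graph, language_ids)
    li = _li_value(lh, rh)
    return labels, li, abs(li - target_li) > tol


def sample_subject_labels(truth: CohortTruth, dominance: list,
                          deviation_rate: float = 0.1,
                          li_params: dict | None = None,
                          li_tol: float = 0.02,
                          subject_mu_kappa: float = 500.0,
                          leakage=None,
                          seed=0) -> CohortTruth:
    """Draw per-subject parcellations: boundary deviations from the group
    labels plus language-network vertex transfers until each subject's LI
    matches a truncated-normal draw from its dominance group's moments.

    ``li_params`` maps dominance group to (mean, SD); None disables the
    asymmetry planting entirely.

    ``leakage`` (optional, K per-network scales in [0, 1)) plants
    inter-subject functional-connectivity variability: each subject draws a
    mixing weight rho_{s,k} <= leakage[k] toward a random partner network's
    latent signal, so networks with larger leakage show more variable
    connectivity directions across subjects (used by the
    variability-recovery experiments).

    Fills the subject-level fields of ``truth`` in place and returns it.
    """
    if li_params is None and dominance:
        li_params = DOMINANCE_LI_PARAMS
    ss = _as_seedseq(seed)
    graph = truth.graph
    children = ss.spawn(len(dominance))
    truth.dominance = list(dominance)
    truth.subject_labels, truth.subject_mu = [], []
    truth.subject_leak_rho, truth.subject_leak_partner = [], []
    truth.target_li, truth.achieved_li, truth.li_flagged = [], [], []
    for dom, child in zip(dominance, children):
        rng = np.random.default_rng(child)
        labels = perturb_boundary_labels(graph, truth.group_labels, deviation_rate, rng)
        if dom is not None and li_params is not None:
            mean, sd = li_params[dom]
            a, b = (-1.0 - mean) / sd, (1.0 - mean) / sd
            target = float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))
            labels, achieved, flagged = plant_laterality(
                graph, labels, truth.language_ids, target, tol=li_tol, rng=rng)
        else:
            target = np.nan
            lh, rh = _li_counts(labels, graph, truth.language_ids)
            achieved, flagged = _li_value(lh, rh), False
        smu = np.stack([
            sample_vmf(truth.mu_true[k], subject_mu_kappa, 1, rng)[0]
            for k in range(truth.K)
        ])
        if leakage is not None:
            scale = np.asarray(leakage, dtype=float)
            rho = scale * rng.uniform(0.5, 1.0, size=truth.K)
            partner = np.array([
                int(rng.choice([j for j in range(1, truth.K + 1) if j != k]))
                for k in range(1, truth.K + 1)])
        else:
            rho = np.zeros(truth.K)
            partner = np.zeros(truth.K, dtype=int)
        truth.subject_leak_rho.append(rho)
        truth.subject_leak_partner.append(partner)
        truth.subject_labels.append(labels)
        truth.subject_mu.append(smu)
        truth.target_li.append(target)
        truth.achieved_li.append(achieved)
        truth.li_flagged.append(bool(flagged))
    truth.generator_params.update({
        "deviation_rate": deviation_rate, "li_tol": li_tol,
        "li_params": {k: list(v) for k, v in (li_params or {}).items()},
        "n_subjects": len(dominance),
    })
    return truth


# --------------------------------------------------------------------------
# time series

def simulate_run(truth: CohortTruth, subject_id: int, session_id: int,
                 T: int = 200, snr: float = 4.0, seed=0,
                 tr_seconds: float = 2.0) -> RunTimeSeries:
    """Simulate one resting run: each network carries an i.i.d. standard
    normal latent signal g_k(t); a vertex with label k observes
    sqrt(snr)*g_k + N(0,1) noise, and each ROI observes its parent
    network's signal the same way.  corr(vertex, own-network ROI) is then
    snr/(snr+1) in expectation, so top-fraction profiles recover labels."""
    if T < 20:
        raise ValueError("T must be >= 20")
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    labels = truth.subject_labels[subject_id]
    g = rng.standard_normal((T, truth.K))
    vertex_noise = rng.standard_normal((T, truth.graph.n_vertices))
    roi_noise = rng.standard_normal((T, truth.R))
    vertex_ts = vertex_noise.copy()
    lab_pos = labels > 0
    signal = g[:, labels[lab_pos] - 1]
    if truth.subject_leak_rho and np.any(truth.subject_leak_rho[subject_id] > 0):
        rho = truth.subject_leak_rho[subject_id][labels[lab_pos] - 1]
        partner = truth.subject_leak_partner[subject_id][labels[lab_pos] - 1]
        signal = np.sqrt(1.0 - rho**2) * signal + rho * g[:, partner - 1]
    vertex_ts[:, lab_pos] += np.sqrt(snr) * signal
    roi_ts = np.sqrt(snr) * g[:, truth.roi_parents - 1] + roi_noise
    return RunTimeSeries(subject_id, session_id, vertex_ts, roi_ts, tr_seconds)


def simulate_stim_run(truth: CohortTruth, subject_id: int,
                      design: StimulationDesign, stim_networks,
                      effect: float = 2.0, seed=0, session_id: int = 0,
                      snr: float = 4.0,
                      tr_seconds: float = 2.0) -> tuple[RunTimeSeries, StimulationDesign]:
    """Simulate a stimulation run: a resting run plus an HRF-convolved boxcar
    of amplitude ``effect`` added to every vertex of the stimulated networks
    during stim blocks."""
    stim_networks = set(int(k) for k in stim_networks)
    if stim_networks and not stim_networks <= set(range(1, truth.K + 1)):
        raise ValueError("stim_networks must be a subset of 1..K")
    run = simulate_run(truth, subject_id, session_id, T=design.n_frames,
                       snr=snr, seed=seed, tr_seconds=tr_seconds)
    if not stim_networks:
        warnings.warn("empty stim_networks: stimulation run is a plain rest run")
        return run, design
    reg = stim_regressor(design.n_frames, design.block_onsets,
                         design.block_durations, design.block_kinds, tr_seconds)
    labels = truth.subject_labels[subject_id]
    target = np.isin(labels, list(stim_networks))
    run.vertex_ts[:, target] += effect * reg[:, None]
    return run, design


# --------------------------------------------------------------------------
# convenience: whole cohorts

def default_dominance_list(design: dict | None = None) -> list:
    design = design or DEFAULT_DOMINANCE_DESIGN
    out = []
    for group in ("left", "bilateral", "right"):
        out.extend([group] * design.get(group, 0))
    return out


def generate_cohort(graph: CorticalGraph, K: int = 5, R: int = 50,
                    dominance: list | None = None, n_subjects: int | None = None,
                    n_runs: int = 2, T: int = 200, snr: float = 4.0,
                    deviation_rate: float = 0.1, seed: int = 0,
                    li_params: dict | None = None,
                    leakage=None,
                    group_labels_from: CohortTruth | None = None) -> tuple[CohortTruth, dict]:
    """Generate a full cohort: group truth, subject labels, and rest runs.

    Returns (truth, runs) with runs keyed by (subject_id, session_id).
    If ``n_subjects`` is given without ``dominance``, subjects carry no
    dominance label (no asymmetry planting). ``group_labels_from`` reuses an
    existing group truth (for multi-site experiments sharing ROI structure).
    """
    ss = _as_seedseq(seed)
    s_truth, s_subj, s_runs = ss.spawn(3)
    if group_labels_from is not None:
        base = group_labels_from
        truth = CohortTruth(graph=graph, K=base.K, R=base.R,
                            group_labels=base.group_labels.copy(),
                            mu_true=base.mu_true.copy(),
                            roi_parents=base.roi_parents.copy(),
                            language_ids=base.language_ids,
                            generator_params=dict(base.generator_params))
    else:
        truth = sample_group_truth(graph, K, R, seed=s_truth)
    if dominance is None:
        dominance = [None] * int(n_subjects or 0)
    sample_subject_labels(truth, dominance, deviation_rate=deviation_rate,
                          li_params=li_params, leakage=leakage, seed=s_subj)
    run_seeds = s_runs.spawn(len(dominance) * n_runs)
    runs = {}
    i = 0
    for s in range(len(dominance)):
        for t in range(n_runs):
            runs[(s, t)] = simulate_run(truth, s, t, T=T, snr=snr, seed=run_seeds[i])
            i += 1
    truth.generator_params.update({"n_runs": n_runs, "T": T, "snr": snr})
    return truth, runs
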