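"""Synthetic longitudinal connectome cohorts and behavioral scores.

The generator emulates the statistical structure the downstream analysis
assumes: nonnegative edge weights with subject-level random intercepts,
left > right intra-hemispheric asymmetry, planted period-specific subnetwork
increases/decreases (including second-period interhemispheric decreases),
missing-at-random participant dropout (59 -> 51 by default), and
monotonically improving proficiency scores optionally coupled to chosen
edges.  Everything is deterministic given the config seed.

Generative model for edge e, participant p, month t:

    w = max(0, base_e + asym_e + b_p + sum(planted shifts active at t) + eps)

with base_e drawn once per cohort from N(baseline_edge_mean,
baseline_edge_sd^2); asym_e = a_p on left cortical-cortical edges (0
elsewhere), where a_p ~ N(asymmetry_delta, asymmetry_subject_sd^2) is each
participant's lateralization offset (between-subject variation in
lateralization keeps the group paired t at a realistic scale);
b_p ~ N(0, subject_sd^2) and eps ~ N(0, noise_sd^2).  A planted
effect of standardized magnitude m shifts its edges by m * noise_sd per
active period: "first"-period effects appear at month 3 and persist,
"second"-period effects appear at month 6, "both" accumulates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import Edge, LongitudinalConnectomes, candidate_edges
from .regions import RegionTable


def _is_connected(edges) -> bool:
    parent: dict[str, str] = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        parent[find(a)] = find(b)
    roots = {find(n) for e in edges for n in e}
    return len(roots) == 1


@dataclass(frozen=True)
class PlantedEffect:
    """A connected subnetwork with a period-specific mean shift.

    ``magnitude`` is the standardized per-period group-mean shift (units of
    ``noise_sd``).  ``subject_sd`` adds between-participant heterogeneity:
    participant p's shift is ``(magnitude + u_p) * noise_sd`` with
    ``u_p ~ N(0, subject_sd^2)`` shared across the effect's edges.  This
    models individual differences in plasticity, which is what makes
    behavior-connectivity coupling statistically detectable: a shift common
    to all participants is invariant under between-participant score
    permutations and carries no individual-difference signal.
    """

    edges: tuple[Edge, ...]
    period: str = "second"      # first | second | both
    direction: str = "increase"  # increase | decrease
    magnitude: float = 1.0       # per-period shift / noise_sd
    subject_sd: float = 0.0      # between-participant shift sd / noise_sd

    def __post_init__(self):
        if self.period not in ("first", "second", "both"):
            raise ValueError(f"unknown period {self.period!r}")
        if self.direction not in ("increase", "decrease"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.magnitude <= 0:
            raise ValueError("magnitude must be positive")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")
        if self.edges and not _is_connected(self.edges):
            raise ValueError("planted edges must form a connected subgraph")

    def n_periods_at(self, timepoint: int) -> int:
        return {
            "first": {3: 1, 6: 1},
            "second": {6: 1},
            "both": {3: 1, 6: 2},
        }[self.period].get(timepoint, 0)

    def shift_at(self, timepoint: int, noise_sd: float,
                 subject_dev: float = 0.0) -> float:
        sign = 1.0 if self.direction == "increase" else -1.0
        return (sign * (self.magnitude + subject_dev) * noise_sd
                * self.n_periods_at(timepoint))


@dataclass(frozen=True)
class ScoreModel:
    """Behavioral score generator (arbitrary proficiency scale).

    Scores exist at months 3 and 6.  Every participant improves: the 3->6
    gain is ``gain_mean + coupling_strength * z + N(0, gain_sd)`` clipped at
    ``min_gain > 0``, where z is the participant's standardized mean change
    on the coupling edges between months 3 and 6.  With
    ``coupling_strength = k`` the expected score-change correlation is
    ``k / sqrt(k^2 + gain_sd^2)``.
    """

    baseline_mean: float = 50.0
    baseline_sd: float = 8.0
    gain_mean: float = 12.0
    gain_sd: float = 4.0
    coupling_edges: tuple[Edge, ...] = ()
    coupling_strength: float = 0.0
    min_gain: float = 0.5


def coupling_for_target_r(r: float, gain_sd: float = 4.0) -> float:
    """Coupling strength giving expected gain/edge-change correlation ``r``."""
    if not 0 <= r < 1:
        raise ValueError("target r must be in [0, 1)")
    return float(gain_sd * r / np.sqrt(1.0 - r * r))


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters (defaults emulate the study design:
    59 participants at months 0 and 3, 51 completing month 6)."""

    n_participants: int = 59
    timepoints: tuple[int, ...] = (0, 3, 6)
    dropout_per_period: tuple[int, ...] = (0, 8)
    baseline_edge_mean: float = 1.0
    baseline_edge_sd: float = 0.25
    subject_sd: float = 0.15
    noise_sd: float = 0.10
    asymmetry_delta: float = 0.08
    asymmetry_subject_sd: float = 0.075
    planted_effects: tuple[PlantedEffect, ...] = ()
    score_model: ScoreModel = field(default_factory=ScoreModel)
    weight_distribution: str = "truncated-normal"  # or "log-normal"
    seed: int = 0

    def __post_init__(self):
        for name in ("baseline_edge_sd", "subject_sd", "noise_sd",
                     "asymmetry_subject_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if sum(self.dropout_per_period) >= self.n_participants:
            raise ValueError("dropout exceeds cohort size")
        if len(self.dropout_per_period) != len(self.timepoints) - 1:
            raise ValueError("need one dropout count per period")
        if self.weight_distribution not in ("truncated-normal", "log-normal"):
            raise ValueError("unknown weight distribution")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,))
    )


def participant_ids(config: SimulationConfig) -> list[str]:
    return [f"P{k:03d}" for k in range(1, config.n_participants + 1)]


def simulate_connectomes(config: SimulationConfig,
                         regions: RegionTable) -> LongitudinalConnectomes:
    """Generate a longitudinal cohort of symmetric connectivity matrices."""
    cands = candidate_edges(regions)
    cand_set = set(cands)
    for eff in config.planted_effects:
        outside = set(eff.edges) - cand_set
        if outside:
            raise ValueError(f"planted edges outside candidate set: {sorted(outside)}")

    rng = _rng(config, 0)
    E = len(cands)
    base = config.baseline_edge_mean + config.baseline_edge_sd * rng.standard_normal(E)
    left_intra = np.array([
        not regions.is_cc(a) and not regions.is_cc(b)
        and regions.hemisphere(a) == "L" and regions.hemisphere(b) == "L"
        for a, b in cands
    ])
    col = {e: k for k, e in enumerate(cands)}
    pids = participant_ids(config)
    b_p = config.subject_sd * rng.standard_normal(len(pids))
    # per-subject lateralization: left intra-hemispheric offset varies
    # across participants around asymmetry_delta
    a_p = (config.asymmetry_delta
           + config.asymmetry_subject_sd * rng.standard_normal(len(pids)))
    # per-subject plasticity deviations, one stream per planted effect
    u = np.array([
        eff.subject_sd * rng.standard_normal(len(pids))
        for eff in config.planted_effects
    ]).reshape(len(config.planted_effects), len(pids))

    # shift[participant, timepoint, edge]
    shift = np.zeros((len(pids), len(config.timepoints), E))
    for f, eff in enumerate(config.planted_effects):
        cols = [col[e] for e in eff.edges]
        for ti, tp in enumerate(config.timepoints):
            if eff.n_periods_at(tp) == 0:
                continue
            per_subj = np.array([
                eff.shift_at(tp, config.noise_sd, u[f, k])
                for k in range(len(pids))
            ])
            shift[:, ti, :][:, cols] += per_subj[:, None]

    # missing-at-random dropout: who is absent from each later timepoint on
    drop_rng = _rng(config, 1)
    remaining = list(pids)
    absent_from: dict[int, set[str]] = {tp: set() for tp in config.timepoints}
    lost: set[str] = set()
    for period, n_drop in enumerate(config.dropout_per_period):
        dropped = set(drop_rng.choice(
            sorted(set(remaining) - lost), size=n_drop, replace=False
        )) if n_drop else set()
        lost |= dropped
        absent_from[config.timepoints[period + 1]] = set(lost)

    n = regions.n_regions
    i_idx = np.array([regions.position(a) for a, _ in cands])
    j_idx = np.array([regions.position(b) for _, b in cands])
    mats: dict[tuple[str, int], np.ndarray] = {}
    for p_ix, pid in enumerate(pids):
        for ti, tp in enumerate(config.timepoints):
            if pid in absent_from.get(tp, set()):
                continue
            eps = config.noise_sd * rng.standard_normal(E)
            lin = (base + a_p[p_ix] * left_intra + b_p[p_ix]
                   + shift[p_ix, ti] + eps)
            if config.weight_distribution == "log-normal":
                w = np.exp(lin / max(config.baseline_edge_mean, 1e-12) - 1.0)
                w *= config.baseline_edge_mean
            else:
                w = np.maximum(lin, 0.0)
            mat = np.zeros((n, n))
            mat[i_idx, j_idx] = w
            mat[j_idx, i_idx] = w
            mats[(pid, tp)] = mat
    return LongitudinalConnectomes(regions, mats)


def null_cohort(config: SimulationConfig,
                regions: RegionTable) -> LongitudinalConnectomes:
    """The identical generative model with no planted effects (H0 harness)."""
    return simulate_connectomes(
        dataclasses.replace(config, planted_effects=()), regions
    )


def _edge_change(data: LongitudinalConnectomes, edges: tuple[Edge, ...],
                 pid: str, lo: int = 3, hi: int = 6) -> float:
    i = np.array([data.region_table.position(a) for a, _ in edges])
    j = np.array([data.region_table.position(b) for _, b in edges])
    return float((data.matrix(pid, hi)[i, j] - data.matrix(pid, lo)[i, j]).mean())


def simulate_scores(config: SimulationConfig,
                    data: LongitudinalConnectomes) -> pd.DataFrame:
    """Proficiency scores at months 3 and 6 (long format).

    Guarantees score(6) > score(3) for every participant observed at both.
    When coupling is configured, gains are linearly tied to each
    participant's standardized mean change on the coupling edges.
    """
    sm = config.score_model
    rng = _rng(config, 2)
    at3 = data.participants_at(3)
    at6 = set(data.participants_at(6))
    if not at3 or not at6:
        raise ValueError("score simulation requires months 3 and 6 in the data")
    base = sm.baseline_mean + sm.baseline_sd * rng.standard_normal(len(at3))
    noise = sm.gain_sd * rng.standard_normal(len(at3))

    z = np.zeros(len(at3))
    if sm.coupling_edges and sm.coupling_strength != 0.0:
        changes = np.array([
            _edge_change(data, tuple(sm.coupling_edges), pid)
            if pid in at6 else np.nan
            for pid in at3
        ])
        valid = ~np.isnan(changes)
        zc = changes[valid]
        sd = zc.std(ddof=1)
        if sd > 0:
            z[valid] = (zc - zc.mean()) / sd

    rows = []
    for k, pid in enumerate(at3):
        s3 = float(base[k])
        rows.append((pid, 3, s3))
        if pid in at6:
            gain = sm.gain_mean + sm.coupling_strength * z[k] + noise[k]
            gain = max(gain, sm.min_gain)
            rows.append((pid, 6, s3 + gain))
    return pd.DataFrame(rows, columns=["participant", "timepoint", "score"])


def simulate_vocabulary(config: SimulationConfig, scores: pd.DataFrame,
                        target_r: float = 0.5, mean: float = 100.0,
                        sd: float = 15.0) -> pd.Series:
    """Vocabulary size at month 6, calibrated to correlate ~``target_r``
    with the month-6 proficiency score."""
    s6 = scores.loc[scores["timepoint"] == 6].set_index("participant")["score"]
    if len(s6) < 3:
        raise ValueError("need month-6 scores to simulate vocabulary")
    rng = _rng(config, 3)
    z = (s6 - s6.mean()) / s6.std(ddof=1)
    noise = rng.standard_normal(len(s6))
    vocab = target_r * z.to_numpy() + np.sqrt(1.0 - target_r**2) * noise
    return pd.Series(mean + sd * vocab, index=s6.index, name="vocabulary")


# -- study-style configurations -------------------------------------------

def recovery_benchmark_config(
    regions: RegionTable, seed: int = 0, n_participants: int = 40,
    n_edges: int = 8, magnitude: float = 1.2,
) -> tuple[SimulationConfig, tuple[Edge, ...]]:
    """Time-model power benchmark: a planted connected decrease.

    A cohort of ``n_participants`` with no dropout carrying one connected
    ``n_edges``-edge second-period decrease of standardized magnitude
    ``magnitude`` on robustly retained edges.  Returns the config and the
    planted edge set (the ground truth for recovery scoring).
    """
    from .connectome import connected_retained_edges, group_threshold

    base = SimulationConfig(n_participants=n_participants,
                            dropout_per_period=(0, 0), seed=seed)
    mask = group_threshold(simulate_connectomes(base, regions), 0.30)
    edges = connected_retained_edges(
        mask, regions, n_edges, "any",
        min_margin=0.2 * base.baseline_edge_sd)
    eff = PlantedEffect(edges, period="second", direction="decrease",
                        magnitude=magnitude)
    return dataclasses.replace(base, planted_effects=(eff,)), edges


def coupling_benchmark_config(
    regions: RegionTable, seed: int = 0, n_participants: int = 40,
    n_edges: int = 8, coupled: bool = True,
) -> tuple[SimulationConfig, tuple[Edge, ...]]:
    """Score-model power benchmark: gains coupled to a connected edge set.

    Individual differences drive the signal: the planted subnetwork has a
    near-zero group-mean trend (magnitude 0.2) but strong between-
    participant plasticity heterogeneity (subject_sd 3.0 in noise units),
    and score gains are coupled to the realized subnetwork change at an
    expected correlation of 0.85 (month-3 score spread kept small, as in a
    cohort of beginners starting from the same level).  A group-mean trend
    alone carries no individual-difference signal and is invariant under
    between-participant score permutations, so these conditions are what
    make score-NBS recovery well-posed.  With ``coupled=False`` the same
    cohort is generated with zero coupling (FWE null harness).
    """
    from .connectome import connected_retained_edges, group_threshold

    base = SimulationConfig(n_participants=n_participants,
                            dropout_per_period=(0, 0), seed=seed)
    mask = group_threshold(simulate_connectomes(base, regions), 0.30)
    edges = connected_retained_edges(
        mask, regions, n_edges, "any",
        min_margin=0.2 * base.baseline_edge_sd)
    eff = PlantedEffect(edges, period="second", direction="increase",
                        magnitude=0.2, subject_sd=3.0)
    sm = ScoreModel(
        baseline_sd=2.0,
        coupling_edges=edges if coupled else (),
        coupling_strength=coupling_for_target_r(0.85) if coupled else 0.0,
    )
    return dataclasses.replace(base, planted_effects=(eff,),
                               score_model=sm), edges

def _star(center: str, partners) -> tuple[Edge, ...]:
    return tuple(sorted(tuple(sorted((center, p))) for p in partners))


def demo_effects(regions: RegionTable) -> tuple[PlantedEffect, ...]:
    """Planted effects emulating the reported plasticity pattern.

    A second-period interhemispheric (cortical-to-CC) decrease, a
    second-period increase in a right intra-hemispheric (temporal-parietal
    style) star, and a small first-period decrease in left cortical-to-CC
    connections.  Works for any bilateral region table with >= 9 cortical
    regions and >= 1 CC region per hemisphere.
    """
    cort_l = regions.cortical_ids("L")
    cort_r = regions.cortical_ids("R")
    cc = regions.cc_ids()
    if len(cort_r) < 9 or not cc:
        raise ValueError("region table too small for the demo effect set")
    cc_post = [r for r in cc if "pCC" in r] or cc
    cc_ant = [r for r in cc if "aCC" in r] or cc
    inter_post = _star(cc_post[0], cort_l[:5] + cort_r[:5])     # 10 edges
    right_sub = _star(cort_r[-1], cort_r[:8])                   # 8 edges
    inter_front = _star(cc_ant[0], cort_l[:4])                  # 4 edges
    return (
        PlantedEffect(inter_post, period="second", direction="decrease",
                      magnitude=1.2),
        PlantedEffect(right_sub, period="second", direction="increase",
                      magnitude=1.0),
        PlantedEffect(inter_front, period="first", direction="decrease",
                      magnitude=0.6),
    )


def study_config(regions: RegionTable, seed: int = 0,
                 target_r: float = 0.5) -> SimulationConfig:
    """Default study-style cohort configuration.

    59 participants, 8 lost before month 6, left-lateralized baselines, and
    planted effects emulating the reported plasticity pattern: a
    second-period decrease over 20 connected interhemispheric
    (cortical-to-CC) edges, a second-period increase over 8 connected right
    intra-hemispheric edges, and a small first-period interhemispheric
    decrease over 4 edges.  Score gains are coupled to the increased
    subnetwork at expected correlation ``target_r``.

    Effects must lie inside the analyzed network, so they are planted on
    robustly retained edges: a null cohort with the same seed is simulated,
    group-thresholded at 30%, and connected edge sets are taken from the
    retained graph with a safety margin above the retention cutoff.
    """
    from .connectome import connected_retained_edges, group_threshold

    base_cfg = SimulationConfig(seed=seed)
    null = simulate_connectomes(base_cfg, regions)
    mask = group_threshold(null, 0.30)
    margin = 0.2 * base_cfg.baseline_edge_sd
    inter_late = connected_retained_edges(
        mask, regions, 20, "interhemispheric", min_margin=margin)
    right_late = connected_retained_edges(
        mask, regions, 8, "right", min_margin=margin)
    inter_early = connected_retained_edges(
        mask, regions, 4, "interhemispheric",
        exclude=set(inter_late), min_margin=margin)
    effects = (
        PlantedEffect(inter_late, period="second", direction="decrease",
                      magnitude=1.2, subject_sd=0.4),
        PlantedEffect(right_late, period="second", direction="increase",
                      magnitude=1.0, subject_sd=0.5),
        PlantedEffect(inter_early, period="first", direction="decrease",
                      magnitude=0.6, subject_sd=0.2),
    )
    sm = ScoreModel(
        coupling_edges=right_late,
        coupling_strength=coupling_for_target_r(target_r),
    )
    return dataclasses.replace(
        base_cfg, planted_effects=effects, score_model=sm)
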