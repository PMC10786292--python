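"""Network-based statistics (NBS) over edge-wise mixed models.

Edge-level statistics come from random-intercept LMEs (time or behavioral
score as the fixed effect).  Edges passing a primary p-threshold are
assembled into signed graphs; family-wise error over connected components
is controlled by permutation: each permutation relabels the data under the
null (timepoint labels within participants for the time model, whole score
trajectories between participants for the score model), recomputes the edge
statistics, and records the maximal component statistic pooled over both
signs.  Observed components are then assigned
``p_fwe = (1 + #{null max >= observed}) / (K + 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ._engine import (
    BatchLMEResult,
    balanced_time_stats,
    batch_lme,
    is_balanced,
    time_design,
)
from .connectome import Edge, EdgeMask, LongitudinalConnectomes
from .models import ModelSpec


class NBSError(ValueError):
    pass


@dataclass(frozen=True)
class NBSConfig:
    """Parameters of the permutation test.

    Defaults follow common practice for this analysis: primary edge
    threshold p < 0.01, K = 5,000 permutations, component-level alpha 0.05,
    component statistic = extent (edge count).
    """

    p_threshold: float = 0.01
    n_permutations: int = 5000
    alpha: float = 0.05
    seed: int = 0
    component_statistic: str = "extent"  # or "intensity"

    def __post_init__(self):
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("need at least 1 permutation")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.component_statistic not in ("extent", "intensity"):
            raise ValueError("component_statistic must be 'extent' or 'intensity'")


@dataclass(frozen=True)
class EdgeStatMap:
    """Per-edge mixed-model statistics for one design."""

    edges: tuple[Edge, ...]
    contrasts: tuple[str, ...]
    estimate: np.ndarray  # (E, C)
    tstat: np.ndarray     # (E, C)
    pval: np.ndarray      # (E, C)
    ok: np.ndarray        # (E,) fit succeeded
    df: float
    spec: ModelSpec

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (a, b) in enumerate(self.edges):
            for c, name in enumerate(self.contrasts):
                rows.append((a, b, name, self.estimate[i, c], self.tstat[i, c],
                             self.pval[i, c], bool(self.ok[i])))
        return pd.DataFrame(rows, columns=["region_a", "region_b", "contrast",
                                           "estimate", "t", "p", "ok"])

    def primary(self) -> tuple[np.ndarray, np.ndarray]:
        """Omnibus per-edge (t, p): the strongest contrast per edge.

        An edge's omnibus p is its smallest contrast p-value and the edge's
        sign is taken from that contrast's t (with equal df this is the
        maximal-|t| rule).  Failed fits report (0, 1).
        """
        p = np.where(np.isnan(self.pval), 1.0, self.pval)
        jsel = np.argmin(p, axis=1)
        idx = np.arange(len(self.edges))
        t = self.tstat[idx, jsel]
        pmin = p[idx, jsel]
        t = np.where(self.ok, t, 0.0)
        pmin = np.where(self.ok, pmin, 1.0)
        return t, pmin


@dataclass(frozen=True)
class SubnetworkResult:
    """A signed connected component of suprathreshold edges."""

    edges: tuple[Edge, ...]
    direction: str                # increase/decrease or positive/negative
    statistic_value: float        # extent or intensity
    p_fwe: float
    component_statistic: str
    mean_t: float
    significant: bool = False

    @property
    def extent(self) -> int:
        return len(self.edges)

    @property
    def member_regions(self) -> tuple[str, ...]:
        return tuple(sorted({r for e in self.edges for r in e}))


@dataclass(frozen=True)
class PeriodSubnetwork:
    """Post-hoc signed subnetwork for one adjacent learning period."""

    period: tuple[int, int]
    direction: str
    edges: tuple[Edge, ...]
    mean_estimate: float
    mean_t: float

    @property
    def extent(self) -> int:
        return len(self.edges)


# -- design assembly -------------------------------------------------------

@dataclass
class _Design:
    Y: np.ndarray            # (n_obs, E)
    groups: np.ndarray       # (n_obs,) subject codes
    levels: np.ndarray       # (n_obs,) timepoints
    scores: np.ndarray | None  # (n_obs,) for the score model
    participants: list[str]
    row_participant: list[str]
    balanced: bool


def _assemble(data: LongitudinalConnectomes, mask: EdgeMask,
              timepoints: list[int] | None = None,
              scores: pd.DataFrame | None = None,
              participants: list[str] | None = None) -> _Design:
    tps = timepoints if timepoints is not None else data.timepoints()
    pids = participants if participants is not None else data.participants()
    score_map = {}
    if scores is not None:
        for row in scores.itertuples(index=False):
            score_map[(str(row.participant), int(row.timepoint))] = float(row.score)
    i, j = mask.index_arrays()
    rows, grp, lev, sc, row_pid = [], [], [], [], []
    code = {}
    for pid in pids:
        for tp in tps:
            if (pid, tp) not in data.matrices:
                continue
            if scores is not None and (pid, tp) not in score_map:
                continue
            rows.append(data.matrix(pid, tp)[i, j])
            grp.append(code.setdefault(pid, len(code)))
            lev.append(tp)
            row_pid.append(pid)
            if scores is not None:
                sc.append(score_map[(pid, tp)])
    if not rows:
        raise NBSError("no observations match the requested design")
    Y = np.asarray(rows)
    groups = np.asarray(grp)
    levels = np.asarray(lev)
    bal = is_balanced(groups, levels)
    return _Design(Y, groups, levels,
                   np.asarray(sc) if scores is not None else None,
                   list(code), row_pid, bal)


def _stats_time(Y: np.ndarray, design: _Design, n_golden: int = 16) -> BatchLMEResult:
    if design.balanced:
        return balanced_time_stats(Y, design.groups, design.levels)
    X = time_design(design.levels)
    return batch_lme(Y, X, design.groups, n_golden=n_golden)


def _stats_score(Y: np.ndarray, score_col: np.ndarray, design: _Design,
                 n_golden: int = 16) -> BatchLMEResult:
    X = np.column_stack([np.ones(len(score_col)), score_col])
    return batch_lme(Y, X, design.groups, n_golden=n_golden)


def _result_to_map(res: BatchLMEResult, edges, contrasts, spec) -> EdgeStatMap:
    # drop the intercept column (column 0)
    return EdgeStatMap(
        edges=tuple(edges),
        contrasts=tuple(contrasts),
        estimate=res.beta[:, 1:],
        tstat=res.tstat[:, 1:],
        pval=res.pval[:, 1:],
        ok=res.ok,
        df=res.df,
        spec=spec,
    )


def edgewise_stats(data: LongitudinalConnectomes, mask: EdgeMask,
                   spec: ModelSpec,
                   scores: pd.DataFrame | None = None) -> EdgeStatMap:
    """Fit the edge-wise random-intercept model on every retained edge.

    For the time model, coefficients are treatment contrasts of each later
    timepoint against baseline; for the score model, the score slope.
    Edges whose fit fails (e.g. constant weight) are flagged with p = 1.
    """
    if mask.n_edges == 0:
        raise NBSError("empty edge mask")
    if spec.fixed_effect == "time":
        design = _assemble(data, mask)
        if len(np.unique(design.levels)) < 2:
            raise NBSError("need at least two timepoints")
        res = _stats_time(design.Y, design)
        contrasts = [f"time[{t}]" for t in np.unique(design.levels)[1:]]
    else:
        if scores is None:
            raise NBSError("score model requires a score table")
        design = _assemble(data, mask, timepoints=[3, 6], scores=scores)
        if np.ptp(design.scores) == 0:
            raise NBSError("scores have zero variance")
        res = _stats_score(design.Y, design.scores, design)
        contrasts = ["score"]
    return _result_to_map(res, mask.edges, contrasts, spec)


# -- component machinery ---------------------------------------------------

def _direction_labels(spec_or_kind) -> tuple[str, str]:
    kind = getattr(spec_or_kind, "fixed_effect", spec_or_kind)
    return ("positive", "negative") if kind == "score" else ("increase", "decrease")


def suprathreshold_components(stats: EdgeStatMap, p_threshold: float,
                              direction: str) -> list[dict]:
    """Connected components of same-signed suprathreshold edges.

    Returns components largest-first (by extent, ties by smallest edge),
    each as a dict with ``edges``, ``extent``, ``intensity`` and ``t``
    (per-edge omnibus t values).
    """
    pos_label, _ = _direction_labels(stats.spec)
    sign = 1.0 if direction in ("increase", "positive") else -1.0
    t, p = stats.primary()
    sel = (p < p_threshold) & (np.sign(t) == sign) & stats.ok
    idx = np.nonzero(sel)[0]
    if len(idx) == 0:
        return []
    g = nx.Graph()
    for k in idx:
        a, b = stats.edges[k]
        g.add_edge(a, b, k=k)
    comps = []
    for nodes in nx.connected_components(g):
        ks = sorted(g.edges[e]["k"] for e in g.subgraph(nodes).edges)
        edges = tuple(sorted(stats.edges[k] for k in ks))
        comps.append({
            "edges": edges,
            "extent": len(edges),
            "intensity": float(np.abs(t[ks]).sum()),
            "mean_t": float(t[ks].mean()),
        })
    comps.sort(key=lambda c: (-c["extent"], c["edges"][0]))
    return comps


def _uf_max_stat(u: np.ndarray, v: np.ndarray, w: np.ndarray) -> float:
    """Max connected-component statistic via union-find (weights summed)."""
    if len(u) == 0:
        return 0.0
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        root = x
        while parent.setdefault(root, root) != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for a, b in zip(u, v):
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[rb] = ra
    sums: dict[int, float] = {}
    for a, wt in zip(u, w):
        r = find(int(a))
        sums[r] = sums.get(r, 0.0) + float(wt)
    return max(sums.values())


def _max_component_stat(t: np.ndarray, p: np.ndarray, ok: np.ndarray,
                        edge_u: np.ndarray, edge_v: np.ndarray,
                        p_threshold: float, statistic: str) -> float:
    """Maximal component statistic over both signs for one permutation."""
    best = 0.0
    for sign in (1.0, -1.0):
        sel = (p < p_threshold) & (np.sign(t) == sign) & ok
        if not sel.any():
            continue
        w = np.ones(sel.sum()) if statistic == "extent" else np.abs(t[sel])
        best = max(best, _uf_max_stat(edge_u[sel], edge_v[sel], w))
    return best


def _edge_endpoint_codes(edges) -> tuple[np.ndarray, np.ndarray]:
    nodes = {r: k for k, r in enumerate(sorted({r for e in edges for r in e}))}
    u = np.array([nodes[a] for a, _ in edges])
    v = np.array([nodes[b] for _, b in edges])
    return u, v


def _permute_within_subject(rng: np.random.Generator,
                            groups: np.ndarray) -> np.ndarray:
    """Row permutation shuffling observations within each subject block."""
    perm = np.arange(len(groups))
    for s in np.unique(groups):
        rows = np.nonzero(groups == s)[0]
        perm[rows] = rng.permutation(rows)
    return perm


def _permute_scores(rng: np.random.Generator, design: _Design) -> np.ndarray:
    """Permute whole score trajectories between availability-matched subjects."""
    pid_rows: dict[int, np.ndarray] = {
        s: np.nonzero(design.groups == s)[0] for s in np.unique(design.groups)
    }
    patterns: dict[tuple[int, ...], list[int]] = {}
    for s, rows in pid_rows.items():
        patterns.setdefault(tuple(sorted(design.levels[rows])), []).append(s)
    new_scores = np.array(design.scores, copy=True)
    for pat, subs in sorted(patterns.items()):
        donors = rng.permutation(subs)
        for s, d in zip(subs, donors):
            rows_s = pid_rows[s][np.argsort(design.levels[pid_rows[s]])]
            rows_d = pid_rows[d][np.argsort(design.levels[pid_rows[d]])]
            new_scores[rows_s] = design.scores[rows_d]
    return new_scores


def _null_distribution(design: _Design, config: NBSConfig, kind: str,
                       edge_u: np.ndarray, edge_v: np.ndarray) -> np.ndarray:
    rng = np.random.default_rng(config.seed)
    null = np.empty(config.n_permutations)
    for k in range(config.n_permutations):
        if kind == "time":
            perm = _permute_within_subject(rng, design.groups)
            res = _stats_time(design.Y[perm], design)
        else:
            sc = _permute_scores(rng, design)
            res = _stats_score(design.Y, sc, design)
        t = res.tstat[:, 1:]
        p = np.where(np.isnan(res.pval[:, 1:]), 1.0, res.pval[:, 1:])
        jsel = np.argmin(p, axis=1)
        idx = np.arange(t.shape[0])
        null[k] = _max_component_stat(
            np.where(res.ok, t[idx, jsel], 0.0),
            np.where(res.ok, p[idx, jsel], 1.0),
            res.ok, edge_u, edge_v, config.p_threshold,
            config.component_statistic,
        )
    return null


def _components_to_results(stats: EdgeStatMap, null: np.ndarray,
                           config: NBSConfig) -> list[SubnetworkResult]:
    K = len(null)
    results = []
    for direction in _direction_labels(stats.spec):
        for comp in suprathreshold_components(stats, config.p_threshold, direction):
            value = comp[config.component_statistic]
            p_fwe = (1.0 + float(np.sum(null >= value))) / (K + 1.0)
            results.append(SubnetworkResult(
                edges=comp["edges"],
                direction=direction,
                statistic_value=float(value),
                p_fwe=p_fwe,
                component_statistic=config.component_statistic,
                mean_t=comp["mean_t"],
                significant=p_fwe < config.alpha,
            ))
    results.sort(key=lambda r: (r.p_fwe, -r.statistic_value,
                                r.direction, r.edges))
    return results


def nbs_test(data: LongitudinalConnectomes, mask: EdgeMask, spec: ModelSpec,
             config: NBSConfig,
             scores: pd.DataFrame | None = None) -> list[SubnetworkResult]:
    """Omnibus NBS: FWE-corrected signed subnetworks for a model spec.

    Fully reproducible given ``config.seed``; ``p_fwe`` can never fall below
    ``1 / (K + 1)``.
    """
    if 1.0 / (config.n_permutations + 1) > config.alpha:
        warnings.warn(
            f"K={config.n_permutations} permutations cannot reach "
            f"alpha={config.alpha}; smallest attainable p_fwe is "
            f"{1.0 / (config.n_permutations + 1):.3g}",
            stacklevel=2,
        )
    stats = edgewise_stats(data, mask, spec, scores=scores)
    edge_u, edge_v = _edge_endpoint_codes(stats.edges)
    if spec.fixed_effect == "time":
        design = _assemble(data, mask)
    else:
        design = _assemble(data, mask, timepoints=[3, 6], scores=scores)
    null = _null_distribution(design, config, spec.fixed_effect, edge_u, edge_v)
    return _components_to_results(stats, null, config)


def posthoc_adjacent(data: LongitudinalConnectomes, mask: EdgeMask,
                     components: list[SubnetworkResult],
                     pairs: list[tuple[int, int]] | None = None,
                     alpha: float = 0.05) -> list[PeriodSubnetwork]:
    """Localize omnibus subnetwork edges to adjacent learning periods.

    For every edge of the given components, the two-timepoint releveled LME
    contrast is computed per adjacent pair; edges with p < alpha are grouped
    into signed connected sub-components per period.
    """
    if pairs is None:
        tps = data.timepoints()
        pairs = list(zip(tps[:-1], tps[1:]))
    comp_edges = tuple(sorted({e for c in components for e in c.edges}))
    if not comp_edges:
        return []
    col = {e: k for k, e in enumerate(mask.edges)}
    sel = np.array([col[e] for e in comp_edges])
    out: list[PeriodSubnetwork] = []
    for lo, hi in pairs:
        design = _assemble(data, mask, timepoints=[lo, hi])
        res = _stats_time(design.Y[:, sel], design)
        t = res.tstat[:, 1]
        p = np.where(res.ok, res.pval[:, 1], 1.0)
        est = res.beta[:, 1]
        for sign, direction in ((1.0, "increase"), (-1.0, "decrease")):
            keep = (p < alpha) & (np.sign(t) == sign) & res.ok
            idx = np.nonzero(keep)[0]
            if len(idx) == 0:
                continue
            g = nx.Graph()
            for k in idx:
                a, b = comp_edges[k]
                g.add_edge(a, b, k=int(k))
            for nodes in nx.connected_components(g):
                ks = sorted(g.edges[e]["k"] for e in g.subgraph(nodes).edges)
                out.append(PeriodSubnetwork(
                    period=(lo, hi),
                    direction=direction,
                    edges=tuple(sorted(comp_edges[k] for k in ks)),
                    mean_estimate=float(est[ks].mean()),
                    mean_t=float(t[ks].mean()),
                ))
    out.sort(key=lambda s: (s.period, s.direction, -s.extent, s.edges))
    return out


def nbs_score(data: LongitudinalConnectomes, scores: pd.DataFrame,
              mask: EdgeMask, config: NBSConfig,
              participants: list[str] | None = None) -> list[SubnetworkResult]:
    """Score-correlated subnetworks (y ~ score + (1 | participant), months 3 and 6).

    Returns positively and negatively associated subnetworks with
    permutation FWE control (score trajectories permuted between
    availability-matched participants).
    """
    if participants is not None:
        scores = scores.loc[scores["participant"].isin(participants)]
    present = {p for p in data.participants()
               if (p, 3) in data.matrices or (p, 6) in data.matrices}
    if participants is not None:
        present &= set(participants)
    with_scores = set(scores["participant"].astype(str))
    if len(present) and len(present - with_scores) > 0.5 * len(present):
        raise NBSError("scores missing for more than half of the participants")
    spec = ModelSpec("score")
    if 1.0 / (config.n_permutations + 1) > config.alpha:
        warnings.warn("K too small to reach alpha", stacklevel=2)
    design = _assemble(data, mask, timepoints=[3, 6], scores=scores,
                       participants=participants)
    if np.ptp(design.scores) == 0:
        raise NBSError("scores have zero variance")
    res = _stats_score(design.Y, design.scores, design)
    stats = _result_to_map(res, mask.edges, ["score"], spec)
    edge_u, edge_v = _edge_endpoint_codes(stats.edges)
    null = _null_distribution(design, config, "score", edge_u, edge_v)
    return _components_to_results(stats, null, config)


def subgroup_split(values: pd.Series | dict, criterion: str = "mean"
                   ) -> tuple[list[str], list[str]]:
    """Split participants into above-mean and at-or-below-mean groups.

    Returns ``(above, at_or_below)`` as sorted participant lists.  Warns
    when a subgroup has fewer than 4 members (low power).
    """
    s = pd.Series(values, dtype=float)
    if criterion == "mean":
        cut = float(s.mean())
    elif criterion == "median":
        cut = float(s.median())
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    above = sorted(str(k) for k, v in s.items() if v > cut)
    below = sorted(str(k) for k, v in s.items() if v <= cut)
    if min(len(above), len(below)) < 4:
        warnings.warn(
            f"subgroup sizes {len(above)}/{len(below)} below 4: "
            "subgroup analyses will be underpowered", stacklevel=2,
        )
    return above, below
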