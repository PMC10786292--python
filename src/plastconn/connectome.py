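"""Connectome containers, edge sets, thresholding and hemispheric summaries.

The connectome is an undirected weighted network over a bilateral region
table.  Candidate edges are intra-hemispheric cortical-cortical pairs plus
cortical-to-corpus-callosum pairs; direct interhemispheric cortical-cortical
pairs are excluded because tractography cannot estimate them robustly, and
CC-CC pairs are anatomically meaningless here.  A single group-level
threshold (the strongest fraction of candidate edges by mean weight across
all participants and timepoints) fixes one edge set for the whole
longitudinal analysis.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import RegionTable

Edge = tuple[str, str]

VALID_TIMEPOINTS = (0, 3, 6)


class ConnectomeError(ValueError):
    """Raised on invalid connectome input."""


def _canon(a: str, b: str) -> Edge:
    """Canonical (lexicographic) ordering of an undirected region pair."""
    return (a, b) if a <= b else (b, a)


@dataclass
class LongitudinalConnectomes:
    """Participant x timepoint collection of symmetric connectivity matrices.

    Matrices are dense square arrays in :class:`RegionTable` row order, with
    zero diagonal and nonnegative weights.  Every participant must have a
    baseline (month 0) matrix; later timepoints may be missing (dropout).
    """

    region_table: RegionTable
    matrices: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for (pid, tp), mat in self.matrices.items():
            self._validate_matrix(pid, tp, mat)
        self._check_baselines()

    def _validate_matrix(self, pid: str, tp: int, mat: np.ndarray) -> None:
        n = self.region_table.n_regions
        if mat.shape != (n, n):
            raise ConnectomeError(f"({pid},{tp}): shape {mat.shape}, expected {(n, n)}")
        if not np.all(np.isfinite(mat)):
            raise ConnectomeError(f"({pid},{tp}): non-finite weights")
        if np.any(mat < 0):
            raise ConnectomeError(f"({pid},{tp}): negative weights")
        if not np.allclose(mat, mat.T):
            raise ConnectomeError(f"({pid},{tp}): matrix not symmetric")
        if np.any(np.diag(mat) != 0):
            raise ConnectomeError(f"({pid},{tp}): nonzero diagonal")
        if tp not in VALID_TIMEPOINTS:
            raise ConnectomeError(f"({pid},{tp}): timepoint not in {VALID_TIMEPOINTS}")

    def _check_baselines(self) -> None:
        missing = [p for p in self.participants() if (p, 0) not in self.matrices]
        if missing:
            raise ConnectomeError(f"participants without baseline: {missing}")

    # -- accessors ---------------------------------------------------------
    def participants(self) -> list[str]:
        return sorted({p for p, _ in self.matrices})

    def timepoints(self) -> list[int]:
        return sorted({t for _, t in self.matrices})

    def participants_at(self, timepoint: int) -> list[str]:
        return sorted(p for p, t in self.matrices if t == timepoint)

    def matrix(self, participant: str, timepoint: int) -> np.ndarray:
        return self.matrices[(participant, timepoint)]

    def __len__(self) -> int:
        return len(self.matrices)

    def n_observations(self) -> int:
        return len(self.matrices)

    # -- IO ----------------------------------------------------------------
    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table of all nonzero upper-triangle weights."""
        ids = self.region_table.region_ids
        rows = []
        for (pid, tp) in sorted(self.matrices):
            mat = self.matrices[(pid, tp)]
            iu, ju = np.nonzero(np.triu(mat, k=1))
            for i, j in zip(iu, ju):
                rows.append((pid, tp, ids[i], ids[j], mat[i, j]))
        return pd.DataFrame(
            rows, columns=["participant", "timepoint", "region_a", "region_b", "weight"]
        )

    def write(self, path: str | Path) -> None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        self.to_long_frame().to_csv(path, sep=sep, index=False)


def read_connectomes(path: str | Path, regions: RegionTable) -> LongitudinalConnectomes:
    """Read a long-format connectome table (TSV or CSV).

    Expected columns: participant, timepoint, region_a, region_b, weight.
    Directed duplicates (a->b and b->a) are symmetrized by their mean;
    unlisted pairs are zero.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    return connectomes_from_frame(frame, regions)


def connectomes_from_frame(
    frame: pd.DataFrame, regions: RegionTable
) -> LongitudinalConnectomes:
    required = {"participant", "timepoint", "region_a", "region_b", "weight"}
    missing = required - set(frame.columns)
    if missing:
        raise ConnectomeError(f"missing columns: {sorted(missing)}")
    if (frame["weight"] < 0).any():
        bad = frame.loc[frame["weight"] < 0].iloc[0]
        raise ConnectomeError(
            f"negative weight {bad['weight']} for pair "
            f"({bad['region_a']}, {bad['region_b']})"
        )
    for col in ("region_a", "region_b"):
        unknown = set(frame[col]) - set(regions.region_ids)
        if unknown:
            raise ConnectomeError(f"unknown region(s): {sorted(unknown)}")
    tp = pd.to_numeric(frame["timepoint"]).astype(int)
    bad_tp = set(tp) - set(VALID_TIMEPOINTS)
    if bad_tp:
        raise ConnectomeError(f"timepoints {sorted(bad_tp)} not in {VALID_TIMEPOINTS}")

    n = regions.n_regions
    pos = {r: regions.position(r) for r in regions.region_ids}
    mats: dict[tuple[str, int], np.ndarray] = {}
    counts: dict[tuple[str, int], np.ndarray] = {}
    for (pid, t), grp in frame.assign(timepoint=tp).groupby(
        ["participant", "timepoint"], sort=True
    ):
        acc = np.zeros((n, n))
        cnt = np.zeros((n, n), dtype=int)
        ia = grp["region_a"].map(pos).to_numpy()
        ib = grp["region_b"].map(pos).to_numpy()
        w = grp["weight"].to_numpy(float)
        if np.any(ia == ib):
            raise ConnectomeError(f"({pid},{t}): self-loop listed")
        np.add.at(acc, (ia, ib), w)
        np.add.at(cnt, (ia, ib), 1)
        # mean of the two directed entries where both are present
        both = (cnt > 0) & (cnt.T > 0)
        sym = np.where(both, (acc + acc.T) / np.maximum(cnt + cnt.T, 1), acc + acc.T)
        np.fill_diagonal(sym, 0.0)
        mats[(str(pid), int(t))] = sym
        counts[(str(pid), int(t))] = cnt
    return LongitudinalConnectomes(regions, mats)


def read_matrix_csv(
    path: str | Path, regions: RegionTable, participant: str, timepoint: int
) -> tuple[tuple[str, int], np.ndarray]:
    """Read one square-matrix CSV (first row/column = region ids)."""
    frame = pd.read_csv(path, index_col=0)
    ids = regions.region_ids
    try:
        frame = frame.loc[ids, ids]
    except KeyError as exc:
        raise ConnectomeError(f"matrix CSV does not cover region table: {exc}") from exc
    mat = frame.to_numpy(float)
    mat = (mat + mat.T) / 2.0
    np.fill_diagonal(mat, 0.0)
    return (participant, int(timepoint)), mat


# -- candidate edges and thresholding --------------------------------------

def candidate_edges(regions: RegionTable) -> list[Edge]:
    """All analyzable region pairs, in lexicographic order.

    Intra-hemispheric cortical-cortical pairs (both hemispheres) plus every
    cortical-to-CC pair; CC-CC and direct interhemispheric cortical-cortical
    pairs are excluded.
    """
    edges: list[Edge] = []
    for hemi in ("L", "R"):
        for a, b in itertools.combinations(regions.cortical_ids(hemi), 2):
            edges.append(_canon(a, b))
    cc = regions.cc_ids()
    for a in regions.cortical_ids():
        for b in cc:
            edges.append(_canon(a, b))
    return sorted(set(edges))


@dataclass(frozen=True)
class EdgeMask:
    """The retained candidate edge set after group-level thresholding."""

    edges: tuple[Edge, ...]
    retention_fraction: float
    mean_weights: pd.Series  # indexed by all candidate edges
    region_table: RegionTable

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/column position arrays for vectorized weight extraction."""
        i = np.array([self.region_table.position(a) for a, _ in self.edges])
        j = np.array([self.region_table.position(b) for _, b in self.edges])
        return i, j

    def edge_weights(self, matrix: np.ndarray) -> np.ndarray:
        i, j = self.index_arrays()
        return matrix[i, j]

    def to_frame(self) -> pd.DataFrame:
        retained = set(self.edges)
        rows = [
            (a, b, float(self.mean_weights[(a, b)]), (a, b) in retained)
            for (a, b) in self.mean_weights.index
        ]
        return pd.DataFrame(rows, columns=["region_a", "region_b", "mean_weight", "retained"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def group_threshold(
    data: LongitudinalConnectomes, fraction: float = 0.30
) -> EdgeMask:
    """Retain the strongest ``fraction`` of candidate edges.

    Edges are ranked by their mean weight across all (participant, timepoint)
    matrices; exactly ``round(fraction * n_candidates)`` edges are retained
    (half-up rounding), with ties at the cutoff broken toward the
    lexicographically smallest region pair.  One mask applies to every
    participant and timepoint, so the same edges are compared longitudinally.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if not data.matrices:
        raise ValueError("no matrices to threshold")
    cands = candidate_edges(data.region_table)
    i = np.array([data.region_table.position(a) for a, _ in cands])
    j = np.array([data.region_table.position(b) for _, b in cands])
    total = np.zeros(len(cands))
    for mat in data.matrices.values():
        total += mat[i, j]
    means = total / len(data.matrices)
    n_keep = int(math.floor(fraction * len(cands) + 0.5))
    order = sorted(range(len(cands)), key=lambda k: (-means[k], cands[k]))
    kept = tuple(sorted(cands[k] for k in order[:n_keep]))
    mean_series = pd.Series(means, index=pd.Index(cands, tupleize_cols=False))
    return EdgeMask(kept, fraction, mean_series, data.region_table)


# -- hemispheric strengths and lateralization ------------------------------

@dataclass(frozen=True)
class HemisphericSummary:
    """Network strengths per hemisphere and the lateralization index.

    ``left_strength``/``right_strength`` sum retained intra-hemispheric
    cortical-cortical weights; ``interhemispheric_strength`` sums retained
    cortical-to-CC weights (the transcallosal approximation).  The
    lateralization index is the standard laterality quotient
    ``(L - R) / (L + R)``, 0 when both strengths are zero.
    """

    left_strength: float
    right_strength: float
    interhemispheric_strength: float

    @property
    def lateralization_index(self) -> float:
        tot = self.left_strength + self.right_strength
        if tot <= 0:
            return 0.0
        return (self.left_strength - self.right_strength) / tot


def classify_edge(edge: Edge, regions: RegionTable) -> str:
    """Classify a retained edge as 'left', 'right' or 'interhemispheric'."""
    a, b = edge
    if regions.is_cc(a) or regions.is_cc(b):
        return "interhemispheric"
    return "left" if regions.hemisphere(a) == "L" else "right"


def hemispheric_summary(
    matrix: np.ndarray, mask: EdgeMask, regions: RegionTable
) -> HemisphericSummary:
    """Sum retained edge weights into hemispheric and interhemispheric strengths."""
    w = mask.edge_weights(matrix)
    cls = np.array([classify_edge(e, regions) for e in mask.edges])
    return HemisphericSummary(
        left_strength=float(w[cls == "left"].sum()),
        right_strength=float(w[cls == "right"].sum()),
        interhemispheric_strength=float(w[cls == "interhemispheric"].sum()),
    )


def connected_retained_edges(
    mask: EdgeMask,
    regions: RegionTable,
    n_edges: int,
    kind: str = "any",
    exclude: set[Edge] | frozenset[Edge] = frozenset(),
    min_margin: float = 0.0,
) -> tuple[Edge, ...]:
    """A deterministic connected set of ``n_edges`` retained edges.

    Grows a connected subgraph over retained edges of the requested class
    (``left``/``right``/``interhemispheric``/``any``) by lexicographic
    breadth-first expansion from the smallest eligible edge.  With
    ``min_margin`` > 0 only edges whose group-mean weight exceeds the
    retention cutoff by that margin are eligible (useful for planting
    effects that must stay retained under perturbation).
    """
    cutoff = min(float(mask.mean_weights[e]) for e in mask.edges)
    eligible = [
        e for e in mask.edges
        if e not in exclude
        and (kind == "any" or classify_edge(e, regions) == kind)
        and float(mask.mean_weights[e]) >= cutoff + min_margin
    ]
    if len(eligible) < n_edges:
        raise ValueError(
            f"only {len(eligible)} eligible {kind} edges, need {n_edges}"
        )
    adjacency: dict[str, list[Edge]] = {}
    for e in eligible:
        for node in e:
            adjacency.setdefault(node, []).append(e)
    for start in eligible:
        chosen = [start]
        chosen_set = {start}
        nodes = set(start)
        while len(chosen) < n_edges:
            frontier = sorted(
                e for node in nodes for e in adjacency[node]
                if e not in chosen_set
            )
            if not frontier:
                break
            nxt = frontier[0]
            chosen.append(nxt)
            chosen_set.add(nxt)
            nodes.update(nxt)
        if len(chosen) == n_edges:
            return tuple(sorted(chosen))
    raise ValueError(f"no connected set of {n_edges} {kind} edges found")


def strength_table(
    data: LongitudinalConnectomes, mask: EdgeMask
) -> pd.DataFrame:
    """Per (participant, timepoint) hemispheric strengths and LI, long format."""
    rows = []
    for (pid, tp) in sorted(data.matrices):
        s = hemispheric_summary(data.matrix(pid, tp), mask, data.region_table)
        rows.append(
            (pid, tp, s.left_strength, s.right_strength,
             s.interhemispheric_strength, s.lateralization_index)
        )
    return pd.DataFrame(
        rows,
        columns=["participant", "timepoint", "left", "right",
                 "interhemispheric", "lateralization_index"],
    )
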