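"""Intensity-correlation clustering of wedge datasets.

Wedges are compared by the Pearson correlation of their internally merged
(Friedel-folded) unique intensities on common reflections; hierarchical
agglomeration uses Ward's minimum-variance criterion on the distance
d = sqrt(1 - CC^2), applied to the raw correlation distances through the
Lance-Williams update (the convention of intensity-based multi-crystal
clustering pipelines, without a squared-Euclidean embedding check).  Nodes
above the isomorphic threshold - 0.7 times the maximum Ward distance - are
flagged as potentially polymorphic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scale_merge import three_run_merge, merging_stats
from .sim_core import WedgeDataset

__all__ = [
    "CCMatrix",
    "Dendrogram",
    "pairwise_cc",
    "ward_cluster",
    "isomorphic_threshold",
    "select_clusters",
    "resolve_indexing_ambiguity",
    "cc_to_distance",
]


def cc_to_distance(cc):
    """Ward input distance d = sqrt(1 - CC^2); maps CC in [-1,1] to [0,1]."""
    return np.sqrt(np.clip(1.0 - np.square(cc), 0.0, 1.0))


@dataclass
class CCMatrix:
    """Pairwise intensity correlations between wedges.

    ``cc`` is symmetric with unit diagonal; entries with fewer than
    ``min_common`` common uniques are NaN and are imputed with the matrix's
    maximum distance when clustering.
    """

    wedge_ids: list[str]
    cc: np.ndarray
    n_common: np.ndarray
    min_common: int

    def distances(self) -> np.ndarray:
        """Distance matrix with missing entries imputed by the maximum distance."""
        d = cc_to_distance(self.cc)
        np.fill_diagonal(d, 0.0)
        if np.isnan(d).any():
            fill = np.nanmax(d) if np.isfinite(np.nanmax(d)) else 1.0
            d = np.where(np.isnan(d), fill, d)
        return d


@dataclass
class Dendrogram:
    """Ward agglomeration tree over wedges.

    Internal node t (t = 0..n-2) has id n + t, children ids, height (Ward
    distance) and the member leaf indices.  Heights are non-decreasing from
    leaves to root.
    """

    leaf_ids: list[str]
    children: list[tuple[int, int]]
    heights: list[float]
    members: list[list[int]]
    threshold: float | None = None
    flags: dict = field(default_factory=dict)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def node_members(self, node_id: int) -> list[int]:
        if node_id < self.n_leaves:
            return [node_id]
        return self.members[node_id - self.n_leaves]

    def node_height(self, node_id: int) -> float:
        if node_id < self.n_leaves:
            return 0.0
        return self.heights[node_id - self.n_leaves]

    def max_height(self) -> float:
        if not self.heights:
            raise ValueError("dendrogram has no internal node")
        return max(self.heights)

    def cut(self, height: float) -> np.ndarray:
        """Cluster label per leaf from cutting all links above ``height``."""
        n = self.n_leaves
        labels = -np.ones(n, dtype=int)
        next_label = 0
        # walk nodes from the root down; a node below the cut is one cluster
        consumed = set()
        for t in range(len(self.children) - 1, -1, -1):
            node = n + t
            if node in consumed:
                continue
            if self.heights[t] <= height:
                for leaf in self.members[t]:
                    labels[leaf] = next_label
                next_label += 1
                stack = list(self.children[t])
                while stack:
                    ch = stack.pop()
                    consumed.add(ch)
                    if ch >= n:
                        stack.extend(self.children[ch - n])
        for leaf in range(n):
            if labels[leaf] < 0:
                labels[leaf] = next_label
                next_label += 1
        return labels

    def node_list(self) -> list[dict]:
        nodes = [
            {"id": i, "height": 0.0, "children": [], "members": [i]}
            for i in range(self.n_leaves)
        ]
        for t, ((a, b), h) in enumerate(zip(self.children, self.heights)):
            nodes.append(
                {
                    "id": self.n_leaves + t,
                    "height": float(h),
                    "children": [int(a), int(b)],
                    "members": [int(m) for m in self.members[t]],
                }
            )
        return nodes

    @classmethod
    def from_node_list(cls, leaf_ids, nodes, threshold=None) -> "Dendrogram":
        n = len(leaf_ids)
        internal = sorted((nd for nd in nodes if nd["children"]), key=lambda nd: nd["id"])
        return cls(
            leaf_ids=list(leaf_ids),
            children=[tuple(nd["children"]) for nd in internal],
            heights=[float(nd["height"]) for nd in internal],
            members=[list(nd["members"]) for nd in internal],
            threshold=threshold,
        )


# ---------------------------------------------------------------------------
# pairwise correlations
# ---------------------------------------------------------------------------


def _internal_merge(wedge: WedgeDataset) -> pd.Series:
    """Friedel-folded unweighted mean intensity per unique key of one wedge."""
    obs = wedge.observations
    if len(obs) == 0:
        raise ValueError(f"wedge {wedge.wedge_id} has no observations")
    return obs.groupby(["kh", "kk", "kl"])["i_obs"].mean()


def pairwise_cc(wedges: list[WedgeDataset], min_common: int = 10) -> CCMatrix:
    """Pairwise Pearson CC on common unique intensities (wedges pre-merged)."""
    if len(wedges) < 2:
        raise ValueError("need at least two wedges")
    merged = [_internal_merge(w) for w in wedges]
    all_keys = pd.Index(sorted(set().union(*[set(m.index) for m in merged])))
    mat = np.full((len(all_keys), len(wedges)), np.nan)
    for j, m in enumerate(merged):
        mat[all_keys.get_indexer(m.index), j] = m.values
    n = len(wedges)
    cc = np.eye(n)
    n_common = np.zeros((n, n), dtype=int)
    have = ~np.isnan(mat)
    for i in range(n):
        for j in range(i + 1, n):
            both = have[:, i] & have[:, j]
            m = int(both.sum())
            n_common[i, j] = n_common[j, i] = m
            if m < min_common:
                cc[i, j] = cc[j, i] = np.nan
                continue
            a, b = mat[both, i], mat[both, j]
            if a.std() == 0 or b.std() == 0:
                cc[i, j] = cc[j, i] = np.nan
                continue
            cc[i, j] = cc[j, i] = float(np.corrcoef(a, b)[0, 1])
    np.fill_diagonal(n_common, [len(m) for m in merged])
    return CCMatrix(
        wedge_ids=[w.wedge_id for w in wedges], cc=cc, n_common=n_common,
        min_common=min_common,
    )


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------


def ward_cluster(ccmatrix: CCMatrix | np.ndarray, wedge_ids=None) -> Dendrogram:
    """Ward agglomeration via the Lance-Williams update.

    Accepts a :class:`CCMatrix` (distances d = sqrt(1-CC^2), missing entries
    imputed) or a raw symmetric distance matrix.  Ties are broken
    deterministically by the smallest leaf id contained in the candidate
    pair, so permuting the input order cannot change memberships.
    """
    if isinstance(ccmatrix, CCMatrix):
        dist = ccmatrix.distances()
        wedge_ids = ccmatrix.wedge_ids
        if np.isnan(ccmatrix.cc).all(axis=0).any():
            pass  # fully-missing rows are imputed at max distance; still clusterable
    else:
        dist = np.asarray(ccmatrix, dtype=float)
        if wedge_ids is None:
            wedge_ids = [str(i) for i in range(len(dist))]
    n = len(dist)
    if n < 2:
        raise ValueError("clustering needs at least two leaves")
    d2 = np.square(dist).astype(float)
    active = list(range(n))  # current cluster node ids
    sizes = {i: 1 for i in range(n)}
    minleaf = {i: i for i in range(n)}
    cur = {}
    for ii, i in enumerate(active):
        for j in active[ii + 1 :]:
            cur[(i, j)] = d2[i][j]
    children: list[tuple[int, int]] = []
    heights: list[float] = []
    members: list[list[int]] = []
    member_of = {i: [i] for i in range(n)}
    next_id = n
    while len(active) > 1:
        best = None
        best_key = None
        for ii, i in enumerate(active):
            for j in active[ii + 1 :]:
                v = cur[(i, j) if i < j else (j, i)]
                key = (v, min(minleaf[i], minleaf[j]), max(minleaf[i], minleaf[j]))
                if best_key is None or key < best_key:
                    best_key = key
                    best = (i, j)
        i, j = best
        h = float(np.sqrt(max(best_key[0], 0.0)))
        si, sj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        # Lance-Williams (Ward) on squared distances
        for k in active:
            if k in (i, j):
                continue
            sk = sizes[k]
            dik = cur[(i, k) if i < k else (k, i)]
            djk = cur[(j, k) if j < k else (k, j)]
            dij = cur[(i, j) if i < j else (j, i)]
            val = (
                (si + sk) * dik + (sj + sk) * djk - sk * dij
            ) / (si + sj + sk)
            cur[(k, new)] = val
        active = [k for k in active if k not in (i, j)] + [new]
        sizes[new] = si + sj
        minleaf[new] = min(minleaf[i], minleaf[j])
        member_of[new] = sorted(member_of[i] + member_of[j])
        children.append((i, j))
        heights.append(h)
        members.append(member_of[new])
    if any(b < a for a, b in zip(heights, heights[1:])):
        raise AssertionError("Ward heights must be non-decreasing")
    return Dendrogram(
        leaf_ids=list(wedge_ids), children=children, heights=heights, members=members
    )


def isomorphic_threshold(dendrogram: Dendrogram, factor: float = 0.7) -> float:
    """Threshold = factor x maximum Ward distance; flags nodes above it.

    Cluster nodes merging above this height may mix polymorphic,
    non-isomorphous data.
    """
    if not dendrogram.heights:
        raise ValueError("threshold undefined for a single leaf")
    thr = factor * dendrogram.max_height()
    dendrogram.threshold = thr
    dendrogram.flags["potentially_polymorphic"] = [
        dendrogram.n_leaves + t
        for t, h in enumerate(dendrogram.heights)
        if h > thr
    ]
    return thr


# ---------------------------------------------------------------------------
# cluster selection
# ---------------------------------------------------------------------------


def select_clusters(
    dendrogram: Dendrogram,
    wedges: list[WedgeDataset],
    completeness_min: float = 95.0,
    multiplicity_min: float = 5.0,
    anomalous: bool = False,
    ground_truth=None,
    min_wedges: int = 2,
) -> list[dict]:
    """Merge every internal node and keep those meeting the selection criteria.

    A node qualifies when completeness >= completeness_min and (anomalous
    multiplicity if ``anomalous`` else multiplicity) >= multiplicity_min.
    ``ground_truth`` (or the wedge metadata) defines the possible unique set
    for completeness.  Returns one dict per qualifying node with the merged
    dataset attached.
    """
    from .sim_core import generate_ground_truth  # local import to avoid cycle

    if ground_truth is None:
        w0 = wedges[0]
        ground_truth = generate_ground_truth(
            w0.cell, w0.pointgroup, w0.d_min or float(w0.observations["d"].min()),
            mode="wilson", seed=0,
        )
    out = []
    for t, mem in enumerate(dendrogram.members):
        if len(mem) < min_wedges:
            continue
        sub = [wedges[i] for i in mem]
        try:
            result = three_run_merge(sub, anomalous=anomalous)
        except ValueError:
            continue
        stats = merging_stats(result.merged, ground_truth)
        mult = stats["multiplicity"]
        ok = stats["completeness"] >= completeness_min and mult >= multiplicity_min
        node = {
            "node_id": dendrogram.n_leaves + t,
            "n_wedges": len(mem),
            "height": dendrogram.heights[t],
            "above_threshold": (
                dendrogram.threshold is not None
                and dendrogram.heights[t] > dendrogram.threshold
            ),
            "completeness": stats["completeness"],
            "multiplicity": mult,
            "qualifies": ok,
            "merged": result.merged,
        }
        if ok:
            out.append(node)
    return out


# ---------------------------------------------------------------------------
# indexing-ambiguity resolution
# ---------------------------------------------------------------------------


def resolve_indexing_ambiguity(
    wedges: list[WedgeDataset],
    ambiguity_ops: list[np.ndarray],
    max_iter: int = 50,
) -> tuple[list[WedgeDataset], np.ndarray]:
    """Break an indexing ambiguity by iterative consensus reindexing.

    ``ambiguity_ops`` lists candidate reindexing matrices (including the
    identity).  A greedy seeding pass breaks the symmetry (the first wedge
    keeps its indexing; each following wedge takes the operator maximizing
    its correlation with the growing consensus), after which rounds of
    leave-one-out reassignment run until stable.  The solution is reported
    up to a global operator.
    """
    ops = [np.asarray(m, dtype=int) for m in ambiguity_ops]
    for m in ops:
        if abs(round(float(np.linalg.det(m)))) != 1:
            raise ValueError("reindexing operators must be invertible (det +/-1)")
    n_ops = len(ops)
    pg = wedges[0].pointgroup
    from .symmetry import bijvoet_key

    # per wedge per op: internally merged intensities keyed by folded unique
    tables: list[list[pd.Series]] = []
    for w in wedges:
        hkl = w.observations[["h", "k", "l"]].values
        per_op = []
        for m in ops:
            keys, _ = bijvoet_key(pg, hkl @ m.T)
            df = pd.DataFrame(keys, columns=["kh", "kk", "kl"])
            df["i"] = w.observations["i_obs"].values
            per_op.append(df.groupby(["kh", "kk", "kl"])["i"].mean())
        tables.append(per_op)

    def _cc(t: pd.Series, ref_sum: dict, ref_n: dict, exclude: pd.Series | None):
        own_vals, ref_vals = [], []
        for key, val in t.items():
            r = ref_sum.get(key, 0.0)
            c = ref_n.get(key, 0)
            if exclude is not None and key in exclude.index:
                r -= exclude[key]
                c -= 1
            if c > 0:
                own_vals.append(val)
                ref_vals.append(r / c)
        if len(own_vals) < 3 or np.std(own_vals) == 0 or np.std(ref_vals) == 0:
            return None
        return float(np.corrcoef(own_vals, ref_vals)[0, 1])

    def _add(t: pd.Series, ref_sum: dict, ref_n: dict, sign: int = 1):
        for key, val in t.items():
            ref_sum[key] = ref_sum.get(key, 0.0) + sign * val
            ref_n[key] = ref_n.get(key, 0) + sign

    # greedy seeding
    assign = np.zeros(len(wedges), dtype=int)
    ref_sum: dict = {}
    ref_n: dict = {}
    _add(tables[0][0], ref_sum, ref_n)
    for j in range(1, len(wedges)):
        best_cc, best_op = -np.inf, 0
        for o in range(n_ops):
            cc = _cc(tables[j][o], ref_sum, ref_n, exclude=None)
            if cc is not None and cc > best_cc:
                best_cc, best_op = cc, o
        assign[j] = best_op
        _add(tables[j][best_op], ref_sum, ref_n)

    # leave-one-out refinement
    for _ in range(max_iter):
        changed = False
        for j in range(len(wedges)):
            own = tables[j][assign[j]]
            best_cc, best_op = -np.inf, assign[j]
            for o in range(n_ops):
                cc = _cc(tables[j][o], ref_sum, ref_n, exclude=own)
                if cc is not None and cc > best_cc:
                    best_cc, best_op = cc, o
            if best_op != assign[j]:
                _add(own, ref_sum, ref_n, sign=-1)
                _add(tables[j][best_op], ref_sum, ref_n)
                assign[j] = best_op
                changed = True
        if not changed:
            break

    out = []
    for j, w in enumerate(wedges):
        if assign[j] == 0 and np.array_equal(ops[0], np.eye(3, dtype=int)):
            out.append(w)
            continue
        m = ops[assign[j]]
        obs = w.observations.copy()
        hkl = obs[["h", "k", "l"]].values @ m.T
        keys, signs = bijvoet_key(pg, hkl)
        obs[["h", "k", "l"]] = hkl
        obs[["kh", "kk", "kl"]] = keys
        obs["sign"] = signs
        out.append(w.with_observations(obs))
    return out, assign
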