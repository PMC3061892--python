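"""Duplication-event inference from a pairwise age matrix.

Under a molecular clock the pairwise duplication ages of a tandem family are
(approximately) ultrametric, and average-linkage agglomeration (UPGMA) is the
canonical way to read off the sequence and times of duplication events: each
merge is one event, its height (already in years — the clock conversion has
done the factor-of-two halving) is the event time. Deviations from
ultrametricity are reported as a coefficient of variation, never repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class EventError(ValueError):
    pass


@dataclass(frozen=True)
class DuplicationEvent:
    time_years: float
    members: tuple[str, ...]  # leaves of the clade created by this merge


@dataclass
class _Node:
    name: str | None
    height: float
    children: tuple["_Node", ...] = ()
    leaves: tuple[str, ...] = ()


@dataclass
class DuplicationHistory:
    gene_names: list[str]
    events: list[DuplicationEvent] = field(default_factory=list)
    ultrametricity_cv: float = 0.0
    _root: _Node | None = None

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def event_times(self) -> list[float]:
        return [e.time_years for e in self.events]


def infer_events(age_matrix, gene_names: list[str]) -> DuplicationHistory:
    """UPGMA agglomeration of a symmetric age matrix into timed events.

    Each merge emits an event at the average-linkage age of the two merged
    clades. Ties are broken deterministically by the lexicographically
    smallest member name of the candidate pairs, so permuting the input
    order never changes the result.
    """
    D = np.asarray(age_matrix, dtype=float)
    n = len(gene_names)
    if D.shape != (n, n):
        raise EventError(f"matrix shape {D.shape} does not fit {n} genes")
    if n < 2:
        raise EventError("need at least 2 genes")
    if np.isnan(D).any():
        raise EventError("age matrix contains NaN")
    if (D < 0).any():
        raise EventError("age matrix contains negative ages")
    if not np.allclose(D, D.T):
        raise EventError("age matrix is not symmetric")
    if not np.allclose(np.diag(D), 0):
        raise EventError("age matrix diagonal must be zero")

    # Cluster state: leaves per cluster (sorted), node, size.
    clusters: dict[int, tuple[tuple[str, ...], _Node]] = {
        i: ((gene_names[i],), _Node(gene_names[i], 0.0, (), (gene_names[i],)))
        for i in range(n)
    }
    # Average-linkage distances between clusters, keyed by frozenset of ids.
    dist = {
        frozenset((i, j)): D[i, j]
        for i in range(n) for j in range(i + 1, n)
    }
    name_by_leaves = {}  # original pairwise ages for cv computation
    events: list[DuplicationEvent] = []
    cvs: list[float] = []
    next_id = n
    idx_of = {gene_names[i]: i for i in range(n)}

    while len(clusters) > 1:
        # pick min distance; tie-break by smallest member name
        best = min(
            dist.items(),
            key=lambda kv: (
                kv[1],
                min(min(clusters[c][0]) for c in kv[0]),
                sorted(min(clusters[c][0]) for c in kv[0]),
            ),
        )
        (pair, h) = best
        a, b = sorted(pair, key=lambda c: min(clusters[c][0]))
        leaves_a, node_a = clusters[a]
        leaves_b, node_b = clusters[b]
        merged_leaves = tuple(sorted(leaves_a + leaves_b))
        # within-merge cross-pair ages, for the ultrametricity report
        cross = np.array(
            [D[idx_of[x], idx_of[y]] for x in leaves_a for y in leaves_b]
        )
        mean = cross.mean()
        cvs.append(float(cross.std() / mean) if mean > 0 else 0.0)
        node = _Node(None, h, (node_a, node_b), merged_leaves)
        events.append(DuplicationEvent(h, merged_leaves))
        na, nb = len(leaves_a), len(leaves_b)
        del clusters[a], clusters[b]
        new_dist = {}
        for c in clusters:
            d_ac = dist[frozenset((a, c))]
            d_bc = dist[frozenset((b, c))]
            new_dist[frozenset((next_id, c))] = (na * d_ac + nb * d_bc) / (na + nb)
        dist = {
            k: v for k, v in dist.items() if a not in k and b not in k
        }
        dist.update(new_dist)
        clusters[next_id] = (merged_leaves, node)
        next_id += 1

    root = next(iter(clusters.values()))[1]
    events.sort(key=lambda e: (e.time_years, e.members))
    history = DuplicationHistory(
        gene_names=list(gene_names),
        events=events,
        ultrametricity_cv=float(max(cvs)) if cvs else 0.0,
        _root=root,
    )
    return history


def to_newick(history: DuplicationHistory, units: str = "Myr") -> str:
    """Serialize the event tree as Newick with ultrametric branch lengths.

    Branch lengths are in million years by default (``units="years"`` keeps
    years). Every leaf-to-root path length equals the root event time.
    """
    scale = 1e-6 if units == "Myr" else 1.0
    root = history._root
    if root is None:
        raise EventError("history carries no tree")

    def render(node: _Node, parent_height: float) -> str:
        bl = (parent_height - node.height) * scale
        if not node.children:
            return f"{node.name}:{bl:.10g}"
        inner = ",".join(render(c, node.height) for c in node.children)
        return f"({inner}):{bl:.10g}"

    inner = ",".join(render(c, root.height) for c in root.children)
    return f"({inner});"
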