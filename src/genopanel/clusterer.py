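"""Place a projected query among panel accessions.

Provides ranked Euclidean distances in PC space, an agglomerative
complete-linkage tree over panel accessions (plus the query, when given),
and newick / dendrogram export. "Closest accession" is defined by raw
PC-space distance, not dendrogram adjacency; the two agree for the first
merge. The agglomeration is written here rather than delegated so the
tie rule (lowest (i, j) cluster-index pair) is pinned and the whole tree
is deterministic given input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .panel_builder import ReferencePanel
from .query_mapper import QueryProfile

_LINKAGES = ("complete", "single", "average")


@dataclass
class DistanceReport:
    """Ranked (label, distance, group) rows for one placed query."""

    query_label: str
    rows: list[tuple[str, float, str]]

    @property
    def k(self) -> int:
        return len(self.rows)

    @property
    def closest(self) -> str:
        return self.rows[0][0]

    def to_tsv(self) -> str:
        out = ["rank\tlabel\tdistance\tgroup"]
        for rank, (label, dist, group) in enumerate(self.rows, start=1):
            out.append(f"{rank}\t{label}\t{dist:.10g}\t{group}")
        return "\n".join(out) + "\n"


@dataclass
class LinkageTree:
    """An agglomerative tree in scipy linkage-matrix form plus leaf labels.

    ``merges`` has one row ``[a, b, height, size]`` per merge; ``a`` and
    ``b`` index leaves (< n) or earlier merges (n + row).
    """

    merges: np.ndarray  # (n_leaves - 1, 4) float64
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def heights(self) -> np.ndarray:
        return self.merges[:, 2].copy()


def rank_distances(panel: ReferencePanel, scores: np.ndarray, k: int = 10,
                   query_label: str = "query") -> DistanceReport:
    """Top-k panel accessions by Euclidean distance in PC space.

    Ties are ordered lexicographically by accession label.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    scores = np.asarray(scores, dtype=np.float64).ravel()
    if scores.shape != (panel.model.n_components,):
        raise ParameterError(
            f"query score vector has {scores.shape[0]} components but the "
            f"panel has {panel.model.n_components}"
        )
    dists = np.linalg.norm(panel.scores - scores[:, None], axis=0)
    order = sorted(range(panel.n_accessions),
                   key=lambda i: (dists[i], panel.labels[i]))
    rows = [
        (panel.labels[i], float(dists[i]), panel.group_of(panel.labels[i]) or "")
        for i in order[: min(k, panel.n_accessions)]
    ]
    return DistanceReport(query_label=query_label, rows=rows)


def _agglomerate(dist: np.ndarray, method: str = "complete") -> np.ndarray:
    """Naive deterministic agglomeration over a square distance matrix.

    At every step the minimum-distance active pair is merged; exact ties
    go to the lowest (i, j) cluster-index pair, where merged clusters get
    ids n, n+1, ... in merge order (scipy convention).
    """
    if method not in _LINKAGES:
        raise ParameterError(f"linkage must be one of {_LINKAGES}, got {method!r}")
    n = dist.shape[0]
    m = 2 * n - 1
    big = np.full((m, m), np.inf)
    big[:n, :n] = dist
    np.fill_diagonal(big, np.inf)
    active = np.zeros(m, dtype=bool)
    active[:n] = True
    sizes = np.ones(m)
    merges = np.empty((n - 1, 4))
    for step in range(n - 1):
        ids = np.flatnonzero(active)
        sub = big[np.ix_(ids, ids)]
        # upper triangle only, so ties resolve to the lowest (i, j) pair
        iu, ju = np.triu_indices(len(ids), k=1)
        flat = sub[iu, ju]
        best = int(np.argmin(flat))
        i, j = int(ids[iu[best]]), int(ids[ju[best]])
        h = float(flat[best])
        new = n + step
        if method == "complete":
            merged = np.maximum(big[i], big[j])
        elif method == "single":
            merged = np.minimum(big[i], big[j])
        else:  # average (UPGMA)
            merged = (sizes[i] * big[i] + sizes[j] * big[j]) / (sizes[i] + sizes[j])
        big[new, :] = merged
        big[:, new] = merged
        big[new, new] = np.inf
        active[i] = active[j] = False
        active[new] = True
        sizes[new] = sizes[i] + sizes[j]
        merges[step] = (i, j, h, sizes[new])
    return merges


def build_tree(panel: ReferencePanel, query: QueryProfile | None = None,
               method: str = "complete") -> LinkageTree:
    """Agglomerative tree on Euclidean PC distances over panel (+ query)."""
    points = panel.scores.T
    labels = list(panel.labels)
    if query is not None:
        if query.scores is None:
            raise ParameterError("query profile has no scores; project it first")
        points = np.vstack([points, np.asarray(query.scores, dtype=np.float64)])
        label = query.label
        while label in labels:
            label += "*"
        labels.append(label)
    if len(labels) < 2:
        raise ParameterError("a tree needs at least 2 leaves")
    diff = points[:, None, :] - points[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    return LinkageTree(merges=_agglomerate(dist, method), labels=labels)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _sanitize(label: str) -> str:
    for ch in "():;, '\"\t\n":
        label = label.replace(ch, "_")
    return label


def to_newick(tree: LinkageTree) -> str:
    """Newick string with branch lengths from merge-height differences."""
    n = tree.n_leaves
    height = {i: 0.0 for i in range(n)}
    for row in range(n - 1):
        height[n + row] = float(tree.merges[row, 2])

    def render(node: int, branch: float) -> str:
        if node < n:
            return f"{_sanitize(tree.labels[node])}:{branch:.12g}"
        a, b, h, _ = tree.merges[node - n]
        inner = ",".join(render(int(c), h - height[int(c)]) for c in (a, b))
        return f"({inner}):{branch:.12g}"

    a, b, h, _ = tree.merges[-1]
    inner = ",".join(render(int(c), h - height[int(c)]) for c in (a, b))
    return f"({inner});"


def plot_dendrogram(tree: LinkageTree, path: str, highlight: str | None = None) -> None:
    """Render the tree as a vector image, marking the highlighted leaf."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    if highlight is not None and highlight not in tree.labels:
        raise ParameterError(
            f"unknown highlight label {highlight!r}; valid labels: "
            f"{sorted(tree.labels)}"
        )
    fig, ax = plt.subplots(figsize=(max(6.0, 0.22 * tree.n_leaves), 6.0))
    dendrogram(tree.merges, labels=tree.labels, ax=ax,
               leaf_rotation=90, color_threshold=0.0)
    for tick in ax.get_xticklabels():
        if highlight is not None and tick.get_text() == highlight:
            tick.set_color("red")
            tick.set_fontweight("bold")
    ax.set_ylabel("complete-linkage height (PC-space distance)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def export_tree(tree: LinkageTree, highlight: str | None = None,
                newick_path: str | None = None,
                image_path: str | None = None) -> str:
    """Export a tree: returns the newick string, optionally writing files."""
    if highlight is not None and highlight not in tree.labels:
        raise ParameterError(
            f"unknown highlight label {highlight!r}; valid labels: "
            f"{sorted(tree.labels)}"
        )
    newick = to_newick(tree)
    if newick_path is not None:
        with open(newick_path, "w") as fh:
            fh.write(newick + "\n")
    if image_path is not None:
        plot_dendrogram(tree, image_path, highlight=highlight)
    return newick
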