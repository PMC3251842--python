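"""Unsupervised hierarchical clustering of signature expression and
GenePattern-style heatmap/clustered-table export.

Defaults are the conventional expression-analysis choices: Pearson
correlation distance (1 − r) with average linkage.  Items are canonicalized
to lexicographic label order before linkage, so the tree is invariant to the
input ordering of samples/probes up to that deterministic tie rule.

The heatmap colours *expression*, which is inverse to ΔCt: the colour map is
applied to negated ΔCt so that red = high expression and blue = low, and the
sign convention is printed in the figure margin.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # headless, deterministic rendering
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .ct import DeltaCtMatrix, write_gct
from .exceptions import ValidationError

DISTANCES = ("pearson", "euclidean")
LINKAGES = ("average", "complete", "single")


@dataclass
class Dendrogram:
    """An agglomeration history over one axis of an expression matrix.

    ``linkage_matrix`` is in scipy format (n−1 merges × [left, right, height,
    size]); ``labels`` are the clustered items in the canonical (sorted)
    order that row/column indices of the linkage refer to.
    """

    linkage_matrix: np.ndarray
    labels: tuple[str, ...]
    axis: str
    distance_name: str
    linkage_name: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def leaf_order(self) -> list[str]:
        """Item labels in dendrogram display order."""
        order = hierarchy.leaves_list(self.linkage_matrix)
        return [self.labels[i] for i in order]

    def cut(self, n_clusters: int) -> dict[str, int]:
        flat = hierarchy.fcluster(self.linkage_matrix, t=n_clusters, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))

    def top_split(self) -> tuple[frozenset, frozenset]:
        """The two-branch partition under the root merge."""
        groups = self.cut(2)
        a = frozenset(l for l, c in groups.items() if c == 1)
        b = frozenset(l for l, c in groups.items() if c == 2)
        return a, b


def _pearson_distance_condensed(X: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    sd = X.std(axis=1)
    constant = np.where(sd == 0)[0]
    if constant.size:
        raise ValidationError(
            "constant row(s) under correlation distance: "
            + ", ".join(str(labels[i]) for i in constant)
        )
    r = np.corrcoef(X)
    d = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return squareform(d, checks=False)


def hierarchical_cluster(
    matrix: DeltaCtMatrix | pd.DataFrame,
    axis: str = "samples",
    *,
    signature=None,
    distance: str = "pearson",
    linkage: str = "average",
) -> Dendrogram:
    """Agglomeratively cluster probes or samples of a ΔCt matrix.

    ``signature`` optionally restricts the matrix to a probe set first (the
    usual presentation clusters only signature genes).
    """
    if axis not in ("samples", "probes"):
        raise ValidationError("axis must be 'samples' or 'probes'")
    if distance not in DISTANCES:
        raise ValidationError(f"distance must be one of {DISTANCES}")
    if linkage not in LINKAGES:
        raise ValidationError(f"linkage must be one of {LINKAGES}")
    values = matrix.values if isinstance(matrix, DeltaCtMatrix) else matrix
    if signature is not None:
        probes = list(signature.probe_ids) if hasattr(signature, "probe_ids") else list(signature)
        missing = [p for p in probes if p not in values.index]
        if missing:
            raise ValidationError(f"signature probe(s) absent: {', '.join(missing)}")
        values = values.loc[probes]
    items = values.T if axis == "samples" else values
    if items.shape[0] < 2:
        raise ValidationError("need at least 2 items to cluster")
    items = items.sort_index(kind="mergesort")  # canonical lexicographic order
    labels = tuple(str(i) for i in items.index)
    X = items.to_numpy(float)
    if distance == "pearson":
        cond = _pearson_distance_condensed(X, labels)
    else:
        cond = pdist(X, metric="euclidean")
    Z = hierarchy.linkage(cond, method=linkage)
    return Dendrogram(
        linkage_matrix=Z,
        labels=labels,
        axis=axis,
        distance_name=distance,
        linkage_name=linkage,
    )


# ---------------------------------------------------------------------------
# Heatmap rendering
# ---------------------------------------------------------------------------

def expression_for_display(values: pd.DataFrame) -> pd.DataFrame:
    """Negated ΔCt: the display scale on which high expression is high."""
    return -values


def render_heatmap(
    matrix: DeltaCtMatrix | pd.DataFrame,
    path: str | Path,
    *,
    probe_order: Sequence[str] | None = None,
    sample_order: Sequence[str] | None = None,
    cmap: str = "bwr",
    dpi: int = 150,
) -> Path:
    """Render an expression heatmap (blue = low expression, red = high) to
    ``path``.  ``probe_order``/``sample_order`` must be permutations of the
    matrix axes, typically dendrogram leaf orders.  Output bytes are
    deterministic for fixed input."""
    values = matrix.values if isinstance(matrix, DeltaCtMatrix) else matrix
    if probe_order is not None:
        if sorted(probe_order) != sorted(values.index):
            raise ValidationError("probe_order is not a permutation of the probe axis")
        values = values.loc[list(probe_order)]
    if sample_order is not None:
        if sorted(sample_order) != sorted(values.columns):
            raise ValidationError("sample_order is not a permutation of the sample axis")
        values = values[list(sample_order)]
    display = expression_for_display(values)
    path = Path(path)
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.4 * display.shape[1] + 2), max(3.0, 0.25 * display.shape[0] + 1.5))
    )
    im = ax.imshow(display.to_numpy(float), aspect="auto", cmap=cmap, interpolation="nearest")
    ax.set_xticks(range(display.shape[1]), labels=display.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(display.shape[0]), labels=display.index, fontsize=7)
    cbar = fig.colorbar(im, ax=ax, shrink=0.7)
    cbar.set_label("expression (−ΔCt)")
    ax.set_title("blue = low expression, red = high (colour scale is −ΔCt)", fontsize=8)
    fig.tight_layout()
    metadata = {"Date": None} if path.suffix.lower() == ".svg" else None
    fig.savefig(path, dpi=dpi, metadata=metadata)
    plt.close(fig)
    return path


# ---------------------------------------------------------------------------
# GCT + CDT/GTR/ATR export
# ---------------------------------------------------------------------------

def _node_names(n_leaves: int, prefix: str) -> list[str]:
    return [f"NODE{i + 1}X" for i in range(n_leaves - 1)]


def _write_tree(Z: np.ndarray, item_ids: list[str], path: Path, prefix: str) -> None:
    """Write a GTR/ATR-style join list: NODEnX, child, child, similarity
    (1 − merge height, so larger = tighter)."""
    n = len(item_ids)
    names = _node_names(n, prefix)
    with open(path, "w") as fh:
        for i, (a, b, height, _) in enumerate(Z):
            a, b = int(a), int(b)
            left = item_ids[a] if a < n else names[a - n]
            right = item_ids[b] if b < n else names[b - n]
            fh.write(f"{names[i]}\t{left}\t{right}\t{1.0 - float(height)!r}\n")


def write_gct_cdt(
    matrix: DeltaCtMatrix | pd.DataFrame,
    directory: str | Path,
    *,
    probe_dendrogram: Dendrogram | None = None,
    sample_dendrogram: Dendrogram | None = None,
    basename: str = "expression",
) -> dict[str, Path]:
    """Write GCT 1.2 plus clustered-data-table files (CDT, and GTR/ATR when
    dendrograms are supplied) consumable by GenePattern-style viewers.  CDT
    rows/columns follow the dendrogram leaf orders."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    values = matrix.values if isinstance(matrix, DeltaCtMatrix) else matrix
    paths: dict[str, Path] = {}
    paths["gct"] = write_gct(values, directory / f"{basename}.gct")

    row_order = list(values.index)
    col_order = list(values.columns)
    if probe_dendrogram is not None:
        row_order = probe_dendrogram.leaf_order
    if sample_dendrogram is not None:
        col_order = sample_dendrogram.leaf_order
    ordered = values.loc[row_order, col_order]

    gids = {p: f"GENE{i + 1}X" for i, p in enumerate(values.index)}
    aids = {s: f"ARRY{i + 1}X" for i, s in enumerate(values.columns)}
    cdt = directory / f"{basename}.cdt"
    with open(cdt, "w") as fh:
        header = ["GID", "UNIQID", "NAME", "GWEIGHT"] + [str(s) for s in col_order]
        fh.write("\t".join(header) + "\n")
        fh.write("\t".join(["AID", "", "", ""] + [aids[s] for s in col_order]) + "\n")
        fh.write("\t".join(["EWEIGHT", "", "", ""] + ["1"] * len(col_order)) + "\n")
        for probe in row_order:
            row = [gids[probe], str(probe), str(probe), "1"]
            row += [repr(float(v)) for v in ordered.loc[probe]]
            fh.write("\t".join(row) + "\n")
    paths["cdt"] = cdt

    if probe_dendrogram is not None:
        gtr = directory / f"{basename}.gtr"
        _write_tree(
            probe_dendrogram.linkage_matrix,
            [gids[p] for p in probe_dendrogram.labels],
            gtr,
            "GENE",
        )
        paths["gtr"] = gtr
    if sample_dendrogram is not None:
        atr = directory / f"{basename}.atr"
        _write_tree(
            sample_dendrogram.linkage_matrix,
            [aids[s] for s in sample_dendrogram.labels],
            atr,
            "ARRY",
        )
        paths["atr"] = atr
    return paths
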