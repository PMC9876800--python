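"""Motif clustering and sequence-logo heights.

Kinases are clustered by their specificity matrices: each PSSM is flattened
to a 198-dimensional vector (22 residue rows x 9 positions; the acceptor
favourabilities are not part of the feature vector) and agglomerated with
Ward minimum-variance linkage on Euclidean distances.  The dendrogram is
exported as an ultrametric Newick tree (node height = linkage height / 2).

Logo heights are ratios to the position median: the height of a letter at a
flank position is its matrix value divided by the median of that position's
randomized-residue values, so a neutral residue has height 1.  The central
S and T heights are the acceptor favourabilities s0 and t0 (their ratio,
normalized so the larger is 1).  Group logos use the element-wise average
matrix of the cluster members.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy

from .alphabet import POSITIONS, ROW_ORDER
from .errors import ValidationError
from .pssm import Pssm, average_pssm

__all__ = [
    "MotifTree",
    "LogoSpec",
    "pssm_to_vector",
    "ward_tree",
    "to_newick",
    "cut_tree",
    "logo_heights",
    "average_pssm",
]


@dataclass
class MotifTree:
    """Ward dendrogram over kinases: leaf labels plus a SciPy linkage matrix."""

    labels: list[str]
    linkage: np.ndarray  # (n_leaves - 1, 4) scipy linkage matrix

    def __post_init__(self) -> None:
        self.linkage = np.asarray(self.linkage, dtype=float)
        if self.linkage.shape != (len(self.labels) - 1, 4):
            raise ValidationError("linkage shape inconsistent with leaf count")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValidationError("non-monotone merge heights")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


@dataclass
class LogoSpec:
    """Letter heights per position for one motif logo.

    ``flank`` maps position -> list of (letter, height); heights below 1 mark
    disfavoured residues.  ``central`` holds the (S, T) acceptor heights.
    """

    kinase_id: str
    flank: dict[int, list[tuple[str, float]]]
    central: tuple[float, float]  # (S height, T height)

    def disfavoured(self, position: int) -> list[str]:
        """Letters with height < 1 at a flank position."""
        return [letter for letter, h in self.flank[position] if h < 1.0]


def pssm_to_vector(pssm: Pssm, positions: tuple[int, ...] = POSITIONS) -> np.ndarray:
    """Flatten a PSSM to a fixed-order feature vector (22 rows x 9 positions).

    s0/t0 are excluded: clustering compares flank selectivity only.
    """
    if tuple(pssm.positions) != tuple(positions):
        raise ValidationError(
            f"pssm {pssm.kinase_id!r}: position set differs from atlas geometry"
        )
    return pssm.matrix.loc[list(ROW_ORDER), list(positions)].values.ravel()


def ward_tree(
    pssms_or_vectors: list[Pssm] | np.ndarray,
    labels: list[str] | None = None,
) -> MotifTree:
    """Ward minimum-variance agglomeration of motif vectors.

    Accepts either a list of PSSMs (labels taken from kinase ids) or a 2-D
    array of feature vectors with explicit labels.
    """
    if isinstance(pssms_or_vectors, (list, tuple)) and pssms_or_vectors and isinstance(
        pssms_or_vectors[0], Pssm
    ):
        labels = [p.kinase_id for p in pssms_or_vectors]
        X = np.vstack([pssm_to_vector(p) for p in pssms_or_vectors])
    else:
        X = np.asarray(pssms_or_vectors, dtype=float)
        if labels is None:
            labels = [f"leaf{i}" for i in range(X.shape[0])]
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("ward_tree requires >= 2 equal-length vectors")
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate kinase ids")
    Z = hierarchy.linkage(X, method="ward")
    return MotifTree(labels=list(labels), linkage=Z)


def _fmt_branch(length: float) -> str:
    s = format(max(length, 0.0), ".6g")
    if "." not in s and "e" not in s:
        s += ".0"
    return s


def to_newick(tree: MotifTree) -> str:
    """Ultrametric Newick string: node height = linkage height / 2.

    Branch length = parent node height - child node height; leaves sit at
    height zero; the string is terminated by ';'.
    """
    n = tree.n_leaves
    node_height = np.concatenate([np.zeros(n), tree.linkage[:, 2] / 2.0])

    def render(node: int, parent_height: float) -> str:
        branch = _fmt_branch(parent_height - node_height[node])
        if node < n:
            return f"{tree.labels[node]}:{branch}"
        left, right = int(tree.linkage[node - n, 0]), int(tree.linkage[node - n, 1])
        h = node_height[node]
        return f"({render(left, h)},{render(right, h)}):{branch}"

    root = n + tree.linkage.shape[0] - 1
    h_root = node_height[root]
    left, right = int(tree.linkage[-1, 0]), int(tree.linkage[-1, 1])
    return f"({render(left, h_root)},{render(right, h_root)});"


def cut_tree(tree: MotifTree, n_clusters: int) -> dict[str, int]:
    """Flat cluster assignment per leaf label at a given cluster count."""
    flat = hierarchy.fcluster(tree.linkage, t=n_clusters, criterion="maxclust")
    return dict(zip(tree.labels, (int(c) for c in flat)))


def logo_heights(pssm: Pssm) -> LogoSpec:
    """Letter heights for one kinase (or one cluster-average matrix).

    Flank heights are matrix value / median of the position's randomized
    values; central S/T heights are s0 and t0.
    """
    rand = list(pssm.randomized_residues)
    flank: dict[int, list[tuple[str, float]]] = {}
    for pos in pssm.positions:
        med = float(pssm.matrix.loc[rand, pos].median())
        if med <= 0:
            raise ValidationError(
                f"pssm {pssm.kinase_id!r}: zero median at position {pos}"
            )
        flank[pos] = [
            (letter, float(pssm.matrix.loc[letter, pos] / med))
            for letter in ROW_ORDER
        ]
    return LogoSpec(
        kinase_id=pssm.kinase_id,
        flank=flank,
        central=(pssm.s0, pssm.t0),
    )


def group_logo(pssms: list[Pssm], group_id: str = "group") -> LogoSpec:
    """Logo of a kinase cluster: average the matrices, then compute heights."""
    return logo_heights(average_pssm(pssms, group_id=group_id))


def plot_logo(spec: LogoSpec, ax=None, top_n: int = 5):
    """Minimal motif-logo rendering: stacked letters scaled by height.

    Shows the ``top_n`` tallest letters per position plus the central S/T.
    """
    import matplotlib.pyplot as plt

    positions = sorted(spec.flank)
    if ax is None:
        _, ax = plt.subplots(figsize=(0.9 * (len(positions) + 1), 3))
    xticks, xlabels = [], []
    for x, pos in enumerate(p for p in positions if p < 0):
        _stack(ax, x, spec.flank[pos], top_n)
        xticks.append(x)
        xlabels.append(str(pos))
    x_center = sum(1 for p in positions if p < 0)
    _stack(ax, x_center, [("S", spec.central[0]), ("T", spec.central[1])], 2,
           color="firebrick")
    xticks.append(x_center)
    xlabels.append("0")
    for x, pos in enumerate(
        (p for p in positions if p > 0), start=x_center + 1
    ):
        _stack(ax, x, spec.flank[pos], top_n)
        xticks.append(x)
        xlabels.append(f"+{pos}")
    ax.set_xticks(xticks, xlabels)
    ax.set_ylabel("height (ratio to position median)")
    ax.set_title(spec.kinase_id)
    return ax


def _stack(ax, x: float, letters: list[tuple[str, float]], top_n: int,
           color: str = "black") -> None:
    tallest = sorted(letters, key=lambda lh: -lh[1])[:top_n]
    y = 0.0
    for letter, h in sorted(tallest, key=lambda lh: lh[1]):
        ax.text(x, y + h / 2, letter, ha="center", va="center",
                fontsize=6 + 8 * min(h, 3) / 3, color=color)
        y += h
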