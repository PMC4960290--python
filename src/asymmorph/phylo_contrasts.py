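"""Phylogenetically independent contrasts on shape data.

Under Brownian evolution along a dated tree, differences between sister
lineages, divided by the square root of their net divergence time, are
exchangeable draws from the evolutionary process — a rotation of the
specimen space that removes the dependence induced by shared ancestry.
This module implements the classic pruning recursion, its application to
Procrustes shape coordinates with either a single grand-mean registration
or a per-contrast recentered J-matrix, principal components of the
contrasts (relative warps of contrasts), and the winnowing scan that
removes leading contrast axes one at a time to ask how close the remainder
comes to a clocklike proportionality between morphological distance and
patristic distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DimensionError, StructuralError
from .io_landmarks import LandmarkConfiguration, LandmarkSample
from .procrustes import (
    MeanFormWithJ,
    ProcrustesFit,
    _align,
    gpa,
    mean_form_in_place,
    project_to_shape_space,
)

__all__ = [
    "Phylogeny",
    "ContrastSet",
    "felsenstein_contrasts",
    "shape_contrasts",
    "contrast_relative_warps",
    "neutrality_scan",
]


class Phylogeny:
    """A rooted, fully bifurcating tree with strictly positive branch lengths.

    Nodes are integer ids; tips carry names.  Polytomies and missing branch
    lengths are rejected outright: the contrast recursion depends on both,
    and no principled default resolution exists.
    """

    def __init__(
        self,
        parent: list[int],
        branch_lengths: list[float],
        tip_names: dict[int, str],
    ) -> None:
        self.parent = np.asarray(parent, dtype=int)
        self.branch_lengths = np.asarray(branch_lengths, dtype=float)
        self.tip_names = dict(tip_names)
        n_nodes = self.parent.size
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise StructuralError(f"tree must have exactly one root, found {roots.size}")
        self.root = int(roots[0])
        self.children_list: list[list[int]] = [[] for _ in range(n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children_list[p].append(i)
        for i, ch in enumerate(self.children_list):
            if len(ch) not in (0, 2):
                raise StructuralError(
                    f"node {i} has {len(ch)} children: tree must be fully bifurcating"
                )
            if len(ch) == 0 and i not in self.tip_names:
                raise StructuralError(f"unnamed tip node {i}")
        for i in range(n_nodes):
            if i != self.root and not (self.branch_lengths[i] > 0):
                raise StructuralError(
                    f"node {i}: branch length must be strictly positive"
                )
        names = list(self.tip_names.values())
        if len(set(names)) != len(names):
            raise StructuralError("duplicate tip names")
        self.tip_order: list[str] = [
            self.tip_names[i] for i in sorted(self.tip_names)
        ]

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick_string(cls, newick: str) -> "Phylogeny":
        import dendropy

        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as e:  # dendropy raises several parse error types
            raise StructuralError(f"Newick parse error: {e}") from None
        parent: list[int] = []
        blens: list[float] = []
        tips: dict[int, str] = {}
        ids: dict[object, int] = {}
        for node in dtree.preorder_node_iter():
            nid = len(parent)
            ids[node] = nid
            if node.parent_node is None:
                parent.append(-1)
                blens.append(np.nan)
            else:
                parent.append(ids[node.parent_node])
                if node.edge.length is None:
                    raise StructuralError(
                        f"missing branch length above node {node.taxon or nid}"
                    )
                blens.append(float(node.edge.length))
            if node.is_leaf():
                if node.taxon is None:
                    raise StructuralError(f"tip node {nid} has no name")
                tips[nid] = node.taxon.label
        return cls(parent, blens, tips)

    @classmethod
    def from_newick_file(cls, path: str | Path) -> "Phylogeny":
        return cls.from_newick_string(Path(path).read_text())

    def to_newick(self) -> str:
        def rec(node: int) -> str:
            if not self.children_list[node]:
                return f"{self.tip_names[node]}:{self.branch_lengths[node]:.12g}"
            inner = ",".join(rec(c) for c in self.children_list[node])
            if node == self.root:
                return f"({inner})"
            return f"({inner}):{self.branch_lengths[node]:.12g}"

        return rec(self.root) + ";"

    # -- queries ------------------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    def children(self, node: int) -> list[tuple[int, float]]:
        return [(c, float(self.branch_lengths[c])) for c in self.children_list[node]]

    def tip_ids(self) -> list[int]:
        return sorted(self.tip_names)

    def patristic_distance_matrix(self) -> np.ndarray:
        """Tip-by-tip matrix of total branch length separating each pair,
        ordered as ``tip_order``: depth_i + depth_j - 2 · depth(MRCA)."""
        V = self.shared_path_covariance()
        d = np.diag(V)
        return d[:, None] + d[None, :] - 2.0 * V

    def shared_path_covariance(self) -> np.ndarray:
        """V_ij = shared branch length from the root to the most recent
        common ancestor of tips i and j (the Brownian tip covariance)."""
        tips = self.tip_ids()
        n = len(tips)
        depth = {self.root: 0.0}
        order = [self.root]
        while order:
            node = order.pop()
            for c in self.children_list[node]:
                depth[c] = depth[node] + float(self.branch_lengths[c])
                order.append(c)
        anc_sets = []
        for t in tips:
            s = {t}
            node = t
            while node != self.root:
                node = int(self.parent[node])
                s.add(node)
            anc_sets.append(s)
        V = np.zeros((n, n))
        for i in range(n):
            V[i, i] = depth[tips[i]]
            for j in range(i + 1, n):
                mrca_depth = max(depth[a] for a in anc_sets[i] & anc_sets[j])
                V[i, j] = V[j, i] = mrca_depth
        return V


# ---------------------------------------------------------------------------
# The pruning recursion
# ---------------------------------------------------------------------------

def felsenstein_contrasts(
    tree: Phylogeny, values: np.ndarray, normalize: bool = True
) -> tuple[np.ndarray, np.ndarray, dict[int, np.ndarray], np.ndarray]:
    """Classic pruning recursion on arbitrary tip values.

    ``values`` is n_tips × p, rows ordered as ``tree.tip_order``.  Returns
    (contrasts (n-1) × p, durations, node value estimates per internal node,
    tip-weight matrix W with contrasts = W @ values).  Durations are the sum
    of the two daughter branch lengths after the usual extension
    v1·v2/(v1+v2) of each pruned node's stem; when ``normalize`` each
    contrast is divided by the square root of its duration, which gives
    every contrast row variance equal to the Brownian rate.
    """
    values = np.atleast_2d(np.asarray(values, float))
    tips = tree.tip_ids()
    if values.shape[0] != len(tips):
        raise DimensionError("one row of values per tip required")
    p = values.shape[1]
    n_nodes = tree.parent.size
    node_val = np.zeros((n_nodes, p))
    node_w = np.zeros((n_nodes, len(tips)))
    extra = np.zeros(n_nodes)
    for idx, t in enumerate(tips):
        node_val[t] = values[idx]
        node_w[t, idx] = 1.0
    contrasts, durations, cw, cnodes = [], [], [], []

    def visit(node: int) -> None:
        ch = tree.children_list[node]
        if not ch:
            return
        c1, c2 = ch
        visit(c1)
        visit(c2)
        v1 = float(tree.branch_lengths[c1]) + extra[c1]
        v2 = float(tree.branch_lengths[c2]) + extra[c2]
        contrasts.append(node_val[c1] - node_val[c2])
        cw.append(node_w[c1] - node_w[c2])
        durations.append(v1 + v2)
        cnodes.append(node)
        w1, w2 = v2 / (v1 + v2), v1 / (v1 + v2)
        node_val[node] = w1 * node_val[c1] + w2 * node_val[c2]
        node_w[node] = w1 * node_w[c1] + w2 * node_w[c2]
        extra[node] = v1 * v2 / (v1 + v2)

    visit(tree.root)
    C = np.array(contrasts)
    W = np.array(cw)
    dur = np.array(durations)
    if normalize:
        C = C / np.sqrt(dur)[:, None]
        W = W / np.sqrt(dur)[:, None]
    node_means = {n: node_val[n] for n in cnodes}
    return C, dur, node_means, W


@dataclass
class ContrastSet:
    """Time-normalized contrasts of shape coordinates.

    ``contrasts`` are (n_tips - 1) × 2k, each divided by the square root of
    its equivalent divergence time.  ``node_means`` maps internal node ids
    to reconstructed configurations (grand-mean frame).  When recentering
    was requested, ``per_contrast_J`` holds the registration built from each
    contrast's own pairwise mean form.
    """

    contrasts: np.ndarray
    durations: np.ndarray
    node_means: dict[int, np.ndarray]
    tip_shape_coords: np.ndarray
    tip_names: list[str]
    grand_mean: MeanFormWithJ
    fit: ProcrustesFit
    normalized: bool = True
    per_contrast_J: list[MeanFormWithJ] | None = None
    tip_weights: np.ndarray | None = None


def shape_contrasts(
    tree: Phylogeny, sample: LandmarkSample, recenter: bool = False
) -> ContrastSet:
    """Independent contrasts of a landmark sample over a dated phylogeny.

    Specimen ids must match tip names bijectively.  The sample is first
    superposed (scaled GPA); the recursion runs on the aligned
    configurations.  With ``recenter=False`` every contrast is the J-projected
    difference of the two endpoint estimates in the grand-mean frame.  With
    ``recenter=True`` each contrast's two endpoint forms (tips or
    reconstructed ancestors) are re-registered through the J of their own
    pairwise mean before differencing, removing the grand-mean registration
    bias that inflates contrasts between forms far from the grand mean.
    """
    ids = [c.specimen_id for c in sample]
    if set(ids) != set(tree.tip_order) or len(ids) != len(tree.tip_order):
        missing = set(tree.tip_order) ^ set(ids)
        raise StructuralError(
            f"specimen ids and tip names must match bijectively (mismatch: {sorted(missing)})"
        )
    fit = gpa(sample, scale=True)
    order = [ids.index(name) for name in tree.tip_order]
    aligned = fit.aligned[order]
    C_raw, dur, node_means, W = felsenstein_contrasts(tree, aligned, normalize=False)
    ref = fit.reference
    labels = sample.labels

    # endpoint estimates at each internal node, in recursion order
    endpoints = _contrast_endpoints(tree, aligned)
    contrasts = np.empty_like(C_raw)
    per_J: list[MeanFormWithJ] | None = [] if recenter else None
    for i, (e1, e2) in enumerate(endpoints):
        if recenter:
            # the pairwise registration keeps the grand-mean orientation so
            # contrast vectors stay comparable across contrasts
            pair_mean = LandmarkConfiguration(
                ((e1 + e2) / 2.0).reshape(-1, 2), labels, "pairmean"
            )
            ref_i = mean_form_in_place(pair_mean)
            a1 = _align(e1.reshape(-1, 2), ref_i.coords, scale=True)[0].reshape(-1)
            a2 = _align(e2.reshape(-1, 2), ref_i.coords, scale=True)[0].reshape(-1)
            contrasts[i] = project_to_shape_space(a1 - a2, ref_i)
            per_J.append(ref_i)
        else:
            contrasts[i] = project_to_shape_space(e1 - e2, ref)
    contrasts = contrasts / np.sqrt(dur)[:, None]
    return ContrastSet(
        contrasts=contrasts,
        durations=dur,
        node_means=node_means,
        tip_shape_coords=fit.shape_coords[order],
        tip_names=list(tree.tip_order),
        grand_mean=ref,
        fit=fit,
        normalized=True,
        per_contrast_J=per_J,
        tip_weights=W / np.sqrt(dur)[:, None],
    )


def _contrast_endpoints(
    tree: Phylogeny, values: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray]]:
    """(endpoint1, endpoint2) per contrast, same order as the recursion."""
    tips = tree.tip_ids()
    p = values.shape[1]
    node_val = np.zeros((tree.parent.size, p))
    extra = np.zeros(tree.parent.size)
    for idx, t in enumerate(tips):
        node_val[t] = values[idx]
    out: list[tuple[np.ndarray, np.ndarray]] = []

    def visit(node: int) -> None:
        ch = tree.children_list[node]
        if not ch:
            return
        c1, c2 = ch
        visit(c1)
        visit(c2)
        v1 = float(tree.branch_lengths[c1]) + extra[c1]
        v2 = float(tree.branch_lengths[c2]) + extra[c2]
        out.append((node_val[c1].copy(), node_val[c2].copy()))
        node_val[node] = (v2 * node_val[c1] + v1 * node_val[c2]) / (v1 + v2)
        extra[node] = v1 * v2 / (v1 + v2)

    visit(tree.root)
    return out


# ---------------------------------------------------------------------------
# Relative warps of contrasts and the winnowing scan
# ---------------------------------------------------------------------------

@dataclass
class ContrastRelativeWarps:
    """Principal axes of the time-normalized contrasts (no centering —
    contrasts have expectation zero under the Brownian null), with the
    contrasts' scores and the tips' reconstructed scores in the grand-mean
    frame."""

    axes: np.ndarray  # n_axes × 2k, orthonormal rows
    singular_values: np.ndarray
    variances: np.ndarray  # per-axis mean square over contrasts
    contrast_scores: np.ndarray
    tip_scores: np.ndarray
    tip_names: list[str]


def contrast_relative_warps(contrasts: ContrastSet, n_axes: int) -> ContrastRelativeWarps:
    C = contrasts.contrasts
    if C.shape[0] < 2:
        raise ValueError("at least 2 contrasts required")
    u, s, vt = np.linalg.svd(C, full_matrices=False)
    rank = int(np.sum(s > 1e-12 * s[0]))
    if n_axes > rank:
        raise ValueError(f"n_axes={n_axes} exceeds contrast rank {rank}")
    axes = vt[:n_axes]
    # canonical sign: largest-magnitude loading positive
    for i in range(n_axes):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    scores = C @ axes.T
    tip_scores = contrasts.tip_shape_coords @ axes.T
    return ContrastRelativeWarps(
        axes=axes,
        singular_values=s[:n_axes],
        variances=s[:n_axes] ** 2 / C.shape[0],
        contrast_scores=scores,
        tip_scores=tip_scores,
        tip_names=list(contrasts.tip_names),
    )


@dataclass
class NeutralityLevel:
    """One winnowing level: pairwise shape distances after removing the
    leading r contrast axes, against patristic distance, with a lowess
    smooth and a through-origin fit of squared distance on time."""

    removed: int
    patristic: np.ndarray
    distances: np.ndarray
    lowess: np.ndarray  # m × 2 (sorted patristic, smoothed distance)
    slope_sq: float  # through-origin slope of squared distance on patristic
    r2_sq: float


def neutrality_scan(
    tree: Phylogeny,
    sample: LandmarkSample,
    contrasts: ContrastSet | None = None,
    max_removed: int = 5,
    patristic_cap: float | None = None,
    lowess_frac: float = 2.0 / 3.0,
    lowess_it: int = 3,
) -> list[NeutralityLevel]:
    """Winnow leading contrast relative warps and test clocklike scaling.

    For r = 0..max_removed the tips' shape coordinates are projected onto
    the orthocomplement of the first r contrast-RW axes; all pairwise shape
    distances in that subspace are paired with patristic distances.  Under
    neutral (isotropic Brownian) evolution squared shape distance grows
    linearly with divergence time at every r; directions dominated by a few
    non-clocklike 'functional' axes break the proportionality until they are
    winnowed away.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

    if contrasts is None:
        contrasts = shape_contrasts(tree, sample)
    C = contrasts.contrasts
    rank = int(np.linalg.matrix_rank(C))
    if max_removed >= rank:
        raise ValueError(f"max_removed={max_removed} must be < contrast rank {rank}")
    rw = contrast_relative_warps(contrasts, max_removed) if max_removed else None
    D = contrasts.tip_shape_coords
    patristic = tree.patristic_distance_matrix()
    iu = np.triu_indices(D.shape[0], k=1)
    pat = patristic[iu]
    keep = np.ones(pat.size, dtype=bool)
    if patristic_cap is not None:
        keep = pat < patristic_cap
    levels = []
    proj = D.copy()
    for r in range(max_removed + 1):
        if r > 0:
            a = rw.axes[r - 1]
            proj = proj - np.outer(proj @ a, a)
        diff = proj[:, None, :] - proj[None, :, :]
        dists = np.sqrt(np.sum(diff**2, axis=-1))[iu]
        x, y = pat[keep], dists[keep]
        sm = sm_lowess(y, x, frac=lowess_frac, it=lowess_it, return_sorted=True)
        sxy = float(np.sum(x * y**2))
        sxx = float(np.sum(x * x))
        slope = sxy / sxx
        resid = y**2 - slope * x
        ss_tot = float(np.sum((y**2) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
        levels.append(
            NeutralityLevel(
                removed=r,
                patristic=x,
                distances=y,
                lowess=sm,
                slope_sq=slope,
                r2_sq=r2,
            )
        )
    return levels
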