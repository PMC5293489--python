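"""Chemical-shift covariance analysis (CHESCA) across protein states.

When a set of perturbations (mutations, phosphorylation) shifts the
equilibrium between the same two conformers, residues sensing that
equilibrium move along straight lines in the spectrum and their combined
chemical shifts co-vary linearly across states.  CHESCA exploits this:

1. each residue's profile across states is reduced to the combined
   chemical shift CCS = 0.2·δ_N + δ_H;
2. residues that do not respond to the activating transition (shift
   difference between the unphosphorylated and phosphorylated reference
   states below 10 Hz in ¹H and 5 Hz in ¹⁵N) are excluded;
3. pairwise Pearson correlations of the CCS profiles are clustered by
   complete linkage on the distance 1 − |r|, and clusters are cut so that
   every within-cluster pair satisfies |r| ≥ 0.97;
4. the clustered sub-matrix is validated by state-level dendrograms and a
   singular value decomposition: one underlying equilibrium coordinate
   puts every network residue on the first principal component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist, squareform

from .peaklist import (
    GYRO_RATIO,
    AlignedStates,
    NucleusClass,
    PeakList,
    ResonanceKey,
    StateSet,
    align_states,
)

__all__ = [
    "CCS_N15_WEIGHT",
    "CORRELATION_CUTOFF",
    "ChescaMatrix",
    "ResidueCluster",
    "NetworkValidation",
    "build_ccs_matrix",
    "filter_by_activation_shift",
    "correlation_clusters",
    "validate_network",
]

#: Weight of δ_N in the combined chemical shift: CCS = 0.2·δ_N + δ_H.
CCS_N15_WEIGHT = 0.2
#: Pairwise |r| a residue cluster must satisfy throughout.
CORRELATION_CUTOFF = 0.97


@dataclass
class ChescaMatrix:
    residues: list[ResonanceKey]
    state_ids: list[str]
    ccs: np.ndarray  # (n_residues, n_states), ppm

    def submatrix(self, members) -> "ChescaMatrix":
        idx = [i for i, k in enumerate(self.residues) if k in set(members)]
        return ChescaMatrix(
            residues=[self.residues[i] for i in idx],
            state_ids=list(self.state_ids),
            ccs=self.ccs[idx],
        )


@dataclass
class ResidueCluster:
    members: list[ResonanceKey]
    min_abs_corr: float
    newick: str  # dendrogram over members; branch lengths from merge heights


@dataclass
class NetworkValidation:
    state_newicks: list[str]  # one state dendrogram per cluster
    svd_scores: np.ndarray  # states x components
    svd_loadings: np.ndarray  # residues x components
    variance_fractions: np.ndarray  # per component, sums to 1
    residues: list[ResonanceKey]

    @property
    def pc1_variance_fraction(self) -> float:
        return float(self.variance_fractions[0])


def build_ccs_matrix(states: StateSet) -> ChescaMatrix:
    """CCS matrix over the residues present in every state."""
    if len(states.states) < 3:
        raise ValueError("CHESCA needs >= 3 states for a defined correlation")
    if states.nucleus_class is not NucleusClass.HN_N:
        raise ValueError("CHESCA operates on backbone amide (HN_N) peak lists")
    aligned = align_states(states)
    ccs = CCS_N15_WEIGHT * aligned.shift_x + aligned.shift_h
    return ChescaMatrix(residues=aligned.keys, state_ids=aligned.state_ids, ccs=ccs)


def filter_by_activation_shift(
    states: StateSet,
    h_cut_hz: float = 10.0,
    n_cut_hz: float = 5.0,
    unphos_id: str = "WT_unphos",
    phos_id: str = "WT_phos",
    rule: str = "and",
) -> StateSet:
    """Drop residues insensitive to the activating transition.

    A residue is excluded when its shift difference between the
    phosphorylated and unphosphorylated reference states is below both
    thresholds (rule="and", default) or below either (rule="or").  Hz
    thresholds are converted to ppm with the StateSet's ¹H frequency and
    the ¹⁵N gyromagnetic ratio.
    """
    if rule not in ("and", "or"):
        raise ValueError("rule must be 'and' or 'or'")
    ref = states.get(unphos_id)
    phos = states.get(phos_id)
    mhz = states.spectrometer_h_mhz
    h_cut_ppm = h_cut_hz / mhz
    n_cut_ppm = n_cut_hz / (mhz * GYRO_RATIO["N15"])
    drop: set[ResonanceKey] = set()
    for key in set(ref.entries) & set(phos.entries):
        a, b = ref.entries[key], phos.entries[key]
        if a.missing or b.missing:
            continue
        small_h = abs(b.shift_h - a.shift_h) < h_cut_ppm
        small_n = abs(b.shift_x - a.shift_x) < n_cut_ppm
        if (small_h and small_n) if rule == "and" else (small_h or small_n):
            drop.add(key)
    new_states = []
    for s in states.states:
        kept = {k: e for k, e in s.entries.items() if k not in drop}
        new_states.append(PeakList(state_id=s.state_id, nucleus_class=s.nucleus_class,
                                   entries=kept))
    return StateSet(states=new_states, spectrometer_h_mhz=mhz)


def _newick(node, labels: list[str]) -> str:
    """Serialize a scipy cluster tree; branch length = parent height − height."""

    def rec(n, parent_height: float) -> str:
        if n.is_leaf():
            return f"{labels[n.id]}:{parent_height:.6g}"
        left = rec(n.left, n.dist)
        right = rec(n.right, n.dist)
        return f"({left},{right}):{parent_height - n.dist:.6g}"

    if node.is_leaf():
        return f"{labels[node.id]}:0;"
    return f"({rec(node.left, node.dist)},{rec(node.right, node.dist)});"


def _drop_flat_profiles(matrix: ChescaMatrix) -> ChescaMatrix:
    sd = matrix.ccs.std(axis=1)
    flat = sd == 0
    if flat.any():
        for i in np.flatnonzero(flat):
            warnings.warn(
                f"residue {matrix.residues[i].label()} has a zero-variance CCS "
                "profile; correlation undefined, residue dropped",
                stacklevel=3,
            )
        keep = [k for k, f in zip(matrix.residues, flat) if not f]
        return matrix.submatrix(keep)
    return matrix


def correlation_clusters(
    matrix: ChescaMatrix, cutoff: float = CORRELATION_CUTOFF
) -> list[ResidueCluster]:
    """Complete-linkage clusters in which every pair has |r| ≥ cutoff.

    Residues are ordered lexicographically before linkage so ties at equal
    merge heights resolve deterministically.  Clusters are the maximal
    subtrees whose all-pairs condition holds, checked exactly on the
    correlation matrix rather than through merge heights; singletons are
    discarded.
    """
    matrix = _drop_flat_profiles(matrix)
    order = sorted(range(len(matrix.residues)), key=lambda i: matrix.residues[i])
    residues = [matrix.residues[i] for i in order]
    X = matrix.ccs[order]
    n = len(residues)
    if n < 2:
        return []
    corr = np.corrcoef(X)
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # enforce exact symmetry
    Z = linkage(squareform(dist, checks=False), method="complete")
    root = to_tree(Z)

    clusters: list[ResidueCluster] = []

    def visit(node) -> None:
        leaves = node.pre_order(lambda leaf: leaf.id)
        if len(leaves) >= 2:
            sub = np.abs(corr[np.ix_(leaves, leaves)])
            off = sub[~np.eye(len(leaves), dtype=bool)]
            if off.min() >= cutoff:
                labels = [residues[i].label() for i in range(n)]
                clusters.append(
                    ResidueCluster(
                        members=sorted(residues[i] for i in leaves),
                        min_abs_corr=float(off.min()),
                        newick=_newick(node, labels),
                    )
                )
                return  # maximal subtree found; don't descend
        if not node.is_leaf():
            visit(node.left)
            visit(node.right)

    visit(root)
    clusters.sort(key=lambda c: c.members[0])
    return clusters


def validate_network(
    matrix: ChescaMatrix, clusters: list[ResidueCluster]
) -> NetworkValidation:
    """State dendrograms per cluster plus SVD of the pooled cluster residues.

    State dendrograms use complete linkage on Euclidean distances between
    states over the cluster's standardized CCS profiles.  The SVD is taken
    of the states × residues matrix with each residue profile centered;
    the squared singular values give the variance captured per component.
    """
    if not clusters:
        raise ValueError("no clusters to validate")
    state_newicks: list[str] = []
    for cl in clusters:
        if len(cl.members) < 2:
            continue
        sub = matrix.submatrix(cl.members)
        prof = sub.ccs
        z = (prof - prof.mean(axis=1, keepdims=True)) / prof.std(axis=1, keepdims=True)
        Z = linkage(pdist(z.T, metric="euclidean"), method="complete")
        state_newicks.append(_newick(to_tree(Z), list(matrix.state_ids)))

    pooled = sorted({m for cl in clusters for m in cl.members if len(cl.members) >= 2})
    sub = matrix.submatrix(pooled)
    X = sub.ccs.T  # states x residues
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    fractions = var / total if total > 0 else np.zeros_like(var)
    return NetworkValidation(
        state_newicks=state_newicks,
        svd_scores=U * s,
        svd_loadings=Vt.T,
        variance_fractions=fractions,
        residues=sub.residues,
    )
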