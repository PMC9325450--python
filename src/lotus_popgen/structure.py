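"""Population structure: p-distance, neighbor-joining tree, genotype PCA.

The p-distance between two diploid samples is the allele-sharing distance
mean(|dosage_i - dosage_j|) / 2 over sites called in both (pairwise
deletion), so opposite homozygotes differ by 1 and a het/hom pair by 0.5.
The NJ agglomeration is the classic Saitou-Nei algorithm with a
deterministic tie-break (lowest index pair on equal Q), which recovers any
additive distance matrix exactly.  PCA uses Patterson normalization:
dosages centered by 2*p-hat and scaled by sqrt(2*p-hat*(1-p-hat)).
"""

from __future__ import annotations

import io
import logging

import dendropy
import numpy as np
import pandas as pd

from lotus_popgen.containers import GenotypeMatrix

logger = logging.getLogger(__name__)


def p_distance_matrix(geno: GenotypeMatrix) -> pd.DataFrame:
    """Allele-sharing p-distance matrix over co-called sites, per pair.

    Uses pairwise deletion: each pair's denominator is its own co-called
    site count.  A pair with zero co-called sites is an error (the distance
    is undefined and the tree would be meaningless).
    """
    if geno.n_samples < 2:
        raise ValueError("p-distance needs at least 2 samples")
    d = geno.dosage
    called = (d != -1).astype(np.float64)
    # decompose sum|di-dj| over dosage classes; matmuls keep this O(n^2 s) in BLAS
    ind = [(d == k).astype(np.float64) for k in (0, 1, 2)]
    co_called = called @ called.T
    diff1 = ind[0] @ ind[1].T + ind[1] @ ind[0].T + ind[1] @ ind[2].T + ind[2] @ ind[1].T
    diff2 = ind[0] @ ind[2].T + ind[2] @ ind[0].T
    num = diff1 + 2.0 * diff2
    if np.any(co_called[~np.eye(len(co_called), dtype=bool)] == 0):
        bad = np.argwhere((co_called == 0) & ~np.eye(len(co_called), dtype=bool))
        i, j = bad[0]
        raise ValueError(
            f"pair ({geno.samples[i]}, {geno.samples[j]}) has no co-called sites; "
            "p-distance undefined"
        )
    dist = num / (2.0 * co_called)
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=geno.samples, columns=geno.samples)


def check_triangle_inequality(dist: pd.DataFrame, tol: float = 1e-12) -> int:
    """Count triangle-inequality violations (reported, never repaired)."""
    d = dist.to_numpy()
    n = d.shape[0]
    violations = 0
    for i in range(n):
        # d[i,j] <= d[i,k] + d[k,j] for all k
        bound = (d[i, :, None] + d.T).min(axis=1)
        violations += int((d[i] > bound + tol).sum())
    if violations:
        logger.info("p-distance: %d triangle-inequality violations", violations)
    return violations


def _validate_distance(dist: pd.DataFrame) -> np.ndarray:
    d = np.asarray(dist.to_numpy(), dtype=np.float64)
    if d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if (d < 0).any():
        raise ValueError("distance matrix must be non-negative")
    return d


def nj_tree(dist: pd.DataFrame, clamp_negative: bool = True) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; returns an unrooted dendropy Tree.

    Ties in the Q-matrix break to the lowest (i, j) pair in the current
    label order, making the output deterministic.  Negative branch lengths
    (possible on non-additive input) are clamped to 0 at the end with a log
    note; the agglomeration itself is untouched.
    """
    d = _validate_distance(dist)
    labels = list(dist.index)
    n = len(labels)
    if n < 3:
        raise ValueError("NJ needs at least 3 taxa")
    # nodes as newick fragments
    nodes = [lab.replace(" ", "_") for lab in labels]
    active = list(range(n))
    dm = d.copy()
    negative_seen = False

    def fmt(length: float) -> str:
        nonlocal negative_seen
        if length < 0:
            negative_seen = True
            if clamp_negative:
                length = 0.0
        return f"{length:.12g}"

    while len(active) > 3:
        r = len(active)
        sub = dm[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) on ties: argmin of flattened row-major scan
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, r)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (row_sums[ai] - row_sums[aj]) / (2.0 * (r - 2))
        lj = dij - li
        # distances from the new node to the remaining taxa
        new_idx = dm.shape[0]
        dm = np.pad(dm, ((0, 1), (0, 1)))
        for ak in active:
            if ak in (i, j):
                continue
            dm[new_idx, ak] = dm[ak, new_idx] = 0.5 * (dm[i, ak] + dm[j, ak] - dij)
        nodes.append(f"({nodes[i]}:{fmt(li)},{nodes[j]}:{fmt(lj)})")
        active = [a for a in active if a not in (i, j)] + [new_idx]

    a, b, c = active
    la = 0.5 * (dm[a, b] + dm[a, c] - dm[b, c])
    lb = 0.5 * (dm[a, b] + dm[b, c] - dm[a, c])
    lc = 0.5 * (dm[a, c] + dm[b, c] - dm[a, b])
    newick = f"({nodes[a]}:{fmt(la)},{nodes[b]}:{fmt(lb)},{nodes[c]}:{fmt(lc)});"
    if negative_seen:
        logger.info("NJ produced negative branch length(s); clamped to 0 for display")
    return dendropy.Tree.get(data=newick, schema="newick")


def tree_path_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Leaf-to-leaf path-length matrix of a tree (for additivity checks)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return pd.DataFrame(out, index=labels, columns=labels)


def genotype_pca(geno: GenotypeMatrix, k: int = 10):
    """PCA of the dosage matrix with Patterson normalization.

    Missing dosages are mean-imputed per site; sites monomorphic among
    called genotypes are dropped.  Components are ordered by decreasing
    eigenvalue with the sign fixed so each component's first nonzero site
    loading is positive.  Returns ``(coords, explained)`` where ``coords``
    is a DataFrame (samples x PCs) and ``explained`` the per-component
    fraction of total variance.
    """
    if geno.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    d = geno.dosage.astype(np.float64)
    called = geno.dosage != -1
    n_called = called.sum(axis=0)
    colsum = np.where(called, d, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p_hat = colsum / np.maximum(2 * n_called, 1)
    keep = (n_called > 0) & (p_hat > 0) & (p_hat < 1)
    d = d[:, keep]
    called = called[:, keep]
    p = p_hat[keep]
    mean = 2.0 * p
    d = np.where(called, d, mean)  # per-site mean imputation
    x = (d - mean) / np.sqrt(2.0 * p * (1.0 - p))

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if len(s) else 0
    if k > rank:
        logger.warning("requested %d components but rank is %d; truncating", k, rank)
        k = rank
    # sign convention: first nonzero loading of each component positive
    for comp in range(k):
        load = vt[comp]
        nz = np.flatnonzero(np.abs(load) > 1e-12)
        if len(nz) and load[nz[0]] < 0:
            vt[comp] = -load
            u[:, comp] = -u[:, comp]
    coords = u[:, :k] * s[:k]
    total_var = float((s**2).sum())
    explained = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    coords_df = pd.DataFrame(
        coords, index=geno.samples, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return coords_df, explained


def write_newick(tree: dendropy.Tree, path: str) -> None:
    buf = io.StringIO()
    tree.write(file=buf, schema="newick", suppress_rooting=True)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
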