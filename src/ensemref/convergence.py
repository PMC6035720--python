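"""Ensemble-overlap metrics for convergence assessment.

Two complementary routes, both operating on harvested structural ensembles:

* cluster-occupancy comparison — the pooled frames of the two ensembles are
  clustered once by affinity propagation on negative pairwise best-fit RMSD
  (so the occupancy vectors share support), and the Jensen–Shannon
  divergence between the two per-ensemble cluster-occupancy distributions
  is reported in nats (0 for identical ensembles, ln 2 for disjoint ones;
  values below ~0.3 indicate similar ensembles);

* subspace overlap — the root mean square inner product (RMSIP) between
  the first 10 eigenvectors of the Calpha-coordinate covariance matrices
  of the two ensembles (1 for fully overlapping fluctuation subspaces).

Affinity propagation is implemented here as the standard
responsibility/availability message-passing scheme; the "preference"
(default 12, applied as given on the -RMSD similarity scale, or "median")
controls the granularity of the clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .timescale import kabsch_rotation, superpose_ensemble

__all__ = [
    "ClusterModel",
    "SubspaceModes",
    "rmsd_matrix",
    "affinity_propagation",
    "js_divergence",
    "cluster_occupancies",
    "compare_ensembles_jsd",
    "pca_modes",
    "rmsip",
]


@dataclass
class ClusterModel:
    """Affinity-propagation clustering result on pooled frames."""

    exemplars: np.ndarray  # indices of cluster exemplars
    labels: np.ndarray  # per-frame cluster index (into exemplars)
    preference: float
    converged: bool
    n_iter: int

    @property
    def n_clusters(self) -> int:
        return len(self.exemplars)


@dataclass
class SubspaceModes:
    """Top eigenpairs of the Calpha-coordinate covariance matrix."""

    vectors: np.ndarray  # (n_modes, 3 n_atoms), orthonormal rows
    eigenvalues: np.ndarray  # descending, >= 0
    total_variance: float

    def __post_init__(self):
        G = self.vectors @ self.vectors.T
        if not np.allclose(G, np.eye(len(self.vectors)), atol=1e-8):
            raise ValueError("eigenvectors are not orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be descending")


# ---------------------------------------------------------------------------
# Pairwise best-fit RMSD
# ---------------------------------------------------------------------------

def rmsd_matrix(ensemble_a, ensemble_b=None, atom_selection="CA",
                superpose: bool = True) -> np.ndarray:
    """Symmetric pairwise RMSD matrix (nm) over pooled frames.

    ``atom_selection`` is an atom name or an index array.  With
    ``superpose=True`` (default) each pair is compared after best-fit
    rotation+translation (batched Kabsch via SVD); otherwise raw coordinate
    RMSD is returned.
    """
    frames = [ensemble_a.coords]
    if ensemble_b is not None:
        frames.append(ensemble_b.coords)
    sel = (ensemble_a.select(atom_selection) if isinstance(atom_selection, str)
           else np.asarray(atom_selection, dtype=int))
    if sel.size == 0:
        raise ValueError("empty atom selection")
    X = np.concatenate(frames)[:, sel]  # (F, n, 3)
    F, n, _ = X.shape
    if not superpose:
        diff = X[:, None] - X[None, :]
        return np.sqrt(np.einsum("ijak,ijak->ij", diff, diff) / n)

    Xc = X - X.mean(axis=1, keepdims=True)
    G = np.einsum("fak,fak->f", Xc, Xc)  # squared norms
    iu, ju = np.triu_indices(F, k=1)
    H = np.einsum("pki,pkj->pij", Xc[iu], Xc[ju])  # (P, 3, 3) cross-covariances
    # Kabsch RMSD from the singular values of H, sign-corrected
    U, S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(np.einsum("pij,pjk->pik", U, Vt)))
    traces = S[:, 0] + S[:, 1] + sign * S[:, 2]
    msd = np.maximum(G[iu] + G[ju] - 2.0 * traces, 0.0) / n
    out = np.zeros((F, F))
    out[iu, ju] = out[ju, iu] = np.sqrt(msd)
    return out


# ---------------------------------------------------------------------------
# Affinity propagation
# ---------------------------------------------------------------------------

def affinity_propagation(similarity: np.ndarray, preference=None,
                         max_iter: int = 1000, damping: float = 0.9,
                         convergence_iter: int = 50) -> ClusterModel:
    """Affinity-propagation clustering by message passing.

    ``similarity`` is a square matrix (higher = more similar; here usually
    -RMSD).  ``preference`` sets the diagonal self-similarity: a number,
    or ``"median"`` / None for the median of the off-diagonal similarities.
    Iterates responsibility/availability updates with the given damping
    until the exemplar set is stable for ``convergence_iter`` consecutive
    iterations; non-convergence is reported via ``converged`` with labels
    still returned.
    """
    S = np.array(similarity, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("similarity must be a square matrix")
    if not (0.5 <= damping < 1.0):
        raise ValueError("damping must lie in [0.5, 1)")
    n = S.shape[0]
    if n == 1:
        return ClusterModel(np.array([0]), np.array([0]),
                            float(S[0, 0]), True, 0)
    if preference is None or (isinstance(preference, str) and preference == "median"):
        pref = float(np.median(S[~np.eye(n, dtype=bool)]))
    else:
        pref = float(preference)
    np.fill_diagonal(S, pref)

    R = np.zeros((n, n))
    A = np.zeros((n, n))
    idx = np.arange(n)
    stable = 0
    prev_exemplars = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # responsibilities
        AS = A + S
        first = np.argmax(AS, axis=1)
        max1 = AS[idx, first]
        AS[idx, first] = -np.inf
        max2 = AS.max(axis=1)
        AS[idx, first] = max1
        Rnew = S - max1[:, None]
        Rnew[idx, first] = S[idx, first] - max2
        R = damping * R + (1.0 - damping) * Rnew
        # availabilities
        Rp = np.maximum(R, 0.0)
        np.fill_diagonal(Rp, R.diagonal())
        col = Rp.sum(axis=0)
        Anew = np.minimum(0.0, col[None, :] - Rp)
        # a(k,k) = sum of positive responsibilities towards k, excluding self
        Anew[idx, idx] = col - Rp.diagonal()
        A = damping * A + (1.0 - damping) * Anew

        exemplars = np.flatnonzero(A.diagonal() + R.diagonal() > 0)
        if prev_exemplars is not None and np.array_equal(exemplars, prev_exemplars) \
                and exemplars.size > 0:
            stable += 1
            if stable >= convergence_iter:
                converged = True
                break
        else:
            stable = 0
        prev_exemplars = exemplars

    exemplars = np.flatnonzero(A.diagonal() + R.diagonal() > 0)
    if exemplars.size == 0:  # degenerate: fall back to the best single exemplar
        exemplars = np.array([int(np.argmax(A.diagonal() + R.diagonal()))])
    labels = np.argmax(S[:, exemplars], axis=1)
    labels[exemplars] = np.arange(exemplars.size)
    # refine exemplars: within each cluster pick the point maximizing the
    # summed intra-cluster similarity, then reassign
    for k in range(exemplars.size):
        members = np.flatnonzero(labels == k)
        if members.size:
            sub = S[np.ix_(members, members)].sum(axis=0)
            exemplars[k] = members[np.argmax(sub)]
    labels = np.argmax(S[:, exemplars], axis=1)
    labels[exemplars] = np.arange(exemplars.size)
    return ClusterModel(exemplars, labels, pref, converged, it)


# ---------------------------------------------------------------------------
# Jensen–Shannon divergence on cluster occupancies
# ---------------------------------------------------------------------------

def cluster_occupancies(labels, n_clusters: int) -> np.ndarray:
    """Normalized cluster-occupancy distribution of one ensemble's frames."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty ensemble has no occupancy distribution")
    counts = np.bincount(labels, minlength=n_clusters).astype(float)
    return counts / counts.sum()


def js_divergence(labels_a, labels_b, base: float = np.e) -> float:
    """Jensen–Shannon divergence (default nats) between the cluster
    occupancies of two ensembles labelled by one joint clustering.

    ``JS = H((P+Q)/2) - H(P)/2 - H(Q)/2`` with 0 log 0 := 0; symmetric,
    bounded by log 2, exactly 0 for identical occupancy distributions.
    """
    la, lb = np.asarray(labels_a, int), np.asarray(labels_b, int)
    if la.size == 0 or lb.size == 0:
        raise ValueError("empty ensemble")
    k = int(max(la.max(), lb.max())) + 1
    p = cluster_occupancies(la, k)
    q = cluster_occupancies(lb, k)

    def entropy(d):
        return float(-np.sum(xlogy(d, d)))

    js = entropy((p + q) / 2.0) - 0.5 * entropy(p) - 0.5 * entropy(q)
    if base != np.e:
        js /= np.log(base)
    return max(js, 0.0) if js < 1e-15 else js


def compare_ensembles_jsd(ensemble_a, ensemble_b, atom_selection="CA",
                          preference="median", damping: float = 0.9,
                          max_iter: int = 1000):
    """Joint AP clustering of the pooled frames + JS divergence.

    Returns (jsd, ClusterModel).  Clustering runs once on the pooled
    frames so the two occupancy vectors share support.
    """
    if ensemble_a.n_frames == 0 or ensemble_b.n_frames == 0:
        raise ValueError("empty ensemble")
    D = rmsd_matrix(ensemble_a, ensemble_b, atom_selection=atom_selection)
    n = D.shape[0]
    # Merge exactly coincident frames first: message-passing on fully
    # degenerate ties can otherwise split identical frames into separate
    # singleton clusters (this also makes a self-comparison exactly zero).
    rep = np.arange(n)
    for i in range(n):
        zeros = np.flatnonzero(D[i, :i] <= 1e-7)
        if zeros.size:
            rep[i] = rep[zeros[0]]
    uniq = np.flatnonzero(rep == np.arange(n))
    model = affinity_propagation(-D[np.ix_(uniq, uniq)],
                                 preference=preference, damping=damping,
                                 max_iter=max_iter)
    labels = np.empty(n, dtype=int)
    labels[uniq] = model.labels
    labels = labels[rep]
    model = ClusterModel(uniq[model.exemplars], labels, model.preference,
                         model.converged, model.n_iter)
    na = ensemble_a.n_frames
    jsd = js_divergence(labels[:na], labels[na:])
    return jsd, model


# ---------------------------------------------------------------------------
# PCA subspaces and RMSIP
# ---------------------------------------------------------------------------

def pca_modes(ensemble, atom_selection="CA", n_modes: int = 10) -> SubspaceModes:
    """Principal components of the Calpha-coordinate covariance.

    Frames are superposed first (iterative alignment to the evolving
    mean); the covariance of the flattened selected coordinates about the
    ensemble mean is diagonalized and the top ``n_modes`` eigenpairs kept.
    """
    sel = (ensemble.select(atom_selection) if isinstance(atom_selection, str)
           else np.asarray(atom_selection, dtype=int))
    if sel.size == 0:
        raise ValueError("empty atom selection")
    if ensemble.n_frames < n_modes + 1:
        raise ValueError(
            f"need at least {n_modes + 1} frames for {n_modes} modes")
    aligned = superpose_ensemble(ensemble, atom_selection=sel)
    X = aligned.coords[:, sel].reshape(ensemble.n_frames, -1)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    return SubspaceModes(vectors=evecs[:, :n_modes].T.copy(),
                         eigenvalues=evals[:n_modes].copy(),
                         total_variance=float(evals.sum()))


def rmsip(modes_a: SubspaceModes, modes_b: SubspaceModes, n: int = 10) -> float:
    """Root mean square inner product over the first ``n`` eigenvectors.

    ``RMSIP = sqrt( (1/n) sum_{i<=n} sum_{j<=n} (v_i . w_j)^2 )`` in
    [0, 1]; 1 when the two retained subspaces coincide.
    """
    V = modes_a.vectors
    W = modes_b.vectors
    if V.shape[0] < n or W.shape[0] < n:
        raise ValueError(f"both mode sets need at least {n} vectors")
    if V.shape[1] != W.shape[1]:
        raise ValueError("mode dimensions differ")
    inner = V[:n] @ W[:n].T
    return float(np.sqrt(np.sum(inner ** 2) / n))
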