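"""Mixing-matrix estimation by adaptive-damping affinity propagation.

Single-source points lie on lines through the origin, one line per column
of the mixing matrix A.  After normalising each feature vector to the
unit half-sphere, the columns of A become tight point clusters, and the
estimation problem becomes: how many clusters, and where are their
centres?  Affinity propagation (AP) answers both without being told the
cluster count; its known weakness — oscillation of the exemplar set under
a fixed damping factor — is handled by the adaptive rule implemented
here: a sliding window of cluster-count flags raises the damping factor
by 0.01 whenever more than two thirds of the window shows an increase in
the cluster count, capped at 1.  K-means (Lloyd) then polishes the AP
exemplars into centroids over *all* points, and the centroids, rescaled
to unit norm, are the columns of the estimated matrix.

An optional Hankel/SVD (SSA-style) low-rank denoising of the mixtures is
available ahead of feature extraction; it is off by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from . import tf as _tf
from .synth import MixingMatrix

logger = logging.getLogger("ubss")

LAMBDA_MAX = 0.99  # lam = 1 freezes the damped updates outright

__all__ = [
    "APState",
    "ClusterResult",
    "hankel_svd_denoise",
    "build_similarity",
    "adapt_damping",
    "ap_cluster",
    "kmeans_refine",
    "silhouette",
    "estimate_mixing_matrix",
    "matrix_error",
    "canonicalize_directions",
]


def canonicalize_directions(rows: np.ndarray) -> np.ndarray:
    """Scale each row to unit norm and flip its sign so the first
    component larger than 1e-12 in magnitude is non-negative."""
    rows = np.asarray(rows, dtype=np.float64)
    norms = np.linalg.norm(rows, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    u = rows / norms
    nz = np.abs(u) > 1e-12
    first = np.argmax(nz, axis=1)
    lead = u[np.arange(u.shape[0]), first]
    flip = np.where(lead < 0, -1.0, 1.0)
    flip[~nz.any(axis=1)] = 1.0
    return u * flip[:, None]


# ---------------------------------------------------------------------------
# Hankel embedding + SVD low-rank denoising (optional preprocessing)
# ---------------------------------------------------------------------------

def hankel_svd_denoise(sequence, energy_keep: float = 0.95) -> np.ndarray:
    """SSA-style denoising: Hankel-embed, truncate the SVD, de-Hankelise.

    The sequence x(1..Num) fills Ha[i, j] = x(i + j - 1) with
    P = (Num+1)/2 = Q for odd Num and P = Num/2 + 1, Q = Num/2 for even
    Num.  The smallest leading set of singular values whose squared sum
    reaches ``energy_keep`` of the total is kept; the low-rank matrix is
    mapped back to a sequence by anti-diagonal averaging.
    """
    x = np.asarray(sequence, dtype=np.float64)
    num = x.size
    if num < 4:
        raise ValueError("sequence too short for Hankel embedding (need >= 4)")
    if not (0 < energy_keep <= 1):
        raise ValueError("energy_keep must lie in (0, 1]")
    if not np.any(x):
        return x.copy()

    if num % 2:
        p = q = (num + 1) // 2
    else:
        p, q = num // 2 + 1, num // 2
    i = np.arange(p)[:, None] + np.arange(q)[None, :]
    ha = x[i]

    u, s, vt = np.linalg.svd(ha, full_matrices=False)
    energy = np.cumsum(s ** 2)
    r = int(np.searchsorted(energy, energy_keep * energy[-1] - 1e-15) + 1)
    low = (u[:, :r] * s[:r]) @ vt[:r]

    out = np.zeros(num)
    counts = np.zeros(num)
    np.add.at(out, i.ravel(), low.ravel())
    np.add.at(counts, i.ravel(), 1.0)
    return out / counts


def _blockwise_denoise(x: np.ndarray, energy_keep: float,
                       block: int = 1024) -> np.ndarray:
    """Apply Hankel/SVD denoising block-by-block so that long recordings
    do not require a Num/2 x Num/2 matrix."""
    out = np.empty_like(x)
    for start in range(0, x.size, block):
        seg = x[start:start + block]
        out[start:start + seg.size] = (
            hankel_svd_denoise(seg, energy_keep) if seg.size >= 4 else seg
        )
    return out


# ---------------------------------------------------------------------------
# Affinity propagation with adaptive damping
# ---------------------------------------------------------------------------

@dataclass
class APState:
    """Mutable state of one AP run.

    ``similarity`` is the L x L matrix s'(i, k) = -||p_i - p_k||^2 with the
    preference (median of the off-diagonal similarities) on the diagonal.
    ``lam`` is the damping factor, confined to [0.5, 1] and only ever
    raised by :func:`adapt_damping`.
    """

    similarity: np.ndarray
    points: np.ndarray
    lam: float = 0.5
    responsibility: np.ndarray = None
    availability: np.ndarray = None
    iteration: int = 0
    flags: list = field(default_factory=list)  # sliding window of 0/1 records
    lam_history: list = field(default_factory=list)
    count_history: list = field(default_factory=list)

    def __post_init__(self):
        n = self.similarity.shape[0]
        if self.responsibility is None:
            self.responsibility = np.zeros((n, n))
        if self.availability is None:
            self.availability = np.zeros((n, n))
        if not (0.5 <= self.lam <= 1.0):
            raise ValueError("damping factor must start in [0.5, 1]")


@dataclass
class ClusterResult:
    n_clusters: int
    exemplars: np.ndarray
    labels: np.ndarray
    centers: np.ndarray
    silhouette_score: float = float("nan")
    objective: float = float("nan")
    objective_history: list = field(default_factory=list)


def build_similarity(points, normalize: bool = True, lam: float = 0.5) -> APState:
    """Negative squared Euclidean similarity matrix with median preference.

    ``points`` may be an :class:`~ubss.tf.SSPSet` or an (L, M) array.  With
    ``normalize`` each feature vector is first scaled to unit norm with the
    sign convention of :func:`canonicalize_directions`.
    """
    feats = points.features if hasattr(points, "features") else np.asarray(points)
    feats = np.asarray(feats, dtype=np.float64)
    if feats.ndim != 2 or feats.shape[0] < 2:
        raise ValueError("need at least 2 points to build a similarity matrix")
    if normalize:
        feats = canonicalize_directions(feats)
    d2 = np.sum((feats[:, None, :] - feats[None, :, :]) ** 2, axis=-1)
    s = -d2
    off = s[~np.eye(s.shape[0], dtype=bool)]
    pref = float(np.median(off))
    np.fill_diagonal(s, pref)
    return APState(similarity=s, points=feats, lam=lam)


def adapt_damping(state: APState, window_len: int = 6) -> float:
    """Raise the damping factor when the cluster count oscillates.

    ``state.flags`` records, per iteration, 1 if the cluster count
    decreased or stayed equal and 0 if it grew.  Once the window holds
    ``window_len`` flags and *strictly* more than 2/3 of them are 0, the
    damping factor is increased by 0.01 (never beyond 1) and the window is
    cleared.  The factor never decreases.
    """
    if len(state.flags) >= window_len:
        window = state.flags[-window_len:]
        zeros = window.count(0)
        bump = 3 * zeros > 2 * len(window)
        if not bump and len(state.count_history) > window_len:
            # The flag rule alone is blind to period-2 oscillation (counts
            # alternating a <-> b yield exactly 50% zeros).  Treat a
            # non-constant count window with no net decrease as
            # oscillation as well.
            w = state.count_history[-(window_len + 1):]
            bump = (max(w) != min(w)) and w[-1] >= w[0]
        if bump:
            # At exactly lam = 1 the damped update is a no-op and the
            # messages freeze, so the usable ceiling sits just below it.
            state.lam = min(state.lam + 0.01, LAMBDA_MAX)
            state.flags.clear()
    return state.lam


def _ap_iterate(state: APState) -> np.ndarray:
    """One damped responsibility/availability update; returns exemplars."""
    s = state.similarity
    lam = state.lam
    n = s.shape[0]

    # responsibility: r(i,k) = s(i,k) - max_{k' != k} [ w(i,k') + s(i,k') ]
    as_ = state.availability + s
    idx = np.argmax(as_, axis=1)
    first = as_[np.arange(n), idx]
    as_[np.arange(n), idx] = -np.inf
    second = as_.max(axis=1)
    as_[np.arange(n), idx] = first
    r_new = s - first[:, None]
    r_new[np.arange(n), idx] = s[np.arange(n), idx] - second
    state.responsibility = lam * state.responsibility + (1 - lam) * r_new

    # availability: w(i,k) = min(0, r(k,k) + sum_{j not in {i,k}} max(0, r(j,k)))
    #               w(k,k) = sum_{j != k} max(0, r(j,k))
    rp = np.maximum(state.responsibility, 0)
    np.fill_diagonal(rp, state.responsibility.diagonal())
    colsum = rp.sum(axis=0)
    w_new = np.minimum(0, colsum[None, :] - rp)
    np.fill_diagonal(w_new, colsum - rp.diagonal())
    state.availability = lam * state.availability + (1 - lam) * w_new

    decision = state.responsibility.diagonal() + state.availability.diagonal()
    return np.flatnonzero(decision > 0)


def ap_cluster(state: APState, max_iter: int = 500, stable_iters: int = 50,
               adaptive: bool = True, window_len: int = 6) -> ClusterResult:
    """Run damped AP message passing to convergence.

    Stops when the exemplar set is unchanged for ``stable_iters``
    consecutive iterations or after ``max_iter`` iterations.  Exemplars
    are the indices with positive diagonal of the decision matrix
    E = R + W; every remaining point is labelled to the exemplar of
    maximal similarity (ties to the lowest exemplar index).  With
    ``adaptive`` the damping factor follows :func:`adapt_damping`.
    """
    prev_exemplars = None
    prev_count = None
    stable = 0
    exemplars = np.array([], dtype=int)

    for _ in range(max_iter):
        state.iteration += 1
        exemplars = _ap_iterate(state)
        count = exemplars.size
        state.count_history.append(count)
        if prev_count is not None:
            # "reduced or consistent" counts as calm (1); growth counts as
            # oscillation evidence (0).  Two refinements close blind spots
            # of a purely count-based record: an empty exemplar set is no
            # clustering at all (0), and an unchanged count whose exemplar
            # *identities* keep churning is a limit cycle, not consistency
            # (0) — both patterns otherwise stall the rule forever.
            if count == 0 or count > prev_count:
                flag = 0
            elif count < prev_count:
                flag = 1
            else:
                flag = 1 if np.array_equal(exemplars, prev_exemplars) else 0
            state.flags.append(flag)
        prev_count = count
        if adaptive:
            adapt_damping(state, window_len)
        state.lam_history.append(state.lam)

        if prev_exemplars is not None and np.array_equal(exemplars, prev_exemplars):
            stable += 1
            if stable >= stable_iters and exemplars.size > 0:
                break
        else:
            stable = 0
        prev_exemplars = exemplars

    if exemplars.size == 0:
        decision = state.responsibility.diagonal() + state.availability.diagonal()
        warnings.warn("AP converged with no positive exemplar; "
                      "falling back to the best decision value")
        exemplars = np.array([int(np.argmax(decision))])

    labels = _assign(state.similarity, exemplars)
    centers = state.points[exemplars]
    return ClusterResult(n_clusters=exemplars.size, exemplars=exemplars,
                         labels=labels, centers=centers)


def _assign(similarity: np.ndarray, exemplars: np.ndarray) -> np.ndarray:
    """Label each point by its most similar exemplar (lowest index wins
    ties); exemplars label themselves."""
    sub = similarity[:, exemplars]
    labels = np.argmax(sub, axis=1)
    for j, k in enumerate(exemplars):
        labels[k] = j
    return labels


def brute_force_exemplars(similarity: np.ndarray):
    """Exhaustive exemplar-subset search maximising the AP objective
    sum_i s(i, exemplar(i)) (preferences included for exemplars).

    Exponential in L — an oracle for small instances only (L <= ~14).
    """
    n = similarity.shape[0]
    if n > 16:
        raise ValueError("brute force limited to small instances")
    best, best_set = -np.inf, None
    for mask in range(1, 1 << n):
        subset = [k for k in range(n) if mask >> k & 1]
        score = sum(similarity[k, k] for k in subset)
        others = [i for i in range(n) if i not in subset]
        if others:
            score += similarity[np.ix_(others, subset)].max(axis=1).sum()
        if score > best + 1e-12:
            best, best_set = score, subset
    return np.array(best_set), best


# ---------------------------------------------------------------------------
# K-means refinement and cluster scoring
# ---------------------------------------------------------------------------

def kmeans_refine(points, init_centers, max_iter: int = 100,
                  tol: float = 1e-8) -> ClusterResult:
    """Lloyd iteration from the AP exemplars.

    Assignment by squared Euclidean distance, centre update by cluster
    mean; the sum-of-squares objective is recorded every iteration and is
    non-increasing.  An emptied cluster is re-seeded to the point farthest
    from all remaining centres (with a warning).  Stops when no centre
    moves more than ``tol`` or after ``max_iter`` iterations.
    """
    feats = points.features if hasattr(points, "features") else np.asarray(points)
    feats = np.asarray(feats, dtype=np.float64)
    centers = np.array(init_centers, dtype=np.float64, copy=True)
    if centers.ndim != 2 or centers.shape[0] < 1:
        raise ValueError("need at least one initial center")
    history = []
    labels = np.zeros(feats.shape[0], dtype=int)

    for _ in range(max_iter):
        d2 = np.sum((feats[:, None, :] - centers[None, :, :]) ** 2, axis=-1)
        labels = np.argmin(d2, axis=1)
        new_centers = centers.copy()
        for j in range(centers.shape[0]):
            members = feats[labels == j]
            if members.size:
                new_centers[j] = members.mean(axis=0)
            else:
                far = np.argmax(d2.min(axis=1))
                new_centers[j] = feats[far]
                warnings.warn(f"k-means cluster {j} emptied; re-seeded to the "
                              "farthest point")
        d2_new = np.sum((feats[:, None, :] - new_centers[None, :, :]) ** 2, axis=-1)
        obj = float(d2_new.min(axis=1).sum())
        history.append(obj)
        shift = float(np.max(np.linalg.norm(new_centers - centers, axis=1)))
        centers = new_centers
        if shift < tol:
            break

    d2 = np.sum((feats[:, None, :] - centers[None, :, :]) ** 2, axis=-1)
    labels = np.argmin(d2, axis=1)
    return ClusterResult(n_clusters=centers.shape[0],
                         exemplars=np.array([], dtype=int), labels=labels,
                         centers=centers, objective=history[-1],
                         objective_history=history)


def silhouette(points, labels) -> float:
    """Mean silhouette coefficient (z - h)/max(h, z) in [-1, 1].

    A single cluster leaves the coefficient undefined; NaN is returned
    with a warning in that case.
    """
    feats = points.features if hasattr(points, "features") else np.asarray(points)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        warnings.warn("silhouette undefined for a single cluster; returning NaN")
        return float("nan")
    from sklearn.metrics import silhouette_score

    return float(silhouette_score(feats, labels))


# ---------------------------------------------------------------------------
# End-to-end matrix estimation
# ---------------------------------------------------------------------------

def estimate_mixing_matrix(mixtures, config=None, **overrides):
    """Estimate the source count and mixing matrix from mixtures.

    Pipeline: SSP extraction -> (optional Hankel/SVD denoising) ->
    direction normalisation -> seeded subsampling to ``l_max`` points ->
    adaptive-damping AP -> K-means refinement over all points -> columns
    of the estimate are the final centroids rescaled to unit norm.

    Returns ``(MixingMatrix estimate, ClusterResult, diagnostics dict)``.
    """
    from .config import RunConfig

    cfg = config or RunConfig()
    if overrides:
        cfg = cfg.replace(**overrides)

    x = mixtures
    if cfg.svd_denoise:
        from .audio import MixtureSet

        data = np.vstack([
            _blockwise_denoise(s.samples, cfg.energy_keep) for s in x
        ])
        x = MixtureSet.from_array(data, x.sample_rate)

    ssps = _tf.extract_ssp(x, cfg.window_len, cfg.hop, cfg.window,
                           cfg.energy_threshold, cfg.eps1, cfg.eps2,
                           cfg.group_size)
    if len(ssps) == 0:
        raise RuntimeError(
            "no single-source points survived the screens; relax the "
            "thresholds (e, eps1, eps2) or supply longer mixtures"
        )

    feats = canonicalize_directions(ssps.features)
    rng = np.random.default_rng(cfg.seed)
    if feats.shape[0] > cfg.l_max:
        pick = rng.choice(feats.shape[0], size=cfg.l_max, replace=False)
        ap_feats = feats[pick]
    else:
        ap_feats = feats

    state = build_similarity(ap_feats, normalize=False, lam=cfg.lambda_init)
    ap_res = ap_cluster(state, cfg.ap_max_iter, cfg.ap_stable_iters,
                        adaptive=True, window_len=cfg.damping_window)

    km = kmeans_refine(feats, ap_res.centers)
    km.silhouette_score = silhouette(feats, km.labels) if km.n_clusters > 1 \
        else float("nan")

    cols = canonicalize_directions(km.centers).T
    a_est = MixingMatrix(cols, method="estimated",
                         params={"n_ssp": len(ssps),
                                 "n_clusters": km.n_clusters},
                         min_separation_deg=0.0)
    diagnostics = {
        "n_ssp": len(ssps),
        "n_ap_points": int(ap_feats.shape[0]),
        "n_clusters": int(km.n_clusters),
        "lambda_trajectory": list(state.lam_history),
        "lambda_final": float(state.lam),
        "cluster_count_trajectory": list(state.count_history),
        "ap_iterations": int(state.iteration),
        "silhouette": float(km.silhouette_score),
        "kmeans_objective": float(km.objective),
    }
    logger.info("estimated mixing matrix: %d SSPs, %d clusters, lambda end %.2f, SC %.3f",
                diagnostics["n_ssp"], diagnostics["n_clusters"],
                diagnostics["lambda_final"], diagnostics["silhouette"])
    return a_est, km, diagnostics


def matrix_error(a_true, a_est) -> float:
    """Mean per-column angular deviation (degrees) under the best column
    permutation (exhaustive for N <= 6).  A column-count mismatch is
    reported as +inf."""
    at = np.asarray(a_true, dtype=np.float64)
    ae = np.asarray(a_est, dtype=np.float64)
    if at.shape[1] != ae.shape[1]:
        warnings.warn(f"column count mismatch: {at.shape[1]} vs {ae.shape[1]}")
        return float("inf")
    ut = canonicalize_directions(at.T)
    ue = canonicalize_directions(ae.T)
    n = ut.shape[0]
    cos = np.clip(np.abs(ue @ ut.T), 0.0, 1.0)  # |cos| between lines
    ang = np.degrees(np.arccos(cos))
    best = np.inf
    for perm in permutations(range(n)):
        err = float(np.mean(ang[list(perm), np.arange(n)]))
        best = min(best, err)
    return best
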