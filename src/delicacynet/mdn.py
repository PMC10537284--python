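"""Distribution-partition normalization (MDN).

The layer groups the feature planes (channels) of a tensor by distributional
similarity and divides each group by its Euclidean norm.  Similarity is
measured with the KL divergence between per-plane value histograms; the
reference distributions are the histograms of the planes with the most
extreme mean absolute activation (subject vs environment proxy).  The
partition assignment is recomputed on every forward pass and treated as
non-differentiable routing; the norm division itself is smooth and receives
exact gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, custom_op
from .nn import Module

__all__ = [
    "kl_divergence",
    "plane_histogram",
    "partition_planes",
    "mdn_normalize",
    "PartitionMap",
    "MDNLayer",
]

SMOOTH_EPS = 1e-8


@dataclass(frozen=True)
class PartitionMap:
    """Per-plane partition labels in {0..K-1}."""

    assignment: np.ndarray
    n_partitions: int

    def __post_init__(self):
        a = np.asarray(self.assignment)
        if a.ndim != 1:
            raise ValueError("assignment must be a 1-D label vector")
        if self.n_partitions < 1:
            raise ValueError("need at least one partition")
        if a.size and (a.min() < 0 or a.max() >= self.n_partitions):
            raise ValueError("labels out of range")


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """KL(P || Q) = sum P(x) ln(P(x)/Q(x)) in nats.

    Terms with P(x)=0 contribute 0.  Where Q(x)=0 but P(x)>0 the divergence
    is infinite in principle; Q is floored at a tiny constant there so the
    result is a large finite number usable for nearest-reference routing.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError(f"distribution length mismatch: {p.shape} vs {q.shape}")
    mask = p > 0
    qa = np.where(q <= 0, 1e-300, q)
    return float(np.sum(p[mask] * np.log(p[mask] / qa[mask])))


def plane_histogram(plane: np.ndarray, n_bins: int) -> np.ndarray:
    """Normalized equal-width histogram over the plane's own min-max range.

    A constant plane puts all its mass in the first bin.  Values exactly on
    an interior bin edge fall into the right-hand bin; the maximum falls in
    the last bin.
    """
    if n_bins < 1:
        raise ValueError(f"bin count must be >= 1, got {n_bins}")
    x = np.asarray(plane, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty plane")
    lo, hi = x.min(), x.max()
    if hi <= lo:
        h = np.zeros(n_bins)
        h[0] = 1.0
        return h
    idx = np.clip(((x - lo) / (hi - lo) * n_bins).astype(np.int64), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(np.float64)
    return counts / counts.sum()


def _plane_histograms(planes: np.ndarray, n_bins: int) -> np.ndarray:
    """Vectorized per-plane histograms over the *shared* value range.

    planes is (C, n_values).  Unlike :func:`plane_histogram` (whose contract
    is a plane's own min-max range), partitioning needs plane distributions
    to be comparable, so all planes are binned over the tensor-wide range;
    constant-but-different planes then land in different bins.
    """
    c, n = planes.shape
    lo, hi = planes.min(), planes.max()
    if hi <= lo:
        hists = np.zeros((c, n_bins))
        hists[:, 0] = 1.0
        return hists
    idx = np.clip(((planes - lo) / (hi - lo) * n_bins).astype(np.int64), 0, n_bins - 1)
    flat = idx + np.arange(c)[:, None] * n_bins
    counts = np.bincount(flat.ravel(), minlength=c * n_bins).astype(np.float64)
    hists = counts.reshape(c, n_bins)
    return hists / hists.sum(axis=1, keepdims=True)


def _kl_matrix(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Pairwise KL(p_i || q_j) for row-stochastic matrices p (C,B), q (K,B)."""
    ps = _smoothed_rows(p)
    qs = _smoothed_rows(q)
    # sum_b p_ib (ln p_ib - ln q_jb)
    ent = np.sum(ps * np.log(ps), axis=1)
    cross = ps @ np.log(qs).T
    return ent[:, None] - cross


def _smoothed_rows(h: np.ndarray) -> np.ndarray:
    s = h + SMOOTH_EPS
    return s / s.sum(axis=1, keepdims=True)


def partition_planes(t: np.ndarray, n_partitions: int, n_bins: int = 32) -> PartitionMap:
    """Assign each feature plane of a (C,H,W) tensor to one of K partitions.

    References for K=2 are the histograms of the planes with the highest and
    lowest mean absolute activation; for K>2, K-medoids under KL divergence
    seeded with evenly spaced activation ranks.  Assignment ties break toward
    the lower partition index.
    """
    t = np.asarray(t, dtype=np.float64)
    if t.ndim != 3:
        raise ValueError(f"expected (C,H,W) tensor, got shape {t.shape}")
    c = t.shape[0]
    if n_partitions < 1:
        raise ValueError("need at least one partition")
    if n_partitions > c:
        raise ValueError(f"K={n_partitions} exceeds plane count {c}")
    if n_partitions == 1:
        return PartitionMap(np.zeros(c, dtype=np.int64), 1)

    planes = t.reshape(c, -1)
    hists = _plane_histograms(planes, n_bins)
    mean_abs = np.abs(planes).mean(axis=1)
    order = np.argsort(mean_abs, kind="stable")

    if n_partitions == 2:
        refs_idx = np.array([order[-1], order[0]])  # highest first, lowest second
        refs = hists[refs_idx]
        kl = _kl_matrix(hists, refs)
        return PartitionMap(np.argmin(kl, axis=1).astype(np.int64), 2)

    # K-medoids under KL, deterministic rank-spread initialization
    ranks = np.linspace(0, c - 1, n_partitions).round().astype(int)
    medoids = list(order[ranks])
    for _ in range(10):
        kl = _kl_matrix(hists, hists[medoids])
        labels = np.argmin(kl, axis=1)
        new_medoids = []
        for k in range(n_partitions):
            members = np.where(labels == k)[0]
            if members.size == 0:
                new_medoids.append(medoids[k])
                continue
            within = _kl_matrix(hists[members], hists[members]).sum(axis=0)
            new_medoids.append(int(members[np.argmin(within)]))
        if new_medoids == medoids:
            break
        medoids = new_medoids
    kl = _kl_matrix(hists, hists[medoids])
    return PartitionMap(np.argmin(kl, axis=1).astype(np.int64), n_partitions)


def mdn_normalize(t: np.ndarray, pm: PartitionMap) -> np.ndarray:
    """Divide every element by the Euclidean norm of its partition's elements.

    Partitions with zero norm pass through unchanged, so an all-zero tensor
    is a fixed point.
    """
    t = np.asarray(t, dtype=np.float64)
    labels = np.asarray(pm.assignment)
    if labels.shape[0] != t.shape[0]:
        raise ValueError("partition map does not cover all planes")
    out = t.copy()
    for k in range(pm.n_partitions):
        members = labels == k
        if not members.any():
            continue
        norm = np.sqrt(np.sum(t[members] ** 2))
        if norm > 0:
            out[members] = t[members] / norm
    return out


class MDNLayer(Module):
    """Differentiable MDN layer for batched (N,C,H,W) tensors.

    Partitioning is recomputed per sample per forward pass from the current
    activations (non-differentiable routing); division by the partition norm
    gets the exact gradient d(x/l)/dx = g/l - x (x.g)/l^3.
    """

    def __init__(self, n_partitions: int = 2, n_bins: int = 32):
        self.n_partitions = n_partitions
        self.n_bins = n_bins

    def __call__(self, x: Tensor) -> Tensor:
        data = x.data
        n = data.shape[0]
        out = np.empty_like(data)
        # per (sample, partition) member masks and norms, reused in backward
        plan: list[list[tuple[np.ndarray, float]]] = []
        for s in range(n):
            pm = partition_planes(data[s], self.n_partitions, self.n_bins)
            groups = []
            out[s] = data[s]
            for k in range(pm.n_partitions):
                members = pm.assignment == k
                if not members.any():
                    continue
                norm = float(np.sqrt(np.sum(data[s][members] ** 2)))
                if norm > 0:
                    out[s][members] = data[s][members] / norm
                groups.append((members, norm))
            plan.append(groups)

        def bwd(g):
            gx = np.zeros_like(data)
            for s in range(n):
                for members, norm in plan[s]:
                    if norm <= 0:
                        gx[s][members] = g[s][members]
                        continue
                    xs = data[s][members]
                    gs = g[s][members]
                    dot = np.sum(xs * gs)
                    gx[s][members] = gs / norm - xs * (dot / norm**3)
            return (gx,)

        return custom_op((x,), out, bwd)
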