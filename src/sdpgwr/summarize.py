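"""Point cluster configurations and per-cluster parameter summaries.

Posterior label draws are reduced to a single clustering in two ways:

* Dahl's least-squares method: pick the retained draw whose pairwise
  co-clustering (membership) matrix is closest in squared distance to the
  posterior mean co-clustering matrix;
* the posterior mode: after aligning every draw's labels to the Dahl
  draw (greedy best-match on the confusion matrix), give each area its
  most frequent label.

Per-cluster coefficient summaries report posterior means and 95% highest
posterior density (HPD) intervals, computed from draws aligned to the
chosen configuration.  All of this is invariant to label switching during
sampling, which is deliberately left unrestricted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mcmc import PosteriorSamples


@dataclass
class ClusterSolution:
    """A point clustering with provenance and per-cluster summaries."""

    labels: np.ndarray            # (n,) contiguous integers starting at 1
    source: str                   # "dahl" | "mode"
    draw_index: int | None = None
    table: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels)[1:]


def membership_matrix(z: np.ndarray) -> np.ndarray:
    """Binary co-clustering matrix B with B[i, j] = 1 iff z_i = z_j."""
    z = np.asarray(z)
    return (z[:, None] == z[None, :]).astype(np.int8)


def coclustering_probability(z_draws: np.ndarray) -> np.ndarray:
    """Posterior mean co-clustering matrix B-bar (entries in [0, 1])."""
    z_draws = np.atleast_2d(z_draws)
    M, n = z_draws.shape
    bbar = np.zeros((n, n))
    for c in range(M):
        bbar += z_draws[c, :, None] == z_draws[c, None, :]
    return bbar / M


def _relabel_contiguous(z: np.ndarray) -> np.ndarray:
    """Map labels to 1..k in order of first appearance."""
    z = np.asarray(z)
    out = np.empty(z.shape[0], dtype=int)
    seen: dict = {}
    for i, v in enumerate(z):
        out[i] = seen.setdefault(v, len(seen) + 1)
    return out


def dahl_select(z_draws: np.ndarray) -> tuple[int, ClusterSolution]:
    """Least-squares draw selection against the mean co-clustering matrix.

    For binary B, sum((B - Bbar)^2) = sum(B) - 2 <B, Bbar> + sum(Bbar^2),
    so the scan needs one pass of inner products.  Ties break to the
    lowest draw index.
    """
    z_draws = np.atleast_2d(np.asarray(z_draws))
    M, n = z_draws.shape
    bbar = coclustering_probability(z_draws)
    const = float((bbar ** 2).sum())
    best_idx, best_dist = 0, np.inf
    for c in range(M):
        B = z_draws[c, :, None] == z_draws[c, None, :]
        dist = B.sum() - 2.0 * bbar[B].sum() + const
        if dist < best_dist - 1e-12:
            best_idx, best_dist = c, dist
    labels = _relabel_contiguous(z_draws[best_idx])
    return best_idx, ClusterSolution(labels=labels, source="dahl",
                                     draw_index=best_idx)


def _greedy_match(ref: np.ndarray, z: np.ndarray) -> dict:
    """Greedy confusion-matrix matching: map labels of ``z`` onto labels of
    ``ref`` by repeatedly pairing the labels with maximal overlap.
    Deterministic: ties break on smaller (ref label, z label)."""
    ref_labels = np.unique(ref)
    z_labels = np.unique(z)
    overlap = {(a, b): int(np.sum((ref == a) & (z == b)))
               for a in ref_labels for b in z_labels}
    mapping: dict = {}
    used_ref, used_z = set(), set()
    pairs = sorted(overlap.items(), key=lambda kv: (-kv[1], kv[0]))
    for (a, b), cnt in pairs:
        if a in used_ref or b in used_z:
            continue
        mapping[b] = a
        used_ref.add(a)
        used_z.add(b)
    # unmatched draw labels keep distinct labels beyond the reference's
    next_label = int(ref_labels.max()) + 1
    for b in z_labels:
        if b not in mapping:
            mapping[b] = next_label
            next_label += 1
    return mapping


def align_draws(z_draws: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Relabel every draw to best agree with ``reference`` (greedy match)."""
    z_draws = np.atleast_2d(np.asarray(z_draws))
    out = np.empty_like(z_draws)
    for c in range(z_draws.shape[0]):
        mapping = _greedy_match(reference, z_draws[c])
        out[c] = np.vectorize(mapping.__getitem__)(z_draws[c])
    return out


def mode_assignment(z_draws: np.ndarray,
                    reference: np.ndarray | None = None) -> ClusterSolution:
    """Per-area posterior-mode labels after alignment to a reference draw.

    The reference defaults to the Dahl selection.  Ties in the per-area
    frequency break to the smaller label.
    """
    z_draws = np.atleast_2d(np.asarray(z_draws))
    if reference is None:
        _, dahl = dahl_select(z_draws)
        reference = dahl.labels
    aligned = align_draws(z_draws, reference)
    n = z_draws.shape[1]
    labels = np.empty(n, dtype=int)
    for i in range(n):
        counts = np.bincount(aligned[:, i])
        labels[i] = int(np.argmax(counts))   # argmax takes the smaller on ties
    return ClusterSolution(labels=_relabel_contiguous(labels), source="mode")


def hpd_interval(samples: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval of sorted samples holding ``level`` mass.

    Uses ceil(level * M) order statistics; among equal-width windows the
    earliest start wins.
    """
    samples = np.sort(np.asarray(samples, dtype=float).ravel())
    M = samples.shape[0]
    if M == 0:
        raise ValueError("empty sample")
    if not 0.0 < level <= 1.0:
        raise ValueError("level must be in (0, 1]")
    m = int(np.ceil(level * M))
    if m < 1:
        m = 1
    if m >= M:
        return float(samples[0]), float(samples[-1])
    widths = samples[m - 1:] - samples[: M - m + 1]
    start = int(np.argmin(widths))           # argmin returns earliest tie
    return float(samples[start]), float(samples[start + m - 1])


def aligned_cluster_beta(samples: PosteriorSamples, solution: ClusterSolution) -> np.ndarray:
    """(M, k, p) array of beta draws matched to the solution's clusters.

    Each draw's labels are aligned to the solution; solution cluster c then
    takes the draw's coefficient vector of its matched label.  Draws in
    which a solution cluster has no matched label hold NaN for it.
    """
    M = samples.n_draws
    k = solution.n_clusters
    p = samples.beta.shape[2]
    out = np.full((M, k, p), np.nan)
    ref = solution.labels
    for c in range(M):
        z = samples.z[c]
        mapping = _greedy_match(ref, z)       # draw label -> solution label
        for draw_label, sol_label in mapping.items():
            if 1 <= sol_label <= k:
                out[c, sol_label - 1] = samples.beta[c, draw_label]
    return out


def cluster_table(samples: PosteriorSamples, solution: ClusterSolution,
                  level: float = 0.95) -> pd.DataFrame:
    """Per-cluster, per-covariate posterior means and HPD intervals."""
    draws = aligned_cluster_beta(samples, solution)
    k, p = draws.shape[1], draws.shape[2]
    sizes = np.bincount(solution.labels, minlength=k + 1)[1:]
    rows = []
    for c in range(k):
        for j in range(p):
            col = draws[:, c, j]
            col = col[np.isfinite(col)]
            if col.size == 0:
                rows.append({"cluster": c + 1, "covariate": j + 1,
                             "size": int(sizes[c]), "mean": np.nan,
                             "hpd_lo": np.nan, "hpd_hi": np.nan,
                             "empty": True})
                continue
            lo, hi = hpd_interval(col, level)
            rows.append({"cluster": c + 1, "covariate": j + 1,
                         "size": int(sizes[c]), "mean": float(col.mean()),
                         "hpd_lo": lo, "hpd_hi": hi, "empty": sizes[c] == 0})
    return pd.DataFrame(rows)


def posterior_area_coefficients(samples: PosteriorSamples) -> np.ndarray:
    """(n, p) per-area posterior mean coefficients: the mean over draws of
    the coefficient vector of the cluster each area occupies in that draw."""
    M, n = samples.z.shape
    p = samples.beta.shape[2]
    acc = np.zeros((n, p))
    for c in range(M):
        acc += samples.beta[c, samples.z[c]]
    return acc / M
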