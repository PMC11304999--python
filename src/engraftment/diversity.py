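"""Alpha diversity, Bray-Curtis dissimilarity, PCoA and one-way PERMANOVA.

These community-ecology primitives are implemented directly from their
definitions so every numerical choice is explicit:

* Shannon entropy H = -sum p_i ln p_i over non-zero proportions (natural log,
  the ecology convention; the base is recorded in the output name).
* Bray-Curtis d(a, b) = sum|a_i - b_i| / sum(a_i + b_i), bounded in [0, 1]
  for non-negative profiles. The default pipeline computes it on log10
  depth-scaled abundances, which up-weights low-abundance taxa relative to
  raw proportions; Euclidean-on-log is available as an alternative metric.
* PCoA: double-centering B = -1/2 J D^2 J, symmetric eigendecomposition,
  coordinates from positive eigenvalues only. Negative eigenvalues (metricity
  violations of a non-Euclidean dissimilarity) are reported, not corrected.
  Axis signs are fixed by making the largest-magnitude coordinate on each
  axis positive, so results are deterministic.
* PERMANOVA: one-way pseudo-F from within/between sums of squared distances,
  permutation p-value with the +1 convention; R^2 = 1 - SS_within/SS_total
  is the fraction of distance variance explained by the grouping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "PermanovaResult",
    "shannon",
    "bray_curtis",
    "distance_matrix",
    "pcoa",
    "permanova",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative dissimilarity matrix with zero diagonal."""

    sample_ids: tuple[str, ...]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        n = len(self.sample_ids)
        if d.shape != (n, n):
            raise ValueError(f"shape {d.shape} does not match {n} sample ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (d < -1e-12).any():
            raise ValueError("negative distances")
        object.__setattr__(self, "data", d)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.data, index=list(self.sample_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class OrdinationResult:
    """Principal-coordinate embedding of a dissimilarity matrix.

    ``coordinates`` has one row per sample and one column per positive axis,
    ordered by decreasing eigenvalue; ``eigenvalues`` keeps all signed
    eigenvalues so metricity violations are visible.
    """

    sample_ids: tuple[str, ...]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=list(self.sample_ids), columns=cols)


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "pseudo_F": self.pseudo_f,
            "R2": self.r_squared,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def shannon(counts: np.ndarray | pd.Series) -> float:
    """Shannon entropy in nats of one sample's counts (or proportions)."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("negative counts")
    total = x.sum()
    if total <= 0:
        raise ValueError("sample has zero depth")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(a: np.ndarray | pd.Series, b: np.ndarray | pd.Series) -> float:
    """Bray-Curtis dissimilarity between two non-negative profiles."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("profiles must be non-negative")
    denom = (a + b).sum()
    if denom == 0:
        raise ValueError("both profiles are all-zero")
    return float(np.abs(a - b).sum() / denom)


def distance_matrix(
    profiles: pd.DataFrame, metric: str = "bray_curtis"
) -> DistanceMatrix:
    """All-pairs dissimilarity over the columns (samples) of a profile table.

    ``metric`` is ``'bray_curtis'`` or ``'euclidean'``; profiles are used as
    given (pass log10-normalized values for the log-ordinated variant).
    """
    samples = tuple(profiles.columns)
    x = profiles.to_numpy(dtype=float).T  # samples x features
    n = len(samples)
    d = np.zeros((n, n))
    if metric == "bray_curtis":
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = bray_curtis(x[i], x[j])
    elif metric == "euclidean":
        sq = (x**2).sum(axis=1)
        g = x @ x.T
        d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * g, 0.0)
        d = np.sqrt(d2)
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(sample_ids=samples, data=d)


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Principal coordinates analysis by double-centering and eigendecomposition."""
    n = dm.n
    if n < 3:
        raise ValueError(f"PCoA needs >= 3 samples, got {n}")
    d2 = dm.data**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    tol = 1e-9 * max(abs(eigvals[0]), 1.0)
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    # deterministic sign: largest-magnitude coordinate on each axis positive
    for k in range(coords.shape[1]):
        idx = np.argmax(np.abs(coords[:, k]))
        if coords[idx, k] < 0:
            coords[:, k] = -coords[:, k]
    pos_sum = eigvals[positive].sum()
    prop = eigvals[positive] / pos_sum if pos_sum > 0 else eigvals[positive]
    return OrdinationResult(
        sample_ids=dm.sample_ids,
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


def _permanova_stats(
    d2: np.ndarray, group_masks: np.ndarray, group_sizes: np.ndarray, ss_total: float
) -> tuple[float, float]:
    """Pseudo-F and R^2 for one labelling, from the squared distance matrix.

    SS_within = sum over groups of (sum of squared distances within the
    group) / group size; SS_total uses all pairs / n.
    """
    ss_within = 0.0
    for mask, size in zip(group_masks, group_sizes):
        sub = d2[np.ix_(mask, mask)]
        ss_within += sub.sum() / (2.0 * size)
    ss_between = ss_total - ss_within
    a = len(group_sizes)
    n = int(group_sizes.sum())
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total
    return f, r2


def permanova(
    dm: DistanceMatrix,
    labels: list[str] | np.ndarray | pd.Series,
    n_perm: int = 999,
    seed: int = 0,
    method: str = "sampled",
) -> PermanovaResult:
    """One-way PERMANOVA of a dissimilarity matrix against a grouping factor.

    With ``method='sampled'`` (default) ``n_perm`` random label permutations
    are drawn from ``numpy.random.default_rng(seed)`` and
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm): p is never 0 and its
    smallest attainable value is 1/(n_perm + 1). With ``method='exhaustive'``
    every distinct relabelling is enumerated (small n only) and p is the
    exact fraction #{F_perm >= F_obs} / #relabellings, the identity included.
    """
    labels = np.asarray(labels)
    if len(labels) != dm.n:
        raise ValueError("labels length does not match distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = [str(u) for u, s in zip(uniq, sizes) if s < 2]
        raise ValueError(f"groups with fewer than 2 samples: {small}")

    d2 = dm.data**2
    n = dm.n
    ss_total = d2.sum() / (2.0 * n)
    masks = np.stack([codes == g for g in range(len(uniq))])
    sizes_f = sizes.astype(float)
    f_obs, r2 = _permanova_stats(d2, masks, sizes_f, ss_total)

    if method == "exhaustive":
        from itertools import permutations as _perms

        seen: set[tuple[int, ...]] = set()
        count_ge = 0
        for perm in _perms(range(n)):
            key = tuple(codes[list(perm)])
            if key in seen:
                continue
            seen.add(key)
            f_perm, _ = _permanova_stats(d2, masks[:, list(perm)], sizes_f, ss_total)
            if f_perm >= f_obs - 1e-12:
                count_ge += 1
        p = count_ge / len(seen)
        n_done = len(seen)
    elif method == "sampled":
        if n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        rng = np.random.default_rng(seed)
        count_ge = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            f_perm, _ = _permanova_stats(d2, masks[:, perm], sizes_f, ss_total)
            if f_perm >= f_obs:
                count_ge += 1
        p = (1 + count_ge) / (1 + n_perm)
        n_done = n_perm
    else:
        raise ValueError(f"unknown method {method!r}")
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r_squared=float(r2),
        p_value=float(p),
        n_permutations=n_done,
        seed=seed,
    )
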