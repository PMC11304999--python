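"""Pairwise rank-sum differential abundance with prevalence filtering and FDR.

The testing recipe for each unordered pair of groups: taxa present (count
>= 1) in fewer than a stated fraction of all samples in the pair's universe
are excluded *before* testing (default threshold 10%, with exactly-10%
retained — "less than" is strict), a two-sided Wilcoxon rank-sum test is run
on relative abundances for each retained taxon, and Benjamini-Hochberg
adjustment is applied within that pair's taxon family. Taxa with q below the
FDR cutoff (default 0.1) are flagged significant.

The rank-sum test uses midranks for ties. Exact p-values enumerate all
C(n_a + n_b, n_a) group splits (feasible for n_a + n_b <= 12); otherwise a
normal approximation with tie-corrected variance and a 0.5 continuity
correction is used. When every observation is identical across both groups
the test is degenerate and p = 1 by convention (flagged in the output).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_tables import StudyBundle
from .normalization import relative_abundance
from .transfer import aggregate_to_rank

__all__ = [
    "DiffAbResult",
    "prevalence_filter",
    "rank_sum_test",
    "bh_fdr",
    "pairwise_group_tests",
    "top_taxa_summary",
]

EXACT_MAX_N = 12


@dataclass(frozen=True)
class DiffAbResult:
    """Per-taxon differential-abundance results for one group pair.

    ``table`` rows are all taxa in the comparison universe; taxa failing the
    prevalence filter carry NaN p/q (excluded before testing, not after).
    """

    group_a: str
    group_b: str
    rank: str
    prevalence_threshold: float
    fdr_cutoff: float
    table: pd.DataFrame

    @property
    def significant(self) -> pd.DataFrame:
        t = self.table
        return t[t["significant"]]

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def prevalence_filter(
    table: pd.DataFrame, threshold: float = 0.10
) -> tuple[pd.Index, pd.Series]:
    """Taxa retained by prevalence across ALL samples of the comparison universe.

    ``table`` is taxa x samples (counts or abundances; presence means value
    >= any positive amount, i.e. nonzero). Returns (retained taxon index,
    per-taxon prevalence). Boundary rule: prevalence exactly equal to the
    threshold is retained.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    prevalence = (table > 0).sum(axis=1) / table.shape[1]
    retained = prevalence.index[prevalence >= threshold]
    return retained, prevalence


def _u_statistic(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, np.ndarray]:
    pooled = np.concatenate([values_a, values_b])
    ranks = rankdata(pooled)  # midranks for ties
    n_a = len(values_a)
    rank_sum_a = ranks[:n_a].sum()
    u_a = rank_sum_a - n_a * (n_a + 1) / 2.0
    return u_a, ranks


def rank_sum_test(
    values_a: np.ndarray | list,
    values_b: np.ndarray | list,
    mode: str = "auto",
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Returns ``(U_a, p)`` where ``U_a`` is the Mann-Whitney U of the first
    group. ``mode`` is ``'exact'`` (full enumeration of group splits,
    n_a + n_b <= 12), ``'normal_approx'`` (tie-corrected variance, 0.5
    continuity correction) or ``'auto'`` (exact when feasible).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a < 2 or n_b < 2:
        raise ValueError(f"each group needs >= 2 values (got {n_a}, {n_b})")
    u_a, ranks = _u_statistic(a, b)
    n = n_a + n_b

    if np.ptp(np.concatenate([a, b])) == 0:
        return u_a, 1.0  # degenerate: all observations identical

    if mode == "auto":
        mode = "exact" if n <= EXACT_MAX_N else "normal_approx"
    if mode == "exact":
        if n > EXACT_MAX_N:
            raise ValueError(f"exact mode limited to n_a+n_b <= {EXACT_MAX_N}")
        mu = n_a * n_b / 2.0
        obs_dev = abs(u_a - mu)
        count = 0
        total = 0
        for idx in combinations(range(n), n_a):
            rank_sum = ranks[list(idx)].sum()
            u = rank_sum - n_a * (n_a + 1) / 2.0
            total += 1
            if abs(u - mu) >= obs_dev - 1e-12:
                count += 1
        return u_a, count / total
    if mode == "normal_approx":
        mu = n_a * n_b / 2.0
        # tie correction: subtract sum(t^3 - t) over tie groups
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
        dev = abs(u_a - mu)
        z = max(dev - 0.5, 0.0) / np.sqrt(var)
        from scipy.stats import norm

        p = min(1.0, 2.0 * norm.sf(z))
        return u_a, float(p)
    raise ValueError(f"unknown mode {mode!r}")


def bh_fdr(p_values: np.ndarray | list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (q-values).

    q_(i) = min over j >= i of p_(j) * m / j, capped at 1; always >= p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def pairwise_group_tests(
    bundle: StudyBundle,
    groups: list[str],
    rank: str = "genus",
    threshold: float = 0.10,
    fdr_cutoff: float = 0.1,
    mode: str = "auto",
) -> dict[tuple[str, str], DiffAbResult]:
    """Differential abundance for every unordered pair of the given groups.

    For each pair: collapse counts to the rank, restrict to the pair's
    samples, prevalence-filter, test retained taxa on relative abundances,
    BH-adjust within that pair's family, flag q < cutoff. BH families are
    per-pair, matching per-pair significant-taxon reporting.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    collapsed = aggregate_to_rank(bundle.counts, bundle.taxonomy, rank)
    results: dict[tuple[str, str], DiffAbResult] = {}
    for ga, gb in combinations(groups, 2):
        sa = bundle.samples_in_group(ga)
        sb = bundle.samples_in_group(gb)
        if len(sa) < 2 or len(sb) < 2:
            raise ValueError(f"group of size < 2 in pair ({ga}, {gb})")
        universe = collapsed.subset_samples(sa + sb)
        rel = relative_abundance(universe)
        retained, prevalence = prevalence_filter(universe.counts, threshold)
        rows = []
        p_list = []
        for taxon in rel.index:
            mean_a = float(rel.loc[taxon, sa].mean())
            mean_b = float(rel.loc[taxon, sb].mean())
            if taxon in retained:
                stat, p = rank_sum_test(
                    rel.loc[taxon, sa].to_numpy(), rel.loc[taxon, sb].to_numpy(), mode
                )
                p_list.append(p)
            else:
                stat, p = np.nan, np.nan
            rows.append((taxon, mean_a, mean_b, float(prevalence[taxon]), stat, p))
        df = pd.DataFrame(
            rows,
            columns=["taxon", "mean_a", "mean_b", "prevalence", "statistic", "p"],
        ).set_index("taxon")
        df["retained"] = df.index.isin(retained)
        df["q"] = np.nan
        if p_list:
            df.loc[df["retained"], "q"] = bh_fdr(np.asarray(p_list))
        df["significant"] = df["q"] < fdr_cutoff
        results[(ga, gb)] = DiffAbResult(
            group_a=ga,
            group_b=gb,
            rank=rank,
            prevalence_threshold=threshold,
            fdr_cutoff=fdr_cutoff,
            table=df,
        )
    return results


def top_taxa_summary(
    bundle: StudyBundle,
    rank: str = "genus",
    n_top: int = 8,
    group_by: str = "group",
) -> pd.DataFrame:
    """Mean relative abundance of the globally top-N taxa per group, plus "Other".

    Taxa are ranked by mean relative abundance across ALL samples; each
    group's row reports the group means of those taxa and
    ``Other = 1 - their sum``, so rows sum to 1.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    collapsed = aggregate_to_rank(bundle.counts, bundle.taxonomy, rank)
    rel = relative_abundance(collapsed)
    top = rel.mean(axis=1).sort_values(ascending=False).index[:n_top]
    groups = bundle.metadata.table[group_by]
    rows = {}
    for group in dict.fromkeys(groups):
        samples = groups.index[groups == group]
        means = rel.loc[top, samples].mean(axis=1)
        rows[group] = {**means.to_dict(), "Other": 1.0 - float(means.sum())}
    out = pd.DataFrame.from_dict(rows, orient="index")
    return out[[*top, "Other"]]
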