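"""Donor-to-recipient transfer efficiency and engraftment consistency.

Transfer efficiency is the Pearson correlation *r* of depth-scaled log10
abundances between an FMT input and a recipient sample; engraftment
consistency is the same statistic over all sample pairs within one recipient
group (low values mean high mouse-to-mouse variability). ASVs are further
classified by transfer fate — transferred, non-transferring (present in the
input, undetected in the recipient: the "y = 0" dots of an input-vs-recipient
scatter), newly detected in vivo ("x = 0") — and efficiency can be
stratified by phylum.

Joint absences carry no information about transfer and mechanically inflate
*r*, so the default ``zero_policy`` drops ASVs absent from both members of a
pair; ``keep_all`` is available to probe sensitivity to this choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .io_tables import RANKS, UNCLASSIFIED, CountTable, StudyBundle, TaxonomyTable
from .normalization import NormalizedTable, normalize_counts

__all__ = [
    "EfficiencyResult",
    "AsvTransferClassification",
    "UndefinedCorrelationError",
    "pairwise_r",
    "aggregate_to_rank",
    "between_group_efficiency",
    "within_group_consistency",
    "classify_asvs",
    "abundance_histogram",
    "stratified_efficiency",
]

LEVELS = ("asv", "genus", "phylum")

#: pooled feature id for ASVs lacking a classified label at the target rank
UNCLASSIFIED_FEATURE = "Unclassified"

_MIN_FEATURES = 3


class UndefinedCorrelationError(ValueError):
    """Pearson r is undefined: fewer than 3 retained features or zero variance."""


@dataclass(frozen=True)
class EfficiencyResult:
    """Pairwise Pearson r values plus their group summary.

    ``pairs`` has columns ``sample_a``, ``sample_b``, ``r`` (``stratum`` too
    when stratified). The summary is reported mean +/- SD over pairs.
    """

    comparison: str
    level: str
    pairs: pd.DataFrame
    zero_policy: str
    input_mode: str | None = None
    mean_depth: float | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def mean_r(self) -> float:
        return float(self.pairs["r"].mean())

    @property
    def sd_r(self) -> float:
        return float(self.pairs["r"].std(ddof=1)) if len(self.pairs) > 1 else 0.0

    def summary(self) -> dict:
        return {
            "comparison": self.comparison,
            "level": self.level,
            "n_pairs": self.n_pairs,
            "mean_r": self.mean_r,
            "sd_r": self.sd_r,
            "zero_policy": self.zero_policy,
            "input_mode": self.input_mode,
        }


@dataclass(frozen=True)
class AsvTransferClassification:
    """Per-ASV transfer fate for one input -> recipient comparison.

    ``table`` columns: ``input_abundance``, ``recipient_abundance`` (both
    log10-normalized) and ``label`` in {transferred, non_transferring,
    newly_detected, absent_both}; the labels partition the ASV universe.
    """

    table: pd.DataFrame
    input_group: str
    recipient: str
    recipient_mode: str

    def counts_per_label(self) -> dict[str, int]:
        counts = self.table["label"].value_counts().to_dict()
        for lab in ("transferred", "non_transferring", "newly_detected", "absent_both"):
            counts.setdefault(lab, 0)
        return counts

    def subset(self, label: str) -> pd.DataFrame:
        return self.table[self.table["label"] == label]


def pairwise_r(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    zero_policy: str = "drop_joint_zeros",
) -> float:
    """Pearson product-moment correlation of two normalized profiles.

    With ``zero_policy='drop_joint_zeros'`` features equal to zero in both
    vectors are removed first. Raises :class:`UndefinedCorrelationError`
    rather than returning NaN when fewer than 3 features remain or either
    retained vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if zero_policy == "drop_joint_zeros":
        keep = (x != 0) | (y != 0)
        x, y = x[keep], y[keep]
    elif zero_policy != "keep_all":
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    if x.size < _MIN_FEATURES:
        raise UndefinedCorrelationError(
            f"only {x.size} features retained (need >= {_MIN_FEATURES})"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in a retained vector")
    return float(np.corrcoef(x, y)[0, 1])


def aggregate_to_rank(
    table: CountTable, taxonomy: TaxonomyTable, rank: str
) -> CountTable:
    """Sum ASV counts into features of the given rank (genus or phylum).

    ASVs that are unclassified at the rank are pooled into a single
    ``Unclassified`` feature, so per-sample depth is conserved exactly.
    """
    if rank == "asv":
        return table
    if rank not in RANKS:
        raise KeyError(f"unknown rank {rank!r}; valid: ('asv',) + {RANKS}")
    labels = taxonomy.rank_labels(rank).reindex(table.asv_ids)
    labels = labels.fillna(UNCLASSIFIED_FEATURE)
    labels = labels.where(
        ~labels.str.lower().isin({UNCLASSIFIED, "unassigned", ""}),
        UNCLASSIFIED_FEATURE,
    )
    grouped = table.counts.groupby(labels.to_numpy()).sum()
    grouped.index.name = "feature_id"
    return CountTable(grouped)


def _normalized_at_level(
    bundle: StudyBundle, sample_ids: list[str], level: str
) -> NormalizedTable:
    """Collapse counts to the level, subset the samples, then normalize.

    The mean depth is computed over exactly the samples entering the analysis.
    Collapsing happens before normalization so genus/phylum analyses are
    self-contained, not re-log-transformed sums.
    """
    if level not in ("asv",) + tuple(LEVELS):
        raise ValueError(f"unknown level {level!r}; valid: {LEVELS}")
    collapsed = aggregate_to_rank(bundle.counts, bundle.taxonomy, level)
    return normalize_counts(collapsed.subset_samples(sample_ids))


def _input_profiles(
    norm: NormalizedTable, input_samples: list[str], input_mode: str
) -> list[tuple[str, pd.Series]]:
    if input_mode == "average_replicates":
        profile = norm.values[input_samples].mean(axis=1)
        name = input_samples[0] if len(input_samples) == 1 else "input_mean"
        return [(name, profile)]
    if input_mode == "per_replicate":
        return [(s, norm.values[s]) for s in input_samples]
    raise ValueError(f"unknown input_mode {input_mode!r}")


def between_group_efficiency(
    bundle: StudyBundle,
    input_group: str,
    recipient_group: str,
    level: str = "asv",
    input_mode: str = "average_replicates",
    zero_policy: str = "drop_joint_zeros",
) -> EfficiencyResult:
    """Transfer efficiency: Pearson r for every (input, recipient) pair.

    Technical replicates of the input are averaged on the normalized scale
    into one profile first (``input_mode='average_replicates'``, the default)
    or kept separate (``'per_replicate'``).
    """
    input_samples = bundle.samples_in_group(input_group)
    recipient_samples = bundle.samples_in_group(recipient_group)
    norm = _normalized_at_level(bundle, input_samples + recipient_samples, level)
    rows = []
    for in_name, in_profile in _input_profiles(norm, input_samples, input_mode):
        for rec in recipient_samples:
            r = pairwise_r(in_profile, norm.values[rec], zero_policy)
            rows.append((in_name, rec, r))
    pairs = pd.DataFrame(rows, columns=["sample_a", "sample_b", "r"])
    return EfficiencyResult(
        comparison=f"between:{input_group}->{recipient_group}",
        level=level,
        pairs=pairs,
        zero_policy=zero_policy,
        input_mode=input_mode,
        mean_depth=norm.mean_depth,
    )


def within_group_consistency(
    bundle: StudyBundle,
    group: str,
    level: str = "asv",
    zero_policy: str = "drop_joint_zeros",
) -> EfficiencyResult:
    """Engraftment consistency: Pearson r over all unordered pairs in a group."""
    samples = bundle.samples_in_group(group)
    if len(samples) < 2:
        raise ValueError(f"group {group!r} has a single sample; need >= 2")
    norm = _normalized_at_level(bundle, samples, level)
    rows = [
        (a, b, pairwise_r(norm.values[a], norm.values[b], zero_policy))
        for a, b in combinations(samples, 2)
    ]
    pairs = pd.DataFrame(rows, columns=["sample_a", "sample_b", "r"])
    return EfficiencyResult(
        comparison=f"within:{group}",
        level=level,
        pairs=pairs,
        zero_policy=zero_policy,
        mean_depth=norm.mean_depth,
    )


def classify_asvs(
    bundle: StudyBundle,
    input_group: str,
    recipient: str,
    recipient_mode: str = "per_sample",
    input_mode: str = "average_replicates",
) -> AsvTransferClassification:
    """Label every ASV by transfer fate for one input -> recipient comparison.

    ``recipient`` is a sample id when ``recipient_mode='per_sample'`` (the
    primary mode: transfer fate is a per-mouse event) or a group name with
    ``'group_mean'``, in which case the group mean of normalized values is
    classified. Presence means raw count >= 1 (a single read counts as
    detected); abundances reported are log10-normalized.
    """
    input_samples = bundle.samples_in_group(input_group)
    if recipient_mode == "per_sample":
        recipient_samples = [recipient]
    elif recipient_mode == "group_mean":
        recipient_samples = bundle.samples_in_group(recipient)
    else:
        raise ValueError(f"unknown recipient_mode {recipient_mode!r}")

    norm = normalize_counts(
        bundle.counts.subset_samples(input_samples + recipient_samples)
    )
    in_abund = _input_profiles(norm, input_samples, input_mode)[0][1]
    rec_abund = norm.values[recipient_samples].mean(axis=1)

    # presence from raw counts: a replicate-averaged input is "present" if any
    # replicate saw a read, matching the single-read detection rule
    in_present = bundle.counts.counts[input_samples].sum(axis=1) >= 1
    rec_present = bundle.counts.counts[recipient_samples].sum(axis=1) >= 1

    label = np.where(
        in_present & rec_present,
        "transferred",
        np.where(
            in_present,
            "non_transferring",
            np.where(rec_present, "newly_detected", "absent_both"),
        ),
    )
    table = pd.DataFrame(
        {
            "input_abundance": in_abund,
            "recipient_abundance": rec_abund,
            "label": label,
        },
        index=bundle.counts.counts.index,
    )
    return AsvTransferClassification(
        table=table,
        input_group=input_group,
        recipient=recipient,
        recipient_mode=recipient_mode,
    )


def abundance_histogram(
    classification: AsvTransferClassification,
    which: str,
    bin_width: float = 0.5,
) -> pd.DataFrame:
    """Histogram of log10-normalized abundance for one fate class.

    Non-transferring ASVs are binned by their *input* abundance, newly
    detected ASVs by their *recipient* abundance. Bins are contiguous
    ``bin_width``-wide intervals anchored at 0 covering the observed range;
    an empty class yields an empty histogram.
    """
    if which == "non_transferring":
        axis = "input_abundance"
    elif which == "newly_detected":
        axis = "recipient_abundance"
    else:
        raise ValueError(f"unknown class {which!r}")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = classification.subset(which)[axis].to_numpy()
    if values.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    n_bins = int(np.floor(values.max() / bin_width)) + 1
    edges = np.arange(0.0, (n_bins + 1) * bin_width, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def stratified_efficiency(
    bundle: StudyBundle,
    input_group: str,
    recipient_group: str,
    stratify_by: str = "phylum",
    input_mode: str = "average_replicates",
    zero_policy: str = "drop_joint_zeros",
) -> dict[str, EfficiencyResult | None]:
    """Transfer efficiency per taxon stratum, on ASV-level values.

    Normalization happens once on the full ASV table; each stratum's r uses
    the ASV subset belonging to that stratum (including an ``Unclassified``
    stratum). Strata where a pair retains fewer than 3 features or has zero
    variance are reported as not-estimable (``None``), never dropped silently.
    """
    input_samples = bundle.samples_in_group(input_group)
    recipient_samples = bundle.samples_in_group(recipient_group)
    norm = _normalized_at_level(bundle, input_samples + recipient_samples, "asv")
    labels = bundle.taxonomy.rank_labels(stratify_by).reindex(norm.asv_ids)
    labels = labels.where(
        ~labels.str.lower().isin({UNCLASSIFIED, "unassigned", ""}),
        UNCLASSIFIED_FEATURE,
    )
    results: dict[str, EfficiencyResult | None] = {}
    for stratum in dict.fromkeys(labels):
        mask = (labels == stratum).to_numpy()
        rows = []
        estimable = True
        for in_name, in_profile in _input_profiles(norm, input_samples, input_mode):
            for rec in recipient_samples:
                try:
                    r = pairwise_r(
                        in_profile.to_numpy()[mask],
                        norm.values[rec].to_numpy()[mask],
                        zero_policy,
                    )
                except UndefinedCorrelationError:
                    estimable = False
                    break
                rows.append((in_name, rec, r))
            if not estimable:
                break
        if not estimable:
            results[stratum] = None
            continue
        pairs = pd.DataFrame(rows, columns=["sample_a", "sample_b", "r"])
        results[stratum] = EfficiencyResult(
            comparison=f"between:{input_group}->{recipient_group}|{stratify_by}={stratum}",
            level="asv",
            pairs=pairs,
            zero_policy=zero_policy,
            input_mode=input_mode,
            mean_depth=norm.mean_depth,
        )
    return results
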