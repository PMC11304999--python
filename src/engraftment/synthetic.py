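"""Synthetic FMT studies with full ground truth.

The generator emulates the statistical structure of a humanized-mouse FMT
experiment so every pipeline statistic can be tested against known truth:

* a pooled donor community with a heavy-tailed (log-normal) abundance
  distribution over a few hundred ASVs, partitioned into named phyla/genera;
* a stochastic cross-host engraftment bottleneck: each donor ASV transfers
  with probability ``pi_i = logistic(alpha + beta * log10 p_i)``, so rare
  taxa fail most often but moderately abundant taxa also drop out;
* host-environment-dependent reassembly: retained taxa are reweighted by a
  per-ASV fitness factor drawn once per transplantation event, plus
  per-recipient log-normal noise; the inflamed-host mode boosts a designated
  pathobiont set, suppresses a designated protective set and adds larger
  per-recipient noise (lower alpha diversity, higher mouse-to-mouse
  variability);
* a low-rate influx of novel taxa undetected in the input (sub-detection
  expansion, sequence change or contamination are observationally
  identical and are not distinguished);
* near-complete retention in serial mouse-to-mouse passage of a pooled
  slurry (arithmetic mean of recipient communities);
* multinomial sequencing at log-normally distributed depth, with technical
  PCR replicates for input slurries.

All randomness flows from one study seed through named substreams, so a
given (scenario, seed) pair is bit-identical across runs.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .io_tables import (
    RANKS,
    CountTable,
    SampleMetadata,
    StudyBundle,
    TaxonomyTable,
    align,
)

__all__ = [
    "EngraftmentParams",
    "DonorCommunity",
    "EngraftmentDraw",
    "SimulatedStudy",
    "SCENARIOS",
    "load_scenario_params",
    "simulate_donor",
    "retention_probabilities",
    "simulate_engraftment",
    "simulate_passage",
    "simulate_study",
    "write_study",
]

# phylum composition of the generated taxonomy (fractions of ASVs) and the
# genus names cycled within each phylum
_PHYLA: dict[str, tuple[float, tuple[str, ...]]] = {
    "Firmicutes": (
        0.55,
        (
            "Blautia",
            "Lachnoclostridium",
            "Faecalibacterium",
            "Ruminococcus",
            "Clostridium_sensu_stricto_1",
            "Enterococcus",
            "Roseburia",
            "Dorea",
        ),
    ),
    "Bacteroidota": (0.22, ("Bacteroides", "Prevotella", "Alistipes", "Parabacteroides")),
    "Proteobacteria": (0.08, ("Escherichia-Shigella", "Klebsiella", "Sutterella")),
    "Actinobacteriota": (0.07, ("Bifidobacterium", "Collinsella")),
    "Verrucomicrobiota": (0.03, ("Akkermansia",)),
    "unclassified": (0.05, ()),
}

_GENUS_GROUP_SIZE = 6  # ASVs per synthetic genus block


@dataclass(frozen=True)
class EngraftmentParams:
    """Knobs of the engraftment model; defaults are the human-to-mouse scenario.

    Abundance noise scales (``fitness_sigma``, ``host_sigma``) are standard
    deviations on the natural-log scale. ``retention_override``, when set,
    replaces the logistic with a uniform per-ASV engraftment probability.
    """

    s_asvs: int = 400
    donor_sigma: float = 2.0  # log-normal shape of donor abundances
    retention_alpha: float = 1.5
    retention_beta: float = 0.9
    retention_override: float | None = None
    retention_correlation: float = 0.9  # cross-recipient correlation of masks
    inflamed_retention_correlation: float = 0.6  # idiosyncratic inflamed engraftment
    phylum_retention: dict[str, float] = field(default_factory=dict)
    fitness_sigma: float = 2.5  # event-level per-ASV reweighting
    host_sigma: float = 0.9  # per-recipient noise, non-inflamed host
    inflamed_host_sigma: float = 1.5
    pathobiont_boost: float = 15.0
    bloom_sigma: float = 1.5  # per-recipient spread of the pathobiont bloom
    protective_suppression: float = 0.08
    influx_rate: float = 4.0  # Poisson mean novel taxa per recipient
    influx_log10_mu: float = -3.0  # novel-taxon proportion before renormalization
    influx_log10_sigma: float = 0.3
    passage_retention: float = 0.97
    passage_fitness_sigma: float = 0.25
    passage_host_sigma: float = 0.25
    passage_influx_rate: float = 1.0
    depth_mean: float = 5e4
    input_depth_mean: float = 2e5  # input slurries are sequenced deeper
    depth_log_sigma: float = 0.2
    n_input_replicates: int = 3
    n_recipients: int = 8
    seed: int = 0


@dataclass(frozen=True)
class DonorCommunity:
    """Ground-truth donor profile plus its technical sequencing replicates."""

    asv_ids: tuple[str, ...]
    proportions: np.ndarray
    taxonomy: TaxonomyTable
    replicate_counts: pd.DataFrame  # ASVs x replicate samples
    group: str


@dataclass(frozen=True)
class EngraftmentDraw:
    """One transplantation event: recipient counts plus per-recipient truth."""

    counts: pd.DataFrame  # features (donor + novel) x recipients
    retention_mask: pd.DataFrame  # donor ASVs x recipients, bool
    true_proportions: pd.DataFrame  # features x recipients
    pi: pd.Series  # per-donor-ASV engraftment probability
    fitness: pd.Series  # event-level fitness factors
    novel_taxonomy: TaxonomyTable
    resampled_recipients: tuple[str, ...] = ()


@dataclass(frozen=True)
class SimulatedStudy:
    """A complete study bundle with attached ground truth."""

    bundle: StudyBundle
    truth: dict
    scenario: str
    seed: int
    params: EngraftmentParams


def _rng(seed: int, *salt: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *salt])


def _make_taxonomy(asv_ids: list[str]) -> TaxonomyTable:
    """Deterministic phylum/genus assignment by fixed fractions (block layout)."""
    n = len(asv_ids)
    rows = {}
    boundaries = []
    acc = 0
    for phylum, (frac, _) in _PHYLA.items():
        size = int(round(frac * n))
        boundaries.append((phylum, acc, acc + size))
        acc += size
    if boundaries:  # absorb rounding remainder into the first phylum
        phylum0, lo0, hi0 = boundaries[0]
        boundaries[0] = (phylum0, lo0, hi0 + (n - acc))
        boundaries = [boundaries[0]] + [
            (p, lo + (n - acc), hi + (n - acc)) for p, lo, hi in boundaries[1:]
        ]
    for phylum, lo, hi in boundaries:
        genera = _PHYLA[phylum][1]
        for k, i in enumerate(range(lo, hi)):
            if phylum == "unclassified":
                lineage = dict.fromkeys(RANKS, "unclassified")
            else:
                if genera:
                    base = genera[(k // _GENUS_GROUP_SIZE) % len(genera)]
                    block = k // (_GENUS_GROUP_SIZE * len(genera))
                    genus = base if block == 0 else f"{base}_{block + 1}"
                else:
                    genus = "unclassified"
                lineage = dict.fromkeys(RANKS, "unclassified")
                lineage.update(domain="Bacteria", phylum=phylum, genus=genus)
            rows[asv_ids[i]] = lineage
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    return TaxonomyTable(table.reindex(asv_ids))


def _sample_depth(
    params: EngraftmentParams, rng: np.random.Generator, kind: str = "recipient"
) -> int:
    mean = params.input_depth_mean if kind == "input" else params.depth_mean
    mu = math.log(mean) - params.depth_log_sigma**2 / 2
    return max(1000, int(round(rng.lognormal(mu, params.depth_log_sigma))))


def _multinomial_column(
    proportions: np.ndarray, depth: int, rng: np.random.Generator
) -> np.ndarray:
    p = proportions / proportions.sum()
    return rng.multinomial(depth, p)


def simulate_donor(
    params: EngraftmentParams, seed: int, group: str = "HM_input"
) -> DonorCommunity:
    """Draw a heavy-tailed donor community and its technical PCR replicates.

    True proportions come from normalized log-normal weights; each replicate
    is an independent multinomial draw at its own sampled depth.
    """
    if params.s_asvs < 10:
        raise ValueError("need at least 10 donor ASVs")
    if params.donor_sigma < 0:
        raise ValueError("donor_sigma must be >= 0")
    rng = _rng(seed, 1)
    asv_ids = [f"asv{i:04d}" for i in range(params.s_asvs)]
    weights = rng.lognormal(0.0, params.donor_sigma, size=params.s_asvs)
    proportions = weights / weights.sum()
    taxonomy = _make_taxonomy(asv_ids)
    reps = {}
    for r in range(params.n_input_replicates):
        depth = _sample_depth(params, rng, kind="input")
        reps[f"{group}_rep{r + 1}"] = _multinomial_column(proportions, depth, rng)
    replicate_counts = pd.DataFrame(reps, index=asv_ids)
    return DonorCommunity(
        asv_ids=tuple(asv_ids),
        proportions=proportions,
        taxonomy=taxonomy,
        replicate_counts=replicate_counts,
        group=group,
    )


def retention_probabilities(
    proportions: np.ndarray,
    taxonomy: TaxonomyTable,
    asv_ids: list[str],
    params: EngraftmentParams,
) -> np.ndarray:
    """Per-ASV engraftment probability.

    Logistic in log10 abundance by default; a uniform override or per-phylum
    overrides replace it where configured.
    """
    if params.retention_override is not None:
        pi = np.full(len(asv_ids), float(params.retention_override))
    else:
        logit = params.retention_alpha + params.retention_beta * np.log10(proportions)
        pi = 1.0 / (1.0 + np.exp(-logit))
    if params.phylum_retention:
        phyla = taxonomy.rank_labels("phylum").reindex(asv_ids).to_numpy()
        for phylum, value in params.phylum_retention.items():
            pi = np.where(phyla == phylum, float(value), pi)
    return np.clip(pi, 0.0, 1.0)


def _designated_sets(
    taxonomy: TaxonomyTable, asv_ids: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Pathobionts = Proteobacteria plus Enterococcus; protective = the
    Blautia/Lachnoclostridium/Faecalibacterium/Roseburia block."""
    phyla = taxonomy.rank_labels("phylum").reindex(asv_ids)
    genera = taxonomy.rank_labels("genus").reindex(asv_ids).fillna("unclassified")
    base_genus = genera.str.replace(r"_\d+$", "", regex=True)
    pathobiont = (phyla == "Proteobacteria") | (base_genus == "Enterococcus")
    protective = base_genus.isin(
        {"Blautia", "Lachnoclostridium", "Faecalibacterium", "Roseburia"}
    )
    return pathobiont.to_numpy(), protective.to_numpy()


def simulate_engraftment(
    donor_proportions: np.ndarray,
    donor_asv_ids: list[str],
    taxonomy: TaxonomyTable,
    params: EngraftmentParams,
    n_recipients: int,
    host: str,
    seed: int,
    event: str = "e1",
    group: str | None = None,
    passage: bool = False,
) -> EngraftmentDraw:
    """Engraft a donor (or pooled slurry) community into ``n_recipients`` hosts.

    ``host='KO'`` activates the inflamed mode. ``passage=True`` switches to
    the serial-passage regime: uniform retention ``passage_retention`` and
    the reduced passage noise scales. Event-level fitness is drawn once and
    shared by all recipients of the call; retention masks and host noise are
    per-recipient. A recipient losing every taxon is redrawn (recorded).
    """
    if host not in ("WT", "KO"):
        raise ValueError(f"host must be 'WT' or 'KO', got {host!r}")
    group = group or f"{event}->{host}"
    # stable across processes, unlike built-in str hashing
    event_salt = zlib.crc32(f"{event}|{host}|{group}".encode()) & 0x7FFFFFFF
    rng = _rng(seed, 2, event_salt)
    asv_ids = list(donor_asv_ids)
    s = len(asv_ids)

    if passage:
        pi = np.full(s, params.passage_retention)
        fitness_sigma = params.passage_fitness_sigma
        host_sigma = params.passage_host_sigma
        influx_rate = params.passage_influx_rate
    else:
        pi = retention_probabilities(donor_proportions, taxonomy, asv_ids, params)
        fitness_sigma = params.fitness_sigma
        host_sigma = params.host_sigma if host == "WT" else params.inflamed_host_sigma
        influx_rate = params.influx_rate
    inflamed = host == "KO"

    fitness = np.exp(rng.normal(0.0, fitness_sigma, size=s))
    pathobiont = protective = None
    if inflamed:
        pathobiont, protective = _designated_sets(taxonomy, asv_ids)
        fitness = fitness * np.where(protective, params.protective_suppression, 1.0)

    recipients = [f"{group}_m{i + 1}" for i in range(n_recipients)]
    masks = np.zeros((s, n_recipients), dtype=bool)
    # Gaussian-copula retention: each recipient's mask is marginally
    # Bernoulli(pi_i) but correlated across recipients of one event, because
    # most transfer failures are properties of the taxon-host pairing, not of
    # the individual mouse.
    rho = (
        params.inflamed_retention_correlation if inflamed else params.retention_correlation
    )
    rho = min(max(rho, 0.0), 1.0)
    z_event = rng.normal(size=s)
    z_threshold = ndtri(np.clip(pi, 1e-12, 1 - 1e-12))
    truth_cols: dict[str, pd.Series] = {}
    count_cols: dict[str, pd.Series] = {}
    novel_rows: dict[str, dict[str, str]] = {}
    resampled = []

    for j, rec in enumerate(recipients):
        for attempt in range(100):
            z = math.sqrt(rho) * z_event + math.sqrt(1 - rho) * rng.normal(size=s)
            mask = (z < z_threshold) & (pi > 0)
            retained = donor_proportions * mask
            if retained.sum() > 0:
                break
        else:
            raise RuntimeError("all-ASV extinction persisted across resampling")
        if attempt > 0:
            warnings.warn(f"recipient {rec}: resampled extinct community", stacklevel=2)
            resampled.append(rec)
        masks[:, j] = mask
        noise = np.exp(rng.normal(0.0, host_sigma, size=s))
        props = retained * fitness * noise
        if inflamed:
            # pathobiont blooms are per-mouse events: which pathobiont expands,
            # and by how much, varies recipient to recipient, raising
            # compositional variability
            bloom = params.pathobiont_boost * np.exp(
                rng.normal(0.0, params.bloom_sigma, size=int(pathobiont.sum()))
            )
            props[pathobiont] = props[pathobiont] * bloom

        n_novel = rng.poisson(influx_rate)
        novel_ids = []
        novel_props = []
        for k in range(n_novel):
            nid = f"nov_{rec}_{k + 1}"
            novel_ids.append(nid)
            novel_props.append(
                10.0
                ** rng.normal(params.influx_log10_mu, params.influx_log10_sigma)
            )
            novel_rows[nid] = dict.fromkeys(RANKS, "unclassified")
        full_ids = asv_ids + novel_ids
        full_props = np.concatenate([props / props.sum(), np.asarray(novel_props)])
        full_props = full_props / full_props.sum()

        depth = _sample_depth(params, rng)
        counts = _multinomial_column(full_props, depth, rng)
        truth_cols[rec] = pd.Series(full_props, index=full_ids)
        count_cols[rec] = pd.Series(counts, index=full_ids)

    counts_df = pd.DataFrame(count_cols).fillna(0).astype(np.int64)
    truth_df = pd.DataFrame(truth_cols).fillna(0.0)
    # donor features first, novel features after, in insertion order
    ordered = asv_ids + [i for i in counts_df.index if i not in set(asv_ids)]
    counts_df = counts_df.reindex(ordered).fillna(0).astype(np.int64)
    truth_df = truth_df.reindex(ordered).fillna(0.0)
    novel_tax = TaxonomyTable(
        pd.DataFrame.from_dict(novel_rows, orient="index", columns=list(RANKS))
        if novel_rows
        else pd.DataFrame(index=pd.Index([], dtype=object), columns=list(RANKS))
    )
    return EngraftmentDraw(
        counts=counts_df,
        retention_mask=pd.DataFrame(masks, index=asv_ids, columns=recipients),
        true_proportions=truth_df,
        pi=pd.Series(pi, index=asv_ids),
        fitness=pd.Series(fitness, index=asv_ids),
        novel_taxonomy=novel_tax,
        resampled_recipients=tuple(resampled),
    )


def simulate_passage(
    previous_true_proportions: pd.DataFrame,
    taxonomy: TaxonomyTable,
    params: EngraftmentParams,
    n_recipients: int,
    host: str,
    seed: int,
    event: str = "p1",
    group: str | None = None,
) -> tuple[pd.Series, EngraftmentDraw]:
    """Pool the previous generation and engraft the slurry into new hosts.

    The slurry is the arithmetic mean of the recipients' true proportions
    (fecal pellets pooled across the donor cage). Returns the pooled profile
    and the next-generation draw (retention ``passage_retention``, reduced
    noise).
    """
    pooled = previous_true_proportions.mean(axis=1)
    pooled = pooled / pooled.sum()
    draw = simulate_engraftment(
        pooled.to_numpy(),
        list(pooled.index),
        taxonomy,
        params,
        n_recipients,
        host,
        seed,
        event=event,
        group=group,
        passage=True,
    )
    return pooled, draw


def _input_metadata(sample_ids: list[str], group: str, generation: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": group,
            "role": "input",
            "host_genotype": "none",
            "transplant_event": "none",
            "generation": generation,
            "replicate_kind": "technical",
        },
        index=sample_ids,
    )


def _recipient_metadata(
    sample_ids: list[str], group: str, host: str, event: str, generation: int
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": group,
            "role": "recipient",
            "host_genotype": host,
            "transplant_event": event,
            "generation": generation,
            "replicate_kind": "biological",
        },
        index=sample_ids,
    )


def _replicate_counts_at(
    proportions: pd.Series, params: EngraftmentParams, rng: np.random.Generator, group: str
) -> pd.DataFrame:
    reps = {}
    for r in range(params.n_input_replicates):
        depth = _sample_depth(params, rng, kind="input")
        reps[f"{group}_rep{r + 1}"] = _multinomial_column(
            proportions.to_numpy(), depth, rng
        )
    return pd.DataFrame(reps, index=proportions.index)


def _assemble(
    frames: list[pd.DataFrame],
    taxonomies: list[TaxonomyTable],
    metadata_frames: list[pd.DataFrame],
) -> StudyBundle:
    all_counts = pd.concat(frames, axis=1).fillna(0).astype(np.int64)
    # preserve first-appearance feature order
    order: list[str] = []
    seen: set[str] = set()
    for frame in frames:
        for fid in frame.index:
            if fid not in seen:
                seen.add(fid)
                order.append(fid)
    all_counts = all_counts.reindex(order).fillna(0).astype(np.int64)
    tax = pd.concat([t.lineages for t in taxonomies])
    tax = tax[~tax.index.duplicated()]
    meta = pd.concat(metadata_frames)
    return align(
        CountTable(all_counts),
        TaxonomyTable(tax.reindex(columns=list(RANKS))),
        SampleMetadata(meta),
    )


def simulate_study(
    scenario: str, seed: int, params: EngraftmentParams | None = None
) -> SimulatedStudy:
    """Generate a complete named-scenario study with ground truth.

    Scenarios: ``human_to_mouse`` (human input, one WT and one inflamed KO
    recipient group), ``mouse_adapted`` (a generation-1 WT cage pooled into a
    slurry that is re-sequenced and passaged into generation-2 WT mice),
    ``two_event`` (two independent transplantation events per arm, for
    event-level clustering contrasts) and ``null`` (16 exchangeable
    recipients split into two arbitrary groups, for type-I-error
    calibration).
    """
    if scenario not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {scenario!r}; valid: {sorted(SCENARIOS)}"
        )
    params = params or load_scenario_params(scenario)
    params = replace(params, seed=seed)
    return SCENARIOS[scenario](params, seed)


def _study_human_to_mouse(params: EngraftmentParams, seed: int) -> SimulatedStudy:
    donor = simulate_donor(params, seed, group="HM_input")
    wt = simulate_engraftment(
        donor.proportions, list(donor.asv_ids), donor.taxonomy, params,
        params.n_recipients, "WT", seed, event="t1", group="HM->WT",
    )
    ko = simulate_engraftment(
        donor.proportions, list(donor.asv_ids), donor.taxonomy, params,
        params.n_recipients, "KO", seed, event="t2", group="HM->KO",
    )
    bundle = _assemble(
        [donor.replicate_counts, wt.counts, ko.counts],
        [donor.taxonomy, wt.novel_taxonomy, ko.novel_taxonomy],
        [
            _input_metadata(list(donor.replicate_counts.columns), "HM_input", 0),
            _recipient_metadata(list(wt.counts.columns), "HM->WT", "WT", "t1", 1),
            _recipient_metadata(list(ko.counts.columns), "HM->KO", "KO", "t2", 1),
        ],
    )
    truth = {
        "donor_proportions": pd.Series(donor.proportions, index=list(donor.asv_ids)),
        "retention_masks": pd.concat([wt.retention_mask, ko.retention_mask], axis=1),
        "true_proportions": pd.concat(
            [wt.true_proportions, ko.true_proportions], axis=1
        ).fillna(0.0),
        "pi": wt.pi,
        "fitness": {"HM->WT": wt.fitness, "HM->KO": ko.fitness},
        "resampled": wt.resampled_recipients + ko.resampled_recipients,
    }
    return SimulatedStudy(bundle, truth, "human_to_mouse", seed, params)


def _study_mouse_adapted(params: EngraftmentParams, seed: int) -> SimulatedStudy:
    donor = simulate_donor(params, seed, group="HM_input")
    gen1 = simulate_engraftment(
        donor.proportions, list(donor.asv_ids), donor.taxonomy, params,
        params.n_recipients, "WT", seed, event="t1", group="NIMM-g1",
    )
    tax_gen1 = TaxonomyTable(
        pd.concat([donor.taxonomy.lineages, gen1.novel_taxonomy.lineages])
    )
    pooled, gen2 = simulate_passage(
        gen1.true_proportions, tax_gen1, params, params.n_recipients,
        "WT", seed, event="t2", group="NIMM-g2->WT",
    )
    slurry_reps = _replicate_counts_at(pooled, params, _rng(seed, 3), "NIMM_input")
    bundle = _assemble(
        [slurry_reps, gen2.counts, gen1.counts],
        [tax_gen1, gen2.novel_taxonomy],
        [
            _input_metadata(list(slurry_reps.columns), "NIMM_input", 1),
            _recipient_metadata(list(gen2.counts.columns), "NIMM-g2->WT", "WT", "t2", 2),
            _recipient_metadata(list(gen1.counts.columns), "NIMM-g1", "WT", "t1", 1),
        ],
    )
    truth = {
        "donor_proportions": pd.Series(donor.proportions, index=list(donor.asv_ids)),
        "pooled_slurry": pooled,
        "retention_masks": gen2.retention_mask,
        "true_proportions": gen2.true_proportions,
        "pi": gen2.pi,
        "resampled": gen1.resampled_recipients + gen2.resampled_recipients,
    }
    return SimulatedStudy(bundle, truth, "mouse_adapted", seed, params)


def _study_two_event(params: EngraftmentParams, seed: int) -> SimulatedStudy:
    per_event = max(3, params.n_recipients // 2)
    donor = simulate_donor(params, seed, group="HM_input")
    hm_events = [
        simulate_engraftment(
            donor.proportions, list(donor.asv_ids), donor.taxonomy, params,
            per_event, "WT", seed, event=f"hm-e{k}", group=f"HM-e{k}->WT",
        )
        for k in (1, 2)
    ]
    gen1 = simulate_engraftment(
        donor.proportions, list(donor.asv_ids), donor.taxonomy, params,
        params.n_recipients, "WT", seed, event="ma-g1", group="MA-g1",
    )
    tax_gen1 = TaxonomyTable(
        pd.concat([donor.taxonomy.lineages, gen1.novel_taxonomy.lineages])
    )
    ma_events = []
    for k in (1, 2):
        _, draw = simulate_passage(
            gen1.true_proportions, tax_gen1, params, per_event,
            "WT", seed, event=f"ma-e{k}", group=f"MA-e{k}->WT",
        )
        ma_events.append(draw)
    frames = [donor.replicate_counts] + [d.counts for d in hm_events + ma_events]
    taxes = [tax_gen1] + [d.novel_taxonomy for d in hm_events + ma_events]
    metas = [_input_metadata(list(donor.replicate_counts.columns), "HM_input", 0)]
    for k, d in zip((1, 2), hm_events):
        metas.append(
            _recipient_metadata(list(d.counts.columns), f"HM-e{k}->WT", "WT", f"hm-e{k}", 1)
        )
    for k, d in zip((1, 2), ma_events):
        metas.append(
            _recipient_metadata(list(d.counts.columns), f"MA-e{k}->WT", "WT", f"ma-e{k}", 2)
        )
    bundle = _assemble(frames, taxes, metas)
    truth = {
        "donor_proportions": pd.Series(donor.proportions, index=list(donor.asv_ids)),
        "arms": {
            "human_to_mouse": [f"HM-e{k}->WT" for k in (1, 2)],
            "mouse_adapted": [f"MA-e{k}->WT" for k in (1, 2)],
        },
    }
    return SimulatedStudy(bundle, truth, "two_event", seed, params)


def _study_null(params: EngraftmentParams, seed: int) -> SimulatedStudy:
    """16 recipients from one transplantation event, arbitrarily split 8/8.

    All recipients share the event-level fitness draw and differ only by
    exchangeable per-recipient randomness, so any group labelling is a true
    null for PERMANOVA.
    """
    donor = simulate_donor(params, seed, group="HM_input")
    draw = simulate_engraftment(
        donor.proportions, list(donor.asv_ids), donor.taxonomy, params,
        16, "WT", seed, event="t1", group="null",
    )
    recipients = list(draw.counts.columns)
    meta_a = _recipient_metadata(recipients[:8], "null-A", "WT", "t1", 1)
    meta_b = _recipient_metadata(recipients[8:], "null-B", "WT", "t1", 1)
    bundle = _assemble(
        [draw.counts],
        [donor.taxonomy, draw.novel_taxonomy],
        [meta_a, meta_b],
    )
    truth = {
        "donor_proportions": pd.Series(donor.proportions, index=list(donor.asv_ids)),
        "retention_masks": draw.retention_mask,
        "true_proportions": draw.true_proportions,
        "pi": draw.pi,
    }
    return SimulatedStudy(bundle, truth, "null", seed, params)


SCENARIOS = {
    "human_to_mouse": _study_human_to_mouse,
    "mouse_adapted": _study_mouse_adapted,
    "two_event": _study_two_event,
    "null": _study_null,
}


def _parse_value(raw: str):
    raw = raw.strip()
    if raw.lower() in ("none", ""):
        return None
    for cast in (int, float):
        try:
            value = cast(raw)
            if cast is int and "." in raw:
                continue
            return value
        except ValueError:
            continue
    return raw


def load_scenario_params(scenario: str) -> EngraftmentParams:
    """Load the checked-in calibrated constants for a named scenario."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; valid: {sorted(SCENARIOS)}")
    ref = resources.files("engraftment.scenarios").joinpath(f"{scenario}.cfg")
    overrides = {}
    with resources.as_file(ref) as path:
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, raw = line.partition("=")
            overrides[key.strip()] = _parse_value(raw)
    return EngraftmentParams(**overrides)


def write_study(study: SimulatedStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write counts/taxonomy/metadata TSVs plus the ground-truth tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "metadata": out / "metadata.tsv",
    }
    study.bundle.counts.to_tsv(paths["counts"])
    study.bundle.taxonomy.to_tsv(paths["taxonomy"])
    study.bundle.metadata.to_tsv(paths["metadata"])
    masks = study.truth.get("retention_masks")
    if masks is not None:
        paths["truth"] = out / "truth.tsv"
        masks.astype(int).to_csv(paths["truth"], sep="\t", index_label="feature_id")
    return paths
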