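"""Lineage-event detection and classification for clonal sub-lineages.

A *distinguishing site* is a SNP at which every focal sample carries the
same genotype and no reference sample carries it. Distinguishing sites
where the focal lineage is heterozygous are gains of heterozygosity
(point mutations); runs of focal-homozygous sites are losses of
heterozygosity (LOH), split by span into short gene-conversion tracts
and chromosome-scale segmental events. Sequencing depth distinguishes
copy-neutral LOH (depth ratio ~1) from hemizygous deletion (~0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import (HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix,
                        NormalizedDepth, SampleRoles)

POINT_MUTATION = "point_mutation_gain_het"
GENE_CONVERSION = "gene_conversion_loh"
SEGMENTAL = "segmental_loh"

COPY_NEUTRAL = "copy_neutral"
DELETION_LIKE = "deletion_like"
UNTESTED = "untested"


@dataclass
class DistinguishingSite:
    """A site separating the focal lineage from all references."""

    index: int  # row in the source GenotypeMatrix
    chrom: str
    pos: int  # 1-based
    focal_call: int  # shared focal genotype class code
    focal_zygosity: str  # "het" or "hom"


@dataclass
class MutationEvent:
    kind: str
    chrom: str
    start: int  # 0-based half-open over supporting sites
    end: int
    n_sites: int
    copy_number_status: str = UNTESTED

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.start >= self.end:
            raise ValueError("require start < end")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class EstimatorConfig:
    """Constants for the generations-since-origin estimate.

    ``mu`` is the de novo mutation rate per site per haploid genome per
    generation, ``genome_size_haploid`` the haploid genome size in bp,
    and ``ploidy_factor`` counts genome copies at risk (2 for a diploid).
    """

    mu: float = 3.5e-9
    genome_size_haploid: float = 224e6
    ploidy_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.genome_size_haploid <= 0 or self.ploidy_factor <= 0:
            raise ValueError("estimator constants must be positive")

    @property
    def expected_per_generation(self) -> float:
        return self.ploidy_factor * self.mu * self.genome_size_haploid


def find_distinguishing_sites(
    gm: GenotypeMatrix, roles: SampleRoles
) -> list[DistinguishingSite]:
    """Sites where all focal samples agree and differ from every reference.

    Reference samples may be polymorphic among themselves; a site
    qualifies as long as none of them matches the shared focal genotype
    class. Sites with a missing call in any focal or reference sample
    are ignored (filtering should already have removed them).
    """
    roles.require_lineage()
    fc = gm.calls[:, gm.sample_index(roles.focal)]
    rc = gm.calls[:, gm.sample_index(roles.reference)]
    focal_agree = (fc == fc[:, :1]).all(axis=1)
    complete = (fc != MISSING).all(axis=1) & (rc != MISSING).all(axis=1)
    differs = (rc != fc[:, :1]).all(axis=1)
    hits = np.flatnonzero(focal_agree & complete & differs)
    out = []
    for i in hits:
        call = int(fc[i, 0])
        out.append(
            DistinguishingSite(
                index=int(i),
                chrom=str(gm.sites.at[i, "chrom"]),
                pos=int(gm.sites.at[i, "pos"]),
                focal_call=call,
                focal_zygosity="het" if call == HET else "hom",
            )
        )
    return out


def classify_events(
    sites: Sequence[DistinguishingSite],
    merge_gap: int = 1000,
    segmental_span: int = 10_000,
) -> list[MutationEvent]:
    """Group distinguishing sites into mutation events.

    Each focal-heterozygous site is one gain-of-heterozygosity point
    mutation. Consecutive focal-homozygous sites on the same chromosome
    whose inter-site distance is at most ``merge_gap`` merge into one
    LOH event; an intervening heterozygous distinguishing site breaks
    the run (the spanned interval is demonstrably not LOH throughout),
    keeping events disjoint. Merged events with span at most
    ``segmental_span`` are gene-conversion tracts, larger ones
    segmental LOH. The total site count is conserved.
    """
    for a, b in zip(sites, sites[1:]):
        if a.chrom == b.chrom and a.pos > b.pos:
            raise ValueError("sites must be sorted by (chrom, pos)")
    events: list[MutationEvent] = []
    run: list[DistinguishingSite] = []

    def flush() -> None:
        if not run:
            return
        start, end = run[0].pos - 1, run[-1].pos
        kind = GENE_CONVERSION if end - start <= segmental_span else SEGMENTAL
        events.append(MutationEvent(kind, run[0].chrom, start, end, len(run)))

    for s in sites:
        if s.focal_zygosity == "het":
            flush()
            run = []
            events.append(
                MutationEvent(POINT_MUTATION, s.chrom, s.pos - 1, s.pos, 1)
            )
            continue
        if run and (s.chrom != run[-1].chrom or s.pos - run[-1].pos > merge_gap):
            flush()
            run = []
        run.append(s)
    flush()
    events.sort(key=lambda e: (e.chrom, e.start))
    return events


@dataclass
class BoundaryInterval:
    """Inner/outer localization of a segmental LOH breakpoint pair.

    The true breakpoints lie between the outermost focal-homozygous
    informative sites (inner bound) and the adjacent flanking
    heterozygous informative sites or chromosome ends (outer bound).
    Coordinates are 0-based half-open; ``span`` is the inner-bound length.
    """

    chrom: str
    inner_start: int
    inner_end: int
    outer_start: int
    outer_end: int
    n_sites: int

    @property
    def span(self) -> int:
        return self.inner_end - self.inner_start


def _hom_runs(
    gm: GenotypeMatrix, roles: SampleRoles, chromosome: str,
    chrom_length: int | None,
) -> list[BoundaryInterval]:
    """All maximal focal-homozygous runs over informative sites.

    Informative sites are those heterozygous in all reference-sister
    samples (falling back to all references when no sister clade is
    annotated); runs are delimited by informative sites at which any
    focal sample is heterozygous — the heterozygous/homozygous genotype
    transition rule for breakpoint localization.
    """
    roles.require_lineage()
    sister = roles.reference_sister or roles.reference
    on_chrom = gm.sites.index[gm.sites["chrom"] == chromosome].to_numpy()
    sc = gm.calls[np.ix_(on_chrom, gm.sample_index(sister))]
    informative = (sc == HET).all(axis=1)
    info_rows = on_chrom[informative]
    if info_rows.size == 0:
        raise ValueError(f"no informative (sister-heterozygous) sites on {chromosome}")
    fc = gm.calls[np.ix_(info_rows, gm.sample_index(roles.focal))]
    hom = np.isin(fc, (HOM_REF, HOM_ALT)).all(axis=1)
    pos = gm.sites["pos"].to_numpy()[info_rows]  # 1-based

    runs: list[BoundaryInterval] = []
    i, n = 0, len(hom)
    while i < n:
        if not hom[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and hom[j + 1]:
            j += 1
        outer_start = int(pos[i - 1]) if i > 0 else 0
        if j < n - 1:
            outer_end = int(pos[j + 1] - 1)
        else:
            outer_end = int(chrom_length) if chrom_length is not None else int(pos[j])
        runs.append(
            BoundaryInterval(
                chrom=chromosome,
                inner_start=int(pos[i] - 1),
                inner_end=int(pos[j]),
                outer_start=outer_start,
                outer_end=outer_end,
                n_sites=int(j - i + 1),
            )
        )
        i = j + 1
    return runs


def find_segmental_runs(
    gm: GenotypeMatrix,
    roles: SampleRoles,
    chromosome: str,
    chrom_length: int | None = None,
    min_span: int = 10_000,
) -> list[BoundaryInterval]:
    """Focal-homozygous runs whose inner span exceeds ``min_span``.

    These are candidate segmental LOH (or deletion) tracts; short runs
    (gene-conversion scale) are left for :func:`classify_events`.
    """
    return [
        r for r in _hom_runs(gm, roles, chromosome, chrom_length)
        if r.span > min_span
    ]


def locate_loh_boundaries(
    gm: GenotypeMatrix,
    roles: SampleRoles,
    chromosome: str,
    chrom_length: int | None = None,
) -> BoundaryInterval | None:
    """Bracket the largest focal-homozygous run on a chromosome.

    The maximal run (most informative sites; ties broken by span then
    position) of informative sites at which every focal sample is
    homozygous gives the inner bound; the flanking informative
    heterozygous sites (or the chromosome ends) give the outer bound,
    so the true breakpoints lie between inner and outer. Returns
    ``None`` when no focal-homozygous run exists.
    """
    runs = _hom_runs(gm, roles, chromosome, chrom_length)
    if not runs:
        return None
    return max(runs, key=lambda r: (r.n_sites, r.span, -r.inner_start))


def check_copy_neutral(
    gm: GenotypeMatrix,
    norm: NormalizedDepth,
    roles: SampleRoles,
    chromosome: str,
    start: int,
    end: int,
    neutral_band: tuple[float, float] = (0.85, 1.15),
    deletion_band: tuple[float, float] = (0.35, 0.65),
) -> tuple[str, float]:
    """Classify an interval's focal/reference normalized depth ratio.

    A ratio near 1 means the focal lineage retains two copies
    (copy-neutral LOH); near 0.5 indicates a hemizygous deletion.
    Interval is 0-based half-open. Returns (status, ratio).
    """
    in_iv = (
        (gm.sites["chrom"] == chromosome)
        & (gm.sites["pos"] > start)
        & (gm.sites["pos"] <= end)
    ).to_numpy()
    if not in_iv.any():
        raise ValueError(f"no retained SNPs in {chromosome}:{start}-{end}")
    rows = np.flatnonzero(in_iv)
    focal_mean = float(np.nanmean(
        norm.values[np.ix_(rows, norm.group_columns(roles.focal))]
    ))
    ref_mean = float(np.nanmean(
        norm.values[np.ix_(rows, norm.group_columns(roles.reference))]
    ))
    ratio = focal_mean / ref_mean
    if neutral_band[0] <= ratio <= neutral_band[1]:
        return COPY_NEUTRAL, ratio
    if deletion_band[0] <= ratio <= deletion_band[1]:
        return DELETION_LIKE, ratio
    return UNTESTED, ratio


@dataclass
class GenerationEstimate:
    expected_per_generation: float
    generations: float
    generations_low: float
    generations_high: float
    n_de_novo: int


def estimate_generations(
    n_de_novo: int, cfg: EstimatorConfig | None = None, confidence: float = 0.95
) -> GenerationEstimate:
    """Generations since lineage origin from the de novo SNP count.

    With mutation rate mu per site per haploid genome per generation and
    haploid genome size G, a diploid accumulates 2 mu G expected de novo
    SNPs per generation; the point estimate is n / (2 mu G) and the
    interval comes from a likelihood-ratio interval on the Poisson mean.
    """
    if n_de_novo < 0:
        raise ValueError("n_de_novo must be >= 0")
    cfg = cfg or EstimatorConfig()
    rate = cfg.expected_per_generation
    lam_lo, lam_hi = _poisson_lr_interval(n_de_novo, confidence)
    return GenerationEstimate(
        expected_per_generation=rate,
        generations=n_de_novo / rate,
        generations_low=lam_lo / rate,
        generations_high=lam_hi / rate,
        n_de_novo=n_de_novo,
    )


def _poisson_lr_interval(n: int, confidence: float) -> tuple[float, float]:
    """Likelihood-ratio interval for a Poisson mean given one count."""
    from scipy.optimize import brentq

    crit = stats.chi2.ppf(confidence, df=1)

    def dev(lam: float) -> float:
        if n == 0:
            return 2.0 * lam - crit
        return 2.0 * (lam - n + n * np.log(n / lam)) - crit

    if n == 0:
        return 0.0, crit / 2.0
    lo = brentq(dev, 1e-12, n)
    hi = brentq(dev, n, n * 10 + 20)
    return float(lo), float(hi)


def summarize_by_chromosome(
    sites: Sequence[DistinguishingSite], precision: int = 1
) -> pd.DataFrame:
    """Count distinguishing sites per chromosome with percentage shares."""
    if not sites:
        return pd.DataFrame(columns=["chrom", "n_sites", "percent"])
    counts = pd.Series([s.chrom for s in sites]).value_counts(sort=False)
    df = pd.DataFrame({"chrom": counts.index, "n_sites": counts.to_numpy()})
    df["percent"] = (100.0 * df["n_sites"] / df["n_sites"].sum()).round(precision)
    return df.sort_values("n_sites", ascending=False, ignore_index=True)


def family_variant_enrichment(
    variants_in_set: int,
    genes_in_set: int,
    variants_outside: int,
    genes_outside: int,
) -> tuple[float, float]:
    """Two-sided Fisher exact test for variant enrichment in a gene family.

    The 2x2 table is [[variants_in_set, genes_in_set],
    [variants_outside, genes_outside]]. Returns (odds ratio, p).
    """
    table = np.array(
        [[variants_in_set, genes_in_set], [variants_outside, genes_outside]]
    )
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if table.sum() == 0:
        raise ValueError("all-zero contingency table")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def events_to_bed(events: Sequence[MutationEvent]) -> pd.DataFrame:
    """BED-like table (0-based half-open) of classified events."""
    return pd.DataFrame(
        [
            {
                "chrom": e.chrom, "start": e.start, "end": e.end,
                "kind": e.kind, "n_sites": e.n_sites,
                "copy_number_status": e.copy_number_status,
            }
            for e in events
        ],
        columns=["chrom", "start", "end", "kind", "n_sites",
                 "copy_number_status"],
    )
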