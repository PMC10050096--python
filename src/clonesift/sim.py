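"""Forward simulator of clonal diploid lineages under central-fusion automixis.

Automictic (thelytokous) parthenogens that restore diploidy by central
fusion inherit one recombined and one non-recombined meiotic product.
Heterozygosity is preserved near centromeres but, with probability 1/2
per crossover, every locus distal to the crossover becomes homozygous in
the offspring — a contiguous, copy-neutral loss of heterozygosity (LOH).
On top of that segmental process the simulator plants Poisson-distributed
de novo point mutations and short gene-conversion LOH tracts with
geometric lengths, emits per-site read depths with copy-number signal
(hemizygous deletions halve expected depth), and logs every planted event
in a machine-readable truth ledger so downstream detection code can be
scored against exact coordinates.

Genotypes are tracked only at segregating sites (founder-heterozygous
plus de novo positions); all other positions are implicitly homozygous
reference. Coordinates are 0-based half-open internally and converted to
1-based on VCF output.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotypes import HET, HOM_ALT, HOM_REF, GenotypeMatrix

DE_NOVO_SNP = "de_novo_snp"
GENE_CONVERSION_LOH = "gene_conversion_loh"
SEGMENTAL_LOH = "segmental_loh"
SEGMENTAL_DELETION = "segmental_deletion"
EVENT_KINDS = (DE_NOVO_SNP, GENE_CONVERSION_LOH, SEGMENTAL_LOH, SEGMENTAL_DELETION)

_BASES = np.array(["A", "C", "G", "T"])
# Conversion tracts are kept sub-kilobase so that they remain in the short
# (gene-conversion) LOH class rather than the chromosome-scale one.
MAX_CONVERSION_TRACT = 999


@dataclass
class SimConfig:
    """Study conditions for a simulated clonal lineage.

    Parameters
    ----------
    chromosome_lengths : list of (name, length bp)
    founder_het_density : expected heterozygous sites per bp in the founder.
    mu : de novo mutation rate per site per haploid genome per generation.
    genome_size_haploid : bp; must equal the sum of chromosome lengths
        (defaults to it).
    crossover_rate : expected crossovers per chromosome per meiosis.
    conversion_rate : expected gene-conversion tracts per genome per
        generation.
    conversion_tract_mean : geometric mean tract length, bp.
    mean_depth : expected reads per site per sample.
    depth_dispersion : negative-binomial overdispersion (variance =
        m + d m^2); 0 gives constant depth. The default 0.01 gives the
        mildly super-Poisson spread of depth at well-mapped sites in
        modern PCR-free libraries; grossly over-depth sites in real
        data are mapping artifacts, which this emission does not model.
    seed : master seed; identical seeds give bit-identical output.
    """

    chromosome_lengths: list[tuple[str, int]]
    founder_het_density: float = 1e-3
    mu: float = 3.5e-9
    genome_size_haploid: int | None = None
    crossover_rate: float = 1.0
    conversion_rate: float = 1.0
    conversion_tract_mean: float = 300.0
    mean_depth: float = 35.0
    depth_dispersion: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chromosome_lengths:
            raise ValueError("at least one chromosome is required")
        for name, length in self.chromosome_lengths:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        total = sum(l for _, l in self.chromosome_lengths)
        if self.genome_size_haploid is None:
            self.genome_size_haploid = total
        elif self.genome_size_haploid != total:
            raise ValueError(
                f"genome_size_haploid={self.genome_size_haploid} does not equal "
                f"sum of chromosome lengths ({total})"
            )
        for attr in ("founder_het_density", "mu", "crossover_rate",
                     "conversion_rate"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        if self.conversion_tract_mean < 1:
            raise ValueError("conversion_tract_mean must be >= 1 bp")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.depth_dispersion < 0:
            raise ValueError("depth_dispersion must be >= 0")

    @property
    def chrom_names(self) -> list[str]:
        return [n for n, _ in self.chromosome_lengths]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosome_lengths)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "chromosome_lengths" in raw:
            raw["chromosome_lengths"] = [
                (str(n), int(l)) for n, l in raw["chromosome_lengths"]
            ]
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        data = {
            "chromosome_lengths": [[n, l] for n, l in self.chromosome_lengths],
            "founder_het_density": self.founder_het_density,
            "mu": self.mu,
            "genome_size_haploid": self.genome_size_haploid,
            "crossover_rate": self.crossover_rate,
            "conversion_rate": self.conversion_rate,
            "conversion_tract_mean": self.conversion_tract_mean,
            "mean_depth": self.mean_depth,
            "depth_dispersion": self.depth_dispersion,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class TruthEvent:
    kind: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    generation: int
    samples: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError("require 0 <= start < end")
        if not self.samples:
            raise ValueError("event must reference at least one sample")
        self.samples = tuple(self.samples)


@dataclass
class SimTruth:
    """Ledger of planted events; the oracle for recovery tests."""

    events: list[TruthEvent] = field(default_factory=list)

    def of_kind(self, *kinds: str) -> list[TruthEvent]:
        return [e for e in self.events if e.kind in kinds]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("event_kind\tchrom\tstart\tend\tgeneration\tsamples\n")
            for e in self.events:
                fh.write(
                    f"{e.kind}\t{e.chrom}\t{e.start}\t{e.end}\t"
                    f"{e.generation}\t{','.join(e.samples)}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimTruth":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        events = [
            TruthEvent(
                kind=r.event_kind, chrom=r.chrom, start=int(r.start),
                end=int(r.end), generation=int(r.generation),
                samples=tuple(str(r.samples).split(",")),
            )
            for r in df.itertuples()
        ]
        return cls(events)


class Cohort:
    """Shared site registry plus per-individual genotype codes.

    Sites are kept sorted per chromosome; every individual holds a code
    array aligned to the registry. Adding a de novo site inserts a
    ``HOM_REF`` entry for all other individuals.
    """

    def __init__(self, cfg: SimConfig):
        self.cfg = cfg
        self.positions: dict[str, list[int]] = {c: [] for c in cfg.chrom_names}
        self.ref: dict[str, list[str]] = {c: [] for c in cfg.chrom_names}
        self.alt: dict[str, list[str]] = {c: [] for c in cfg.chrom_names}
        self.individuals: dict[str, dict[str, np.ndarray]] = {}

    @property
    def samples(self) -> list[str]:
        return list(self.individuals)

    def n_sites(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.positions[chrom])
        return sum(len(p) for p in self.positions.values())

    def add_individual(self, name: str, copy_of: str | None = None) -> None:
        if name in self.individuals:
            raise ValueError(f"individual {name!r} already exists")
        if copy_of is None:
            codes = {
                c: np.full(len(self.positions[c]), HOM_REF, dtype=np.int8)
                for c in self.positions
            }
        else:
            codes = {c: a.copy() for c, a in self.individuals[copy_of].items()}
        self.individuals[name] = codes

    def drop_individual(self, name: str) -> None:
        del self.individuals[name]

    def has_site(self, chrom: str, pos: int) -> bool:
        arr = self.positions[chrom]
        i = np.searchsorted(arr, pos)
        return i < len(arr) and arr[i] == pos

    def insert_site(self, chrom: str, pos: int, ref: str, alt: str) -> int:
        """Register a new segregating site; everyone starts HOM_REF."""
        if not 0 <= pos < self.cfg.lengths[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        i = int(np.searchsorted(self.positions[chrom], pos))
        if i < len(self.positions[chrom]) and self.positions[chrom][i] == pos:
            raise ValueError(f"site {chrom}:{pos} already segregating")
        self.positions[chrom].insert(i, pos)
        self.ref[chrom].insert(i, ref)
        self.alt[chrom].insert(i, alt)
        for codes in self.individuals.values():
            codes[chrom] = np.insert(codes[chrom], i, HOM_REF)
        return i

    def site_range(self, chrom: str, start: int, end: int) -> slice:
        """Registry index slice of sites with start <= pos < end."""
        arr = self.positions[chrom]
        return slice(
            int(np.searchsorted(arr, start)), int(np.searchsorted(arr, end))
        )

    def to_matrix(self, samples: Sequence[str] | None = None) -> GenotypeMatrix:
        """Export to a 1-based :class:`GenotypeMatrix` (depths unset)."""
        samples = list(samples) if samples is not None else self.samples
        frames, calls = [], []
        for chrom in self.cfg.chrom_names:
            if not self.positions[chrom]:
                continue
            frames.append(pd.DataFrame({
                "chrom": chrom,
                "pos": np.asarray(self.positions[chrom], dtype=np.int64) + 1,
                "ref": self.ref[chrom],
                "alt": self.alt[chrom],
            }))
            calls.append(np.column_stack(
                [self.individuals[s][chrom] for s in samples]
            ))
        if frames:
            sites = pd.concat(frames, ignore_index=True)
            call_arr = np.vstack(calls).astype(np.int8)
        else:
            sites = pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
            call_arr = np.zeros((0, len(samples)), dtype=np.int8)
        return GenotypeMatrix(
            sites=sites,
            calls=call_arr,
            depths=np.full(call_arr.shape, -1, dtype=np.int32),
            samples=samples,
        )


def simulate_founder(cfg: SimConfig, rng: np.random.Generator | None = None) -> Cohort:
    """Create a cohort holding one fully heterozygous founder.

    Heterozygous site counts are Poisson(density x length) per
    chromosome with uniform positions; each site gets a uniform ref base
    and a distinct alt base.
    """
    rng = rng if rng is not None else cfg.rng()
    cohort = Cohort(cfg)
    cohort.add_individual("founder")
    for chrom, length in cfg.chromosome_lengths:
        n = rng.poisson(cfg.founder_het_density * length)
        n = min(n, length)
        pos = np.sort(rng.choice(length, size=n, replace=False))
        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        cohort.positions[chrom] = [int(p) for p in pos]
        cohort.ref[chrom] = list(_BASES[ref_idx])
        cohort.alt[chrom] = list(_BASES[alt_idx])
        cohort.individuals["founder"][chrom] = np.full(n, HET, dtype=np.int8)
    return cohort


def _random_base_pair(rng: np.random.Generator) -> tuple[str, str]:
    r = int(rng.integers(0, 4))
    a = (r + int(rng.integers(1, 4))) % 4
    return str(_BASES[r]), str(_BASES[a])


def plant_de_novo_snp(
    cohort: Cohort,
    individual: str,
    chrom: str,
    pos: int,
    rng: np.random.Generator,
    generation: int = 0,
    samples: tuple[str, ...] | None = None,
) -> TruthEvent:
    """Place a gain-of-heterozygosity point mutation at a non-segregating site."""
    ref, alt = _random_base_pair(rng)
    i = cohort.insert_site(chrom, pos, ref, alt)
    cohort.individuals[individual][chrom][i] = HET
    return TruthEvent(DE_NOVO_SNP, chrom, pos, pos + 1, generation,
                      samples or (individual,))


def _homozygose(codes: np.ndarray, sl: slice, rng: np.random.Generator) -> None:
    """Collapse heterozygous calls in a slice to one allele per site."""
    seg = codes[sl]
    het = seg == HET
    if het.any():
        pick = rng.integers(0, 2, size=int(het.sum()))
        seg[het] = np.where(pick == 0, HOM_REF, HOM_ALT).astype(np.int8)
        codes[sl] = seg


def plant_conversion_tract(
    cohort: Cohort,
    individual: str,
    chrom: str,
    start: int,
    length: int,
    rng: np.random.Generator,
    generation: int = 0,
    samples: tuple[str, ...] | None = None,
) -> TruthEvent:
    """Convert heterozygous sites within [start, start+length) to homozygous."""
    end = min(start + length, cohort.cfg.lengths[chrom])
    sl = cohort.site_range(chrom, start, end)
    _homozygose(cohort.individuals[individual][chrom], sl, rng)
    return TruthEvent(GENE_CONVERSION_LOH, chrom, start, end, generation,
                      samples or (individual,))


def plant_segmental_loh(
    cohort: Cohort,
    individual: str,
    chrom: str,
    breakpoint: int,
    rng: np.random.Generator,
    generation: int = 0,
    samples: tuple[str, ...] | None = None,
) -> TruthEvent:
    """Crossover-induced LOH of every locus distal to ``breakpoint``.

    The centromere sits at position 0 of each chromosome, so the distal
    segment is [breakpoint, chromosome end).
    """
    end = cohort.cfg.lengths[chrom]
    if not 0 <= breakpoint < end:
        raise ValueError(f"breakpoint {breakpoint} outside {chrom}")
    sl = cohort.site_range(chrom, breakpoint, end)
    _homozygose(cohort.individuals[individual][chrom], sl, rng)
    return TruthEvent(SEGMENTAL_LOH, chrom, breakpoint, end, generation,
                      samples or (individual,))


def plant_segmental_deletion(
    cohort: Cohort,
    individual: str,
    chrom: str,
    start: int,
    end: int,
    rng: np.random.Generator,
    generation: int = 0,
    samples: tuple[str, ...] | None = None,
) -> TruthEvent:
    """Hemizygous deletion: genotypes collapse to one allele; depth halves.

    Only the genotype effect is applied here; pass the event interval to
    :func:`simulate_depths` to obtain the depth signal.
    """
    end = min(end, cohort.cfg.lengths[chrom])
    sl = cohort.site_range(chrom, start, end)
    _homozygose(cohort.individuals[individual][chrom], sl, rng)
    return TruthEvent(SEGMENTAL_DELETION, chrom, start, end, generation,
                      samples or (individual,))


def _draw_tract_length(cfg: SimConfig, rng: np.random.Generator) -> int:
    length = int(rng.geometric(1.0 / cfg.conversion_tract_mean))
    return min(length, MAX_CONVERSION_TRACT)


def _chrom_by_length(cfg: SimConfig, rng: np.random.Generator) -> str:
    lengths = np.array([l for _, l in cfg.chromosome_lengths], dtype=float)
    i = rng.choice(len(lengths), p=lengths / lengths.sum())
    return cfg.chromosome_lengths[i][0]


def mutate_generation(
    cohort: Cohort,
    individual: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    generation: int,
) -> list[TruthEvent]:
    """Apply one generation of the mutational processes to ``individual``.

    De novo SNP count is Poisson(2 mu G) (two haploid genome copies);
    gene-conversion tract count Poisson(conversion_rate); crossovers
    Poisson(crossover_rate) per chromosome, each rendering distal loci
    homozygous with probability 1/2 (one of the two segregation outcomes
    of central fusion).
    """
    events: list[TruthEvent] = []
    n_mut = rng.poisson(2.0 * cfg.mu * cfg.genome_size_haploid)
    for _ in range(n_mut):
        while True:
            chrom = _chrom_by_length(cfg, rng)
            pos = int(rng.integers(0, cfg.lengths[chrom]))
            if not cohort.has_site(chrom, pos):
                break
        events.append(
            plant_de_novo_snp(cohort, individual, chrom, pos, rng, generation)
        )
    for _ in range(rng.poisson(cfg.conversion_rate)):
        chrom = _chrom_by_length(cfg, rng)
        start = int(rng.integers(0, cfg.lengths[chrom]))
        events.append(
            plant_conversion_tract(
                cohort, individual, chrom, start,
                _draw_tract_length(cfg, rng), rng, generation
            )
        )
    for chrom, length in cfg.chromosome_lengths:
        for _ in range(rng.poisson(cfg.crossover_rate)):
            if rng.random() < 0.5:
                bp = int(rng.integers(0, length))
                events.append(
                    plant_segmental_loh(cohort, individual, chrom, bp, rng,
                                        generation)
                )
    return events


def propagate_lineage(
    cohort: Cohort,
    generations: int,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    parent: str = "founder",
    keep: str = "all",
) -> tuple[list[str], SimTruth]:
    """Descend ``generations`` single-offspring generations from ``parent``.

    Returns the per-generation offspring names (``gen1`` ...) and the
    truth ledger of all planted events. ``keep='last'`` discards
    intermediate individuals to bound memory in long runs.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    if keep not in ("all", "last"):
        raise ValueError("keep must be 'all' or 'last'")
    rng = rng if rng is not None else cfg.rng()
    truth = SimTruth()
    names: list[str] = []
    current = parent
    for g in range(1, generations + 1):
        child = f"gen{g}"
        cohort.add_individual(child, copy_of=current)
        truth.events.extend(mutate_generation(cohort, child, cfg, rng, g))
        if keep == "last" and current != parent:
            cohort.drop_individual(current)
        names.append(child)
        current = child
    return names, truth


@dataclass
class DepthInterval:
    """Interval with altered copy number for a subset of samples."""

    chrom: str
    start: int
    end: int
    samples: tuple[str, ...]
    factor: float = 0.5  # hemizygous deletion halves expected depth


def simulate_depths(
    cohort: Cohort,
    cfg: SimConfig,
    deletions: Sequence[DepthInterval] = (),
    rng: np.random.Generator | None = None,
    samples: Sequence[str] | None = None,
) -> np.ndarray:
    """Emit integer read depths per site per sample.

    Negative-binomial with mean ``mean_depth`` (scaled by any deletion
    factor) and variance ``m + d m^2``; dispersion 0 emits the constant
    rounded mean. Rows follow registry site order across chromosomes in
    config order; columns follow ``samples`` (default: cohort order).
    """
    rng = rng if rng is not None else cfg.rng()
    samples = list(samples) if samples is not None else cohort.samples
    col = {s: j for j, s in enumerate(samples)}
    n_sites = cohort.n_sites()
    means = np.full((n_sites, len(samples)), float(cfg.mean_depth))
    offset = 0
    for chrom in cfg.chrom_names:
        n = len(cohort.positions[chrom])
        pos = np.asarray(cohort.positions[chrom])
        for d in deletions:
            if d.chrom != chrom:
                continue
            inside = (pos >= d.start) & (pos < d.end)
            for s in d.samples:
                if s in col:
                    means[offset:offset + n, col[s]][inside] *= d.factor
        offset += n
    d = cfg.depth_dispersion
    if d == 0:
        return np.rint(means).astype(np.int32)
    r = 1.0 / d  # NB size; variance = m + m^2 / r
    depths = rng.negative_binomial(r, r / (r + means))
    return depths.astype(np.int32)


def emit_vcf(
    cohort: Cohort,
    depths: np.ndarray,
    truth: SimTruth,
    vcf_path: str | Path,
    truth_path: str | Path | None = None,
    samples: Sequence[str] | None = None,
) -> None:
    """Write the cohort as a VCF 4.2 file with GT and DP, plus the truth TSV.

    Positions are converted from the simulator's 0-based coordinates to
    VCF 1-based. Output is deterministic for a fixed cohort and depths.
    """
    import pysam

    samples = list(samples) if samples is not None else cohort.samples
    if not samples:
        raise ValueError("cohort has no individuals to write")
    header = pysam.VariantHeader()
    header.add_line('##source=clonesift.sim')
    for chrom, length in cohort.cfg.chromosome_lengths:
        header.contigs.add(chrom, length=length)
    header.add_meta(
        "FORMAT",
        items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
               ("Description", "Genotype")],
    )
    header.add_meta(
        "FORMAT",
        items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"),
               ("Description", "Read depth")],
    )
    for s in samples:
        header.add_sample(s)

    gt_map = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1)}
    with pysam.VariantFile(str(vcf_path), "w", header=header) as out:
        row = 0
        for chrom in cohort.cfg.chrom_names:
            for i, pos in enumerate(cohort.positions[chrom]):
                rec = out.new_record(
                    contig=chrom, start=pos, stop=pos + 1,
                    alleles=(cohort.ref[chrom][i], cohort.alt[chrom][i]),
                )
                for j, s in enumerate(samples):
                    code = int(cohort.individuals[s][chrom][i])
                    rec.samples[s]["GT"] = gt_map[code]
                    rec.samples[s]["DP"] = int(depths[row, j])
                out.write(rec)
                row += 1
    if truth_path is not None:
        truth.to_tsv(truth_path)


@dataclass
class PlantedCohort:
    """A planted-design cohort: focal clones vs wild-type references."""

    cohort: Cohort
    truth: SimTruth
    depths: np.ndarray  # aligned to cohort.samples
    deletions: list[DepthInterval]
    focal: list[str]
    reference: list[str]
    reference_sister: list[str]

    def roles(self):
        from .genotypes import (ROLE_FOCAL, ROLE_REFERENCE,
                                ROLE_REFERENCE_SISTER, SampleRoles)
        mapping = {s: ROLE_FOCAL for s in self.focal}
        for s in self.reference:
            mapping[s] = (ROLE_REFERENCE_SISTER if s in self.reference_sister
                          else ROLE_REFERENCE)
        return SampleRoles(mapping)


def simulate_planted_cohort(
    cfg: SimConfig,
    n_focal: int = 2,
    n_reference: int = 15,
    n_de_novo: int = 9,
    n_conversion: int = 19,
    segmental: tuple[str, int] | None = None,
    deletion: tuple[str, int, int] | None = None,
    min_separation: int = 20_000,
    rng: np.random.Generator | None = None,
) -> PlantedCohort:
    """Build a cohort with an exact, planted complement of lineage events.

    All references are copies of the founder; all focal individuals are
    copies of a single mutated ancestor, so every planted event is shared
    by the focal samples and absent from every reference — the geometry a
    clonal sub-lineage presents a few generations after its origin.

    De novo SNPs and conversion tracts are placed on chromosomes other
    than the ``segmental``/``deletion`` ones, pairwise separated by at
    least ``min_separation`` bp so each planted event yields exactly one
    called event; each conversion tract is placed to cover at least one
    founder-heterozygous site (a tract covering none is undetectable in
    principle). The first two references are labelled the sister clade.
    """
    rng = rng if rng is not None else cfg.rng()
    cohort = simulate_founder(cfg, rng)
    focal = [f"focal_{i+1}" for i in range(n_focal)]
    reference = [f"wt_{i+1:02d}" for i in range(n_reference)]
    cohort.add_individual(focal[0], copy_of="founder")

    excluded = set()
    if segmental is not None:
        excluded.add(segmental[0])
    if deletion is not None:
        excluded.add(deletion[0])
    open_chroms = [(c, l) for c, l in cfg.chromosome_lengths if c not in excluded]
    if not open_chroms and (n_de_novo or n_conversion):
        raise ValueError("no chromosome left for point/conversion events")

    truth = SimTruth()
    placed: list[tuple[str, int, int]] = []

    def clear(chrom: str, start: int, end: int) -> bool:
        for c, s, e in placed:
            if c == chrom and start < e + min_separation and s - min_separation < end:
                return False
        return True

    lengths = np.array([l for _, l in open_chroms], dtype=float)
    probs = lengths / lengths.sum()

    for _ in range(n_de_novo):
        for _attempt in range(10_000):
            chrom, length = open_chroms[rng.choice(len(open_chroms), p=probs)]
            pos = int(rng.integers(0, length))
            if not cohort.has_site(chrom, pos) and clear(chrom, pos, pos + 1):
                break
        else:
            raise RuntimeError("could not place de novo SNP; genome too crowded")
        truth.events.append(
            plant_de_novo_snp(cohort, focal[0], chrom, pos, rng,
                              samples=tuple(focal))
        )
        placed.append((chrom, pos, pos + 1))

    for _ in range(n_conversion):
        for _attempt in range(10_000):
            chrom, length = open_chroms[rng.choice(len(open_chroms), p=probs)]
            tract = _draw_tract_length(cfg, rng)
            start = int(rng.integers(0, max(length - tract, 1)))
            sl = cohort.site_range(chrom, start, start + tract)
            covered = cohort.individuals[focal[0]][chrom][sl]
            if (covered == HET).any() and clear(chrom, start, start + tract):
                break
        else:
            raise RuntimeError("could not place conversion tract over a het site")
        truth.events.append(
            plant_conversion_tract(cohort, focal[0], chrom, start, tract, rng,
                                   samples=tuple(focal))
        )
        placed.append((chrom, start, start + tract))

    if segmental is not None:
        chrom, breakpoint = segmental
        truth.events.append(
            plant_segmental_loh(cohort, focal[0], chrom, breakpoint, rng,
                                samples=tuple(focal))
        )
    deletions: list[DepthInterval] = []
    if deletion is not None:
        chrom, start, end = deletion
        truth.events.append(
            plant_segmental_deletion(cohort, focal[0], chrom, start, end, rng,
                                     samples=tuple(focal))
        )
        deletions.append(DepthInterval(chrom, start, end, tuple(focal)))

    for name in focal[1:]:
        cohort.add_individual(name, copy_of=focal[0])
    for name in reference:
        cohort.add_individual(name, copy_of="founder")
    cohort.drop_individual("founder")

    sample_order = focal + reference
    depths = simulate_depths(cohort, cfg, deletions, rng, samples=sample_order)
    # Reorder cohort dict to match depth columns.
    cohort.individuals = {s: cohort.individuals[s] for s in sample_order}
    return PlantedCohort(
        cohort=cohort, truth=truth, depths=depths, deletions=deletions,
        focal=focal, reference=reference, reference_sister=reference[:2],
    )
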