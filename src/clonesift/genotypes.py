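"""Genotype matrices from multi-sample VCFs, hard filtering, and depth normalization.

The central container is :class:`GenotypeMatrix`: biallelic SNP sites by
samples, with genotype classes and per-sample read depths. Positions are
1-based (VCF native) throughout this module; interval-based modules use
0-based half-open coordinates and convert explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# Genotype class codes used across the package.
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

ROLE_FOCAL = "focal"
ROLE_REFERENCE = "reference"
ROLE_REFERENCE_SISTER = "reference_sister"
ROLE_OUTGROUP = "outgroup"
VALID_ROLES = frozenset(
    {ROLE_FOCAL, ROLE_REFERENCE, ROLE_REFERENCE_SISTER, ROLE_OUTGROUP}
)

_BASES = frozenset("ACGT")


@dataclass
class GenotypeMatrix:
    """Sites x samples genotype calls with depths.

    Parameters
    ----------
    sites : pandas.DataFrame
        Columns ``chrom`` (str), ``pos`` (1-based int), ``ref``, ``alt``
        (single bases). Sorted by chromosome (order of first appearance)
        then position; no duplicate (chrom, pos).
    calls : ndarray of int8, shape (n_sites, n_samples)
        Genotype class codes: ``HOM_REF``, ``HET``, ``HOM_ALT`` or
        ``MISSING``.
    depths : ndarray of int32, shape (n_sites, n_samples)
        Read depth per call; ``-1`` where unavailable.
    samples : list of str
    """

    sites: pd.DataFrame
    calls: np.ndarray
    depths: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.depths = np.asarray(self.depths, dtype=np.int32)
        n = len(self.sites)
        if self.calls.shape != (n, len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} sites x {len(self.samples)} samples"
            )
        if self.depths.shape != self.calls.shape:
            raise ValueError("depths shape does not match calls shape")
        if n:
            key = pd.MultiIndex.from_frame(self.sites[["chrom", "pos"]])
            if key.duplicated().any():
                raise ValueError("duplicate (chrom, pos) in sites")
            for _, grp in self.sites.groupby("chrom", sort=False):
                if not grp["pos"].is_monotonic_increasing:
                    raise ValueError("positions not sorted within chromosome")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def chroms(self) -> list[str]:
        """Chromosomes in order of first appearance."""
        return list(dict.fromkeys(self.sites["chrom"]))

    def sample_index(self, names: Iterable[str]) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([idx[n] for n in names], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown sample {exc.args[0]!r}") from None

    def take_sites(self, mask_or_index: np.ndarray) -> "GenotypeMatrix":
        """Row subset preserving order."""
        mask_or_index = np.asarray(mask_or_index)
        if mask_or_index.dtype == bool:
            mask_or_index = np.flatnonzero(mask_or_index)
        return GenotypeMatrix(
            sites=self.sites.iloc[mask_or_index],
            calls=self.calls[mask_or_index],
            depths=self.depths[mask_or_index],
            samples=list(self.samples),
        )

    def select_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        cols = self.sample_index(names)
        return GenotypeMatrix(
            sites=self.sites,
            calls=self.calls[:, cols],
            depths=self.depths[:, cols],
            samples=list(names),
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write chrom, pos, ref, alt plus per-sample GT code and DP."""
        out = self.sites.copy()
        for j, s in enumerate(self.samples):
            out[f"GT:{s}"] = self.calls[:, j]
            out[f"DP:{s}"] = self.depths[:, j]
        out.to_csv(path, sep="\t", index=False)


@dataclass
class SampleRoles:
    """Sample -> analysis role assignment.

    Roles: ``focal`` (the clonal sub-lineage under study), ``reference``
    (wild-type relatives), ``reference_sister`` (the reference samples
    forming the focal lineage's sister clade; counted among the
    references), ``outgroup``.
    """

    roles: dict[str, str]

    def __post_init__(self) -> None:
        bad = {r for r in self.roles.values() if r not in VALID_ROLES}
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")

    def _with(self, *wanted: str) -> list[str]:
        return [s for s, r in self.roles.items() if r in wanted]

    @property
    def focal(self) -> list[str]:
        return self._with(ROLE_FOCAL)

    @property
    def reference(self) -> list[str]:
        return self._with(ROLE_REFERENCE, ROLE_REFERENCE_SISTER)

    @property
    def reference_sister(self) -> list[str]:
        return self._with(ROLE_REFERENCE_SISTER)

    @property
    def outgroup(self) -> list[str]:
        return self._with(ROLE_OUTGROUP)

    def require_lineage(self) -> None:
        if not self.focal:
            raise ValueError("no samples with role 'focal'")
        if not self.reference:
            raise ValueError("no samples with role 'reference'")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleRoles":
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["sample", "role"], dtype=str)
        return cls(dict(zip(df["sample"], df["role"])))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s, r in self.roles.items():
                fh.write(f"{s}\t{r}\n")


@dataclass
class FilterConfig:
    """Hard-filter settings.

    ``depth_multiplier`` times the global median depth is the exclusive
    upper bound on per-sample depth: any sample at or above it removes
    the site. ``drop_missing`` removes sites with any missing call.
    """

    depth_multiplier: float = 2.0
    drop_missing: bool = True

    def __post_init__(self) -> None:
        if self.depth_multiplier <= 0:
            raise ValueError("depth_multiplier must be > 0")


@dataclass
class ReadSummary:
    n_records: int = 0
    n_kept: int = 0
    n_indel: int = 0
    n_multiallelic: int = 0
    n_other: int = 0
    contig_lengths: dict = field(default_factory=dict)


def read_vcf_matrix(
    path: str | Path, samples: Sequence[str] | None = None
) -> tuple[GenotypeMatrix, ReadSummary]:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are retained; indels and multi-allelic
    records are counted in the returned :class:`ReadSummary`. Depth is
    taken from the per-sample ``DP`` FORMAT field (``-1`` if absent).
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path, gts012=True)
    if samples is not None:
        unknown = set(samples) - set(vcf.samples)
        if unknown:
            raise ValueError(f"samples not in VCF {path}: {sorted(unknown)}")
        vcf.close()
        vcf = VCF(path, gts012=True, samples=list(samples))
    names = list(vcf.samples)

    summary = ReadSummary()
    try:
        summary.contig_lengths = {
            n: int(l) for n, l in zip(vcf.seqnames, vcf.seqlens)
        }
    except Exception:  # header without contig lengths
        summary.contig_lengths = {}
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    calls: list[np.ndarray] = []
    depths: list[np.ndarray] = []
    for v in vcf:
        summary.n_records += 1
        if len(v.ALT) != 1:
            summary.n_multiallelic += 1
            continue
        ref, alt = v.REF, v.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            summary.n_indel += 1
            continue
        if ref not in _BASES or alt not in _BASES:
            summary.n_other += 1
            continue
        summary.n_kept += 1
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(ref)
        alts.append(alt)
        gt = np.asarray(v.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING  # gts012: 3 == unknown
        calls.append(gt)
        dp = v.format("DP")
        if dp is None:
            depths.append(np.full(len(names), -1, dtype=np.int32))
        else:
            dp = np.asarray(dp, dtype=np.int32).reshape(-1)
            dp[dp < 0] = -1
            depths.append(dp)
    vcf.close()

    sites = pd.DataFrame(
        {"chrom": chroms, "pos": np.array(poss, dtype=np.int64),
         "ref": refs, "alt": alts}
    )
    gm = GenotypeMatrix(
        sites=sites,
        calls=np.array(calls, dtype=np.int8).reshape(len(sites), len(names)),
        depths=np.array(depths, dtype=np.int32).reshape(len(sites), len(names)),
        samples=names,
    )
    return gm, summary


@dataclass
class HardFilterResult:
    matrix: GenotypeMatrix
    depth_threshold: float
    global_median_depth: float
    n_removed_missing: int
    n_removed_depth: int


def hard_filter(gm: GenotypeMatrix, cfg: FilterConfig | None = None) -> HardFilterResult:
    """Remove sites with missing calls or excessive depth.

    The depth cutoff is ``depth_multiplier`` x the global median of all
    (non-missing) depths, computed before any removal; a site is removed
    if any sample's depth is greater than or equal to the cutoff.
    """
    cfg = cfg or FilterConfig()
    known = gm.depths[gm.depths >= 0]
    median = float(np.median(known)) if known.size else float("nan")
    threshold = cfg.depth_multiplier * median

    missing_mask = (gm.calls == MISSING).any(axis=1) if cfg.drop_missing else np.zeros(
        gm.n_sites, dtype=bool
    )
    if known.size:
        depth_mask = (gm.depths >= threshold).any(axis=1)
    else:
        depth_mask = np.zeros(gm.n_sites, dtype=bool)
    keep = ~(missing_mask | depth_mask)
    if gm.n_sites and not keep.any():
        warnings.warn("hard_filter removed every site", stacklevel=2)
    return HardFilterResult(
        matrix=gm.take_sites(keep),
        depth_threshold=threshold,
        global_median_depth=median,
        n_removed_missing=int(missing_mask.sum()),
        n_removed_depth=int((depth_mask & ~missing_mask).sum()),
    )


@dataclass
class NormalizedDepth:
    """Per-sample median-normalized depths for a filtered matrix."""

    values: np.ndarray  # float64 (n_sites, n_samples); NaN where depth missing
    per_sample_median: np.ndarray
    samples: list[str]

    def group_columns(self, names: Sequence[str]) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.samples)}
        return np.array([idx[n] for n in names], dtype=int)


def normalize_depth(gm: GenotypeMatrix) -> NormalizedDepth:
    """Divide each sample's depths by that sample's median over all sites.

    Sequencing libraries differ in loading concentration, so depths are
    made comparable across samples by scaling each to a median of 1.
    """
    vals = gm.depths.astype(float)
    vals[gm.depths < 0] = np.nan
    medians = np.nanmedian(vals, axis=0) if gm.n_sites else np.full(gm.n_samples, np.nan)
    for j, s in enumerate(gm.samples):
        if not np.isfinite(medians[j]) or medians[j] == 0:
            raise ValueError(f"sample {s!r} has no usable depth (median 0 or missing)")
    return NormalizedDepth(
        values=vals / medians, per_sample_median=medians, samples=list(gm.samples)
    )


def contig_mean_depth(gm: GenotypeMatrix, norm: NormalizedDepth) -> pd.DataFrame:
    """Mean normalized depth per contig per sample (long format)."""
    rows = []
    for chrom, grp in gm.sites.groupby("chrom", sort=False):
        block = norm.values[grp.index.to_numpy()]
        means = np.nanmean(block, axis=0)
        for s, m in zip(gm.samples, means):
            rows.append({"chrom": chrom, "sample": s, "mean_norm_depth": m})
    return pd.DataFrame(rows, columns=["chrom", "sample", "mean_norm_depth"])
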