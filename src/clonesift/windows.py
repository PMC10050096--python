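"""Windowed relative-heterozygosity and normalized-depth chromosome scans.

Chromosomes are tiled with fixed, non-overlapping windows (default
250 kbp, 0-based half-open; the trailing partial window is retained and
flagged). Relative heterozygosity in a window is the fraction of sites
heterozygous in the reference sister clade that remain heterozygous in
the focal samples — near 1 where the focal lineage retains ancestral
heterozygosity and near 0 across a loss-of-heterozygosity tract.
Windows with no informative sites are undefined (NaN), not zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import (HET, HOM_ALT, HOM_REF, GenotypeMatrix,
                        NormalizedDepth, SampleRoles)


@dataclass
class WindowStat:
    chrom: str
    start: int
    end: int
    n_informative_sites: int
    relative_heterozygosity: float  # NaN when undefined
    depth_by_group: dict[str, float]
    partial: bool = False


def _tile(length: int, window: int):
    for start in range(0, length, window):
        end = min(start + window, length)
        yield start, end, end - start < window


def _chrom_lengths_from_sites(gm: GenotypeMatrix) -> dict[str, int]:
    return {
        str(c): int(g["pos"].max())
        for c, g in gm.sites.groupby("chrom", sort=False)
    }


def relative_heterozygosity(
    gm: GenotypeMatrix,
    roles: SampleRoles,
    window: int = 250_000,
    chrom_lengths: Mapping[str, int] | None = None,
    sister_mode: str = "all",
) -> list[WindowStat]:
    """Per-window fraction of sister-clade heterozygosity retained by focals.

    Informative sites are heterozygous in all sister samples
    (``sister_mode='all'``, the default: the denominator is the clade's
    shared ancestral heterozygosity) or in any (``'any'``). The value is
    the fraction of informative window sites heterozygous in all focal
    samples; windows with no informative sites get NaN.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if sister_mode not in ("all", "any"):
        raise ValueError("sister_mode must be 'all' or 'any'")
    roles.require_lineage()
    sister = roles.reference_sister or roles.reference
    if not sister:
        raise ValueError("no reference_sister (or reference) samples")
    lengths = dict(chrom_lengths) if chrom_lengths else _chrom_lengths_from_sites(gm)

    sis_cols = gm.sample_index(sister)
    foc_cols = gm.sample_index(roles.focal)
    out: list[WindowStat] = []
    for chrom, grp in gm.sites.groupby("chrom", sort=False):
        rows = grp.index.to_numpy()
        pos0 = grp["pos"].to_numpy() - 1  # to 0-based
        sis = gm.calls[np.ix_(rows, sis_cols)] == HET
        informative = sis.all(axis=1) if sister_mode == "all" else sis.any(axis=1)
        focal_het = (gm.calls[np.ix_(rows, foc_cols)] == HET).all(axis=1)
        for start, end, partial in _tile(lengths[str(chrom)], window):
            in_w = (pos0 >= start) & (pos0 < end)
            n_inf = int((informative & in_w).sum())
            if n_inf:
                value = float((informative & in_w & focal_het).sum()) / n_inf
            else:
                value = float("nan")
            out.append(WindowStat(str(chrom), start, end, n_inf, value, {},
                                  partial))
    return out


def windowed_depth(
    gm: GenotypeMatrix,
    norm: NormalizedDepth,
    roles: SampleRoles,
    window: int = 250_000,
    chrom_lengths: Mapping[str, int] | None = None,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> list[WindowStat]:
    """Mean normalized depth per window per sample group.

    Default groups are ``focal`` and ``reference`` (sister clade when
    annotated, otherwise all references). Windows without retained SNPs
    are undefined (NaN per group).
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if groups is None:
        roles.require_lineage()
        groups = {
            "focal": roles.focal,
            "reference": roles.reference_sister or roles.reference,
        }
    cols = {g: norm.group_columns(names) for g, names in groups.items()}
    lengths = dict(chrom_lengths) if chrom_lengths else _chrom_lengths_from_sites(gm)

    out: list[WindowStat] = []
    for chrom, grp in gm.sites.groupby("chrom", sort=False):
        rows = grp.index.to_numpy()
        pos0 = grp["pos"].to_numpy() - 1
        for start, end, partial in _tile(lengths[str(chrom)], window):
            in_w = np.flatnonzero((pos0 >= start) & (pos0 < end))
            depth = {}
            for g, c in cols.items():
                if in_w.size:
                    depth[g] = float(np.nanmean(norm.values[np.ix_(rows[in_w], c)]))
                else:
                    depth[g] = float("nan")
            out.append(WindowStat(str(chrom), start, end, int(in_w.size),
                                  float("nan"), depth, partial))
    return out


def windows_to_frame(stats: Sequence[WindowStat]) -> pd.DataFrame:
    """Flatten WindowStats (e.g. for TSV export)."""
    rows = []
    for w in stats:
        row = {
            "chrom": w.chrom, "start": w.start, "end": w.end,
            "n_sites": w.n_informative_sites,
            "rel_het": w.relative_heterozygosity, "partial": w.partial,
        }
        for g, v in w.depth_by_group.items():
            row[f"depth_{g}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
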