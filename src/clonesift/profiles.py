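"""Per-chromosome sequence-feature profiles for supergene diagnosis.

Supergene-bearing chromosomes (social chromosomes, Y-like chromosomes)
are typically fragmented in assemblies, transposable-element rich,
exon-poor and structural-variant dense. This module computes those four
profiles per chromosome: contigs per Mbp, and the proportions of the
ungapped length covered by TEs, exons, and structural variants.

All intervals are 0-based half-open BED conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class ChromosomeProfile:
    chrom: str
    ungapped_length: int
    contig_count: int | None = None
    contigs_per_mbp: float | None = None
    proportion_te: float | None = None
    proportion_exon: float | None = None
    proportion_sv: float | None = None


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read the first three columns of a BED file (chrom, start, end)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={0: str, 1: np.int64, 2: np.int64},
    )
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].iloc[0]
        raise ValueError(f"empty/inverted BED interval {bad.chrom}:{bad.start}-{bad.end}")
    return df


def _check_bounds(df: pd.DataFrame, lengths: Mapping[str, int], label: str) -> None:
    for r in df.itertuples():
        if r.chrom not in lengths:
            raise ValueError(f"{label} record on unknown chromosome {r.chrom!r}")
        if r.end > lengths[r.chrom]:
            raise ValueError(
                f"{label} interval {r.chrom}:{r.start}-{r.end} exceeds "
                f"chromosome length {lengths[r.chrom]}"
            )


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping or abutting sorted-by-start intervals."""
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s), np.array(out_e)


def merged_bp(df: pd.DataFrame, chrom: str) -> int:
    sub = df[df["chrom"] == chrom]
    s, e = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
    return int((e - s).sum())


def _overlaps_any(df: pd.DataFrame, other: pd.DataFrame) -> np.ndarray:
    """Boolean per row of df: overlaps any interval of other (same chrom)."""
    flags = np.zeros(len(df), dtype=bool)
    for chrom, sub in df.groupby("chrom", sort=False):
        o = other[other["chrom"] == chrom]
        if o.empty:
            continue
        os, oe = merge_intervals(o["start"].to_numpy(), o["end"].to_numpy())
        # interval [s,e) overlaps a merged block iff the previous block end > s
        idx = np.searchsorted(os, sub["end"].to_numpy(), side="left") - 1
        valid = idx >= 0
        hit = np.zeros(len(sub), dtype=bool)
        hit[valid] = oe[idx[valid]] > sub["start"].to_numpy()[valid]
        flags[sub.index.to_numpy()] = hit
    return flags


def feature_proportions(
    ungapped_lengths: Mapping[str, int],
    te: pd.DataFrame,
    exons: pd.DataFrame,
) -> pd.DataFrame:
    """TE and exon proportions with element-level mutual exclusion.

    Any TE element overlapping any exon element is dropped entirely, and
    vice versa; surviving elements are merged per chromosome and their
    occupancy divided by the ungapped chromosome length. The exclusion
    is symmetric in the two inputs.
    """
    te = te.reset_index(drop=True)
    exons = exons.reset_index(drop=True)
    _check_bounds(te, ungapped_lengths, "TE")
    _check_bounds(exons, ungapped_lengths, "exon")
    te_kept = te[~_overlaps_any(te, exons)]
    ex_kept = exons[~_overlaps_any(exons, te)]
    rows = []
    for chrom, length in ungapped_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive ungapped length")
        rows.append({
            "chrom": chrom,
            "proportion_te": merged_bp(te_kept, chrom) / length,
            "proportion_exon": merged_bp(ex_kept, chrom) / length,
        })
    return pd.DataFrame(rows)


def sv_proportion(
    sv: pd.DataFrame,
    ungapped_lengths: Mapping[str, int],
    min_len: int = 50,
) -> pd.DataFrame:
    """Proportion of each chromosome covered by structural variants.

    Structural variants are indels of at least ``min_len`` bp; shorter
    records are dropped, survivors merged, occupancy divided by the
    ungapped length.
    """
    sv = sv.reset_index(drop=True)
    _check_bounds(sv, ungapped_lengths, "SV")
    kept = sv[(sv["end"] - sv["start"]) >= min_len]
    return pd.DataFrame(
        [
            {"chrom": c, "proportion_sv": merged_bp(kept, c) / l}
            for c, l in ungapped_lengths.items()
        ]
    )


def contigs_per_mbp(
    contig_counts: Mapping[str, int], lengths: Mapping[str, int]
) -> pd.DataFrame:
    """Assembly fragmentation: contig count per megabase per chromosome."""
    rows = []
    for chrom, n in contig_counts.items():
        if n < 1:
            raise ValueError(f"chromosome {chrom!r} has contig count < 1")
        if lengths[chrom] <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length")
        rows.append({"chrom": chrom, "contigs_per_mbp": n / (lengths[chrom] / 1e6)})
    return pd.DataFrame(rows)


def ungapped_lengths_from_gaps(
    lengths: Mapping[str, int], gaps: pd.DataFrame | None
) -> dict[str, int]:
    """Chromosome length minus total assembly-gap (N-run) length."""
    out = dict(lengths)
    if gaps is None or gaps.empty:
        return out
    _check_bounds(gaps, lengths, "gap")
    for chrom in out:
        out[chrom] = out[chrom] - merged_bp(gaps, chrom)
    return out


def read_fai_lengths(path: str | Path) -> dict[str, int]:
    """Chromosome lengths from a FASTA index (.fai)."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1],
                     names=["chrom", "length"], dtype={0: str, 1: np.int64})
    return dict(zip(df["chrom"], df["length"]))


def profile_chromosomes(
    lengths: Mapping[str, int],
    gaps: pd.DataFrame | None = None,
    te: pd.DataFrame | None = None,
    exons: pd.DataFrame | None = None,
    sv: pd.DataFrame | None = None,
    contig_counts: Mapping[str, int] | None = None,
    sv_min_len: int = 50,
) -> pd.DataFrame:
    """Combined per-chromosome profile table (columns absent when inputs are)."""
    ungapped = ungapped_lengths_from_gaps(lengths, gaps)
    out = pd.DataFrame(
        {"chrom": list(ungapped), "ungapped_length": list(ungapped.values())}
    )
    if te is not None and exons is not None:
        out = out.merge(feature_proportions(ungapped, te, exons), on="chrom")
    if sv is not None:
        out = out.merge(sv_proportion(sv, ungapped, sv_min_len), on="chrom")
    if contig_counts is not None:
        out = out.merge(contigs_per_mbp(contig_counts, lengths), on="chrom")
    return out
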