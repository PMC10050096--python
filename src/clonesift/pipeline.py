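"""End-to-end orchestration: filter, distinguish, classify, verify, report.

The pipeline executes the clonal-lineage workflow in order: hard-filter
the genotype matrix, normalize depths, find sites distinguishing the
focal sub-lineage, classify them into mutation events, localize and
depth-verify segmental LOH, scan windows, and estimate generations since
the lineage's origin. Every stage's output is written under the output
directory together with a JSON manifest of parameters and input hashes;
deterministic stages are byte-identical on rerun.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import events as ev
from . import windows as ws
from .genotypes import (FilterConfig, GenotypeMatrix, NormalizedDepth,
                        SampleRoles, hard_filter, normalize_depth,
                        read_vcf_matrix)


@dataclass
class PipelineConfig:
    vcf: str
    roles: str
    out_dir: str = "clonesift_out"
    depth_multiplier: float = 2.0
    drop_missing: bool = True
    merge_gap: int = 1000
    segmental_span: int = 10_000
    window: int = 250_000
    neutral_band: tuple[float, float] = (0.85, 1.15)
    deletion_band: tuple[float, float] = (0.35, 0.65)
    mu: float = 3.5e-9
    genome_size_haploid: float = 224e6
    ploidy_factor: float = 2.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for band in ("neutral_band", "deletion_band"):
            setattr(cfg, band, tuple(getattr(cfg, band)))
        return cfg


@dataclass
class PipelineResult:
    config: PipelineConfig
    matrix: GenotypeMatrix
    norm: NormalizedDepth
    filter_result: Any
    read_summary: Any
    sites: list
    chrom_summary: pd.DataFrame
    events: list
    boundaries: dict
    window_het: list
    window_depth: list
    generations: ev.GenerationEstimate | None
    report_text: str = ""


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read_inputs"
    try:
        roles = SampleRoles.from_tsv(cfg.roles)
        roles.require_lineage()
        gm_raw, read_summary = read_vcf_matrix(cfg.vcf)

        stage = "hard_filter"
        fres = hard_filter(
            gm_raw, FilterConfig(cfg.depth_multiplier, cfg.drop_missing)
        )
        gm = fres.matrix
        gm.to_tsv(out / "filtered_matrix.tsv")

        stage = "normalize_depth"
        norm = normalize_depth(gm)

        stage = "find_distinguishing_sites"
        sites = ev.find_distinguishing_sites(gm, roles)
        pd.DataFrame(
            [{"chrom": s.chrom, "pos": s.pos, "focal_call": s.focal_call,
              "zygosity": s.focal_zygosity} for s in sites]
        ).to_csv(out / "distinguishing_sites.tsv", sep="\t", index=False)
        chrom_summary = ev.summarize_by_chromosome(sites)
        chrom_summary.to_csv(out / "chromosome_summary.tsv", sep="\t", index=False)

        # Chromosome-scale LOH is localized first via the het/hom
        # transition rule; its sites are excised so the short-tract
        # merge cannot fragment a multi-Mbp run into spurious pieces.
        stage = "locate_segmental_loh"
        lengths = read_summary.contig_lengths
        boundaries: dict[str, list[ev.BoundaryInterval]] = {}
        seg_events: list[ev.MutationEvent] = []
        excised = np.zeros(len(sites), dtype=bool)
        for chrom in dict.fromkeys(s.chrom for s in sites):
            try:
                runs = ev.find_segmental_runs(
                    gm, roles, chrom, lengths.get(chrom), cfg.segmental_span
                )
            except ValueError:  # no informative sites on this chromosome
                continue
            if runs:
                boundaries[chrom] = runs
            for r in runs:
                covered = [
                    k for k, s in enumerate(sites)
                    if s.chrom == chrom and s.focal_zygosity == "hom"
                    and r.inner_start < s.pos <= r.inner_end
                ]
                excised[covered] = True
                seg_events.append(
                    ev.MutationEvent(ev.SEGMENTAL, chrom, r.inner_start,
                                     r.inner_end, max(len(covered), r.n_sites))
                )

        stage = "classify_events"
        remaining = [s for k, s in enumerate(sites) if not excised[k]]
        events = ev.classify_events(remaining, cfg.merge_gap, cfg.segmental_span)
        events.extend(seg_events)
        events.sort(key=lambda e: (e.chrom, e.start))

        stage = "verify_copy_number"
        for e in events:
            if e.kind != ev.SEGMENTAL:
                continue
            status, _ratio = ev.check_copy_neutral(
                gm, norm, roles, e.chrom, e.start, e.end,
                cfg.neutral_band, cfg.deletion_band,
            )
            e.copy_number_status = status
        ev.events_to_bed(events).to_csv(out / "events.tsv", sep="\t", index=False)

        stage = "window_scan"
        window_het = ws.relative_heterozygosity(
            gm, roles, cfg.window, lengths or None
        )
        window_depth = ws.windowed_depth(gm, norm, roles, cfg.window,
                                         lengths or None)
        het_df = ws.windows_to_frame(window_het)
        dep_df = ws.windows_to_frame(window_depth)
        merged = het_df.drop(columns=["partial"]).merge(
            dep_df[[c for c in dep_df.columns if c not in ("n_sites", "rel_het")]],
            on=["chrom", "start", "end"],
        )
        merged.to_csv(out / "windows.tsv", sep="\t", index=False)

        stage = "estimate_generations"
        n_point = sum(1 for e in events if e.kind == ev.POINT_MUTATION)
        generations = ev.estimate_generations(
            n_point,
            ev.EstimatorConfig(cfg.mu, cfg.genome_size_haploid, cfg.ploidy_factor),
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    result = PipelineResult(
        config=cfg, matrix=gm, norm=norm, filter_result=fres,
        read_summary=read_summary, sites=sites, chrom_summary=chrom_summary,
        events=events, boundaries=boundaries, window_het=window_het,
        window_depth=window_depth, generations=generations,
    )
    result.report_text = write_report(result)
    (out / "report.txt").write_text(result.report_text)

    manifest = {
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
        },
        "inputs": {
            "vcf": {"path": str(cfg.vcf), "sha256": _sha256(cfg.vcf)},
            "roles": {"path": str(cfg.roles), "sha256": _sha256(cfg.roles)},
        },
        "counts": {
            "records_read": read_summary.n_records,
            "snps_kept": read_summary.n_kept,
            "sites_after_filter": gm.n_sites,
            "removed_missing": fres.n_removed_missing,
            "removed_depth": fres.n_removed_depth,
            "distinguishing_sites": len(sites),
            "events": len(events),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return result


def write_report(result: PipelineResult) -> str:
    """Human-readable summary; every number traces to a stage output."""
    lines: list[str] = []
    add = lines.append
    cfg = result.config
    add("clonal lineage genomic report")
    add("=" * 31)
    fr = result.filter_result
    add(f"sites read (biallelic SNPs): {result.read_summary.n_kept}")
    add(f"hard filter: depth >= {fr.depth_threshold:.1f} "
        f"({cfg.depth_multiplier} x global median {fr.global_median_depth:.1f}); "
        f"removed {fr.n_removed_missing} missing, {fr.n_removed_depth} over-depth")
    add(f"sites retained: {result.matrix.n_sites}")
    add("")
    n = len(result.sites)
    add(f"distinguishing sites (focal vs all references): {n}")
    if n:
        for r in result.chrom_summary.itertuples():
            add(f"  {r.chrom}: {r.n_sites} ({r.percent:.1f}%)")
    add("")
    if result.events:
        kinds = pd.Series([e.kind for e in result.events]).value_counts()
        add("events: " + ", ".join(f"{k}={v}" for k, v in kinds.items()))
        for e in result.events:
            if e.kind == ev.SEGMENTAL:
                add(f"  segmental LOH {e.chrom}:{e.start}-{e.end} "
                    f"({e.span/1e6:.2f} Mbp, {e.n_sites} sites, "
                    f"{e.copy_number_status})")
    else:
        add("events: none (zero distinguishing sites classified)")
    for chrom, runs in result.boundaries.items():
        for b in runs:
            add(f"  {chrom} boundary: inner [{b.inner_start}, {b.inner_end}) "
                f"span {b.span/1e6:.2f} Mbp; outer [{b.outer_start}, {b.outer_end})")
    add("")
    g = result.generations
    if g is not None:
        add(f"de novo point mutations: {g.n_de_novo}")
        add(f"expected de novo per generation (2 mu G): "
            f"{g.expected_per_generation:.3f}")
        add(f"generations since origin: {g.generations:.2f} "
            f"(95% interval {g.generations_low:.2f}-{g.generations_high:.2f})")
    defined = [w for w in result.window_het
               if np.isfinite(w.relative_heterozygosity)]
    add(f"windows with data: {len(defined)}/{len(result.window_het)} "
        f"({cfg.window/1000:.0f} kbp)")
    return "\n".join(lines) + "\n"
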