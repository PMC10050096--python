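"""IUPAC-coded alignments from genotype matrices, for diploid-aware trees.

Diploid genotypes at biallelic SNPs are collapsed to one symbol per
sample: homozygotes to the base, heterozygotes to the two-base IUPAC
ambiguity code (R, Y, S, W, K, M). Sites with a missing call in any
sample are dropped. Tree inference itself belongs to external ML
software; the pairwise divergence matrix here is a sanity companion,
scoring a het/hom pair sharing one allele as half a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import HET, HOM_ALT, HOM_REF, MISSING, GenotypeMatrix

IUPAC = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}
AMBIGUITY_ALLELES = {code: pair for pair, code in IUPAC.items()}
for _b in "ACGT":
    AMBIGUITY_ALLELES[_b] = frozenset(_b)


@dataclass
class IupacAlignment:
    samples: list[str]
    sequences: dict[str, str]
    site_map: pd.DataFrame  # chrom, pos (1-based), ref, alt per column

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("aligned sequences have unequal lengths")
        if self.sequences and lengths != {len(self.site_map)}:
            raise ValueError("site_map length does not match alignment")

    @property
    def length(self) -> int:
        return len(self.site_map)

    def to_fasta(self, path: str | Path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(self.sequences[s]), id=s, description="")
            for s in self.samples
        ]
        seqio_write(records, str(path), "fasta")

    def to_phylip(self, path: str | Path) -> None:
        """Relaxed PHYLIP (name, whitespace, sequence per line)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.samples)} {self.length}\n")
            for s in self.samples:
                fh.write(f"{s}  {self.sequences[s]}\n")


def to_iupac_alignment(gm: GenotypeMatrix) -> tuple[IupacAlignment, int]:
    """Convert a biallelic SNP matrix to an IUPAC alignment.

    hom-ref becomes the reference base, hom-alt the alternate base, and
    heterozygotes the ambiguity code of the two. Sites with any missing
    call are excluded; the count of excluded sites is returned.
    """
    bad = gm.sites[~gm.sites["ref"].isin(list("ACGT"))
                   | ~gm.sites["alt"].isin(list("ACGT"))]
    if len(bad):
        r = bad.iloc[0]
        raise ValueError(f"non-SNP alleles at {r.chrom}:{r.pos} ({r.ref}/{r.alt})")
    complete = (gm.calls != MISSING).all(axis=1)
    n_dropped = int(gm.n_sites - complete.sum())
    sub = gm.take_sites(complete)

    ref = sub.sites["ref"].to_numpy()
    alt = sub.sites["alt"].to_numpy()
    het = np.array([IUPAC[frozenset((r, a))] for r, a in zip(ref, alt)])
    lookup = np.stack([ref, het, alt])  # indexed by genotype code 0/1/2
    sequences = {
        s: "".join(lookup[sub.calls[:, j], np.arange(sub.n_sites)])
        for j, s in enumerate(sub.samples)
    }
    aln = IupacAlignment(
        samples=list(sub.samples), sequences=sequences,
        site_map=sub.sites.reset_index(drop=True),
    )
    return aln, n_dropped


def genotype_from_symbol(symbol: str, ref: str, alt: str) -> int:
    """Recover the genotype class from an alignment symbol (round trip)."""
    alleles = AMBIGUITY_ALLELES[symbol]
    if alleles == frozenset((ref, alt)):
        return HET
    if alleles == frozenset(ref):
        return HOM_REF
    if alleles == frozenset(alt):
        return HOM_ALT
    raise ValueError(f"symbol {symbol!r} inconsistent with {ref}/{alt}")


def _site_distance(a: str, b: str) -> float:
    if a == b:
        return 0.0
    sa, sb = AMBIGUITY_ALLELES[a], AMBIGUITY_ALLELES[b]
    return 0.5 if sa & sb else 1.0


_DIST_TABLE: dict[tuple[str, str], float] = {
    (a, b): _site_distance(a, b)
    for a in AMBIGUITY_ALLELES
    for b in AMBIGUITY_ALLELES
}


def pairwise_divergence(aln: IupacAlignment) -> pd.DataFrame:
    """Mean per-site mismatch between all sample pairs.

    Ambiguity-aware: symbols sharing exactly one allele (het versus a
    matching homozygote, or two hets sharing one base) score 0.5;
    disjoint symbols score 1. Symmetric with a zero diagonal.
    """
    if len(aln.samples) < 2:
        raise ValueError("need at least 2 samples")
    n = len(aln.samples)
    mat = np.zeros((n, n))
    seqs = [aln.sequences[s] for s in aln.samples]
    for i in range(n):
        for j in range(i + 1, n):
            if len(seqs[i]) != len(seqs[j]):
                raise ValueError("sequence length mismatch")
            if aln.length:
                d = sum(_DIST_TABLE[(x, y)] for x, y in zip(seqs[i], seqs[j]))
                mat[i, j] = mat[j, i] = d / aln.length
    return pd.DataFrame(mat, index=aln.samples, columns=aln.samples)
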