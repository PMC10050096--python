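import numpy as np
import pandas as pd
import pytest

from clonesift.genotypes import GenotypeMatrix
from clonesift.pipeline import PipelineConfig, run_pipeline
from clonesift.sim import SimConfig, emit_vcf, simulate_planted_cohort

# Planted study design used across the suite: 20 Mbp over 5 chromosomes,
# 2 focal + 15 reference samples, founder het density 1e-3, exactly
# 9 de novo SNPs + 19 sub-kilobase conversion tracts on chr1-4, one
# 2.25 Mbp segmental copy-neutral LOH and one 0.5 Mbp half-depth
# deletion control on chr5.
PLANT_SEED = 1
CHROMS = [(f"chr{i + 1}", 4_000_000) for i in range(5)]
SEGMENTAL = ("chr5", 1_750_000)
DELETION = ("chr5", 200_000, 700_000)


def make_planted(seed: int = PLANT_SEED):
    cfg = SimConfig(chromosome_lengths=list(CHROMS), seed=seed)
    return cfg, simulate_planted_cohort(cfg, segmental=SEGMENTAL,
                                        deletion=DELETION)


@pytest.fixture(scope="session")
def planted():
    return make_planted()


@pytest.fixture(scope="session")
def planted_run(planted, tmp_path_factory):
    """The planted cohort written to VCF and pushed through the pipeline."""
    cfg, p = planted
    d = tmp_path_factory.mktemp("planted")
    vcf, truth, roles = d / "cohort.vcf", d / "truth.tsv", d / "roles.tsv"
    emit_vcf(p.cohort, p.depths, p.truth, vcf, truth)
    p.roles().to_tsv(roles)
    result = run_pipeline(
        PipelineConfig(vcf=str(vcf), roles=str(roles), out_dir=str(d / "out"))
    )
    return p, result, d


def toy_matrix(calls, depths=None, chrom="chr1", start_pos=100, step=100,
               samples=None):
    """Small GenotypeMatrix from a (sites x samples) call list."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if depths is None:
        depths = np.full((n, m), 30, dtype=np.int32)
    if samples is None:
        samples = [f"s{j}" for j in range(m)]
    sites = pd.DataFrame({
        "chrom": [chrom] * n,
        "pos": np.arange(start_pos, start_pos + n * step, step, dtype=np.int64),
        "ref": ["A"] * n,
        "alt": ["G"] * n,
    })
    return GenotypeMatrix(sites=sites, calls=calls,
                          depths=np.asarray(depths, dtype=np.int32),
                          samples=list(samples))
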