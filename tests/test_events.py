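"""Event detection and classification against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clonesift.events import (COPY_NEUTRAL, DELETION_LIKE, GENE_CONVERSION,
                              POINT_MUTATION, SEGMENTAL, DistinguishingSite,
                              EstimatorConfig, check_copy_neutral,
                              classify_events, estimate_generations,
                              family_variant_enrichment,
                              find_distinguishing_sites,
                              locate_loh_boundaries, summarize_by_chromosome)
from clonesift.genotypes import (HET, HOM_ALT, HOM_REF, SampleRoles,
                                 normalize_depth)

from conftest import toy_matrix


def lineage_roles(n_focal, n_ref, samples):
    mapping = {samples[i]: "focal" for i in range(n_focal)}
    mapping.update({samples[i]: "reference"
                    for i in range(n_focal, n_focal + n_ref)})
    return SampleRoles(mapping)


def brute_force_distinguishing(calls, n_focal):
    """Per-site literal re-check of the definition."""
    hits = []
    for i, row in enumerate(calls):
        focal, ref = row[:n_focal], row[n_focal:]
        if len(set(focal)) == 1 and focal[0] not in ref:
            hits.append(i)
    return hits


class TestFindDistinguishingSites:
    def test_focal_disagreement_excluded(self):
        gm = toy_matrix([[HET, HOM_REF, HOM_REF]])
        roles = lineage_roles(2, 1, gm.samples)
        assert find_distinguishing_sites(gm, roles) == []

    def test_toy_matrix_matches_hand_check(self):
        # 5 sites x (2 focal + 3 reference); sites 0 and 3 qualify.
        calls = [
            [HOM_ALT, HOM_ALT, HET, HET, HET],
            [HET, HET, HET, HOM_REF, HET],
            [HET, HOM_ALT, HOM_REF, HOM_REF, HOM_REF],
            [HET, HET, HOM_REF, HOM_REF, HOM_REF],
            [HOM_REF, HOM_REF, HOM_REF, HET, HOM_REF],
        ]
        gm = toy_matrix(calls)
        roles = lineage_roles(2, 3, gm.samples)
        found = find_distinguishing_sites(gm, roles)
        assert [s.index for s in found] == [0, 3]
        assert found[0].focal_zygosity == "hom"
        assert found[1].focal_zygosity == "het"
        assert [s.index for s in found] == brute_force_distinguishing(calls, 2)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n_sites, n_focal, n_ref = rng.integers(1, 30), 2, 3
        calls = rng.integers(0, 3, size=(n_sites, n_focal + n_ref))
        gm = toy_matrix(calls)
        roles = lineage_roles(n_focal, n_ref, gm.samples)
        found = [s.index for s in find_distinguishing_sites(gm, roles)]
        assert found == brute_force_distinguishing(calls.tolist(), n_focal)

    def test_no_focal_samples_rejected(self):
        gm = toy_matrix([[HET, HET]])
        with pytest.raises(ValueError, match="focal"):
            find_distinguishing_sites(
                gm, SampleRoles({s: "reference" for s in gm.samples})
            )


def site(chrom, pos, zyg):
    return DistinguishingSite(index=0, chrom=chrom, pos=pos,
                              focal_call=HET if zyg == "het" else HOM_ALT,
                              focal_zygosity=zyg)


class TestClassifyEvents:
    def test_single_het_site_is_point_mutation(self):
        events = classify_events([site("chr1", 500, "het")])
        e, = events
        assert (e.kind, e.start, e.end, e.n_sites) == (POINT_MUTATION, 499, 500, 1)

    def test_merge_rule_hand_example(self):
        sites = [site("chr1", 100, "hom"), site("chr1", 600, "hom"),
                 site("chr1", 5000, "hom")]
        events = classify_events(sites)
        assert [(e.kind, e.start, e.end, e.n_sites) for e in events] == [
            (GENE_CONVERSION, 99, 600, 2),
            (GENE_CONVERSION, 4999, 5000, 1),
        ]

    def test_span_splits_conversion_from_segmental(self):
        run = [site("chr1", p, "hom") for p in range(1000, 13001, 800)]
        events = classify_events(run, merge_gap=1000, segmental_span=10_000)
        e, = events
        assert e.kind == SEGMENTAL and e.n_sites == len(run)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            classify_events([site("chr1", 600, "hom"), site("chr1", 100, "hom")])

    @pytest.mark.parametrize("seed", range(10))
    def test_conserves_sites_and_events_disjoint(self, seed):
        rng = np.random.default_rng(seed)
        sites = []
        for chrom in ("chr1", "chr2"):
            pos = np.sort(rng.choice(100_000, size=rng.integers(1, 40),
                                     replace=False)) + 1
            sites += [site(chrom, int(p),
                           "het" if rng.random() < 0.3 else "hom")
                      for p in pos]
        events = classify_events(sites)
        assert sum(e.n_sites for e in events) == len(sites)
        by_chrom = {}
        for e in events:
            by_chrom.setdefault(e.chrom, []).append((e.start, e.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_merging_invariant_to_chunking(self):
        rng = np.random.default_rng(42)
        pos = np.sort(rng.choice(50_000, size=30, replace=False)) + 1
        sites = [site("chr1", int(p), "hom") for p in pos]
        whole = classify_events(sites)
        # Chunk at an inter-site gap wider than merge_gap: same result.
        gaps = np.diff(pos)
        cut = int(np.argmax(gaps)) + 1
        assert gaps.max() > 1000
        split = classify_events(sites[:cut]) + classify_events(sites[cut:])
        assert [(e.kind, e.start, e.end) for e in whole] == \
            [(e.kind, e.start, e.end) for e in split]


class TestLohBoundaries:
    def test_saturated_chromosome_outer_bounds_are_ends(self):
        calls = [[HOM_ALT, HOM_ALT, HET, HET]] * 5
        gm = toy_matrix(calls, start_pos=1000, step=1000)
        roles = SampleRoles({"s0": "focal", "s1": "focal",
                             "s2": "reference_sister", "s3": "reference_sister"})
        b = locate_loh_boundaries(gm, roles, "chr1", chrom_length=10_000)
        assert (b.outer_start, b.outer_end) == (0, 10_000)
        assert (b.inner_start, b.inner_end) == (999, 5000)
        assert b.n_sites == 5

    def test_recovers_simulated_tract_within_marker_spacing(self):
        # Informative SNPs every 10 kbp on a 3 Mbp chromosome; focal samples
        # homozygous across [500 kbp, 2.75 Mbp).
        pos = np.arange(10_000, 3_000_000, 10_000)
        tract = (500_000, 2_750_000)
        calls = np.full((len(pos), 4), HET, dtype=np.int8)
        inside = (pos - 1 >= tract[0]) & (pos - 1 < tract[1])
        calls[inside, 0] = HOM_ALT
        calls[inside, 1] = HOM_REF
        gm = toy_matrix(calls, start_pos=10_000, step=10_000)
        roles = SampleRoles({"s0": "focal", "s1": "focal",
                             "s2": "reference_sister", "s3": "reference_sister"})
        b = locate_loh_boundaries(gm, roles, "chr1", chrom_length=3_000_000)
        truth_span = tract[1] - tract[0]
        assert abs(b.span - truth_span) <= 20_000
        assert b.outer_start <= tract[0] <= b.inner_start
        assert b.inner_end <= tract[1] <= b.outer_end

    def test_no_homozygous_run_returns_none(self):
        gm = toy_matrix([[HET, HET]] * 3)
        roles = SampleRoles({"s0": "focal", "s1": "reference_sister"})
        assert locate_loh_boundaries(gm, roles, "chr1") is None

    def test_no_informative_sites_raises(self):
        gm = toy_matrix([[HET, HOM_REF]] * 3)
        roles = SampleRoles({"s0": "focal", "s1": "reference_sister"})
        with pytest.raises(ValueError, match="informative"):
            locate_loh_boundaries(gm, roles, "chr1")


class TestCopyNeutral:
    def test_identical_groups_ratio_exactly_one(self):
        depths = [[30, 30], [45, 45], [20, 20]]
        gm = toy_matrix([[HOM_ALT, HET]] * 3, depths)
        roles = SampleRoles({"s0": "focal", "s1": "reference"})
        status, ratio = check_copy_neutral(gm, normalize_depth(gm), roles,
                                           "chr1", 0, 1000)
        assert status == COPY_NEUTRAL and ratio == 1.0

    def test_planted_loh_neutral_and_deletion_flagged(self, planted_run):
        p, result, _ = planted_run
        norm = normalize_depth(result.matrix)
        roles = p.roles()
        status, ratio = check_copy_neutral(
            result.matrix, norm, roles, "chr5", 1_750_000, 4_000_000)
        assert status == COPY_NEUTRAL and abs(ratio - 1.0) < 0.05
        status, ratio = check_copy_neutral(
            result.matrix, norm, roles, "chr5", 200_000, 700_000)
        assert status == DELETION_LIKE and abs(ratio - 0.5) < 0.05

    def test_empty_interval_rejected(self):
        gm = toy_matrix([[HET, HET]] * 3)
        roles = SampleRoles({"s0": "focal", "s1": "reference"})
        with pytest.raises(ValueError, match="no retained SNPs"):
            check_copy_neutral(gm, normalize_depth(gm), roles,
                               "chr1", 900_000, 950_000)


class TestEstimateGenerations:
    def test_expected_rate_from_constants(self):
        est = estimate_generations(9)
        assert est.expected_per_generation == pytest.approx(1.568)
        assert round(est.expected_per_generation, 1) == 1.6
        assert est.generations == pytest.approx(9 / 1.568)

    def test_zero_count(self):
        est = estimate_generations(0)
        assert est.generations == 0
        assert est.generations_low == 0
        assert est.generations_high > 0

    def test_interval_brackets_estimate_and_is_poisson_consistent(self):
        est = estimate_generations(9)
        assert est.generations_low < est.generations < est.generations_high
        # Deviance at both interval ends equals the chi-square critical value.
        crit = stats.chi2.ppf(0.95, 1)
        for lam in (est.generations_low * est.expected_per_generation,
                    est.generations_high * est.expected_per_generation):
            dev = 2 * (lam - 9 + 9 * np.log(9 / lam))
            assert dev == pytest.approx(crit, abs=1e-6)

    def test_linear_in_count_and_inverse_in_rate(self):
        a = estimate_generations(4)
        b = estimate_generations(8)
        assert b.generations == pytest.approx(2 * a.generations)
        half_mu = EstimatorConfig(mu=3.5e-9 / 2)
        c = estimate_generations(4, half_mu)
        assert c.generations == pytest.approx(2 * a.generations)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            estimate_generations(-1)
        with pytest.raises(ValueError):
            EstimatorConfig(mu=0)


class TestSummarize:
    def test_percentages(self):
        sites = [site("chr13", i + 1, "hom") for i in range(364)]
        sites += [site("other", i + 1, "het") for i in range(36)]
        df = summarize_by_chromosome(sites)
        assert df["n_sites"].sum() == 400
        assert df.set_index("chrom").at["chr13", "percent"] == 91.0

    def test_single_chromosome_is_100(self):
        df = summarize_by_chromosome([site("chr1", 5, "het")])
        assert list(df["percent"]) == [100.0]

    def test_toy_counts(self):
        sites = [site("A", 1, "het")] + [site("B", p, "het") for p in (1, 2, 3)]
        df = summarize_by_chromosome(sites)
        assert dict(zip(df["chrom"], df["percent"])) == {"A": 25.0, "B": 75.0}

    def test_empty(self):
        assert summarize_by_chromosome([]).empty


def enumerate_fisher(table):
    """Two-sided Fisher p by full enumeration of the hypergeometric support."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = stats.hypergeom.pmf(a, n, row1, col1)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = stats.hypergeom.pmf(x, n, row1, col1)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


class TestFamilyVariantEnrichment:
    def test_symmetric_table_is_null(self):
        odds, p = family_variant_enrichment(5, 5, 5, 5)
        assert odds == 1.0 and p == 1.0

    def test_reported_gene_family_table_significant(self):
        odds, p = family_variant_enrichment(22, 24, 48, 176)
        assert p < 0.001
        assert odds > 1

    def test_small_table_matches_enumeration(self):
        _, p = family_variant_enrichment(3, 1, 1, 3)
        assert p == pytest.approx(enumerate_fisher([[3, 1], [1, 3]]))

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_enumeration_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(0, 12, size=4)
        if a + b + c + d == 0:
            a = 1
        _, p = family_variant_enrichment(int(a), int(b), int(c), int(d))
        assert p == pytest.approx(enumerate_fisher([[a, b], [c, d]]), rel=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            family_variant_enrichment(0, 0, 0, 0)
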