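import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from somarna.annotation import Gene, GenomeAnnotation, Region
from somarna.filters import (
    accession_summaries,
    bias_tests,
    flag_outlier_candidates,
    outlier_accession_filter,
    passing,
    polynucleotide_filter,
    recurrence_filter,
    region_mask_filter,
    remove_germline,
    select_candidate_sites,
    sequencing_error_filter,
    splice_junction_filter,
    unambiguous_region_filter,
    vaf_filter,
)
from somarna.io import join_vector

from conftest import make_candidate


def make_pileup_row(ref="C", counts=None, coverage=None, baseq_all=36, accession="a1",
                    pos=100):
    counts = counts or {"C": 34, "T": 6}
    cov = coverage if coverage is not None else sum(counts.values())
    row = {
        "accession": accession, "chrom": "chr1", "pos": pos, "ref": ref,
        "count_A": counts.get("A", 0), "count_C": counts.get("C", 0),
        "count_G": counts.get("G", 0), "count_T": counts.get("T", 0),
        "coverage": cov,
    }
    nonref = {b: c for b, c in counts.items() if b != ref and c > 0}
    alt_n = max(nonref.values()) if nonref else 0
    ref_n = counts.get(ref, 0)
    rng = np.random.default_rng(pos)
    for side, n in (("ref", ref_n), ("alt", alt_n)):
        row[f"{side}_read_pos"] = join_vector(rng.integers(0, 95, n))
        row[f"{side}_mapq"] = join_vector(np.full(n, 60))
        row[f"{side}_baseq"] = join_vector(np.full(n, baseq_all))
        row[f"{side}_strand"] = join_vector(rng.integers(0, 2, n))
    row["baseq_pass"] = cov if baseq_all >= 30 else 0
    return row


class TestSelection:
    def test_boundary_coverage_and_minor_count_emitted(self):
        pileup = pd.DataFrame([make_pileup_row(counts={"C": 34, "T": 6})])
        out = select_candidate_sites(pileup)
        assert len(out) == 1
        assert out.iloc[0]["alt"] == "T"
        assert out.iloc[0]["alt_count"] == 6

    def test_below_coverage_cutoff_dropped(self):
        pileup = pd.DataFrame([make_pileup_row(counts={"C": 33, "T": 6})])
        assert select_candidate_sites(pileup).empty

    def test_three_allele_site_dropped(self):
        pileup = pd.DataFrame(
            [make_pileup_row(counts={"C": 90, "T": 5, "G": 5}, coverage=100)]
        )
        assert select_candidate_sites(pileup).empty

    def test_minor_count_uses_quality_passing_reads(self):
        # six alt reads but all below Phred 30 -> dropped
        row = make_pileup_row(counts={"C": 40, "T": 6})
        row["alt_baseq"] = join_vector([29] * 6)
        assert select_candidate_sites(pd.DataFrame([row])).empty

    def test_minor_can_be_reference_allele(self):
        # high-VAF site: reference is the minor allele; still a candidate
        pileup = pd.DataFrame([make_pileup_row(counts={"C": 7, "T": 50})])
        out = select_candidate_sites(pileup)
        assert len(out) == 1 and out.iloc[0]["alt"] == "T"


class TestPositionFilters:
    def test_germline_exact_position_only(self):
        cand = pd.DataFrame([
            make_candidate(pos=99), make_candidate(pos=100), make_candidate(pos=101),
        ])
        germ = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "ref": ["C"], "alt": ["G"]})
        remove_germline(cand, germ)
        assert cand["flag_germline"].tolist() == [False, True, False]

    def test_germline_empty_vcf_no_flags(self):
        cand = pd.DataFrame([make_candidate()])
        remove_germline(cand, pd.DataFrame(columns=["chrom", "pos", "ref", "alt"]))
        assert not cand["flag_germline"].any()

    def test_mask_half_open_boundaries(self):
        cand = pd.DataFrame([make_candidate(pos=10), make_candidate(pos=20)])
        bed = pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [20]})
        region_mask_filter(cand, bed, "blacklist")
        assert cand["flag_blacklist"].tolist() == [True, False]

    def test_mask_matches_brute_force_scan(self):
        rng = np.random.default_rng(1)
        cand = pd.DataFrame([make_candidate(pos=int(p)) for p in rng.integers(0, 2000, 1000)])
        starts = rng.integers(0, 2000, 50)
        bed = pd.DataFrame({
            "chrom": "chr1", "start": starts, "end": starts + rng.integers(1, 60, 50),
        })
        region_mask_filter(cand, bed, "blacklist")
        expected = [
            any(s <= p < e for s, e in zip(bed["start"], bed["end"]))
            for p in cand["pos"]
        ]
        assert cand["flag_blacklist"].tolist() == expected

    def test_splice_distance_boundaries(self):
        ends = {"chr1": np.array([100])}
        cand = pd.DataFrame([
            make_candidate(pos=100),  # at the terminal base: distance 0
            make_candidate(pos=106),  # distance 6 -> flagged
            make_candidate(pos=107),  # distance 7 -> kept
        ])
        splice_junction_filter(cand, ends)
        assert cand["flag_splice_junction"].tolist() == [True, True, False]

    def test_splice_matches_brute_force(self):
        rng = np.random.default_rng(2)
        ends = np.sort(rng.choice(3000, 40, replace=False))
        cand = pd.DataFrame([make_candidate(pos=int(p)) for p in rng.integers(0, 3000, 500)])
        splice_junction_filter(cand, {"chr1": ends})
        expected = [min(abs(p - e) for e in ends) < 7 for p in cand["pos"]]
        assert cand["flag_splice_junction"].tolist() == expected

    def test_polynucleotide_window_boundaries(self):
        # run-free backbone with a single planted A7 at [50, 57)
        seq = "ACGT" * 75
        seq = seq[:50] + "A" * 7 + seq[57:]
        ref = {"chr1": seq}
        from somarna.simulate import find_runs
        assert find_runs(seq, 7) == [(50, 57)]
        cand = pd.DataFrame([
            make_candidate(pos=62),   # 5 bases downstream of the run -> flagged
            make_candidate(pos=77),   # distance 21 from run end -> kept
            make_candidate(pos=53),   # inside the run -> flagged
            make_candidate(pos=76),   # distance 20 -> flagged
        ])
        polynucleotide_filter(cand, ref)
        assert cand["flag_polynucleotide"].tolist() == [True, False, True, True]

    def test_polynucleotide_matches_brute_force(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 5000, p=[0.4, 0.1, 0.1, 0.4]))
        ref = {"chr1": seq}
        from somarna.simulate import find_runs
        runs = find_runs(seq, 7)
        cand = pd.DataFrame([make_candidate(pos=int(p)) for p in rng.integers(0, 5000, 800)])
        polynucleotide_filter(cand, ref)
        expected = []
        for p in cand["pos"]:
            d = math.inf
            for s, e in runs:
                if s <= p < e:
                    d = 0
                else:
                    d = min(d, min(abs(p - s), abs(p - (e - 1))))
            expected.append(d <= 20)
        assert cand["flag_polynucleotide"].tolist() == expected

    def test_polynucleotide_out_of_bounds_position_errors(self):
        cand = pd.DataFrame([make_candidate(pos=500)])
        with pytest.raises(ValueError, match="outside"):
            polynucleotide_filter(cand, {"chr1": "ACGT" * 10})

    def test_unambiguous_region_filter(self, toy_annotation):
        cand = pd.DataFrame([
            make_candidate(pos=410),  # inside g1/g2 overlap -> ambiguous
            make_candidate(pos=120),  # intronic -> flagged
            make_candidate(pos=200),  # single-gene exon -> kept
        ])
        unambiguous_region_filter(cand, toy_annotation)
        assert cand["flag_ambiguous_region"].tolist() == [True, True, False]


class TestBinomialFilters:
    def test_zero_alt_certainly_error(self):
        cand = pd.DataFrame([make_candidate(ref_count=40, alt_count=0)])
        sequencing_error_filter(cand)
        assert cand["flag_seq_error"].all()

    def test_boundary_case_40_6_kept(self):
        cand = pd.DataFrame([make_candidate(ref_count=34, alt_count=6)])
        sequencing_error_filter(cand)
        assert not cand["flag_seq_error"].any()

    def test_high_coverage_low_count_flagged(self):
        c = make_candidate(ref_count=9994, alt_count=6)
        c["coverage"] = 10_000
        cand = pd.DataFrame([c])
        sequencing_error_filter(cand)
        assert cand["flag_seq_error"].all()

    def test_zero_coverage_errors(self):
        c = make_candidate()
        c["coverage"] = 0
        with pytest.raises(ValueError, match="coverage"):
            sequencing_error_filter(pd.DataFrame([c]))

    def test_vaf_all_alt_flagged(self):
        cand = pd.DataFrame([make_candidate(ref_count=0, alt_count=40)])
        vaf_filter(cand)
        assert cand["flag_vaf"].all()

    def test_vaf_examples(self):
        cand = pd.DataFrame([
            make_candidate(ref_count=34, alt_count=6),   # kept
            make_candidate(ref_count=20, alt_count=20),  # flagged (tail > 0.5)
        ])
        vaf_filter(cand)
        assert cand["flag_vaf"].tolist() == [False, True]

    def test_binomial_filters_match_pmf_summation(self):
        """Upper/lower binomial tails agree with direct pmf sums to 1e-12."""
        from somarna.filters import sequencing_error_prob, vaf_lower_tail

        rng = np.random.default_rng(11)
        for _ in range(300):
            n = int(rng.integers(1, 400))
            k = int(rng.integers(0, min(n, 60) + 1))
            upper = float(sequencing_error_prob(k, n, 0.001))
            oracle_up = math.fsum(stats.binom.pmf(np.arange(k, n + 1), n, 0.001))
            assert upper == pytest.approx(oracle_up, rel=1e-12, abs=1e-300)
            lower = float(vaf_lower_tail(k, n))
            oracle_lo = math.fsum(stats.binom.pmf(np.arange(0, k + 1), n, 0.5))
            assert lower == pytest.approx(oracle_lo, rel=1e-12)


class TestBiasTests:
    def test_identical_distribution_calibration(self):
        """Alt values subsampled from the ref vector: joint pass >= 90%."""
        rng = np.random.default_rng(42)
        rows = []
        for i in range(200):
            n2, n1 = 40, 12
            rp = rng.integers(0, 95, n2)
            bq = np.clip(np.round(rng.normal(36, 2, n2)), 2, 41).astype(int)
            st = rng.integers(0, 2, n2)
            sel = rng.choice(n2, n1, replace=False)
            rows.append(make_candidate(
                pos=i, ref_count=n2, alt_count=n1,
                ref_read_pos=join_vector(rp), alt_read_pos=join_vector(rp[sel]),
                ref_baseq=join_vector(bq), alt_baseq=join_vector(bq[sel]),
                ref_strand=join_vector(st), alt_strand=join_vector(st[sel]),
                ref_mapq=join_vector(np.full(n2, 60)),
                alt_mapq=join_vector(np.full(n1, 60)),
            ))
        cand = pd.DataFrame(rows)
        bias_tests(cand)
        assert passing(cand).mean() >= 0.90

    def test_clustered_alt_read_positions_flagged(self):
        rng = np.random.default_rng(0)
        cand = pd.DataFrame([make_candidate(
            ref_count=20, alt_count=20,
            alt_read_pos=join_vector(np.zeros(20, dtype=int)),
            ref_read_pos=join_vector(rng.integers(0, 94, 20)),
        )])
        bias_tests(cand)
        assert cand["flag_read_pos_bias"].all()

    def test_total_tie_gives_p_one_kept(self):
        cand = pd.DataFrame([make_candidate(
            ref_count=10, alt_count=10,
            alt_mapq=join_vector(np.full(10, 60)),
            ref_mapq=join_vector(np.full(10, 60)),
        )])
        bias_tests(cand)
        assert not cand["flag_map_qual_bias"].any()

    def test_small_groups_match_exact_enumeration(self):
        """Tie-free small groups use the exact U distribution."""
        from somarna.filters import _mannwhitney_p
        from itertools import combinations

        x = np.array([1.0, 5.0, 9.0, 13.0])
        y = np.array([2.0, 4.0, 6.0, 8.0])
        p = _mannwhitney_p(x, y)
        # enumeration oracle: all group assignments of the pooled values
        pooled = np.concatenate([x, y])

        def ustat(g1):
            g1 = np.array(g1)
            g2 = np.array([v for v in pooled if v not in g1])
            return sum((a > b) for a in g1 for b in g2)

        u_obs = ustat(x)
        us = [ustat(c) for c in combinations(pooled, len(x))]
        lo = np.mean([u <= min(u_obs, 16 - u_obs) for u in us])
        hi = np.mean([u >= max(u_obs, 16 - u_obs) for u in us])
        assert p == pytest.approx(min(1.0, lo + hi), abs=1e-12)

    def test_shifted_mapping_quality_flagged(self):
        cand = pd.DataFrame([make_candidate(
            ref_count=20, alt_count=15,
            alt_mapq=join_vector(np.full(15, 40)),
            ref_mapq=join_vector(np.full(20, 60)),
        )])
        bias_tests(cand)
        assert cand["flag_map_qual_bias"].all()


class TestCrossAccessionFilters:
    def test_recurrent_locus_flags_all_records(self):
        cand = pd.DataFrame([
            make_candidate(accession=f"a{i}", pos=100) for i in range(2)
        ] + [make_candidate(accession="a9", pos=500)])
        recurrence_filter(cand, n_accessions=100)
        assert cand["flag_recurrent"].tolist() == [True, True, False]

    def test_four_percent_threshold_uses_ceiling(self):
        # ceil(0.04 * 671) = 27 accessions
        cand = pd.DataFrame([
            make_candidate(accession=f"a{i}", pos=100) for i in range(27)
        ] + [make_candidate(accession=f"b{i}", pos=500) for i in range(26)])
        recurrence_filter(cand, n_accessions=671)
        at_100 = cand["pos"] == 100
        assert cand.loc[at_100, "flag_recurrence_fraction"].all()
        assert not cand.loc[~at_100, "flag_recurrence_fraction"].any()

    def test_recurrence_ignores_already_flagged_records(self):
        cand = pd.DataFrame([
            make_candidate(accession="a1", pos=100),
            make_candidate(accession="a2", pos=100),
        ])
        cand["flag_vaf"] = [True, False]  # one record already failed upstream
        recurrence_filter(cand, n_accessions=50)
        assert not cand["flag_recurrent"].any()

    def test_outlier_group_iqr_rule(self):
        summaries = pd.DataFrame({
            "accession": [f"a{i}" for i in range(8)],
            "total_depth": [100, 101, 102, 103, 104, 400, 401, 402],
            "mutation_count": [5, 5, 5, 5, 50, 5, 5, 5],
        })
        out = outlier_accession_filter(summaries)
        assert out.loc[out["mutation_count"] == 50, "outlier"].all()
        assert not out.loc[out["mutation_count"] == 5, "outlier"].any()

    def test_identical_counts_flag_nothing_but_singletons(self):
        summaries = pd.DataFrame({
            "accession": [f"a{i}" for i in range(6)],
            "total_depth": [100, 101, 102, 103, 104, 1000],
            "mutation_count": [7, 7, 7, 7, 7, 7],
        })
        out = outlier_accession_filter(summaries)
        # the depth-1000 accession sits alone in the top bin
        assert out.loc[out["total_depth"] == 1000, "outlier"].all()
        assert not out.loc[out["total_depth"] < 1000, "outlier"].any()

    def test_fewer_than_four_accessions_errors(self):
        summaries = pd.DataFrame({
            "accession": ["a", "b", "c"],
            "total_depth": [1, 2, 3],
            "mutation_count": [0, 0, 0],
        })
        with pytest.raises(ValueError, match="4 accessions"):
            outlier_accession_filter(summaries)

    def test_accession_summaries_count_survivors_only(self):
        cand = pd.DataFrame([
            make_candidate(accession="a1", pos=1),
            make_candidate(accession="a1", pos=2),
            make_candidate(accession="a2", pos=3),
        ])
        cand["flag_vaf"] = [False, True, False]
        depth = pd.Series({"a1": 1000, "a2": 2000, "a3": 1500})
        s = accession_summaries(cand, depth).set_index("accession")
        assert s.loc["a1", "mutation_count"] == 1
        assert s.loc["a3", "mutation_count"] == 0


def test_filter_flag_monotonicity(sim_dataset):
    """Raising the coverage cutoff can only shrink the candidate set."""
    _, _, result = sim_dataset
    base = select_candidate_sites(result.pileup, min_coverage=40)
    strict = select_candidate_sites(result.pileup, min_coverage=41)
    base_keys = set(zip(base["accession"], base["chrom"], base["pos"]))
    strict_keys = set(zip(strict["accession"], strict["chrom"], strict["pos"]))
    assert strict_keys <= base_keys
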