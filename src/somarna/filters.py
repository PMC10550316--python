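"""Candidate selection, germline removal and the artifact-filter cascade.

Each filter is independently callable and records its decision in a named
boolean flag column on the candidate table; a candidate *passes* iff no
flag is set.  Filter order matters only for the recurrence and outlier
filters, which consume only candidates surviving everything upstream.

Flag names: germline, blacklist, rna_edit, splice_junction, seq_error, vaf,
read_pos_bias, map_qual_bias, base_qual_bias, strand_bias, var_dist_bias,
polynucleotide, recurrence_fraction, recurrent, outlier_accession,
ambiguous_region.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from somarna.annotation import GenomeAnnotation, merge_intervals, positions_in_intervals
from somarna.io import split_vector
from somarna.simulate import find_runs

logger = logging.getLogger(__name__)

FLAGS = [
    "germline",
    "blacklist",
    "rna_edit",
    "splice_junction",
    "seq_error",
    "vaf",
    "read_pos_bias",
    "map_qual_bias",
    "base_qual_bias",
    "strand_bias",
    "var_dist_bias",
    "polynucleotide",
    "recurrence_fraction",
    "recurrent",
    "outlier_accession",
    "ambiguous_region",
]

ATTR_COLS = [
    f"{side}_{what}"
    for side in ("ref", "alt")
    for what in ("read_pos", "mapq", "baseq", "strand")
]


def _flag_col(name: str) -> str:
    return f"flag_{name}"


def add_flag(candidates: pd.DataFrame, name: str, mask) -> None:
    col = _flag_col(name)
    if col not in candidates.columns:
        candidates[col] = False
    candidates[col] |= np.asarray(mask, dtype=bool)


def flag_columns(candidates: pd.DataFrame) -> list[str]:
    return [c for c in candidates.columns if c.startswith("flag_")]


def passing(candidates: pd.DataFrame) -> pd.Series:
    cols = flag_columns(candidates)
    if not cols:
        return pd.Series(True, index=candidates.index)
    return ~candidates[cols].any(axis=1)


# ---------------------------------------------------------------------------
# Candidate selection


def select_candidate_sites(
    pileup: pd.DataFrame,
    min_coverage: int = 40,
    min_base_phred: int = 30,
    min_minor_count: int = 6,
) -> pd.DataFrame:
    """Select sites with exactly two observed base calls as candidates.

    A site is emitted when its raw coverage reaches ``min_coverage``,
    exactly two bases are observed (one of them the reference), and the
    minor allele has at least ``min_minor_count`` reads at base quality
    ``min_base_phred`` or above.  Sites showing three or more alleles are
    dropped (logged), not errored.
    """
    counts = pileup[["count_A", "count_C", "count_G", "count_T"]].to_numpy()
    coverage = pileup["coverage"].to_numpy()
    n_alleles = (counts > 0).sum(axis=1)
    multi = n_alleles > 2
    if multi.any():
        logger.info("dropped %d sites with >2 observed base calls", int(multi.sum()))
    cand_mask = (n_alleles == 2) & (coverage >= min_coverage)
    sub = pileup.loc[cand_mask].copy()
    if sub.empty:
        return _empty_candidates(pileup)

    sub_counts = counts[cand_mask]
    base_idx = {b: i for i, b in enumerate("ACGT")}
    ref_idx = sub["ref"].map(base_idx).to_numpy()
    # the non-reference allele; sites where the reference itself is not one
    # of the two observed calls are dropped
    ref_count_raw = sub_counts[np.arange(len(sub)), ref_idx]
    has_ref = ref_count_raw > 0
    if (~has_ref).any():
        logger.info(
            "dropped %d biallelic sites not containing the reference base",
            int((~has_ref).sum()),
        )
    sub = sub.loc[has_ref].copy()
    sub_counts = sub_counts[has_ref]
    ref_idx = ref_idx[has_ref]
    nonref = sub_counts.copy()
    nonref[np.arange(len(sub)), ref_idx] = 0
    alt_idx = nonref.argmax(axis=1)
    sub["alt"] = np.array(list("ACGT"))[alt_idx]

    # quality-passing allele counts from the per-read base qualities
    ref_pass = np.empty(len(sub), dtype=np.int64)
    alt_pass = np.empty(len(sub), dtype=np.int64)
    for i, (rbq, abq, rc, ac) in enumerate(
        zip(
            sub["ref_baseq"].to_numpy(),
            sub["alt_baseq"].to_numpy(),
            sub_counts[np.arange(len(sub)), ref_idx],
            nonref[np.arange(len(sub)), alt_idx],
        )
    ):
        rv = split_vector(str(rbq), int)
        av = split_vector(str(abq), int)
        ref_pass[i] = int((rv >= min_base_phred).sum()) if len(rv) else int(rc)
        alt_pass[i] = int((av >= min_base_phred).sum()) if len(av) else int(ac)

    minor = np.minimum(ref_pass, alt_pass)
    keep = (minor >= min_minor_count) & (alt_pass >= 1)
    out = sub.loc[keep].copy()
    out["ref_count"] = ref_pass[keep]
    out["alt_count"] = alt_pass[keep]
    cols = [
        "accession", "chrom", "pos", "ref", "alt",
        "ref_count", "alt_count", "coverage",
    ] + ATTR_COLS
    return out[cols].reset_index(drop=True)


def _empty_candidates(pileup: pd.DataFrame) -> pd.DataFrame:
    cols = [
        "accession", "chrom", "pos", "ref", "alt",
        "ref_count", "alt_count", "coverage",
    ] + ATTR_COLS
    return pd.DataFrame(columns=cols)


# ---------------------------------------------------------------------------
# Position-based filters


def remove_germline(candidates: pd.DataFrame, germline: pd.DataFrame) -> pd.DataFrame:
    """Flag candidates at annotated germline variant positions.

    Matching is by position only (any alternate allele); ``germline`` is a
    table with 0-based chrom/pos columns, e.g. from
    :func:`somarna.io.read_vcf_positions`.
    """
    positions = set(zip(germline["chrom"], germline["pos"].astype(int)))
    mask = [
        (c, int(p)) in positions
        for c, p in zip(candidates["chrom"], candidates["pos"])
    ]
    add_flag(candidates, "germline", mask)
    return candidates


def region_mask_filter(
    candidates: pd.DataFrame, bed: pd.DataFrame, flag_name: str
) -> pd.DataFrame:
    """Flag candidates inside BED intervals (0-based half-open)."""
    mask = np.zeros(len(candidates), dtype=bool)
    for chrom, sub in bed.groupby("chrom"):
        sel = (candidates["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        ivals = list(zip(sub["start"].astype(int), sub["end"].astype(int)))
        mask[sel] = positions_in_intervals(
            candidates.loc[sel, "pos"].to_numpy(), ivals
        )
    add_flag(candidates, flag_name, mask)
    return candidates


def splice_junction_filter(
    candidates: pd.DataFrame,
    exon_ends: dict[str, np.ndarray],
    min_distance: int = 7,
) -> pd.DataFrame:
    """Flag candidates closer than ``min_distance`` bases to an exon end.

    ``exon_ends`` maps chromosome to sorted terminal exonic base positions;
    distance is ``|pos - end|``, so a candidate at the terminal base itself
    is at distance 0.
    """
    mask = np.zeros(len(candidates), dtype=bool)
    for chrom, ends in exon_ends.items():
        sel = (candidates["chrom"] == chrom).to_numpy()
        if not sel.any() or len(ends) == 0:
            continue
        pos = candidates.loc[sel, "pos"].to_numpy()
        idx = np.searchsorted(ends, pos)
        dist = np.full(pos.shape, np.iinfo(np.int64).max)
        ok = idx < len(ends)
        dist[ok] = np.abs(ends[idx[ok]] - pos[ok])
        okl = idx > 0
        dist[okl] = np.minimum(dist[okl], np.abs(pos[okl] - ends[idx[okl] - 1]))
        mask[sel] = dist < min_distance
    add_flag(candidates, "splice_junction", mask)
    return candidates


def polynucleotide_filter(
    candidates: pd.DataFrame,
    reference: dict[str, str],
    run_length: int = 7,
    window: int = 20,
) -> pd.DataFrame:
    """Flag candidates within ``window`` bases of a homopolymer run.

    A run is a maximal stretch of at least ``run_length`` identical bases;
    distance 0 means the candidate lies inside the run, and candidates at
    base-distance up to and including ``window`` are flagged.
    """
    mask = np.zeros(len(candidates), dtype=bool)
    for chrom, seq in reference.items():
        sel = (candidates["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        pos = candidates.loc[sel, "pos"].to_numpy()
        if (pos < 0).any() or (pos >= len(seq)).any():
            raise ValueError(f"candidate position outside reference {chrom}")
        widened = merge_intervals(
            [(max(0, s - window), e + window) for s, e in find_runs(seq, run_length)]
        )
        mask[sel] = positions_in_intervals(pos, widened)
    missing = ~candidates["chrom"].isin(reference.keys())
    if missing.any():
        raise ValueError("candidate chromosome missing from reference")
    add_flag(candidates, "polynucleotide", mask)
    return candidates


def unambiguous_region_filter(
    candidates: pd.DataFrame, annotation: GenomeAnnotation
) -> pd.DataFrame:
    """Flag candidates outside unambiguous UTR/exonic intervals."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for gene in annotation.genes:
        for r in gene.regions:
            if r.unambiguous:
                by_chrom.setdefault(gene.chrom, []).append((r.start, r.end))
    mask = np.ones(len(candidates), dtype=bool)
    for chrom, ivals in by_chrom.items():
        sel = (candidates["chrom"] == chrom).to_numpy()
        if sel.any():
            inside = positions_in_intervals(candidates.loc[sel, "pos"].to_numpy(), ivals)
            mask[sel] = ~inside
    add_flag(candidates, "ambiguous_region", mask)
    return candidates


# ---------------------------------------------------------------------------
# Binomial filters


def sequencing_error_prob(alt_count, coverage, p_err: float = 0.001):
    """Upper-tail binomial probability P(X >= alt_count | n=coverage, p_err)."""
    alt_count = np.asarray(alt_count)
    coverage = np.asarray(coverage)
    if (coverage <= 0).any():
        raise ValueError("coverage must be positive")
    return stats.binom.sf(alt_count - 1, coverage, p_err)


def sequencing_error_filter(
    candidates: pd.DataFrame, p_err: float = 0.001, alpha: float = 1e-4
) -> pd.DataFrame:
    """Flag candidates explainable as sequencing error.

    Flagged iff the inclusive upper tail P(X >= k | n, p_err) is at least
    ``alpha``: too probable under pure sequencing error at the Phred-30
    error rate.  ``n`` is the site coverage, ``k`` the alternate count.
    """
    tail = sequencing_error_prob(
        candidates["alt_count"], candidates["coverage"], p_err
    )
    add_flag(candidates, "seq_error", tail >= alpha)
    return candidates


def vaf_lower_tail(alt_count, total):
    """Lower-tail binomial probability P(K <= k | n, 0.5)."""
    return stats.binom.cdf(np.asarray(alt_count), np.asarray(total), 0.5)


def vaf_filter(candidates: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Flag candidates whose allele counts are consistent with VAF >= 0.5.

    Flagged iff P(K <= k | n=ref+alt, p=0.5) > ``alpha`` — the data cannot
    rule out a true variant allele frequency of one half or more, the
    signature of a missed germline heterozygote.
    """
    n = candidates["ref_count"].to_numpy() + candidates["alt_count"].to_numpy()
    tail = vaf_lower_tail(candidates["alt_count"].to_numpy(), n)
    add_flag(candidates, "vaf", tail > alpha)
    return candidates


# ---------------------------------------------------------------------------
# Read-attribute bias tests


def _mannwhitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney p; exact for small tie-free groups.

    Degenerate inputs (all values identical) carry no evidence of bias and
    return p = 1.
    """
    if len(x) == 0 or len(y) == 0:
        return math.nan
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return 1.0
    ties = len(np.unique(combined)) < len(combined)
    if len(x) <= 8 and len(y) <= 8 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def _mean_pairwise_distance(values: np.ndarray, pool: np.ndarray) -> np.ndarray:
    """Per-read mean absolute distance to all *other* reads at the site.

    Distances are taken against the pooled read set (ref and alt) so that
    under the null hypothesis the per-read values are exchangeable between
    groups and the rank test keeps its nominal level; within-group
    distances would make the values mutually dependent and the test
    badly anti-conservative.
    """
    diff = np.abs(values[:, None] - pool[None, :])
    return (diff.sum(axis=1) - 0.0) / (len(pool) - 1)


BIAS_FLAGS = {
    "read_pos_bias": "read_pos",
    "map_qual_bias": "mapq",
    "base_qual_bias": "baseq",
    "strand_bias": "strand",
}


def bias_tests(candidates: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Mann-Whitney bias tests on per-read attributes, alt vs ref reads.

    Five flags: read position, mapping quality, base quality, strand
    (encoded 0/1) and variant distance (per-read mean pairwise distance of
    variant positions within reads).  A candidate is flagged when the
    two-sided p-value falls below ``alpha``.  Tests lacking reads on either
    side are skipped (not flagged) and logged.
    """
    n = len(candidates)
    flags = {name: np.zeros(n, dtype=bool) for name in BIAS_FLAGS}
    flags["var_dist_bias"] = np.zeros(n, dtype=bool)
    skipped = 0
    for i in range(n):
        row = candidates.iloc[i]
        for flag_name, attr in BIAS_FLAGS.items():
            x = split_vector(str(row[f"alt_{attr}"]), float)
            y = split_vector(str(row[f"ref_{attr}"]), float)
            p = _mannwhitney_p(x, y)
            if math.isnan(p):
                skipped += 1
                continue
            flags[flag_name][i] = p < alpha
        xa = split_vector(str(row["alt_read_pos"]), float)
        ya = split_vector(str(row["ref_read_pos"]), float)
        if len(xa) >= 2 and len(ya) >= 2:
            pool = np.concatenate([xa, ya])
            p = _mannwhitney_p(
                _mean_pairwise_distance(xa, pool),
                _mean_pairwise_distance(ya, pool),
            )
            if not math.isnan(p):
                flags["var_dist_bias"][i] = p < alpha
        else:
            skipped += 1
    if skipped:
        logger.info("bias tests skipped for %d candidate/test pairs", skipped)
    for name, mask in flags.items():
        add_flag(candidates, name, mask)
    return candidates


# ---------------------------------------------------------------------------
# Cross-accession filters (consume prior survivors only)


def recurrence_filter(
    candidates: pd.DataFrame,
    n_accessions: int,
    max_fraction: float = 0.04,
    max_accessions: int = 1,
) -> pd.DataFrame:
    """Flag loci mutated in multiple accessions among prior survivors.

    Two stages on the survivor set: ``recurrence_fraction`` when a locus is
    mutated in at least ``ceil(max_fraction * n_accessions)`` accessions,
    and ``recurrent`` when it is mutated in more than ``max_accessions``
    accessions.
    """
    surv = passing(candidates)
    key = list(zip(candidates["chrom"], candidates["pos"]))
    counts: dict[tuple, set] = {}
    for k, acc, ok in zip(key, candidates["accession"], surv):
        if ok:
            counts.setdefault(k, set()).add(acc)
    n_per_locus = np.array([len(counts.get(k, ())) for k in key])
    # recurrence is defined over >=2 accessions; the ceiling keeps the 4%
    # rule meaningful for small cohorts
    frac_threshold = max(2, math.ceil(max_fraction * n_accessions))
    add_flag(candidates, "recurrence_fraction", surv.to_numpy() & (n_per_locus >= frac_threshold))
    add_flag(candidates, "recurrent", surv.to_numpy() & (n_per_locus > max_accessions))
    return candidates


def accession_summaries(
    candidates: pd.DataFrame, pileup_depth: pd.Series
) -> pd.DataFrame:
    """Per-accession total depth and surviving mutation count.

    ``pileup_depth`` maps accession to summed coverage over all its sites.
    Every accession in ``pileup_depth`` is summarized, including those with
    zero surviving mutations.
    """
    surv = candidates.loc[passing(candidates)]
    m = surv.groupby("accession").size()
    df = pd.DataFrame({"total_depth": pileup_depth})
    df["mutation_count"] = m.reindex(df.index).fillna(0).astype(int)
    df.index.name = "accession"
    return df.reset_index()


def outlier_accession_filter(
    summaries: pd.DataFrame,
    n_groups: int = 4,
    iqr_k: float = 1.5,
) -> pd.DataFrame:
    """Flag outlier accessions by a groupwise interquartile-range rule.

    Accessions are partitioned into ``n_groups`` equal-width bins over
    total depth.  Within each bin, an accession is an outlier when its
    mutation count m_a lies outside [Q25 - k*IQR, Q75 + k*IQR] (linearly
    interpolated quartiles); an accession alone in its bin is flagged too.
    """
    if len(summaries) < 4:
        raise ValueError("outlier detection needs at least 4 accessions")
    d = summaries["total_depth"].to_numpy(dtype=float)
    m = summaries["mutation_count"].to_numpy(dtype=float)
    edges = np.linspace(d.min(), d.max(), n_groups + 1)
    group = np.clip(np.digitize(d, edges[1:-1], right=True), 0, n_groups - 1)
    outlier = np.zeros(len(summaries), dtype=bool)
    for g in range(n_groups):
        sel = group == g
        if not sel.any():
            continue
        if sel.sum() == 1:
            outlier[sel] = True  # singleton depth group
            continue
        q25, q75 = np.percentile(m[sel], [25, 75])
        iqr = q75 - q25
        lo, hi = q25 - iqr_k * iqr, q75 + iqr_k * iqr
        outlier[sel] = (m[sel] < lo) | (m[sel] > hi)
    out = summaries.copy()
    out["depth_group"] = group + 1
    out["outlier"] = outlier
    return out


def flag_outlier_candidates(
    candidates: pd.DataFrame, summaries: pd.DataFrame
) -> pd.DataFrame:
    flagged = set(summaries.loc[summaries["outlier"], "accession"])
    add_flag(candidates, "outlier_accession", candidates["accession"].isin(flagged))
    return candidates


# ---------------------------------------------------------------------------
# Cascade


def apply_filters(
    pileup: pd.DataFrame,
    germline: pd.DataFrame,
    annotation: GenomeAnnotation,
    blacklist: pd.DataFrame | None = None,
    rna_edit: pd.DataFrame | None = None,
    config=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full cascade; return (candidates with flags, filter summary).

    Order: selection, germline, masks, splice junctions, binomial filters,
    bias tests, polynucleotide, recurrence, outlier accessions, and the
    unambiguous-region restriction.  The recurrence and outlier stages see
    only candidates surviving everything upstream.
    """
    from somarna.config import RunConfig

    cfg = config or RunConfig()
    cand = select_candidate_sites(
        pileup,
        min_coverage=cfg.min_coverage,
        min_base_phred=cfg.min_base_phred,
        min_minor_count=cfg.min_minor_count,
    )
    n_selected = len(cand)
    if cand.empty:
        return cand, pd.DataFrame(columns=["filter", "flagged"])
    remove_germline(cand, germline)
    region_mask_filter(cand, blacklist if blacklist is not None else pd.DataFrame(
        columns=["chrom", "start", "end"]), "blacklist")
    region_mask_filter(cand, rna_edit if rna_edit is not None else pd.DataFrame(
        columns=["chrom", "start", "end"]), "rna_edit")
    splice_junction_filter(
        cand, annotation.exon_end_positions(), min_distance=cfg.splice_min_distance
    )
    sequencing_error_filter(cand, p_err=cfg.seq_error_p, alpha=cfg.seq_error_alpha)
    vaf_filter(cand, alpha=cfg.vaf_alpha)
    bias_tests(cand, alpha=cfg.bias_alpha)
    polynucleotide_filter(
        cand, annotation.chromosomes,
        run_length=cfg.polyrun_length, window=cfg.polyrun_window,
    )
    n_accessions = pileup["accession"].nunique()
    recurrence_filter(
        cand, n_accessions,
        max_fraction=cfg.recurrence_fraction, max_accessions=1,
    )
    depth = pileup.groupby("accession")["coverage"].sum()
    summaries = outlier_accession_filter(
        accession_summaries(cand, depth),
        n_groups=cfg.n_depth_groups, iqr_k=cfg.iqr_k,
    )
    flag_outlier_candidates(cand, summaries)
    unambiguous_region_filter(cand, annotation)
    cand["PASS"] = passing(cand)

    summary_rows = [("selected", n_selected)]
    for col in flag_columns(cand):
        summary_rows.append((col.removeprefix("flag_"), int(cand[col].sum())))
    summary_rows.append(("PASS", int(cand["PASS"].sum())))
    summary = pd.DataFrame(summary_rows, columns=["filter", "flagged"])
    for _, row in summary.iterrows():
        logger.info("filter %-20s %d", row["filter"], row["flagged"])
    return cand, summary
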