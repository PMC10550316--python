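"""Genewise model covariates and offsets.

For each gene, mutation type and strand class this module computes the
quantities entering the mutation-rate model: the base-aware effective gene
length b (the offset), the normalized transcriptional depth d*, GC content,
the log2 late/early replication-timing signal and overlap-weighted
chromatin signals.  All genewise aggregation runs over the gene's
*unambiguous* UTR/exonic intervals — the same support on which mutations
are callable — and l_g denotes their summed length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from somarna.annotation import (
    COMPLEMENT,
    Gene,
    GenomeAnnotation,
    interval_overlap,
    merge_intervals,
    positions_in_intervals,
)
from somarna.simulate import CHROMATIN_TRACKS, Tracks

logger = logging.getLogger(__name__)

MUTATION_TYPES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
STRAND_CLASSES = ["coding", "template"]


def assign_strand(ref: str, alt: str, gene_strand: str) -> tuple[str, str]:
    """Collapse a mutation to its pyrimidine type and strand class.

    Purine-reference substitutions are complemented so the reference is a
    pyrimidine; the mutation is on the *template* strand when that
    pyrimidine lies on the strand opposite the gene.
    """
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"bad alleles {ref}>{alt}")
    if ref in "CT":
        mut_type, pyr_strand = f"{ref}>{alt}", "+"
    else:
        mut_type, pyr_strand = f"{COMPLEMENT[ref]}>{COMPLEMENT[alt]}", "-"
    strand_class = "coding" if pyr_strand == gene_strand else "template"
    return mut_type, strand_class


def required_forward_base(base: str, gene_strand: str, strand_class: str) -> str:
    """Forward-strand reference base implied by (pyrimidine, strand class)."""
    if base not in ("C", "T"):
        raise ValueError(f"base must be C or T, got {base!r}")
    pyr_strand = gene_strand if strand_class == "coding" else (
        "-" if gene_strand == "+" else "+"
    )
    return base if pyr_strand == "+" else COMPLEMENT[base]


# ---------------------------------------------------------------------------
# Site-level pass summaries


def site_pass_summary(pileup: pd.DataFrame, min_coverage: int = 40) -> pd.DataFrame:
    """Per-position summary over accessions passing site-level filters.

    Returns one row per (chrom, pos) that passes in at least one accession,
    with the summed depth across passing accessions.
    """
    ok = pileup.loc[pileup["coverage"] >= min_coverage]
    agg = ok.groupby(["chrom", "pos"], sort=True)["coverage"].sum()
    return agg.rename("depth_sum").reset_index()


# ---------------------------------------------------------------------------
# Offsets


@dataclass
class GeneOffsets:
    b: int          # effective gene length (sites)
    depth_sum: int  # total depth over those sites, summed across accessions

    @property
    def d_star(self) -> float:
        return self.depth_sum / self.b if self.b else float("nan")


def gene_offsets(
    gene: Gene,
    base: str,
    strand_class: str,
    site_summary: pd.DataFrame,
    reference: dict[str, str],
) -> GeneOffsets:
    """Effective gene length and summed depth for one (gene, base, strand).

    b is the number of unambiguous UTR/exonic positions whose reference
    base, read on the strand implied by the gene strand and strand class,
    equals the required pyrimidine, and which pass site-level filters in at
    least one accession; the depth sum runs over the same positions.
    """
    fwd = required_forward_base(base, gene.strand, strand_class)
    ivals = merge_intervals(gene.intervals(unambiguous_only=True))
    if not ivals:
        return GeneOffsets(0, 0)
    sub = site_summary.loc[site_summary["chrom"] == gene.chrom]
    pos = sub["pos"].to_numpy()
    inside = positions_in_intervals(pos, ivals)
    if not inside.any():
        return GeneOffsets(0, 0)
    seq = reference[gene.chrom]
    pos_in = pos[inside]
    base_ok = np.array([seq[p] == fwd for p in pos_in])
    b = int(base_ok.sum())
    depth = int(sub["depth_sum"].to_numpy()[inside][base_ok].sum())
    return GeneOffsets(b, depth)


# ---------------------------------------------------------------------------
# Sequence and track covariates


def gc_content(gene: Gene, annotation: GenomeAnnotation) -> float:
    """(G+C) fraction over the gene's unambiguous UTR/exonic bases."""
    seq = annotation.chromosomes[gene.chrom]
    ivals = merge_intervals(gene.intervals(unambiguous_only=True))
    bases = "".join(seq[s:e] for s, e in ivals)
    if not bases:
        return float("nan")
    return (bases.count("G") + bases.count("C")) / len(bases)


def _gene_support(gene: Gene) -> tuple[list[tuple[int, int]], int]:
    ivals = merge_intervals(gene.intervals(unambiguous_only=True))
    return ivals, sum(e - s for s, e in ivals)


def replication_timing_signal(
    gene: Gene, early: pd.DataFrame, late: pd.DataFrame
) -> float:
    """log2 overlap-weighted mean of late/early replication signal ratios.

    Returns NaN when no track region overlaps the gene; early signal must
    be strictly positive wherever it overlaps.
    """
    ivals, l_g = _gene_support(gene)
    if l_g == 0:
        return float("nan")
    e_sub = early.loc[early["chrom"] == gene.chrom]
    l_sub = late.loc[late["chrom"] == gene.chrom]
    if len(e_sub) != len(l_sub) or not np.array_equal(
        e_sub[["start", "end"]].to_numpy(), l_sub[["start", "end"]].to_numpy()
    ):
        raise ValueError("early/late tracks must share region boundaries")
    total = 0.0
    any_overlap = False
    for (s, e, ev), lv in zip(
        e_sub[["start", "end", "value"]].itertuples(index=False),
        l_sub["value"],
    ):
        o = interval_overlap(int(s), int(e), ivals)
        if o == 0:
            continue
        if ev <= 0:
            raise ValueError("early replication signal must be positive")
        any_overlap = True
        total += (lv / ev) * o
    if not any_overlap:
        return float("nan")
    return float(np.log2(total / l_g))


def chromatin_signal(gene: Gene, replicate_tracks: list[pd.DataFrame]) -> float:
    """Overlap-weighted mark signal, summed across replicate files.

    Each replicate contributes sum_r s_r * o_r / l_g where s_r is the
    region signal in [0, 1] and o_r its overlap with the gene's
    unambiguous UTR/exonic intervals; NaN when no region overlaps.
    """
    if not replicate_tracks:
        raise ValueError("no replicate files for chromatin mark")
    ivals, l_g = _gene_support(gene)
    if l_g == 0:
        return float("nan")
    total = 0.0
    any_overlap = False
    for track in replicate_tracks:
        sub = track.loc[track["chrom"] == gene.chrom]
        for s, e, v in sub[["start", "end", "value"]].itertuples(index=False):
            o = interval_overlap(int(s), int(e), ivals)
            if o:
                any_overlap = True
                total += v * o
    if not any_overlap:
        return float("nan")
    return total / l_g


def gene_covariates(annotation: GenomeAnnotation, tracks: Tracks) -> pd.DataFrame:
    """One row per gene: gc_content, replication_timing and chromatin marks."""
    rows = []
    for gene in annotation.genes:
        row = {"gene_id": gene.gene_id, "gc_content": gc_content(gene, annotation)}
        row["replication_timing"] = replication_timing_signal(
            gene, tracks.rt_early, tracks.rt_late
        )
        for mark in CHROMATIN_TRACKS:
            row[mark] = chromatin_signal(gene, tracks.chromatin[mark])
        rows.append(row)
    return pd.DataFrame(rows)


COVARIATE_COLS = ["gc_content", "replication_timing"] + CHROMATIN_TRACKS


# ---------------------------------------------------------------------------
# Model table


def standardize(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    """Scale columns to zero mean and unit (population) variance in place."""
    for c in cols:
        v = df[c].to_numpy(dtype=float)
        sd = v.std()
        df[c] = (v - v.mean()) / sd if sd > 0 else 0.0
    return df


def assign_mutations_to_genes(
    mutations: pd.DataFrame, annotation: GenomeAnnotation
) -> pd.DataFrame:
    """Attach gene_id, mutation_type and strand_class to PASS mutations.

    Mutations outside every unambiguous interval are dropped (they cannot
    be attributed to a single gene).
    """
    rows = []
    for gene in annotation.genes:
        ivals = merge_intervals(gene.intervals(unambiguous_only=True))
        if not ivals:
            continue
        sel = mutations["chrom"] == gene.chrom
        if not sel.any():
            continue
        sub = mutations.loc[sel]
        inside = positions_in_intervals(sub["pos"].to_numpy(), ivals)
        for _, mrow in sub.loc[inside].iterrows():
            mut_type, strand_class = assign_strand(
                mrow["ref"], mrow["alt"], gene.strand
            )
            rows.append(
                {
                    "accession": mrow["accession"],
                    "chrom": mrow["chrom"],
                    "pos": mrow["pos"],
                    "ref": mrow["ref"],
                    "alt": mrow["alt"],
                    "gene_id": gene.gene_id,
                    "mutation_type": mut_type,
                    "strand_class": strand_class,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "accession", "chrom", "pos", "ref", "alt",
            "gene_id", "mutation_type", "strand_class",
        ],
    )


def build_feature_table(
    mutations: pd.DataFrame,
    annotation: GenomeAnnotation,
    tracks: Tracks,
    pileup: pd.DataFrame,
    min_coverage: int = 40,
) -> dict[str, pd.DataFrame]:
    """Assemble one modeling table per mutation type.

    Each table has one row per (gene, strand class) with the mutation
    count m, effective gene length b, normalized depth d_star and the
    standardized covariate columns.  Rows with b = 0 and genes lacking
    track coverage are excluded; standardization happens per table after
    those exclusions.
    """
    site_summary = site_pass_summary(pileup, min_coverage=min_coverage)
    covs = gene_covariates(annotation, tracks).set_index("gene_id")
    assigned = assign_mutations_to_genes(mutations, annotation)
    out: dict[str, pd.DataFrame] = {}
    for mut_type in MUTATION_TYPES:
        base = mut_type[0]
        m_counts = (
            assigned.loc[assigned["mutation_type"] == mut_type]
            .groupby(["gene_id", "strand_class"])
            .size()
        )
        rows = []
        for gene in annotation.genes:
            if gene.gene_id not in covs.index:
                continue
            crow = covs.loc[gene.gene_id]
            if crow[COVARIATE_COLS].isna().any():
                continue  # missing track coverage: gene excluded
            for strand_class in STRAND_CLASSES:
                off = gene_offsets(
                    gene, base, strand_class, site_summary, annotation.chromosomes
                )
                if off.b == 0:
                    continue
                rows.append(
                    {
                        "gene_id": gene.gene_id,
                        "strand_class": strand_class,
                        "m": int(m_counts.get((gene.gene_id, strand_class), 0)),
                        "b": off.b,
                        "d_star": off.d_star,
                        **{c: crow[c] for c in COVARIATE_COLS},
                    }
                )
        table = pd.DataFrame(rows)
        if not table.empty:
            table = standardize(table, COVARIATE_COLS)
        out[mut_type] = table
    return out
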