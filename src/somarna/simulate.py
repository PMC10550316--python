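"""Synthetic genomes, signal tracks and multi-accession pileups.

Everything the somatic-mutation pipeline consumes can be generated here:
a small multi-gene genome with strand-annotated UTR/exon structure, a
germline VCF, mask BEDs, replication-timing and chromatin bedGraph tracks
with configurable correlation structure, and per-accession pileup-level
site observations carrying per-read attributes.

Planted truths fall into one class of true somatic mutation plus six
artifact classes mirroring what the filter cascade is built to remove:
germline variants missing from the VCF (``germline_leak``), errors next to
homopolymer runs (``polynucleotide``), splice-edge mapping errors
(``splice_edge``), high-VAF variants (``high_vaf``), variants whose
supporting reads have biased attributes (``read_bias``) and accessions with
an inflated mutation rate (``outlier_accession``).

Randomness derives from one master seed; every sub-generator draws from an
independent stream labeled by purpose, so regenerating one output does not
perturb the others.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from somarna.annotation import (
    COMPLEMENT,
    Gene,
    GenomeAnnotation,
    Region,
    merge_intervals,
    positions_in_intervals,
)
from somarna.io import join_vector

BASES = np.array(["A", "C", "G", "T"])

HISTONE_MARKS = [
    "H3K4me1", "H3K4me2", "H3K4me3", "H3K9ac", "H3K9me1", "H3K9me2",
    "H3K14ac", "H3K23ac", "H3K27ac", "H3K27me1", "H3K27me3", "H3K36ac",
    "H3K36me3", "H3K56ac", "H4K16ac",
]
CHROMATIN_TRACKS = ["dna_accessibility", "dna_methylation"] + HISTONE_MARKS
ALL_TRACKS = ["replication_timing"] + CHROMATIN_TRACKS

_PURPOSE = {
    "genome": 1,
    "tracks": 2,
    "pileup": 3,
    "masks": 4,
    "truth": 5,
}


def stream(seed: int, purpose: str) -> np.random.Generator:
    """Independent RNG stream for one generator purpose under a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_PURPOSE[purpose],))
    )


class PackingError(ValueError):
    """Requested genes do not fit on the requested chromosomes."""


def find_runs(seq: str, min_len: int = 7) -> list[tuple[int, int]]:
    """Maximal homopolymer runs of at least ``min_len``, 0-based half-open."""
    return [
        (m.start(), m.end())
        for m in re.finditer(r"(.)\1{%d,}" % (min_len - 1), seq)
    ]


# ---------------------------------------------------------------------------
# Genome


@dataclass
class LengthParams:
    """Gene-structure length distribution (all in bases)."""

    utr_len_mean: float = 60.0
    exon_len_mean: float = 150.0
    n_exons_mean: float = 1.5
    intron_len_mean: float = 90.0
    intergenic_mean: float = 250.0
    overlap_rate: float = 0.1
    chrom_length: int | None = None  # fixed length; error if packing fails


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p)


def simulate_genome(
    n_chrom: int = 2,
    n_genes: int = 20,
    length_params: LengthParams | None = None,
    gc_target: float = 0.42,
    polyrun_rate: float = 0.0008,
    seed: int = 0,
) -> GenomeAnnotation:
    """Generate a random annotated genome.

    Genes are laid out left to right with intergenic gaps; a fraction
    (``overlap_rate``) is placed overlapping its predecessor on the opposite
    strand so that ambiguous UTR/exonic intervals exist (when
    ``overlap_rate > 0`` at least one overlapping pair is guaranteed).
    Homopolymer runs of at least seven bases are planted at ``polyrun_rate``
    per base, emulating the poly(A)/poly(T) tracts that generate artifacts
    in real libraries.
    """
    if n_chrom < 1 or n_genes < 1:
        raise ValueError("n_chrom and n_genes must be positive")
    if not 0 < gc_target < 1:
        raise ValueError("gc_target must be in (0, 1)")
    lp = length_params or LengthParams()
    rng = stream(seed, "genome")

    genes: list[Gene] = []
    cursors = [0] * n_chrom
    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    prev_gene_on_chrom: list[Gene | None] = [None] * n_chrom

    for gi in range(n_genes):
        ci = gi % n_chrom
        # gene structure: UTR, exons, UTR separated by introns
        n_exons = 1 + rng.poisson(max(lp.n_exons_mean - 1.0, 0.0))
        block_lens = [max(20, int(rng.gamma(4.0, lp.utr_len_mean / 4.0)))]
        block_lens += [
            max(40, int(rng.gamma(4.0, lp.exon_len_mean / 4.0)))
            for _ in range(n_exons)
        ]
        block_lens.append(max(20, int(rng.gamma(4.0, lp.utr_len_mean / 4.0))))
        intron_lens = [
            max(30, int(rng.gamma(4.0, lp.intron_len_mean / 4.0)))
            for _ in range(len(block_lens) - 1)
        ]

        force_overlap = gi == n_chrom and lp.overlap_rate > 0  # second gene on chr1
        overlap = force_overlap or (
            prev_gene_on_chrom[ci] is not None and rng.random() < lp.overlap_rate
        )
        if overlap and prev_gene_on_chrom[ci] is not None:
            prev = prev_gene_on_chrom[ci]
            depth = int(rng.integers(20, 1 + min(100, len(prev.regions[-1]))))
            start = max(0, prev.end - depth)
        else:
            gap = max(50, int(rng.gamma(4.0, lp.intergenic_mean / 4.0)))
            start = cursors[ci] + gap

        labels = ["UTR"] + ["exon"] * n_exons + ["UTR"]
        regions = []
        pos = start
        for bi, (blen, label) in enumerate(zip(block_lens, labels)):
            regions.append(Region(start=pos, end=pos + blen, label=label))
            pos += blen
            if bi < len(intron_lens):
                pos += intron_lens[bi]
        if gi == 0:
            strand = "+"
        elif gi == n_chrom:
            strand = "-"
        else:
            strand = "+" if rng.random() < 0.5 else "-"
        gene = Gene(
            gene_id=f"gene{gi + 1:03d}",
            chrom=chrom_names[ci],
            strand=strand,
            regions=regions,
        )
        genes.append(gene)
        prev_gene_on_chrom[ci] = gene
        cursors[ci] = max(cursors[ci], gene.end)

    chromosomes: dict[str, str] = {}
    for ci, name in enumerate(chrom_names):
        length = cursors[ci] + 200
        if lp.chrom_length is not None:
            if cursors[ci] > lp.chrom_length:
                raise PackingError(
                    f"{name}: genes need {cursors[ci]} bp but chrom_length is "
                    f"{lp.chrom_length}"
                )
            length = lp.chrom_length
        seq = _random_sequence(rng, length, gc_target)
        # plant homopolymer runs
        n_runs = rng.poisson(polyrun_rate * length)
        for _ in range(n_runs):
            run_len = 7 + rng.geometric(0.5) - 1
            start = int(rng.integers(0, max(1, length - run_len)))
            seq[start:start + run_len] = rng.choice(BASES)
        chromosomes[name] = "".join(seq)

    ann = GenomeAnnotation(chromosomes=chromosomes, genes=genes)
    ann.validate()
    ann.annotate_ambiguity()
    return ann


# ---------------------------------------------------------------------------
# Tracks


@dataclass
class CovariateSpec:
    """Per-track means/variances and the cross-track correlation matrix.

    Chromatin tracks (accessibility, methylation, histone marks) are
    clipped Gaussians on [0, 1]; replication timing is parameterized by the
    latent log2 late/early ratio.  ``correlation`` is over the latent
    Gaussians in the order of :data:`ALL_TRACKS`.
    """

    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    correlation: np.ndarray | None = None
    region_len_range: tuple[int, int] = (200, 600)
    replicates: dict[str, int] = field(default_factory=dict)
    n_blacklist: int = 4
    blacklist_len_range: tuple[int, int] = (100, 300)
    n_rna_edit: int = 20

    def mean(self, track: str) -> float:
        return self.means.get(track, 0.0 if track == "replication_timing" else 0.4)

    def sd(self, track: str) -> float:
        return self.sds.get(track, 0.7 if track == "replication_timing" else 0.15)

    def corr_matrix(self) -> np.ndarray:
        k = len(ALL_TRACKS)
        if self.correlation is None:
            corr = np.eye(k)
            # positive H3K4me1/H3K36me3 correlation, as seen in real chromatin
            i = ALL_TRACKS.index("H3K4me1")
            j = ALL_TRACKS.index("H3K36me3")
            corr[i, j] = corr[j, i] = 0.6
            return corr
        corr = np.asarray(self.correlation, dtype=float)
        if corr.shape != (k, k):
            raise ValueError(f"correlation must be {k}x{k} over {ALL_TRACKS}")
        return corr


@dataclass
class Tracks:
    """Generated signal tracks and masks, bedGraph-shaped DataFrames."""

    rt_early: pd.DataFrame
    rt_late: pd.DataFrame
    chromatin: dict[str, list[pd.DataFrame]]  # track -> one DF per replicate
    blacklist: pd.DataFrame
    rna_edit: pd.DataFrame


def simulate_tracks(
    annotation: GenomeAnnotation,
    covariate_spec: CovariateSpec | None = None,
    seed: int = 0,
) -> Tracks:
    """Generate replication-timing, chromatin and mask tracks.

    Region signals are drawn from a multivariate Gaussian across tracks so
    that genewise aggregated covariates realize the requested correlation
    structure (up to clipping at [0, 1] and sampling noise).
    """
    spec = covariate_spec or CovariateSpec()
    corr = spec.corr_matrix()
    if not np.allclose(corr, corr.T):
        raise ValueError("correlation matrix must be symmetric")
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is not positive definite") from exc
    rng = stream(seed, "tracks")

    regions = []  # (chrom, start, end)
    lo, hi = spec.region_len_range
    for chrom, seq in annotation.chromosomes.items():
        pos = 0
        while pos < len(seq):
            end = min(len(seq), pos + int(rng.integers(lo, hi)))
            regions.append((chrom, pos, end))
            pos = end
    n = len(regions)
    z = rng.standard_normal((n, len(ALL_TRACKS))) @ chol.T

    rdf = pd.DataFrame(regions, columns=["chrom", "start", "end"])
    rt_idx = ALL_TRACKS.index("replication_timing")
    log2_ratio = spec.mean("replication_timing") + spec.sd("replication_timing") * z[:, rt_idx]
    early = rng.uniform(5.0, 15.0, size=n)
    late = early * np.exp2(log2_ratio)
    rt_early = rdf.assign(value=early)
    rt_late = rdf.assign(value=late)

    chromatin: dict[str, list[pd.DataFrame]] = {}
    for ti, track in enumerate(ALL_TRACKS):
        if track == "replication_timing":
            continue
        base = np.clip(spec.mean(track) + spec.sd(track) * z[:, ti], 0.0, 1.0)
        reps = []
        for _ in range(spec.replicates.get(track, 1)):
            jitter = rng.normal(0.0, 0.01, size=n)
            reps.append(rdf.assign(value=np.clip(base + jitter, 0.0, 1.0)))
        chromatin[track] = reps

    mrng = stream(seed, "masks")
    bl_rows = []
    for chrom, seq in annotation.chromosomes.items():
        for _ in range(spec.n_blacklist):
            blen = int(mrng.integers(*spec.blacklist_len_range))
            start = int(mrng.integers(0, max(1, len(seq) - blen)))
            bl_rows.append((chrom, start, start + blen))
    blacklist = pd.DataFrame(bl_rows, columns=["chrom", "start", "end"])

    # RNA edits sit inside transcribed regions
    exonic = _exonic_positions(annotation)
    er_rows = []
    if len(exonic) and spec.n_rna_edit:
        pick = mrng.choice(len(exonic), size=min(spec.n_rna_edit, len(exonic)), replace=False)
        for i in pick:
            chrom, pos = exonic[i]
            er_rows.append((chrom, int(pos), int(pos) + 1))
    rna_edit = pd.DataFrame(er_rows, columns=["chrom", "start", "end"])

    return Tracks(
        rt_early=rt_early,
        rt_late=rt_late,
        chromatin=chromatin,
        blacklist=blacklist,
        rna_edit=rna_edit,
    )


def _exonic_positions(annotation: GenomeAnnotation) -> list[tuple[str, int]]:
    out = []
    for chrom in annotation.chromosomes:
        ivals = merge_intervals(
            [
                (r.start, r.end)
                for g in annotation.genes
                if g.chrom == chrom
                for r in g.regions
            ]
        )
        for s, e in ivals:
            out.extend((chrom, p) for p in range(s, e))
    return out


# ---------------------------------------------------------------------------
# Pileup


@dataclass
class TruthSpec:
    """How many records of each truth class to plant, and their parameters.

    The default mutation load (``n_true_somatic`` over the default 50
    accessions) is about ten private mutations per accession, matching the
    per-accession load realized in large multi-accession RNA-seq studies;
    much sparser loads make the groupwise IQR outlier rule erratic because
    the per-accession counts become too discrete for stable quartiles.
    """

    n_true_somatic: int = 500
    true_vaf: float = 0.25
    n_germline_leak: int = 30
    leak_extra_accessions_mean: float = 2.0
    n_polynucleotide: int = 20
    n_splice_edge: int = 15
    n_high_vaf: int = 20
    high_vaf: float = 0.9
    n_read_bias: int = 20
    n_outlier_accessions: int = 1
    outlier_multiplier: float = 10.0
    n_annotated_germline: int = 30
    germline_carrier_frac: float = 0.5
    artifact_vaf: float = 0.3


@dataclass
class DepthParams:
    mean_coverage: float = 60.0
    nb_dispersion: float = 8.0
    accession_depth_sd: float = 0.2  # lognormal sigma on per-accession depth
    gene_expression_sd: float = 0.3  # lognormal sigma per accession x gene
    min_planted_coverage: int = 45   # planted records sit at detectable sites


@dataclass
class ErrorParams:
    base_error_rate: float = 0.001  # matches a Phred-30 error probability
    read_length: int = 95
    baseq_mean: float = 36.0
    baseq_sd: float = 2.0
    mapq: int = 60
    bias_mapq_shift: int = 20
    bias_read_pos_max: int = 15


@dataclass
class SimulationTruth:
    """Planted records with their class, plus the generator's parameters."""

    records: pd.DataFrame  # accession, chrom, pos, ref, alt, artifact_class
    generator_params: dict
    seed: int


@dataclass
class PileupResult:
    pileup: pd.DataFrame
    truth: SimulationTruth
    germline: pd.DataFrame  # chrom, pos, ref, alt for the emitted VCF
    accessions: list[str]


def _cond_binomial(
    rng: np.random.Generator, n: np.ndarray, p: float, minimum: int
) -> np.ndarray:
    """Binomial draws conditioned to be at least ``minimum``."""
    k = rng.binomial(n, p)
    for _ in range(1000):
        low = k < minimum
        if not low.any():
            break
        k[low] = rng.binomial(n[low], p)
    k[k < minimum] = minimum
    return k


def _cond_coverage(
    rng: np.random.Generator, dp: DepthParams, size: int
) -> np.ndarray:
    """Coverage for planted sites, conditioned at or above the detectable floor."""
    nbp = dp.nb_dispersion / (dp.nb_dispersion + dp.mean_coverage)
    cov = rng.negative_binomial(dp.nb_dispersion, nbp, size=size)
    for _ in range(1000):
        low = cov < dp.min_planted_coverage
        if not low.any():
            break
        cov[low] = rng.negative_binomial(dp.nb_dispersion, nbp, size=int(low.sum()))
    cov[cov < dp.min_planted_coverage] = dp.min_planted_coverage
    return cov


def plantable_positions(
    annotation: GenomeAnnotation,
    min_boundary_distance: int = 7,
    run_min_len: int = 7,
    run_window: int = 20,
    avoid_intervals: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Positions where a planted somatic mutation is detectable in principle.

    Restricted to unambiguous UTR/exonic bases at least
    ``min_boundary_distance`` bases from every interval boundary, more than
    ``run_window`` bases from any homopolymer run of ``run_min_len`` or
    longer, and outside ``avoid_intervals`` (e.g. the mask BEDs).
    """
    rows = []
    for chrom, seq in annotation.chromosomes.items():
        ivals = []
        for g in annotation.genes:
            if g.chrom != chrom:
                continue
            for r in g.regions:
                if r.unambiguous:
                    ivals.append((r.start, r.end))
        if not ivals:
            continue
        pos_list = []
        for s, e in merge_intervals(ivals):
            s2, e2 = s + min_boundary_distance, e - min_boundary_distance
            if e2 > s2:
                pos_list.append(np.arange(s2, e2))
        if not pos_list:
            continue
        pos = np.concatenate(pos_list)
        # boundary distance against *all* interval boundaries of this chrom
        bounds = np.array(
            sorted(
                {b for g in annotation.genes if g.chrom == chrom
                 for r in g.regions for b in (r.start, r.end - 1)}
            )
        )
        idx = np.searchsorted(bounds, pos)
        dist = np.full(pos.shape, np.iinfo(np.int64).max)
        ok = idx < len(bounds)
        dist[ok] = np.abs(bounds[idx[ok]] - pos[ok])
        okl = idx > 0
        dist[okl] = np.minimum(dist[okl], np.abs(pos[okl] - bounds[idx[okl] - 1]))
        pos = pos[dist >= min_boundary_distance]
        # away from homopolymer runs
        runs = find_runs(seq, run_min_len)
        widened = merge_intervals(
            [(max(0, s - run_window), e + run_window) for s, e in runs]
        )
        pos = pos[~positions_in_intervals(pos, widened)]
        if avoid_intervals is not None and len(avoid_intervals):
            sub = avoid_intervals[avoid_intervals["chrom"] == chrom]
            ivs = list(zip(sub["start"].astype(int), sub["end"].astype(int)))
            pos = pos[~positions_in_intervals(pos, ivs)]
        for p in pos:
            rows.append((chrom, int(p)))
    return pd.DataFrame(rows, columns=["chrom", "pos"])


def simulate_pileup(
    annotation: GenomeAnnotation,
    truth_spec: TruthSpec | None = None,
    n_accessions: int = 50,
    depth_params: DepthParams | None = None,
    error_params: ErrorParams | None = None,
    seed: int = 0,
    avoid_intervals: pd.DataFrame | None = None,
) -> PileupResult:
    """Emit per-accession site observations with planted truths.

    The background is sequencing noise only: per-site error reads at
    ``base_error_rate``, almost never reaching the candidate-selection
    minor-allele threshold.  Planted records overwrite the background at
    their (accession, position); true somatic mutations are private to one
    accession with sub-0.5 VAF while germline leaks recur across accessions
    at VAF about 0.5.
    """
    if n_accessions < 2:
        raise ValueError("need at least 2 accessions")
    ts = truth_spec or TruthSpec()
    dp = depth_params or DepthParams()
    ep = error_params or ErrorParams()
    rng = stream(seed, "pileup")
    trng = stream(seed, "truth")

    accessions = [f"acc{i + 1:03d}" for i in range(n_accessions)]

    # --- site grid: all UTR/exonic positions, every gene ------------------
    chrom_list, pos_list, gene_idx_list = [], [], []
    for gi, gene in enumerate(annotation.genes):
        for s, e in merge_intervals([(r.start, r.end) for r in gene.regions]):
            p = np.arange(s, e)
            chrom_list.append(np.full(p.shape, gene.chrom, dtype=object))
            pos_list.append(p)
            gene_idx_list.append(np.full(p.shape, gi))
    chroms = np.concatenate(chrom_list)
    positions = np.concatenate(pos_list)
    gene_idx = np.concatenate(gene_idx_list)
    # overlapping genes can list a position twice; keep the first
    key = pd.MultiIndex.from_arrays([chroms, positions])
    keep = ~key.duplicated()
    chroms, positions, gene_idx = chroms[keep], positions[keep], gene_idx[keep]
    n_pos = len(positions)
    ref = np.array(
        [annotation.chromosomes[c][p] for c, p in zip(chroms, positions)]
    )
    ref_code = np.searchsorted(BASES, ref)

    # --- coverage ---------------------------------------------------------
    acc_mult = np.exp(rng.normal(0.0, dp.accession_depth_sd, size=n_accessions))
    gene_mult = np.exp(
        rng.normal(0.0, dp.gene_expression_sd, size=(n_accessions, len(annotation.genes)))
    )
    acc_idx = np.repeat(np.arange(n_accessions), n_pos)
    site_idx = np.tile(np.arange(n_pos), n_accessions)
    mu = dp.mean_coverage * acc_mult[acc_idx] * gene_mult[acc_idx, gene_idx[site_idx]]
    nbp = dp.nb_dispersion / (dp.nb_dispersion + mu)
    cov = rng.negative_binomial(dp.nb_dispersion, nbp)

    # --- background errors ------------------------------------------------
    err = rng.binomial(cov, ep.base_error_rate)
    err_base = np.full(len(cov), -1, dtype=np.int8)
    has_err = err > 0
    # error reads at one site all share one (random, non-reference) base
    shift = rng.integers(1, 4, size=int(has_err.sum()))
    err_base[has_err] = (ref_code[site_idx[has_err]] + shift) % 4

    counts = np.zeros((len(cov), 4), dtype=np.int32)
    counts[np.arange(len(cov)), ref_code[site_idx]] = cov - err
    counts[has_err, err_base[has_err]] += err[has_err]

    # --- planted truths ---------------------------------------------------
    plantable = plantable_positions(annotation, avoid_intervals=avoid_intervals)
    site_lookup = {
        (c, int(p)): i for i, (c, p) in enumerate(zip(chroms, positions))
    }
    plantable = plantable[
        [(c, int(p)) in site_lookup for c, p in zip(plantable["chrom"], plantable["pos"])]
    ].reset_index(drop=True)
    pool = trng.permutation(len(plantable))
    pool_iter = iter(pool)

    def take_positions(k: int) -> list[tuple[str, int]]:
        out = []
        for _ in range(k):
            try:
                i = next(pool_iter)
            except StopIteration:
                break
            out.append((plantable["chrom"].iat[i], int(plantable["pos"].iat[i])))
        return out

    truth_rows = []  # accession_idx, chrom, pos, alt_code, class, vaf-kind
    biased = []      # parallel flag: biased read attributes

    def plant(acc: int, chrom: str, pos: int, alt_code: int, alt_count: int,
              coverage: int, cls: str, bias: bool = False) -> None:
        row = acc * n_pos + site_lookup[(chrom, pos)]
        counts[row, :] = 0
        rc = ref_code[site_lookup[(chrom, pos)]]
        counts[row, rc] = coverage - alt_count
        counts[row, alt_code] = alt_count
        cov[row] = coverage
        truth_rows.append(
            (accessions[acc], chrom, pos, BASES[rc], BASES[alt_code], cls)
        )
        biased.append((row, bias))

    def random_alt(rc: int) -> int:
        return int((rc + trng.integers(1, 4)) % 4)

    # outlier accessions first so their extra load is known
    outlier_accs = list(
        trng.choice(n_accessions, size=ts.n_outlier_accessions, replace=False)
    ) if ts.n_outlier_accessions else []

    def plant_private(n: int, vaf: float, cls: str, accs: list[int] | None = None,
                      bias: bool = False) -> None:
        sites = take_positions(n)
        if not sites:
            return
        covs = _cond_coverage(trng, dp, len(sites))
        alts = _cond_binomial(trng, covs, vaf, 6)
        for (chrom, pos), c, a in zip(sites, covs, alts):
            acc = int(trng.choice(accs)) if accs else int(trng.integers(n_accessions))
            rc = ref_code[site_lookup[(chrom, pos)]]
            plant(acc, chrom, pos, random_alt(rc), int(a), int(c), cls, bias)

    plant_private(ts.n_true_somatic, ts.true_vaf, "true_somatic")
    plant_private(ts.n_high_vaf, ts.high_vaf, "high_vaf")
    plant_private(ts.n_read_bias, ts.true_vaf, "read_bias", bias=True)
    if outlier_accs:
        extra = int(round(ts.outlier_multiplier * ts.n_true_somatic / n_accessions))
        for acc in outlier_accs:
            plant_private(extra, ts.true_vaf, "outlier_accession", accs=[acc])

    # germline leaks: recurrent across >=2 accessions at VAF ~ 0.5
    for chrom, pos in take_positions(ts.n_germline_leak):
        k = 2 + int(trng.poisson(ts.leak_extra_accessions_mean))
        k = min(k, n_accessions)
        accs = trng.choice(n_accessions, size=k, replace=False)
        rc = ref_code[site_lookup[(chrom, pos)]]
        alt_code = random_alt(rc)
        covs = _cond_coverage(trng, dp, k)
        alts = trng.binomial(covs, 0.5)
        for acc, c, a in zip(accs, covs, alts):
            plant(int(acc), chrom, pos, alt_code, int(a), int(c), "germline_leak")

    # splice-edge errors: within 7 bp of a region boundary
    edge_pos = []
    for gene in annotation.genes:
        for r in gene.regions:
            if not r.unambiguous:
                continue
            for p in (r.start, r.start + 3, r.end - 4, r.end - 1):
                if (gene.chrom, int(p)) in site_lookup:
                    edge_pos.append((gene.chrom, int(p)))
    edge_pos = list(dict.fromkeys(edge_pos))
    trng.shuffle(edge_pos)
    used = {(c, p) for _, c, p, _, _, _ in truth_rows}
    edge_pos = [cp for cp in edge_pos if cp not in used][: ts.n_splice_edge]
    if edge_pos:
        covs = _cond_coverage(trng, dp, len(edge_pos))
        alts = _cond_binomial(trng, covs, ts.artifact_vaf, 6)
        for (chrom, pos), c, a in zip(edge_pos, covs, alts):
            acc = int(trng.integers(n_accessions))
            rc = ref_code[site_lookup[(chrom, pos)]]
            plant(acc, chrom, pos, random_alt(rc), int(a), int(c), "splice_edge")

    # polynucleotide-adjacent errors: within 20 bp of a homopolymer run
    used = {(c, p) for _, c, p, _, _, _ in truth_rows}
    poly_pos = []
    for chrom, seq in annotation.chromosomes.items():
        widened = merge_intervals(
            [(max(0, s - 20), e + 20) for s, e in find_runs(seq, 7)]
        )
        for s, e in widened:
            for p in range(s, e):
                if (chrom, p) in site_lookup and (chrom, p) not in used:
                    poly_pos.append((chrom, p))
    trng.shuffle(poly_pos)
    poly_pos = poly_pos[: ts.n_polynucleotide]
    if poly_pos:
        covs = _cond_coverage(trng, dp, len(poly_pos))
        alts = _cond_binomial(trng, covs, ts.artifact_vaf, 6)
        for (chrom, pos), c, a in zip(poly_pos, covs, alts):
            acc = int(trng.integers(n_accessions))
            rc = ref_code[site_lookup[(chrom, pos)]]
            plant(acc, chrom, pos, random_alt(rc), int(a), int(c), "polynucleotide")

    # annotated germline variants (present in the emitted VCF)
    germ_rows = []
    for chrom, pos in take_positions(ts.n_annotated_germline):
        rc = ref_code[site_lookup[(chrom, pos)]]
        alt_code = random_alt(rc)
        germ_rows.append((chrom, pos, BASES[rc], BASES[alt_code]))
        k = max(2, int(round(ts.germline_carrier_frac * n_accessions)))
        accs = trng.choice(n_accessions, size=k, replace=False)
        covs = _cond_coverage(trng, dp, k)
        alts = trng.binomial(covs, 0.5)
        for acc, c, a in zip(accs, covs, alts):
            plant(int(acc), chrom, pos, alt_code, int(a), int(c), "annotated_germline")
    germline = pd.DataFrame(germ_rows, columns=["chrom", "pos", "ref", "alt"])

    # --- assemble the table ----------------------------------------------
    nonzero = cov > 0
    rows = np.nonzero(nonzero)[0]
    coverage = counts[rows].sum(axis=1)
    df = pd.DataFrame(
        {
            "accession": np.array(accessions, dtype=object)[acc_idx[rows]],
            "chrom": chroms[site_idx[rows]],
            "pos": positions[site_idx[rows]],
            "ref": ref[site_idx[rows]],
            "count_A": counts[rows, 0],
            "count_C": counts[rows, 1],
            "count_G": counts[rows, 2],
            "count_T": counts[rows, 3],
            "coverage": coverage,
        }
    )
    row_to_out = {int(r): i for i, r in enumerate(rows)}
    bias_rows = {row_to_out[r] for r, b in biased if b and r in row_to_out}

    # per-read attributes wherever a non-reference read exists
    rc_out = ref_code[site_idx[rows]]
    cmat = counts[rows]
    nonref = cmat.copy()
    nonref[np.arange(len(rows)), rc_out] = 0
    alt_code_out = nonref.argmax(axis=1)
    alt_n = nonref[np.arange(len(rows)), alt_code_out]
    ref_n = cmat[np.arange(len(rows)), rc_out]
    need = alt_n > 0

    attrs = {
        f"{side}_{what}": np.full(len(rows), "", dtype=object)
        for side in ("ref", "alt")
        for what in ("read_pos", "mapq", "baseq", "strand")
    }
    idxs = np.nonzero(need)[0]
    for i in idxs:
        bias = i in bias_rows
        for side, n_reads in (("ref", int(ref_n[i])), ("alt", int(alt_n[i]))):
            if n_reads == 0:
                continue
            if side == "alt" and bias:
                rp = rng.integers(0, ep.bias_read_pos_max, size=n_reads)
                mq = np.full(n_reads, ep.mapq - ep.bias_mapq_shift)
            else:
                rp = rng.integers(0, ep.read_length, size=n_reads)
                mq = np.full(n_reads, ep.mapq)
            bq = np.clip(
                np.round(rng.normal(ep.baseq_mean, ep.baseq_sd, size=n_reads)),
                2, 41,
            ).astype(int)
            st = rng.integers(0, 2, size=n_reads)
            attrs[f"{side}_read_pos"][i] = join_vector(rp)
            attrs[f"{side}_mapq"][i] = join_vector(mq)
            attrs[f"{side}_baseq"][i] = join_vector(bq)
            attrs[f"{side}_strand"][i] = join_vector(st)
    for k, v in attrs.items():
        df[k] = v

    # total reads at or above Phred 30 (reference reads without emitted
    # attributes are counted at the ambient pass rate of ~1)
    baseq_pass = coverage.copy()
    for i in idxs:
        nref = int(ref_n[i])
        nalt = int(alt_n[i])
        rp = attrs["ref_baseq"][i]
        ap = attrs["alt_baseq"][i]
        passing = 0
        if rp:
            passing += int(np.sum(np.array(rp.split(","), dtype=int) >= 30))
        if ap:
            passing += int(np.sum(np.array(ap.split(","), dtype=int) >= 30))
        baseq_pass[i] = passing + (int(coverage[i]) - nref - nalt)
    df["baseq_pass"] = baseq_pass

    truth_df = pd.DataFrame(
        truth_rows,
        columns=["accession", "chrom", "pos", "ref", "alt", "artifact_class"],
    )
    params = {
        "truth_spec": asdict(ts),
        "depth_params": asdict(dp),
        "error_params": asdict(ep),
        "n_accessions": n_accessions,
    }
    truth = SimulationTruth(records=truth_df, generator_params=params, seed=seed)
    return PileupResult(
        pileup=df.reset_index(drop=True),
        truth=truth,
        germline=germline,
        accessions=accessions,
    )
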