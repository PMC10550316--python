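"""Genome annotation model: strand-annotated genes with UTR/exon intervals.

All coordinates are 0-based half-open internally.  A region interval is
*unambiguous* when it overlaps no UTR/exonic interval of any other gene;
mutations and genewise features are restricted to unambiguous intervals
because an RNA-seq read from an overlap cannot be assigned to one gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_LABELS = ("UTR", "exon")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


@dataclass
class Region:
    """One UTR or exon interval, 0-based half-open."""

    start: int
    end: int
    label: str = "exon"
    unambiguous: bool = True

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty region [{self.start}, {self.end})")
        if self.label not in VALID_LABELS:
            raise ValueError(f"region label must be one of {VALID_LABELS}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def start(self) -> int:
        return min(r.start for r in self.regions)

    @property
    def end(self) -> int:
        return max(r.end for r in self.regions)

    def intervals(self, unambiguous_only: bool = False) -> list[tuple[int, int]]:
        return [
            (r.start, r.end)
            for r in self.regions
            if r.unambiguous or not unambiguous_only
        ]


@dataclass
class GenomeAnnotation:
    """Reference sequences plus the gene models laid on top of them."""

    chromosomes: dict[str, str]
    genes: list[Gene]

    def validate(self) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        for gene in self.genes:
            if gene.chrom not in self.chromosomes:
                raise ValueError(f"{gene.gene_id}: unknown chromosome {gene.chrom}")
            clen = len(self.chromosomes[gene.chrom])
            prev_end = -1
            for r in gene.regions:
                if r.start < 0 or r.end > clen:
                    raise ValueError(
                        f"{gene.gene_id}: region [{r.start},{r.end}) outside "
                        f"chromosome of length {clen}"
                    )
                if r.start < prev_end:
                    raise ValueError(
                        f"{gene.gene_id}: regions overlap or are unsorted"
                    )
                prev_end = r.end

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def annotate_ambiguity(self) -> None:
        """Set each region's ``unambiguous`` flag.

        A region is unambiguous iff it overlaps no region of a *different*
        gene on the same chromosome (either strand — read assignment in
        unstranded RNA-seq cannot separate antisense overlaps).
        """
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for gi, gene in enumerate(self.genes):
            for r in gene.regions:
                by_chrom.setdefault(gene.chrom, []).append((r.start, r.end, gi))
        for gi, gene in enumerate(self.genes):
            others = [
                (s, e) for s, e, og in by_chrom.get(gene.chrom, []) if og != gi
            ]
            if not others:
                for r in gene.regions:
                    r.unambiguous = True
                continue
            starts = np.array(sorted(s for s, _ in others))
            # keep per-interval ends aligned with sorted starts
            order = sorted(others)
            ends = np.array([e for _, e in order])
            for r in gene.regions:
                # any other interval with start < r.end and end > r.start
                idx = np.searchsorted(starts, r.end, side="left")
                r.unambiguous = not bool(np.any(ends[:idx] > r.start))

    def unambiguous_intervals(self, gene_id: str) -> list[tuple[int, int]]:
        return self.gene(gene_id).intervals(unambiguous_only=True)

    def exon_end_positions(self) -> dict[str, np.ndarray]:
        """Terminal exonic bases of every region, per chromosome.

        Both boundaries of each UTR/exon interval are reported, expressed as
        the first and last base inside the interval (0-based).  These are the
        positions splice-junction mapping artifacts cluster around.
        """
        ends: dict[str, set[int]] = {}
        for gene in self.genes:
            s = ends.setdefault(gene.chrom, set())
            for r in gene.regions:
                s.add(r.start)
                s.add(r.end - 1)
        return {c: np.array(sorted(v), dtype=np.int64) for c, v in ends.items()}


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge possibly-overlapping half-open intervals."""
    if not intervals:
        return []
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def positions_in_intervals(
    pos: np.ndarray, intervals: list[tuple[int, int]]
) -> np.ndarray:
    """Boolean mask: which half-open merged intervals contain each position."""
    pos = np.asarray(pos, dtype=np.int64)
    if not intervals:
        return np.zeros(pos.shape, dtype=bool)
    merged = merge_intervals(list(intervals))
    starts = np.array([s for s, _ in merged], dtype=np.int64)
    ends = np.array([e for _, e in merged], dtype=np.int64)
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    out = np.zeros(pos.shape, dtype=bool)
    out[ok] = pos[ok] < ends[idx[ok]]
    return out


def interval_overlap(
    a_start: int, a_end: int, intervals: list[tuple[int, int]]
) -> int:
    """Total overlap (bp) of [a_start, a_end) with a set of intervals."""
    total = 0
    for s, e in intervals:
        total += max(0, min(a_end, e) - max(a_start, s))
    return total
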