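import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from somarna.annotation import Gene, GenomeAnnotation, Region
from somarna.io import join_vector
from somarna.simulate import simulate_genome, simulate_pileup, simulate_tracks

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_annotation() -> GenomeAnnotation:
    """Two chromosomes, three genes; gene2 overlaps gene1's last exon."""
    rng = np.random.default_rng(12)
    chr1 = "".join(rng.choice(list("ACGT"), size=1200))
    chr2 = "".join(rng.choice(list("ACGT"), size=800))
    genes = [
        Gene("g1", "chr1", "+", [
            Region(50, 100, "UTR"),
            Region(150, 300, "exon"),
            Region(350, 420, "UTR"),
        ]),
        Gene("g2", "chr1", "-", [
            Region(400, 500, "UTR"),
            Region(550, 700, "exon"),
        ]),
        Gene("g3", "chr2", "-", [
            Region(100, 160, "UTR"),
            Region(200, 400, "exon"),
            Region(450, 500, "UTR"),
        ]),
    ]
    ann = GenomeAnnotation(chromosomes={"chr1": chr1, "chr2": chr2}, genes=genes)
    ann.validate()
    ann.annotate_ambiguity()
    return ann


@pytest.fixture(scope="session")
def sim_dataset():
    """One full synthetic dataset at the default study conditions."""
    ann = simulate_genome(seed=1)
    tracks = simulate_tracks(ann, seed=1)
    masks = pd.concat([tracks.blacklist, tracks.rna_edit], ignore_index=True)
    result = simulate_pileup(ann, seed=1, avoid_intervals=masks)
    return ann, tracks, result


def make_candidate(
    pos=100,
    ref="C",
    alt="T",
    ref_count=34,
    alt_count=6,
    accession="a1",
    chrom="chr1",
    rng=None,
    **attr_overrides,
):
    """One candidate row with plausible per-read attributes."""
    rng = rng or np.random.default_rng(0)
    attrs = {}
    for side, n in (("ref", ref_count), ("alt", alt_count)):
        attrs[f"{side}_read_pos"] = join_vector(rng.integers(0, 95, n))
        attrs[f"{side}_mapq"] = join_vector(np.full(n, 60))
        attrs[f"{side}_baseq"] = join_vector(
            np.clip(np.round(rng.normal(36, 2, n)), 2, 41).astype(int)
        )
        attrs[f"{side}_strand"] = join_vector(rng.integers(0, 2, n))
    attrs.update(attr_overrides)
    return {
        "accession": accession,
        "chrom": chrom,
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "ref_count": ref_count,
        "alt_count": alt_count,
        "coverage": ref_count + alt_count,
        **attrs,
    }
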