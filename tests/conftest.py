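import numpy as np
import pandas as pd
import pytest

import oryzanc as oz
import oryzanc.simulate as sim

SEED = 0


@pytest.fixture(scope="session")
def config():
    return oz.SimConfig(seed=SEED)


@pytest.fixture(scope="session")
def annotation(config):
    return sim.generate_annotation(config)


@pytest.fixture(scope="session")
def lnc_bundle(config, annotation):
    return sim.generate_lncrna_candidates(config, annotation)


@pytest.fixture(scope="session")
def circ_bundle(config, annotation):
    return sim.generate_circ_calls(config, annotation)


@pytest.fixture(scope="session")
def toy_annotation():
    """Two hand-placed genes on a 100-kb chromosome, plus a control contig.

    geneA: + strand, [10000, 16000), exons [10000,12000) [14000,16000)
    geneB: - strand, [30000, 36000), exons [30000,32000) [34000,36000)
    """
    genes = {
        "geneA": oz.Gene(
            id="geneA", chrom="Chr1", start=10_000, end=16_000, strand="+",
            exons=((10_000, 12_000), (14_000, 16_000)),
        ),
        "geneB": oz.Gene(
            id="geneB", chrom="Chr1", start=30_000, end=36_000, strand="-",
            exons=((30_000, 32_000), (34_000, 36_000)),
        ),
    }
    return oz.GenomeAnnotation(
        chromosomes={"Chr1": 100_000, "ChrC": 10_000},
        genes=genes,
        control_contig="ChrC",
    )


def make_transcript(start, end, strand="+", chrom="Chr1", **kw):
    kw.setdefault("id", f"t{start}_{end}_{strand}")
    kw.setdefault("mean_fpkm", 1.0)
    return oz.TranscriptRecord(
        chrom=chrom, start=start, end=end, strand=strand,
        exons=((start, end),), **kw,
    )


def random_transcripts(rng, ann, n, length_range=(100, 4000)):
    """Random features biased toward gene-adjacent placements (hard cases)."""
    genes = list(ann.genes.values())
    chroms = ann.nuclear_chromosomes
    out = []
    for i in range(n):
        length = int(rng.integers(*length_range))
        if genes and rng.random() < 0.7:
            g = genes[int(rng.integers(len(genes)))]
            anchor = int(rng.integers(g.start - 2000, g.end + 2000))
            chrom = g.chrom
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            anchor = int(rng.integers(0, ann.chromosomes[chrom]))
        start = max(0, min(anchor, ann.chromosomes[chrom] - length - 1))
        out.append(
            make_transcript(
                start, start + length,
                strand="+" if rng.random() < 0.5 else "-",
                chrom=chrom, id=f"rand{i}",
            )
        )
    return out


def features_frame(genes):
    return pd.DataFrame(
        {
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
        },
        index=[g.id for g in genes],
    )
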