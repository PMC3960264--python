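import io

import numpy as np
import pytest

from srnascan import Annotation, GeneFeature, GenomicInterval, MappedRead, Replicon


@pytest.fixture
def small_annotation() -> Annotation:
    """Two replicons, one feature of each type, well separated."""
    replicons = [
        Replicon("chr", 20_000, False),
        Replicon("pSYSA", 8_000, True),
    ]
    features = [
        GeneFeature(GenomicInterval("chr", 1_000, 4_000, "+"), "rRNA", "rrn1"),
        GeneFeature(GenomicInterval("chr", 5_000, 5_100, "+"), "tRNA", "trn1"),
        GeneFeature(GenomicInterval("chr", 6_000, 7_500, "+"), "CDS", "cds_plus"),
        GeneFeature(GenomicInterval("chr", 9_000, 10_500, "-"), "CDS", "cds_minus"),
        GeneFeature(GenomicInterval("chr", 12_000, 12_300, "+"), "misc_RNA", "misc1"),
        GeneFeature(GenomicInterval("pSYSA", 2_000, 3_200, "+"), "CDS", "cds_plasmid"),
    ]
    return Annotation(replicons, features)


def random_annotation(rng: np.random.Generator, max_features: int = 100) -> Annotation:
    """A random (possibly overlapping) annotation on a short genome."""
    length = int(rng.integers(2_000, 10_000))
    n = int(rng.integers(0, max_features + 1))
    feats = []
    for i in range(n):
        start = int(rng.integers(0, length - 10))
        end = int(rng.integers(start + 1, min(length, start + 1_500) + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        ftype = str(rng.choice(["rRNA", "tRNA", "CDS", "misc_RNA"], p=[0.1, 0.1, 0.6, 0.2]))
        feats.append(
            GeneFeature(GenomicInterval("chr", start, end, strand), ftype, f"g{i}")
        )
    return Annotation([Replicon("chr", length)], feats)


def random_reads(
    rng: np.random.Generator, annotation: Annotation, n: int, read_length: int = 81
) -> list[MappedRead]:
    length = annotation.replicons["chr"].length
    reads = []
    for i in range(n):
        start = int(rng.integers(0, max(1, length - read_length)))
        end = min(length, start + read_length)
        strand = "+" if rng.random() < 0.5 else "-"
        reads.append(MappedRead(f"r{i}", GenomicInterval("chr", start, end, strand)))
    return reads


def sam_text(records: list[str], replicons: list[tuple[str, int]]) -> io.StringIO:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    lines += [f"@SQ\tSN:{name}\tLN:{length}" for name, length in replicons]
    lines += records
    return io.StringIO("\n".join(lines) + "\n")
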