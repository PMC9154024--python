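import pytest

from splicigen.config import PipelineConfig
from splicigen.io import AlignedRead, Annotation, Gene, Genome, Transcript


@pytest.fixture
def cfg():
    return PipelineConfig()


@pytest.fixture
def toy_annotation():
    """One '+'-strand gene, exons [100,200), [300,400), [500,600)."""
    t = Transcript(
        "toy.t1", "toy", "chr1", "+",
        exons=[(100, 200), (300, 400), (500, 600)],
        cds=[(100, 200), (300, 400), (500, 600)],
        cds_phases=[0, 0, 0], start_codon=100,
    )
    g = Gene("toy", "chr1", "+", transcripts={"toy.t1": t}, start=100, end=600)
    return Annotation([g])


def _place(length, pieces):
    seq = ["A"] * length
    for pos, s in pieces:
        seq[pos : pos + len(s)] = list(s)
    return "".join(seq)


@pytest.fixture
def mini_fixture():
    """Single-gene exon-skipping fixture.

    E1 = "ATGGCTAAA" at [100,109), E2 = "GGGCCC" at [200,206),
    E3 = "TTTTGAGGG" at [300,309).  Tumor reads splice E1 directly onto E3;
    normal reads cover the annotated 3-exon transcript.
    """
    genome = Genome.from_dict(
        {"chrT": _place(400, [(100, "ATGGCTAAA"), (200, "GGGCCC"), (300, "TTTTGAGGG")])}
    )
    t = Transcript(
        "t1", "g1", "chrT", "+",
        exons=[(100, 109), (200, 206), (300, 309)],
        cds=[(100, 109), (200, 206), (300, 303)],
        cds_phases=[0, 0, 0], start_codon=100,
    )
    gene = Gene("g1", "chrT", "+", transcripts={"t1": t}, start=100, end=309)
    annotation = Annotation([gene])

    var_seq = "ATGGCTAAA" + "TTTTGAGGG"
    ref_seq = "ATGGCTAAA" + "GGGCCC" + "TTTTGAGGG"
    tumor = [
        AlignedRead(f"t{i}", var_seq, "chrT", 100, [("M", 9), ("N", 191), ("M", 9)])
        for i in range(25)
    ]
    normal = []
    for i in range(25):
        normal.append(AlignedRead(f"n{i}a", ref_seq[:12], "chrT", 100,
                                  [("M", 9), ("N", 91), ("M", 3)]))
        normal.append(AlignedRead(f"n{i}b", ref_seq[6:18], "chrT", 106,
                                  [("M", 3), ("N", 91), ("M", 6), ("N", 94), ("M", 3)]))
        normal.append(AlignedRead(f"n{i}c", ref_seq[12:], "chrT", 203,
                                  [("M", 3), ("N", 94), ("M", 9)]))
    return genome, annotation, tumor, normal
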