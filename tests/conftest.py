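import numpy as np
import pytest

from fusionkit.io_formats import Annotation, FusionCall, Genome, Transcript


@pytest.fixture
def toy_genome() -> Genome:
    rng = np.random.default_rng(42)
    return Genome(
        {
            "c1": "".join(rng.choice(list("ACGT"), size=2000)),
            "c2": "".join(rng.choice(list("ACGT"), size=2000)),
        }
    )


@pytest.fixture
def toy_annotation() -> Annotation:
    """Two plus-strand and one minus-strand gene with whole-exon CDS."""
    t1 = Transcript("tA.1", "gA", "c1", "+", [(101, 200), (301, 400), (501, 600)],
                    [(101, 200), (301, 400), (501, 600)])
    t2 = Transcript("tB.1", "gB", "c2", "+", [(101, 250), (401, 550)],
                    [(101, 250), (401, 550)])
    t3 = Transcript("tC.1", "gC", "c1", "-", [(1001, 1150), (1301, 1400)],
                    [(1001, 1150), (1301, 1400)])
    return Annotation(
        {
            "gA": ("c1", "+", [t1]),
            "gB": ("c2", "+", [t2]),
            "gC": ("c1", "-", [t3]),
        }
    )


def make_call(**kw) -> FusionCall:
    base = dict(
        sample_id="S1", tool="toolA", gene5="gA", gene3="gB", chrom5="c1",
        bp5=200, strand5="+", chrom3="c2", bp3=401, strand3="+", junction_reads=5,
    )
    base.update(kw)
    return FusionCall(**base)


@pytest.fixture
def call_factory():
    return make_call
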