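import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from mexquant.gene_model import (
    Exon,
    MicroexonGeneModel,
    load_exon_sequences,
    load_gene_model,
)
from mexquant.sj import SpliceJunctionRecord

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def make_toy_model(strand: str = "+", **overrides) -> MicroexonGeneModel:
    """Toy plus-strand locus: donor exon ends at 1000, microexons of 3/18/22 nt,
    terminal exon starts at 1501 (acceptor boundaries at 1100/1200/1300/1500)."""
    kwargs = dict(
        gene_id="TOY",
        chrom="chr1",
        strand="+",
        exons=(
            Exon("ex4", 901, 1000),
            Exon("m3", 1101, 1103, is_microexon=True),
            Exon("m18", 1201, 1218, is_microexon=True),
            Exon("m22", 1301, 1322, is_microexon=True),
            Exon("ex6", 1501, 1600),
        ),
        donor_exon_id="ex4",
        terminal_exon_id="ex6",
    )
    kwargs.update(overrides)
    model = MicroexonGeneModel(**kwargs)
    if strand == "-":
        model = mirror_model(model)
    return model


MIRROR_CONSTANT = 10_000


def mirror_pos(pos: int, c: int = MIRROR_CONSTANT) -> int:
    return c - pos


def mirror_model(model: MicroexonGeneModel, c: int = MIRROR_CONSTANT) -> MicroexonGeneModel:
    """Coordinate-mirrored, strand-flipped copy of a model (oracle for strand tests)."""
    exons = tuple(
        dataclasses.replace(e, start=c - e.end, end=c - e.start) for e in model.exons
    )
    return dataclasses.replace(
        model, strand="-" if model.strand == "+" else "+", exons=exons
    )


def mirror_record(rec: SpliceJunctionRecord, c: int = MIRROR_CONSTANT) -> SpliceJunctionRecord:
    return dataclasses.replace(
        rec,
        intron_start=c - rec.intron_end,
        intron_end=c - rec.intron_start,
        strand_code={0: 0, 1: 2, 2: 1}[rec.strand_code],
    )


@pytest.fixture
def toy_model():
    return make_toy_model()


@pytest.fixture(scope="session")
def rps24_model():
    return load_gene_model("RPS24")


@pytest.fixture(scope="session")
def rps24_sequences():
    return load_exon_sequences()
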