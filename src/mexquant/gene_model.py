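"""Microexon splicing-locus models.

A :class:`MicroexonGeneModel` describes the region of a gene where a run of
microexons (exons shorter than ~30 nt) sits between two constitutive flanking
exons.  All downstream quantification is anchored at the donor (5' splice
site) of the upstream constitutive exon: every splice-junction read leaving
that donor is classified by the acceptor (3' splice site) it lands on, which
identifies the first exon of the isoform's variable region.

The built-in ``"RPS24"`` model describes the RPS24 exon-4..exon-6 region with
its three microexons (3, 18 and 22 nt).  Because the reference genome is not
redistributed with this package, the packaged coordinates and exon sequences
are a synthetic stand-in (see ``data/rps24_synthetic.yaml``): they preserve
the published architecture — microexon lengths, the in-frame stop codon inside
the 22-nt exon, the one-lysine difference between the two microexon-containing
protein isoforms, the PKE C-terminus of the all-skipped isoform, and the
published ex4F/ex6R primer sequences — but the genomic positions are
placeholders, not hg38.

Coordinates are 1-based inclusive throughout (the STAR ``SJ.out.tab``
dialect); BED input is converted at load time.
"""

from __future__ import annotations

import dataclasses
import warnings
from importlib import resources
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping

import yaml
from Bio.Seq import Seq

MICROEXON_MAX_NT = 30

__all__ = [
    "Exon",
    "Primer",
    "MicroexonGeneModel",
    "IsoformCombination",
    "TranslationResult",
    "InvalidModelError",
    "GeneNotFoundError",
    "load_gene_model",
    "load_exon_sequences",
    "donor_site",
    "acceptor_map",
    "enumerate_isoforms",
    "translate_isoform",
]


class InvalidModelError(ValueError):
    """Raised when a gene model violates the locus-structure invariants."""


class GeneNotFoundError(LookupError):
    """Raised when the requested gene is absent from the source."""


@dataclasses.dataclass(frozen=True)
class Exon:
    """One exon, genomic coordinates 1-based inclusive."""

    exon_id: str
    start: int
    end: int
    is_microexon: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclasses.dataclass(frozen=True)
class Primer:
    """A PCR primer anchored inside one exon.

    ``offset`` is the 0-based transcript-orientation offset of the primer's
    first covered base within the exon; the amplicon runs from the forward
    primer start through the last base covered by the reverse primer.
    """

    sequence: str
    exon_id: str
    offset: int


@dataclasses.dataclass(frozen=True)
class TranslationResult:
    protein: str
    c_terminal: str
    stop_found: bool


@dataclasses.dataclass(frozen=True)
class IsoformCombination:
    """One inclusion/exclusion combination of the model's microexons.

    ``label`` is unique across combinations.  For structures the field has
    resolved experimentally the model's ``canonical_structures`` table maps
    exon content to the junction-style name (e.g. the 3+22 structure is called
    "ex4:3bp" because its donor junction lands on the 3-bp exon); all other
    combinations get a content label like "inc:18+22".  ``junction_label`` is
    the donor-anchored junction the combination would produce in SJ data and
    is shared between combinations with the same first included exon.
    """

    included: tuple[str, ...]
    label: str
    junction_label: str
    transcript_length_delta: int
    amplicon_length: int | None = None


@dataclasses.dataclass(frozen=True)
class MicroexonGeneModel:
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Exon, ...]  # transcript 5'->3' order
    donor_exon_id: str
    terminal_exon_id: str
    primer_fwd: Primer | None = None
    primer_rev: Primer | None = None
    cds_frame_offset: int = 0
    canonical_structures: Mapping[str, tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        _validate(self)

    # -- convenience accessors -------------------------------------------
    @property
    def donor_exon(self) -> Exon:
        return self.exons[0]

    @property
    def terminal_exon(self) -> Exon:
        return self.exons[-1]

    @property
    def microexons(self) -> tuple[Exon, ...]:
        return self.exons[1:-1]

    def exon(self, exon_id: str) -> Exon:
        for e in self.exons:
            if e.exon_id == exon_id:
                return e
        raise KeyError(exon_id)

    @property
    def junction_labels(self) -> tuple[str, ...]:
        """Acceptor category labels in transcript order (microexons, then terminal)."""
        labels = [f"{self.donor_exon_id}:{m.length}bp" for m in self.microexons]
        labels.append(f"{self.donor_exon_id}:{self.terminal_exon_id}")
        return tuple(labels)


def _validate(model: MicroexonGeneModel) -> None:
    if model.strand not in {"+", "-"}:
        raise InvalidModelError(f"invalid model: strand must be '+' or '-', got {model.strand!r}")
    if len(model.exons) < 2:
        raise InvalidModelError("invalid model: need at least a donor/acceptor exon pair")
    ids = [e.exon_id for e in model.exons]
    if len(set(ids)) != len(ids):
        raise InvalidModelError("invalid model: duplicate exon ids")
    # transcript order must be monotone in the strand direction
    starts = [e.start for e in model.exons]
    if model.strand == "+":
        ordered = all(a.end < b.start for a, b in zip(model.exons, model.exons[1:]))
    else:
        ordered = all(a.start > b.end for a, b in zip(model.exons, model.exons[1:]))
    if not ordered:
        raise InvalidModelError("invalid model: exons overlap or are out of transcript order")
    for e in model.exons:
        if e.start > e.end:
            raise InvalidModelError(f"invalid model: exon {e.exon_id} has start > end")
    if model.exons[0].exon_id != model.donor_exon_id:
        raise InvalidModelError("invalid model: donor exon must be the first exon in transcript order")
    if model.exons[-1].exon_id != model.terminal_exon_id:
        raise InvalidModelError("invalid model: terminal exon must be the last exon in transcript order")
    for e in model.microexons:
        if not e.is_microexon:
            raise InvalidModelError(f"invalid model: internal exon {e.exon_id} not flagged as microexon")
        if e.length >= MICROEXON_MAX_NT:
            warnings.warn(
                f"exon {e.exon_id} is flagged as a microexon but is {e.length} nt "
                f"(>= {MICROEXON_MAX_NT} nt)",
                stacklevel=3,
            )
    if not 0 <= model.cds_frame_offset <= 2:
        raise InvalidModelError("invalid model: cds_frame_offset must be 0..2")
    for primer, anchor in ((model.primer_fwd, model.donor_exon_id), (model.primer_rev, model.terminal_exon_id)):
        if primer is None:
            continue
        if primer.exon_id != anchor:
            raise InvalidModelError(
                f"primer outside amplicon: primer anchored on {primer.exon_id!r}, expected {anchor!r}"
            )
        exon = model.exon(primer.exon_id)
        if primer.offset < 0 or primer.offset + len(primer.sequence) > exon.length:
            raise InvalidModelError("primer outside amplicon: primer exceeds exon bounds")


# ---------------------------------------------------------------------------
# loading


def load_gene_model(source, gene_id: str | None = None) -> MicroexonGeneModel:
    """Load a gene model from a YAML config, GTF, BED6 file or built-in name.

    ``source`` may be ``"RPS24"`` (the packaged synthetic stand-in model), a
    mapping (parsed YAML config), or a path ending in .yaml/.yml, .gtf/.gff
    or .bed.  GTF/BED exons are reordered to transcript orientation; internal
    exons are flagged as microexons.
    """
    if isinstance(source, Mapping):
        return _model_from_config(dict(source), gene_id)
    if isinstance(source, str) and source.upper() == "RPS24":
        with resources.files("mexquant.data").joinpath("rps24_synthetic.yaml").open() as fh:
            return _model_from_config(yaml.safe_load(fh), gene_id)
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"gene model source not found: {path}")
    suffix = path.suffix.lower()
    if suffix in {".yaml", ".yml"}:
        with open(path) as fh:
            return _model_from_config(yaml.safe_load(fh), gene_id)
    if suffix in {".gtf", ".gff", ".gff3"}:
        return _model_from_gtf(path, gene_id)
    if suffix == ".bed":
        return _model_from_bed(path, gene_id)
    raise ValueError(f"unrecognized gene model format: {path}")


def _model_from_config(cfg: dict, gene_id: str | None) -> MicroexonGeneModel:
    name = cfg.get("gene_id")
    if gene_id is not None and name != gene_id:
        raise GeneNotFoundError(f"gene not found: {gene_id}")
    exon_entries = cfg.get("exons", [])
    exons = tuple(
        Exon(
            exon_id=str(e["id"]),
            start=int(e["start"]),
            end=int(e["end"]),
            is_microexon=bool(e.get("microexon", False)),
        )
        for e in exon_entries
    )
    strand = str(cfg.get("strand", "+"))
    exons = _transcript_order(exons, strand)
    primers = cfg.get("primers") or {}

    def _primer(key: str) -> Primer | None:
        p = primers.get(key)
        if p is None:
            return None
        return Primer(sequence=str(p["sequence"]).upper(), exon_id=str(p["exon"]), offset=int(p["offset"]))

    canonical = cfg.get("canonical_structures")
    if canonical is not None:
        canonical = {str(k): tuple(v) for k, v in canonical.items()}
    return MicroexonGeneModel(
        gene_id=str(name),
        chrom=str(cfg["chrom"]),
        strand=strand,
        exons=exons,
        donor_exon_id=str(cfg["donor_exon"]),
        terminal_exon_id=str(cfg["terminal_exon"]),
        primer_fwd=_primer("forward"),
        primer_rev=_primer("reverse"),
        cds_frame_offset=int(cfg.get("cds_frame_offset", 0)),
        canonical_structures=canonical,
    )


def _transcript_order(exons: Iterable[Exon], strand: str) -> tuple[Exon, ...]:
    return tuple(sorted(exons, key=lambda e: e.start, reverse=(strand == "-")))


def _assemble_region(gene_id, chrom, strand, exons) -> MicroexonGeneModel:
    """Build a model from bare exon intervals: first/last exons flank, middles are microexons."""
    exons = _transcript_order(exons, strand)
    if len(exons) < 2:
        raise InvalidModelError("invalid model: need at least a donor/acceptor exon pair")
    flagged = [dataclasses.replace(exons[0], is_microexon=False)]
    flagged += [dataclasses.replace(e, is_microexon=True) for e in exons[1:-1]]
    flagged.append(dataclasses.replace(exons[-1], is_microexon=False))
    return MicroexonGeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=tuple(flagged),
        donor_exon_id=flagged[0].exon_id,
        terminal_exon_id=flagged[-1].exon_id,
    )


def _model_from_gtf(path: Path, gene_id: str | None) -> MicroexonGeneModel:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True, disable_infer_transcripts=True,
    )
    exons = []
    chrom = strand = None
    for feat in db.features_of_type("exon"):
        gid = (feat.attributes.get("gene_id") or [None])[0]
        if gene_id is not None and gid != gene_id:
            continue
        chrom, strand = feat.seqid, feat.strand
        eid = (feat.attributes.get("exon_id") or [f"exon{len(exons) + 1}"])[0]
        exons.append(Exon(exon_id=eid, start=feat.start, end=feat.end))
    if not exons:
        raise GeneNotFoundError(f"gene not found: {gene_id}")
    return _assemble_region(gene_id or "gene", chrom, strand, exons)


def _model_from_bed(path: Path, gene_id: str | None) -> MicroexonGeneModel:
    """BED6: 0-based half-open intervals, name column used as exon id."""
    exons = []
    chrom = strand = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise InvalidModelError("invalid model: BED6 requires 6 columns")
            chrom, strand = fields[0], fields[5]
            exons.append(Exon(exon_id=fields[3], start=int(fields[1]) + 1, end=int(fields[2])))
    if not exons:
        raise GeneNotFoundError(f"gene not found: {gene_id}")
    return _assemble_region(gene_id or "gene", chrom, strand, exons)


def load_exon_sequences(fasta_path=None) -> dict[str, str]:
    """Read per-exon sequences keyed by record id.

    With no argument, returns the packaged synthetic RPS24 stand-in sequences.
    """
    from Bio import SeqIO

    if fasta_path is None:
        with resources.files("mexquant.data").joinpath("rps24_exons_synthetic.fa").open() as fh:
            return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}


# ---------------------------------------------------------------------------
# interrogation


def donor_site(model: MicroexonGeneModel) -> int:
    """First intronic base after the donor exon, in genomic coordinates.

    This is the donor-side intron boundary a splice-junction record must match
    (STAR's intron-start field on the plus strand, intron-end on the minus).
    """
    if model.strand == "+":
        return model.donor_exon.end + 1
    return model.donor_exon.start - 1


def acceptor_map(model: MicroexonGeneModel) -> dict[int, str]:
    """Map the last intronic base before each acceptor exon to its category label."""
    mapping: dict[int, str] = {}
    labels = model.junction_labels
    acceptors = list(model.microexons) + [model.terminal_exon]
    for exon, label in zip(acceptors, labels):
        pos = exon.start - 1 if model.strand == "+" else exon.end + 1
        mapping[pos] = label
    return mapping


def _base_amplicon_length(model: MicroexonGeneModel) -> int | None:
    if model.primer_fwd is None or model.primer_rev is None:
        return None
    donor_part = model.donor_exon.length - model.primer_fwd.offset
    terminal_part = model.primer_rev.offset + len(model.primer_rev.sequence)
    return donor_part + terminal_part


def enumerate_isoforms(model: MicroexonGeneModel) -> list[IsoformCombination]:
    """All 2^k inclusion/exclusion combinations of the model's k microexons.

    Combinations are returned sorted by transcript length delta (the sum of
    included microexon lengths), ties broken by exon content.  When both
    primers are present each combination carries its expected PCR amplicon
    length (base amplicon + delta).
    """
    micro = model.microexons
    base = _base_amplicon_length(model)
    canonical = {frozenset(v): k for k, v in (model.canonical_structures or {}).items()}
    combos = []
    for mask in product((False, True), repeat=len(micro)):
        included = tuple(e for e, keep in zip(micro, mask) if keep)
        ids = tuple(e.exon_id for e in included)
        delta = sum(e.length for e in included)
        if ids:
            junction = f"{model.donor_exon_id}:{included[0].length}bp"
        else:
            junction = f"{model.donor_exon_id}:{model.terminal_exon_id}"
        label = canonical.get(frozenset(ids))
        if label is None:
            if not ids:
                label = junction
            else:
                label = "inc:" + "+".join(str(e.length) for e in included)
        combos.append(
            IsoformCombination(
                included=ids,
                label=label,
                junction_label=junction,
                transcript_length_delta=delta,
                amplicon_length=None if base is None else base + delta,
            )
        )
    combos.sort(key=lambda c: (c.transcript_length_delta, c.included))
    return combos


def translate_isoform(
    model: MicroexonGeneModel,
    combination: IsoformCombination,
    exon_sequences: Mapping[str, str],
) -> TranslationResult:
    """Translate the spliced coding sequence of one isoform combination.

    The spliced sequence is donor exon + included microexons + terminal exon
    (transcript orientation); translation starts at ``cds_frame_offset`` within
    the donor exon and stops at the first in-frame stop codon.  ``c_terminal``
    is the part of the protein encoded downstream of the donor exon — the
    region where microexon choice changes the protein.
    """
    order = [model.donor_exon_id, *combination.included, model.terminal_exon_id]
    parts = []
    for eid in order:
        exon = model.exon(eid)
        try:
            seq = exon_sequences[eid]
        except KeyError:
            raise ValueError(f"sequence mismatch: no sequence for exon {eid!r}") from None
        seq = seq.upper().replace("U", "T")
        if len(seq) != exon.length:
            raise ValueError(
                f"sequence mismatch: exon {eid!r} is {exon.length} nt but sequence has {len(seq)} nt"
            )
        parts.append(seq)
    cds = "".join(parts)[model.cds_frame_offset :]
    cds = cds[: len(cds) // 3 * 3]
    aa = str(Seq(cds).translate())
    stop_found = "*" in aa
    protein = aa.split("*", 1)[0]
    donor_codons = (model.donor_exon.length - model.cds_frame_offset) // 3
    return TranslationResult(
        protein=protein,
        c_terminal=protein[donor_codons:],
        stop_found=stop_found,
    )
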