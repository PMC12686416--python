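"""Donor-anchored isoform quantification from splice-junction tables.

The core measurement: among all splice-junction reads leaving the donor (5'
splice site) of the constitutive upstream exon, classify each junction by the
acceptor (3' splice site) it reaches.  The total donor-anchored read count is
used as the gene-expression proxy and each acceptor category's share of it is
that isoform's proportion.
"""

from __future__ import annotations

import dataclasses
import gzip
import io
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .gene_model import MicroexonGeneModel, acceptor_map, donor_site

__all__ = [
    "SpliceJunctionRecord",
    "IsoformCounts",
    "FormatError",
    "STAR_DIALECT",
    "read_sj_table",
    "classify_junctions",
    "quantify",
    "detect_isoform",
    "merge_cohort",
]

OTHER_LABEL = "other"
DETECTION_THRESHOLD = 0.05  # presence call: proportion strictly above 5%

# STAR SJ.out.tab columns (all 1-based genomic coordinates, intron extents)
STAR_DIALECT: dict = {
    "columns": {
        "chrom": 0,
        "intron_start": 1,
        "intron_end": 2,
        "strand_code": 3,
        "motif_code": 4,
        "annotated": 5,
        "unique_reads": 6,
        "multi_reads": 7,
        "max_overhang": 8,
    },
    "n_columns": 9,
    "skip_header": 0,
}


class FormatError(ValueError):
    """Malformed splice-junction table."""


@dataclasses.dataclass(frozen=True)
class SpliceJunctionRecord:
    """One splice junction: intron extent (1-based inclusive) plus read support."""

    chrom: str
    intron_start: int
    intron_end: int
    strand_code: int = 0  # 0 undefined, 1 plus, 2 minus
    motif_code: int = 0
    annotated: int = 0
    unique_reads: int = 0
    multi_reads: int = 0
    max_overhang: int = 0

    def __post_init__(self) -> None:
        if self.intron_start > self.intron_end:
            raise FormatError("intron_start > intron_end")
        if self.unique_reads < 0 or self.multi_reads < 0:
            raise FormatError("negative read count")


@dataclasses.dataclass
class IsoformCounts:
    """Per-sample donor-anchored category counts and proportions.

    ``proportions`` is ``None`` (undefined) when ``total_donor_reads`` is
    below ``min_total_used`` — low-coverage samples are flagged rather than
    reported as zeros.
    """

    sample_id: str
    counts: dict[str, int]
    total_donor_reads: int
    proportions: dict[str, float] | None
    min_total_used: int


def _open_text(source):
    if hasattr(source, "read"):
        return source, False
    path = Path(source)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb")), True
    return open(path), True


def read_sj_table(source, dialect: str | Mapping = "star") -> list[SpliceJunctionRecord]:
    """Parse a splice-junction table (STAR ``SJ.out.tab`` by default).

    ``source`` is a path (``.gz`` accepted) or a text file-like object.
    ``dialect`` is ``"star"``, ``"gdc"`` (GDC splice-junction quantification
    files: same columns, tolerates header lines), or a mapping with keys
    ``columns`` (field name -> 0-based column index), ``n_columns`` and
    ``skip_header``.  Malformed lines raise :class:`FormatError` naming the
    line number.
    """
    if dialect == "star":
        spec = STAR_DIALECT
    elif dialect == "gdc":
        spec = {**STAR_DIALECT, "skip_header": None}  # skip leading non-numeric lines
    elif isinstance(dialect, Mapping):
        spec = {**STAR_DIALECT, **dialect}
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    cols = spec["columns"]
    n_expected = spec["n_columns"]

    fh, owned = _open_text(source)
    records: list[SpliceJunctionRecord] = []
    try:
        skip = spec["skip_header"]
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if skip is None:  # GDC: skip header lines until the first numeric row
                if len(fields) > cols["intron_start"] and not fields[cols["intron_start"]].isdigit():
                    continue
            elif lineno <= skip:
                continue
            if len(fields) != n_expected:
                raise FormatError(
                    f"format error: line {lineno}: expected {n_expected} columns, got {len(fields)}"
                )
            try:
                records.append(
                    SpliceJunctionRecord(
                        chrom=fields[cols["chrom"]],
                        intron_start=int(fields[cols["intron_start"]]),
                        intron_end=int(fields[cols["intron_end"]]),
                        strand_code=int(fields[cols["strand_code"]]),
                        motif_code=int(fields[cols["motif_code"]]),
                        annotated=int(fields[cols["annotated"]]),
                        unique_reads=int(fields[cols["unique_reads"]]),
                        multi_reads=int(fields[cols["multi_reads"]]),
                        max_overhang=int(fields[cols["max_overhang"]]),
                    )
                )
            except (ValueError, FormatError) as exc:
                if isinstance(exc, FormatError) and str(exc).startswith("format error"):
                    raise
                raise FormatError(f"format error: line {lineno}: {exc}") from None
    finally:
        if owned:
            fh.close()
    return records


def classify_junctions(
    records: Iterable[SpliceJunctionRecord], model: MicroexonGeneModel
) -> list[tuple[str, SpliceJunctionRecord]]:
    """Keep records anchored at the model's donor site, labelled by acceptor.

    Records on other chromosomes or with any other donor (including microexon
    donors) are dropped; acceptors not in the model's map are labelled
    ``"other"``.
    """
    site = donor_site(model)
    amap = acceptor_map(model)
    plus = model.strand == "+"
    out = []
    for rec in records:
        if rec.chrom != model.chrom:
            continue
        donor_pos = rec.intron_start if plus else rec.intron_end
        if donor_pos != site:
            continue
        acceptor_pos = rec.intron_end if plus else rec.intron_start
        out.append((amap.get(acceptor_pos, OTHER_LABEL), rec))
    return out


def quantify(
    records: Iterable[SpliceJunctionRecord],
    model: MicroexonGeneModel,
    sample_id: str = "sample",
    min_total: int = 10,
    count_field: str = "unique",
) -> IsoformCounts:
    """Aggregate donor-anchored junction reads into per-category counts and proportions.

    ``count_field`` is ``"unique"`` (default: uniquely mapping junction reads
    only) or ``"unique+multi"``.  Proportions are defined only when the donor
    total reaches ``min_total``; the denominator includes ``"other"``
    acceptors.
    """
    if min_total < 1:
        raise ValueError("min_total must be >= 1")
    if count_field not in {"unique", "unique+multi"}:
        raise ValueError(f"count_field must be 'unique' or 'unique+multi', got {count_field!r}")
    counts = {label: 0 for label in model.junction_labels}
    counts[OTHER_LABEL] = 0
    for label, rec in classify_junctions(records, model):
        n = rec.unique_reads
        if count_field == "unique+multi":
            n += rec.multi_reads
        counts[label] += n
    total = sum(counts.values())
    proportions = {k: v / total for k, v in counts.items()} if total >= min_total else None
    return IsoformCounts(
        sample_id=sample_id,
        counts=counts,
        total_donor_reads=total,
        proportions=proportions,
        min_total_used=min_total,
    )


def detect_isoform(
    counts: IsoformCounts, threshold: float = DETECTION_THRESHOLD
) -> dict[str, bool] | None:
    """Presence call per category: proportion strictly above ``threshold``.

    Returns ``None`` when proportions are undefined (low-coverage sample).
    """
    if counts.proportions is None:
        return None
    return {label: p > threshold for label, p in counts.proportions.items()}


def merge_cohort(
    per_sample: Sequence[IsoformCounts],
    metadata: pd.DataFrame,
    join_key: str = "sample_id",
) -> pd.DataFrame:
    """Join per-sample proportions to a sample metadata table.

    Returns one row per sample with a proportion column per category,
    ``total_donor_reads`` and a ``defined`` flag (samples with undefined
    proportions keep NaN proportions, they are never dropped silently).
    """
    ids = [ic.sample_id for ic in per_sample]
    dupes = sorted({s for s in ids if ids.count(s) > 1})
    if dupes:
        raise ValueError(f"duplicate sample_id: {', '.join(dupes)}")
    if join_key not in metadata.columns:
        raise ValueError(f"metadata has no {join_key!r} column")
    meta_ids = metadata[join_key]
    if meta_ids.duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    missing = sorted(set(ids) - set(meta_ids))
    if missing:
        raise ValueError(f"metadata key missing for samples: {', '.join(missing)}")

    rows = []
    for ic in per_sample:
        row: dict = {join_key: ic.sample_id, "total_donor_reads": ic.total_donor_reads,
                     "defined": ic.proportions is not None}
        for label in ic.counts:
            row[label] = ic.proportions[label] if ic.proportions is not None else float("nan")
        rows.append(row)
    table = pd.DataFrame(rows)
    return table.merge(metadata, on=join_key, how="left", validate="one_to_one")


def counts_table(per_sample: Sequence[IsoformCounts], threshold: float = DETECTION_THRESHOLD) -> pd.DataFrame:
    """Long-format report: one row per sample x category (count, proportion, detected)."""
    rows = []
    for ic in per_sample:
        det = detect_isoform(ic, threshold)
        for label, count in ic.counts.items():
            rows.append(
                {
                    "sample_id": ic.sample_id,
                    "category": label,
                    "count": count,
                    "proportion": None if ic.proportions is None else ic.proportions[label],
                    "detected": None if det is None else det[label],
                    "total_donor_reads": ic.total_donor_reads,
                }
            )
    return pd.DataFrame(rows)
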