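"""Reading, writing and coordinate normalization for locus sequences and features.

All coordinates are 0-based half-open internally.  GenBank feature tables
(1-based inclusive) and BED (0-based half-open) are converted on the way in
and out; user-facing report positions that mimic figure axes ("nt after the
stop codon") are 1-based and produced only at the reporting layer.

Sequences are restricted to the nucleotide alphabet {A, C, G, T, N} and are
upper-cased on input.  ``N`` is a permitted placeholder but exact-match
searches elsewhere in the package treat any window containing ``N`` as
never matching.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

VALID_ALPHABET = frozenset("ACGTN")

FEATURE_TYPES = frozenset(
    {"exon", "CDS", "repeat", "TE", "LTR", "TIR", "enhancer", "stop_codon", "other"}
)


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T,N}, upper-cased."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - VALID_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid characters {sorted(bad)} "
                "(alphabet is A,C,G,T,N)"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Feature:
    """An annotated interval on a sequence, 0-based half-open."""

    seq_id: str
    type: str
    start: int
    end: int
    strand: str = "."
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.type!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.seq_id}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SplicedGeneModel:
    """An ordered set of exons forming one CDS on a single sequence/strand.

    Exons are ordered 5'->3' in transcription order (for minus-strand genes
    the first exon is the one with the largest genomic coordinate).
    """

    gene_id: str
    exons: tuple
    cds_length: int
    protein_length: int

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @classmethod
    def from_exons(cls, gene_id: str, exons: Sequence[Feature]) -> "SplicedGeneModel":
        if not exons:
            raise ValueError("gene model requires at least one exon")
        strand = exons[0].strand
        if any(e.strand != strand for e in exons):
            raise ValueError("exons of one model must share a strand")
        genomic = sorted(exons, key=lambda e: e.start)
        for prev, nxt in zip(genomic, genomic[1:]):
            if nxt.start < prev.end:
                raise ValueError("exons overlap")
        ordered = genomic if strand != "-" else genomic[::-1]
        cds_length = sum(e.length for e in ordered)
        return cls(
            gene_id=gene_id,
            exons=tuple(ordered),
            cds_length=cds_length,
            protein_length=cds_length // 3 - 1,
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into SequenceRecords (order preserved)."""
    path = Path(path)
    with open(path) as handle:
        first = None
        for lineno, line in enumerate(handle, 1):
            if line.strip():
                first = (lineno, line)
                break
        if first is None:
            raise FormatError(f"{path}: empty file (line 1)")
        lineno, line = first
        if not line.startswith(">"):
            raise FormatError(f"{path}: line {lineno}: expected FASTA header '>'")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(
            SequenceRecord(id=rec.id, seq=str(rec.seq), description=rec.description)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

_GB_TYPE_MAP = {
    "CDS": "CDS",
    "exon": "exon",
    "repeat_region": "repeat",
    "mobile_element": "TE",
    "LTR": "LTR",
    "stop_codon": "stop_codon",
}


def read_genbank_features(path):
    """Parse a GenBank flat file into (SequenceRecord, [Feature], [SplicedGeneModel]).

    CDS ``join(...)`` locations (either strand; ``complement(join(...))`` is
    normalized by Biopython) become SplicedGeneModels with exons in
    transcription order.  Coordinates are converted from GenBank 1-based
    inclusive to internal 0-based half-open.
    """
    path = Path(path)
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise FormatError(f"{path}: not a readable GenBank record: {exc}") from exc
    try:
        seq = str(rec.seq).upper()
    except Exception as exc:  # Bio.Seq.UndefinedSequenceError: no ORIGIN block
        raise FormatError(f"{path}: missing ORIGIN sequence block: {exc}") from exc
    if not seq:
        raise FormatError(f"{path}: missing or empty ORIGIN sequence block")
    record = SequenceRecord(id=rec.id, seq=seq, description=rec.description)

    features: list[Feature] = []
    models: list[SplicedGeneModel] = []
    n_cds = 0
    for feat in rec.features:
        ftype = _GB_TYPE_MAP.get(feat.type)
        if ftype is None:
            continue
        strand = {1: "+", -1: "-", None: "."}[feat.location.strand]
        parts = sorted(feat.location.parts, key=lambda p: int(p.start))
        for part in parts:
            start, end = int(part.start), int(part.end)
            if not (0 <= start < end <= len(seq)):
                raise FormatError(
                    f"{path}: feature {feat.type} span [{start},{end}) outside "
                    f"sequence of length {len(seq)}"
                )
        if ftype == "CDS":
            n_cds += 1
            gene_id = feat.qualifiers.get(
                "gene", feat.qualifiers.get("locus_tag", [f"cds_{n_cds}"])
            )[0]
            exons = [
                Feature(record.id, "exon", int(p.start), int(p.end), strand,
                        {"gene_id": gene_id})
                for p in parts
            ]
            features.extend(exons)
            models.append(SplicedGeneModel.from_exons(gene_id, exons))
        else:
            for part in parts:
                features.append(
                    Feature(record.id, ftype, int(part.start), int(part.end), strand,
                            {k: v[0] for k, v in feat.qualifiers.items()})
                )
    return record, features, models


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


class TranslationError(ValueError):
    pass


def spliced_cds(record: SequenceRecord, model: SplicedGeneModel) -> str:
    """Concatenate exon sequences in transcription order (strand-adjusted)."""
    parts = []
    for exon in model.exons:
        sub = record.seq[exon.start:exon.end]
        if exon.strand == "-":
            sub = revcomp(sub)
        parts.append(sub)
    return "".join(parts)


def translate_spliced(record: SequenceRecord, model: SplicedGeneModel) -> str:
    """Standard-code translation of a spliced CDS, excluding the terminal stop.

    The CDS must begin with ATG, end in a stop codon, and contain no internal
    stop codon; violations raise TranslationError naming the offending codon.
    """
    cds = spliced_cds(record, model)
    if len(cds) % 3 != 0:
        raise TranslationError(f"CDS length {len(cds)} not divisible by 3")
    if not cds.startswith("ATG"):
        raise TranslationError(f"CDS does not start with ATG (got {cds[:3]})")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    if codons[-1] not in _STANDARD_TABLE.stop_codons:
        raise TranslationError(f"CDS does not end in a stop codon (got {codons[-1]})")
    protein = []
    for idx, codon in enumerate(codons[:-1]):
        if codon in _STANDARD_TABLE.stop_codons:
            raise TranslationError(f"internal stop codon {codon} at codon index {idx}")
        protein.append(_STANDARD_TABLE.forward_table[codon])
    return "".join(protein)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Feature serialization: GFF3 / BED
# ---------------------------------------------------------------------------

def write_bed(features: Iterable[Feature], path) -> None:
    """Write features as BED6 (0-based half-open, as stored internally)."""
    with open(path, "w") as out:
        for f in features:
            name = f.attrs.get("Name", f.attrs.get("gene_id", f.type))
            out.write(f"{f.seq_id}\t{f.start}\t{f.end}\t{name}\t0\t{f.strand}\n")


def read_bed(path) -> list[Feature]:
    feats = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}: line {lineno}: BED needs >= 3 columns")
            ftype = cols[3] if len(cols) > 3 and cols[3] in FEATURE_TYPES else "other"
            strand = cols[5] if len(cols) > 5 else "."
            attrs = {"Name": cols[3]} if len(cols) > 3 else {}
            feats.append(Feature(cols[0], ftype, int(cols[1]), int(cols[2]),
                                 strand, attrs))
    return feats


def write_gff3(features: Iterable[Feature], path) -> None:
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in sorted(f.attrs.items())) or "."
            out.write(
                f"{f.seq_id}\tjunctioneer\t{f.type}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


def read_gff3(path) -> list[Feature]:
    feats = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}: line {lineno}: GFF3 needs 9 columns")
            ftype = cols[2] if cols[2] in FEATURE_TYPES else "other"
            attrs = {}
            if cols[8] != ".":
                for item in cols[8].split(";"):
                    if "=" in item:
                        k, v = item.split("=", 1)
                        attrs[k] = v
            feats.append(
                Feature(cols[0], ftype, int(cols[3]) - 1, int(cols[4]), cols[6], attrs)
            )
    return feats


# ---------------------------------------------------------------------------
# Tabular report writing (TSV / JSON / BED)
# ---------------------------------------------------------------------------

def write_reports(rows: Sequence[dict], path, fmt: str, columns=None) -> None:
    """Write a list of flat dict rows as TSV, JSON or BED.

    Column order is deterministic: the ``columns`` argument if given, else the
    sorted union of keys.  BED rows must carry seq_id/start/end (+ optional
    name/strand).  TSV and JSON round-trip losslessly through
    :func:`read_report`.
    """
    fmt = fmt.upper()
    if fmt not in ("TSV", "JSON", "BED"):
        raise ValueError(f"unknown report format {fmt!r} (use TSV, JSON or BED)")
    rows = list(rows)
    if fmt == "JSON":
        with open(path, "w") as out:
            json.dump(rows, out, indent=2, sort_keys=True)
            out.write("\n")
        return
    if fmt == "BED":
        with open(path, "w") as out:
            for r in rows:
                out.write(
                    f"{r['seq_id']}\t{r['start']}\t{r['end']}\t"
                    f"{r.get('name', '.')}\t0\t{r.get('strand', '.')}\n"
                )
        return
    if columns is None:
        keys = set()
        for r in rows:
            keys.update(r)
        columns = sorted(keys)
    with open(path, "w") as out:
        out.write("\t".join(columns) + "\n")
        for r in rows:
            out.write("\t".join(_tsv_cell(r.get(c)) for c in columns) + "\n")


def _tsv_cell(value) -> str:
    if value is None:
        return ""
    return json.dumps(value) if isinstance(value, (list, dict)) else str(value)


def read_report(path, fmt: str) -> list[dict]:
    fmt = fmt.upper()
    if fmt == "JSON":
        with open(path) as handle:
            return json.load(handle)
    if fmt == "TSV":
        with open(path) as handle:
            lines = handle.read().splitlines()
        header = lines[0].split("\t")
        return [dict(zip(header, line.split("\t"))) for line in lines[1:]]
    raise ValueError(f"unknown report format {fmt!r}")
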