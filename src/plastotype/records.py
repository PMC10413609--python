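"""Annotated circular plastome records and GenBank/FASTA I/O.

Internal coordinates are 0-based, half-open. GenBank flat files use 1-based
inclusive coordinates; conversion happens only at the I/O boundary. Features
that span the circular origin are stored as a single exon with ``wraps=True``
rather than being split, so one gene is always one feature.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from ._util import revcomp
from .errors import ContractError, CoordinateError, FormatError, ParameterError

CATEGORIES = ("protein-coding", "tRNA", "rRNA")

_GB_TYPE = {"protein-coding": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}
_GB_TYPE_INV = {"CDS": "protein-coding", "tRNA": "tRNA", "rRNA": "rRNA"}


def _category_from_name(name: str) -> str:
    if name.startswith("trn"):
        return "tRNA"
    if name.startswith("rrn"):
        return "rRNA"
    return "protein-coding"


@dataclass(frozen=True)
class GenomeInterval:
    """Half-open interval on a (possibly circular) sequence.

    ``wraps`` marks intervals that cross the origin; their effective length is
    ``(L - start) + end`` where ``L`` is the sequence length.
    """

    start: int
    end: int
    wraps: bool = False
    strand: str = "+"

    def length(self, seq_len: int | None = None) -> int:
        if self.wraps:
            if seq_len is None:
                raise ParameterError("wrapping interval needs the sequence length")
            return (seq_len - self.start) + self.end
        return self.end - self.start

    def midpoint(self, seq_len: int) -> int:
        return (self.start + self.length(seq_len) // 2) % seq_len

    def contains(self, pos: int, seq_len: int) -> bool:
        pos %= seq_len
        if self.wraps:
            return pos >= self.start or pos < self.end
        return self.start <= pos < self.end

    def shifted(self, offset: int, seq_len: int) -> "GenomeInterval":
        """Interval after rotating the origin by ``offset`` (new = old - offset)."""
        length = self.length(seq_len)
        ns = (self.start - offset) % seq_len
        ne_raw = ns + length
        if ne_raw <= seq_len:
            return replace(self, start=ns, end=ne_raw, wraps=False)
        return replace(self, start=ns, end=ne_raw - seq_len, wraps=True)


@dataclass
class GeneFeature:
    """A gene with one or more exon intervals on a fixed strand."""

    name: str
    category: str
    exons: list[GenomeInterval]
    pseudo: bool = False
    trans_spliced: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ContractError("feature name must be non-empty")
        if self.category not in CATEGORIES:
            raise ParameterError(f"unknown feature category {self.category!r}")
        if not self.exons:
            raise ContractError(f"feature {self.name} has no exons")

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    def span_start(self) -> int:
        """5'-most genomic offset by coordinate (minimum exon start)."""
        return min(e.start for e in self.exons)

    def total_length(self, seq_len: int) -> int:
        return sum(e.length(seq_len) for e in self.exons)

    def midpoint(self, seq_len: int) -> int:
        first = self.exons[0]
        if len(self.exons) == 1:
            return first.midpoint(seq_len)
        half = self.total_length(seq_len) // 2
        for exon in self.exons:
            elen = exon.length(seq_len)
            if half < elen:
                return (exon.start + half) % seq_len
            half -= elen
        return first.midpoint(seq_len)


@dataclass
class PlastomeRecord:
    """A circular plastid genome: sequence plus typed gene features."""

    identifier: str
    organism: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ContractError("sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)

    def interval_sequence(self, interval: GenomeInterval) -> str:
        s = self.sequence
        if interval.wraps:
            return s[interval.start :] + s[: interval.end]
        return s[interval.start : interval.end]

    def feature_sequence(self, feature: GeneFeature) -> str:
        """Spliced coding-strand sequence of a feature."""
        parts = [self.interval_sequence(e) for e in feature.exons]
        seq = "".join(parts)
        return revcomp(seq) if feature.strand == "-" else seq

    def features_named(self, name: str) -> list[GeneFeature]:
        return [f for f in self.features if f.name == name]


@dataclass
class GeneStats:
    """Table-1-style gene statistics.

    Totals count every annotated feature instance (IR-duplicated genes count
    twice, pseudogenes included); unique counts distinct gene names.
    """

    total_genes: int
    unique_genes: int
    protein_coding_total: int
    protein_coding_unique: int
    trna_total: int
    trna_unique: int
    rrna_total: int
    rrna_unique: int
    intron_gene_names: set[str]
    trans_spliced_gene_names: set[str]
    gc_total: float
    gc_lsc: float | None = None
    gc_ssc: float | None = None
    gc_ir: float | None = None


# ---------------------------------------------------------------------------
# sequence statistics


def gc_content(seq_or_record, interval: GenomeInterval | None = None) -> float:
    """GC fraction of a sequence (or an interval of a record); N bases are
    excluded from both numerator and denominator."""
    if isinstance(seq_or_record, PlastomeRecord):
        seq = (
            seq_or_record.interval_sequence(interval)
            if interval is not None
            else seq_or_record.sequence
        )
    else:
        seq = seq_or_record
    if not seq:
        raise ContractError("empty sequence")
    gc = seq.count("G") + seq.count("C")
    atgc = gc + seq.count("A") + seq.count("T")
    if atgc == 0:
        raise ContractError("all-N sequence: GC content undefined")
    return gc / atgc


def gene_statistics(record: PlastomeRecord, partition=None) -> GeneStats:
    """Count genes per category; per-region GC only when a partition is given."""
    totals = {c: 0 for c in CATEGORIES}
    names: dict[str, set[str]] = {c: set() for c in CATEGORIES}
    intron_names: set[str] = set()
    trans_names: set[str] = set()
    for f in record.features:
        totals[f.category] += 1
        names[f.category].add(f.name)
        if f.trans_spliced:
            trans_names.add(f.name)
        elif len(f.exons) >= 2:
            intron_names.add(f.name)
    all_names = set().union(*names.values()) if record.features else set()
    kw: dict = {}
    if partition is not None and not partition.ir_absent:
        kw["gc_lsc"] = gc_content(record, partition.lsc)
        kw["gc_ssc"] = gc_content(record, partition.ssc)
        kw["gc_ir"] = gc_content(record, partition.irb)
    return GeneStats(
        total_genes=sum(totals.values()),
        unique_genes=len(all_names),
        protein_coding_total=totals["protein-coding"],
        protein_coding_unique=len(names["protein-coding"]),
        trna_total=totals["tRNA"],
        trna_unique=len(names["tRNA"]),
        rrna_total=totals["rRNA"],
        rrna_unique=len(names["rRNA"]),
        intron_gene_names=intron_names,
        trans_spliced_gene_names=trans_names,
        gc_total=gc_content(record.sequence),
        **kw,
    )


# ---------------------------------------------------------------------------
# rotation


def rotate_to_gene(record: PlastomeRecord, gene: str) -> PlastomeRecord:
    """Rotate a circular record so ``gene`` starts at offset 0.

    If the gene is absent the record is returned unchanged with a warning
    appended (plastome convention: rotate to trnH-GUG).
    """
    if not record.circular:
        raise ContractError("rotation requires a circular record")
    hits = record.features_named(gene)
    if not hits:
        out = replace_record(record)
        out.warnings = record.warnings + [f"rotation gene {gene} absent; unrotated"]
        return out
    origin = hits[0].span_start()
    return rotate(record, origin)


def rotate(record: PlastomeRecord, origin: int) -> PlastomeRecord:
    L = len(record)
    origin %= L
    seq = record.sequence[origin:] + record.sequence[:origin]
    feats = [
        GeneFeature(
            name=f.name,
            category=f.category,
            exons=[e.shifted(origin, L) for e in f.exons],
            pseudo=f.pseudo,
            trans_spliced=f.trans_spliced,
        )
        for f in record.features
    ]
    return PlastomeRecord(
        identifier=record.identifier,
        organism=record.organism,
        sequence=seq,
        circular=record.circular,
        features=feats,
        warnings=list(record.warnings),
    )


def replace_record(record: PlastomeRecord) -> PlastomeRecord:
    """Shallow structural copy of a record."""
    return PlastomeRecord(
        identifier=record.identifier,
        organism=record.organism,
        sequence=record.sequence,
        circular=record.circular,
        features=[
            GeneFeature(f.name, f.category, list(f.exons), f.pseudo, f.trans_spliced)
            for f in record.features
        ],
        warnings=list(record.warnings),
    )


# ---------------------------------------------------------------------------
# GenBank I/O


def _location_for(feature: GeneFeature, seq_len: int):
    parts = []
    for exon in feature.exons:
        strand = 1 if exon.strand == "+" else -1
        if exon.wraps:
            parts.append(SimpleLocation(exon.start, seq_len, strand))
            parts.append(SimpleLocation(0, exon.end, strand))
        else:
            parts.append(SimpleLocation(exon.start, exon.end, strand))
    if len(parts) == 1:
        return parts[0]
    return CompoundLocation(parts, operator="join")


def write_genbank(record: PlastomeRecord, path) -> None:
    """Emit a GenBank flat file; read_genbank(write_genbank(r)) == r."""
    L = len(record)
    seqrec = SeqRecord(
        Seq(record.sequence),
        id=record.identifier,
        name=record.identifier[:16],
        description=record.organism,
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.circular else "linear",
            "organism": record.organism,
            "source": record.organism,
        },
    )
    for f in record.features:
        quals: dict = {"gene": [f.name]}
        if f.trans_spliced:
            quals["trans_splicing"] = [""]
        if any(e.wraps for e in f.exons):
            quals["note"] = ["wraps_origin"]
        if f.pseudo:
            quals["pseudo"] = [""]
            ftype = "gene"
        else:
            ftype = _GB_TYPE[f.category]
        seqrec.features.append(
            SeqFeature(_location_for(f, L), type=ftype, qualifiers=quals)
        )
    with open(path, "w") as fh:
        SeqIO.write(seqrec, fh, "genbank")


def _exons_from_location(location, seq_len: int, wraps_hint: bool) -> list[GenomeInterval]:
    parts = list(location.parts)
    strand = "+" if (parts[0].strand or 1) >= 0 else "-"
    if wraps_hint and len(parts) == 2:
        a, b = parts
        if int(a.end) == seq_len and int(b.start) == 0:
            return [GenomeInterval(int(a.start), int(b.end), wraps=True, strand=strand)]
        if int(b.end) == seq_len and int(a.start) == 0:
            return [GenomeInterval(int(b.start), int(a.end), wraps=True, strand=strand)]
    exons = []
    for p in parts:
        s, e = int(p.start), int(p.end)
        if not (0 <= s < e <= seq_len):
            raise CoordinateError(f"feature part {s}..{e} outside sequence of {seq_len} bp")
        exons.append(GenomeInterval(s, e, strand="+" if (p.strand or 1) >= 0 else "-"))
    return exons


def read_genbank(path) -> PlastomeRecord:
    """Read an annotated plastome from a GenBank flat file.

    CDS/tRNA/rRNA features become typed GeneFeatures; ``gene`` features are
    used only when carrying /pseudo or when no typed feature shares the name.
    Ambiguity codes other than N are normalised to N (count recorded in
    ``warnings``).
    """
    try:
        seqrec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise FormatError(f"cannot parse GenBank file {path}: {exc}") from exc
    raw = str(seqrec.seq).upper()
    if not raw:
        raise FormatError("GenBank record has no sequence")
    seq = re.sub("[^ACGTN]", "N", raw)
    warnings = []
    n_fixed = sum(1 for a, b in zip(raw, seq) if a != b)
    if n_fixed:
        warnings.append(f"normalized {n_fixed} ambiguity bases to N")
    L = len(seq)
    circular = seqrec.annotations.get("topology", "") == "circular"
    features: list[GeneFeature] = []
    typed_names: set[str] = set()
    gene_feats = []
    for sf in seqrec.features:
        name = (sf.qualifiers.get("gene") or sf.qualifiers.get("locus_tag") or [None])[0]
        if name is None:
            continue
        wraps_hint = "wraps_origin" in sf.qualifiers.get("note", [])
        if sf.type in _GB_TYPE_INV:
            features.append(
                GeneFeature(
                    name=name,
                    category=_GB_TYPE_INV[sf.type],
                    exons=_exons_from_location(sf.location, L, wraps_hint),
                    pseudo="pseudo" in sf.qualifiers,
                    trans_spliced="trans_splicing" in sf.qualifiers,
                )
            )
            typed_names.add(name)
        elif sf.type == "gene":
            gene_feats.append((name, sf, wraps_hint))
    for name, sf, wraps_hint in gene_feats:
        if "pseudo" in sf.qualifiers or name not in typed_names:
            features.append(
                GeneFeature(
                    name=name,
                    category=_category_from_name(name),
                    exons=_exons_from_location(sf.location, L, wraps_hint),
                    pseudo="pseudo" in sf.qualifiers,
                    trans_spliced="trans_splicing" in sf.qualifiers,
                )
            )
    return PlastomeRecord(
        identifier=seqrec.id if seqrec.id != "<unknown id>" else seqrec.name,
        organism=seqrec.annotations.get("organism", seqrec.description or ""),
        sequence=seq,
        circular=circular,
        features=features,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# FASTA I/O


def write_fasta(record: PlastomeRecord, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{record.identifier} {record.organism}\n")
        for i in range(0, len(record.sequence), 70):
            fh.write(record.sequence[i : i + 70] + "\n")


def read_fasta(path) -> list[PlastomeRecord]:
    """Read plain FASTA; records come back unannotated and assumed circular."""
    out = []
    for seqrec in SeqIO.parse(str(path), "fasta"):
        raw = str(seqrec.seq).upper()
        seq = re.sub("[^ACGTN]", "N", raw)
        out.append(
            PlastomeRecord(
                identifier=seqrec.id,
                organism=" ".join(seqrec.description.split()[1:]),
                sequence=seq,
            )
        )
    if not out:
        raise FormatError(f"no FASTA records in {path}")
    return out
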