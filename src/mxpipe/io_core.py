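"""Shared domain types and I/O for the pipeline.

Coordinates are GFF3-style 1-based closed everywhere; any half-open arithmetic
is confined to function internals.  Sequences are stored upper-case; RNA is
stored as T internally and converted to U only for display.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")
SS3_ALPHABET = frozenset("HEC")

_ALPHABETS = {
    "nucleotide": NUCLEOTIDE_ALPHABET,
    "protein": PROTEIN_ALPHABET,
    "ss3": SS3_ALPHABET,
}


class ParseError(ValueError):
    """Malformed input file; message names the offending line where known."""


class ValidationError(ValueError):
    """A domain-type invariant was violated."""


class InternalStopError(ValueError):
    """Translation hit a stop codon before the final codon."""

    def __init__(self, record_id: str, positions: list[int]):
        self.record_id = record_id
        self.positions = positions
        super().__init__(
            f"internal stop codon(s) in {record_id} at codon(s) {positions}"
        )


@dataclass(frozen=True)
class SequenceRecord:
    """An identified sequence with an alphabet tag.

    ``id`` is the first whitespace-delimited token of the FASTA header;
    ``description`` holds the remainder.
    """

    id: str
    seq: str
    description: str = ""
    alphabet: str = "nucleotide"

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise ValidationError(f"bad sequence id {self.id!r}")
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.seq:
            raise ValidationError(f"empty sequence for {self.id}")
        allowed = _ALPHABETS[self.alphabet]
        bad = set(self.seq) - allowed
        if bad:
            raise ValidationError(
                f"illegal {self.alphabet} character(s) {sorted(bad)} in {self.id}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class Interval:
    """1-based closed interval."""

    start: int
    end: int

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValidationError(f"bad interval {self.start}..{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Interval") -> bool:
        return self.start <= other.end and other.start <= self.end


def _bases(intervals: Iterable[Interval]) -> set[int]:
    out: set[int] = set()
    for iv in intervals:
        out.update(range(iv.start, iv.end + 1))
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(len(iv) for iv in intervals)


@dataclass
class GeneModel:
    """One mRNA-level gene model.

    Interval lists are sorted by ascending coordinate regardless of strand.
    ``partial`` marks models whose CDS need not be a multiple of 3.
    """

    locus_tag: str
    contig_id: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    partial: bool = False
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValidationError(f"{self.locus_tag}: bad strand {self.strand!r}")
        for name in ("exons", "cds", "utr5", "utr3"):
            setattr(self, name, sorted(getattr(self, name)))

    @property
    def span(self) -> Interval:
        return Interval(self.exons[0].start, self.exons[-1].end)

    @property
    def cds_length(self) -> int:
        return total_length(self.cds)

    def introns(self) -> list[Interval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start - a.end >= 2:
                out.append(Interval(a.end + 1, b.start - 1))
        return out

    def validate(self) -> None:
        if not self.exons:
            raise ValidationError(f"{self.locus_tag}: no exons")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValidationError(f"{self.locus_tag}: overlapping exons")
        exon_bases = _bases(self.exons)
        for name in ("cds", "utr5", "utr3"):
            if not _bases(getattr(self, name)) <= exon_bases:
                raise ValidationError(
                    f"{self.locus_tag}: {name} extends outside exons"
                )
        if self.cds and not self.partial:
            if self.cds_length % 3 != 0 or self.cds_length == 0:
                raise ValidationError(
                    f"{self.locus_tag}: CDS length {self.cds_length} not a "
                    "positive multiple of 3"
                )


@dataclass(frozen=True)
class HitRecord:
    """One row of 12-column tabular pairwise-alignment output."""

    query: str
    subject: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self):
        if self.evalue < 0:
            raise ValidationError(f"negative e-value for {self.query}/{self.subject}")
        if not 0 <= self.pct_identity <= 100:
            raise ValidationError(f"bad identity for {self.query}/{self.subject}")


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline with their defaults.

    Defaults reproduce the screening thresholds of the study this pipeline
    models: RBH e-value cutoff 0.001, dual-targeting consensus >0.5,
    tail-anchor window 32 aa, beta-barrel secondary-structure filters
    (>=25 % strand, <=10 % helix over <=300 aa, <=50 % helix over the
    8-residue beta-signal), cd-hit-style clustering at 100 %/95 % identity
    with equal lengths, last-100-bp 3'UTR window, 10 bp Kozak flanks and
    5 kb coding-density windows.
    """

    evalue_max: float = 0.001
    targeting_prob_min: float = 0.5
    ta_cterm_window: int = 32
    mbomp_context: int = 300
    mbomp_min_strand: float = 0.25
    mbomp_max_helix: float = 0.10
    mbomp_max_signal_helix: float = 0.50
    beta_signal_len: int = 8
    beta_cterm_window: int = 15
    utr3_tail_window: int = 100
    kozak_flank: int = 10
    cluster_exact_identity: float = 1.00
    cluster_near_identity: float = 0.95
    coding_window: int = 5000
    motif_k: int = 6
    telomere_unit: str = "TTAGGG"
    telomere_min_units: int = 5
    telomere_search_window: int = 1000
    telomere_max_mismatch: int = 2
    full_length_tolerance: int = 0
    fusion_overlap_frac: float = 0.5

    def validate(self) -> None:
        for name in (
            "targeting_prob_min", "mbomp_min_strand", "mbomp_max_helix",
            "mbomp_max_signal_helix", "cluster_exact_identity",
            "cluster_near_identity", "fusion_overlap_frac",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name}={v} outside [0,1]")
        for name in (
            "ta_cterm_window", "mbomp_context", "beta_signal_len",
            "utr3_tail_window", "kozak_flank", "coding_window", "motif_k",
            "telomere_min_units", "telomere_search_window",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.evalue_max < 0 or self.full_length_tolerance < 0:
            raise ValidationError("negative threshold")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path, alphabet: str = "nucleotide") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (upper-cased, validated)."""
    path = Path(path)
    records = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # pragma: no cover - SeqIO is lenient
        raise ParseError(f"{path}: {exc}") from exc
    for rec in parsed:
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        try:
            records.append(
                SequenceRecord(rec.id, str(rec.seq), desc, alphabet=alphabet)
            )
        except ValidationError as exc:
            line = _find_offending_line(path, rec.id)
            raise ParseError(f"{path}:{line}: {exc}") from exc
    return records


def _find_offending_line(path: Path, rec_id: str) -> int:
    with open(path) as fh:
        in_rec = False
        for i, line in enumerate(fh, 1):
            if line.startswith(">"):
                in_rec = line[1:].split()[0] == rec_id if line[1:].split() else False
            elif in_rec:
                return i
    return 0


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GFF3

_UTR5_TYPES = {"five_prime_UTR", "5'UTR", "five_prime_utr"}
_UTR3_TYPES = {"three_prime_UTR", "3'UTR", "three_prime_utr"}


def read_gff3(path, infer_utrs: bool = True) -> list[GeneModel]:
    """Read GFF3 into one GeneModel per mRNA.

    When a model has CDS and exons but no annotated UTR features and
    ``infer_utrs`` is set, UTR intervals are inferred as exon bases outside
    the CDS span (5' vs 3' assigned by strand).
    """
    path = Path(path)
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique",
        keep_order=True, checklines=0,
    )
    ids = {f.id for f in db.all_features()}
    for feat in db.all_features():
        for parent in feat.attributes.get("Parent", []):
            if parent not in ids:
                raise ParseError(
                    f"{path}: feature {feat.id or feat.featuretype} references "
                    f"unknown Parent {parent}"
                )
    models = []
    for mrna in db.features_of_type(("mRNA", "transcript"), order_by="start"):
        exons, cds, utr5, utr3 = [], [], [], []
        for child in db.children(mrna):
            iv = Interval(child.start, child.end)
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "CDS":
                cds.append(iv)
            elif child.featuretype in _UTR5_TYPES:
                utr5.append(iv)
            elif child.featuretype in _UTR3_TYPES:
                utr3.append(iv)
        if not exons:
            exons = sorted(set(cds) | set(utr5) | set(utr3))
        tag = mrna.attributes.get("locus_tag", [mrna.id])[0]
        model = GeneModel(
            locus_tag=tag,
            contig_id=mrna.seqid,
            strand=mrna.strand if mrna.strand in "+-" else "+",
            exons=exons,
            cds=cds,
            utr5=utr5,
            utr3=utr3,
            partial="partial" in mrna.attributes.get("note", []),
        )
        if infer_utrs and model.cds and not model.utr5 and not model.utr3:
            _infer_utrs(model)
        if model.cds and total_length(model.cds) % 3 != 0:
            # tolerate partial models from the wild; flag, don't refuse
            model.partial = True
        try:
            model.validate()
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
        models.append(model)
    return models


def _infer_utrs(model: GeneModel) -> None:
    cds_start = model.cds[0].start
    cds_end = model.cds[-1].end
    left, right = [], []
    for ex in model.exons:
        if ex.start < cds_start:
            left.append(Interval(ex.start, min(ex.end, cds_start - 1)))
        if ex.end > cds_end:
            right.append(Interval(max(ex.start, cds_end + 1), ex.end))
    if model.strand == "+":
        model.utr5, model.utr3 = left, right
    else:
        model.utr5, model.utr3 = right, left


def write_gff3(models: Sequence[GeneModel], path) -> None:
    """Write models as gene/mRNA/exon/CDS/UTR features with a version pragma."""
    lines = ["##gff-version 3"]
    for m in sorted(models, key=lambda m: (m.contig_id, m.span.start)):
        gid = f"gene:{m.locus_tag}"
        span = m.span
        base = f"{m.contig_id}\tmxpipe"
        lines.append(
            f"{base}\tgene\t{span.start}\t{span.end}\t.\t{m.strand}\t.\tID={gid}"
        )
        lines.append(
            f"{base}\tmRNA\t{span.start}\t{span.end}\t.\t{m.strand}\t.\t"
            f"ID={m.locus_tag};Parent={gid};locus_tag={m.locus_tag}"
        )
        for iv in m.exons:
            lines.append(
                f"{base}\texon\t{iv.start}\t{iv.end}\t.\t{m.strand}\t.\t"
                f"Parent={m.locus_tag}"
            )
        for iv, phase in zip(m.cds, _cds_phases(m)):
            lines.append(
                f"{base}\tCDS\t{iv.start}\t{iv.end}\t.\t{m.strand}\t{phase}\t"
                f"Parent={m.locus_tag}"
            )
        for iv in m.utr5:
            lines.append(
                f"{base}\tfive_prime_UTR\t{iv.start}\t{iv.end}\t.\t{m.strand}"
                f"\t.\tParent={m.locus_tag}"
            )
        for iv in m.utr3:
            lines.append(
                f"{base}\tthree_prime_UTR\t{iv.start}\t{iv.end}\t.\t{m.strand}"
                f"\t.\tParent={m.locus_tag}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _cds_phases(model: GeneModel) -> list[int]:
    pieces = model.cds if model.strand == "+" else list(reversed(model.cds))
    phases, consumed = [], 0
    for iv in pieces:
        phases.append((3 - consumed % 3) % 3)
        consumed += len(iv)
    return phases if model.strand == "+" else list(reversed(phases))


# ---------------------------------------------------------------------------
# Sequence operations

def as_contig_map(contigs) -> Mapping[str, str]:
    if isinstance(contigs, Mapping):
        return contigs
    return {c.id: c.seq for c in contigs}


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_cds(contigs, model: GeneModel) -> SequenceRecord:
    """Concatenate CDS pieces in ascending order; revcomp on the minus strand."""
    cmap = as_contig_map(contigs)
    if model.contig_id not in cmap:
        raise ValidationError(
            f"{model.locus_tag}: unknown contig {model.contig_id}"
        )
    contig = cmap[model.contig_id]
    parts = []
    for iv in model.cds:
        if iv.end > len(contig):
            raise ValidationError(
                f"{model.locus_tag}: CDS {iv.start}..{iv.end} outside contig "
                f"{model.contig_id} (length {len(contig)})"
            )
        parts.append(contig[iv.start - 1: iv.end])
    seq = "".join(parts)
    if model.strand == "-":
        seq = revcomp(seq)
    return SequenceRecord(model.locus_tag, seq, alphabet="nucleotide")


def spliced_seq(contigs, model: GeneModel, which: str = "exons") -> str:
    """Spliced sequence of a feature class, in transcript (5'->3') orientation."""
    cmap = as_contig_map(contigs)
    contig = cmap[model.contig_id]
    ivs = getattr(model, which)
    seq = "".join(contig[iv.start - 1: iv.end] for iv in ivs)
    return revcomp(seq) if model.strand == "-" else seq


def translate(nt: SequenceRecord, allow_internal_stop: bool = False) -> SequenceRecord:
    """Translate with the standard code; a single terminal stop is trimmed.

    Internal stops raise :class:`InternalStopError` unless explicitly allowed
    (in which case they remain as ``*`` in the protein).
    """
    if len(nt.seq) % 3 != 0:
        raise ValidationError(
            f"{nt.id}: length {len(nt.seq)} is not a multiple of 3"
        )
    aa = str(Seq(nt.seq).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    internal = [i + 1 for i, c in enumerate(aa) if c == "*"]
    if internal and not allow_internal_stop:
        raise InternalStopError(nt.id, internal)
    if not aa:
        raise ValidationError(f"{nt.id}: empty protein after stop trimming")
    return SequenceRecord(nt.id, aa, nt.description, alphabet="protein")


# ---------------------------------------------------------------------------
# Tabular hits

_HIT_COLUMNS = [
    "query", "subject", "pct_identity", "aln_len", "mismatches", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hits(path) -> list[HitRecord]:
    """Read 12-column tabular alignment hits (TSV; '#' lines are comments)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                records.append(HitRecord(
                    fields[0], fields[1], float(fields[2]), int(fields[3]),
                    int(fields[4]), int(fields[5]), int(fields[6]),
                    int(fields[7]), int(fields[8]), int(fields[9]),
                    float(fields[10]), float(fields[11]),
                ))
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_hits(records: Iterable[HitRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(_HIT_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.query}\t{r.subject}\t{r.pct_identity:.2f}\t{r.aln_len}\t"
                f"{r.mismatches}\t{r.gapopen}\t{r.qstart}\t{r.qend}\t"
                f"{r.sstart}\t{r.send}\t{r.evalue:.3g}\t{r.bitscore:.1f}\n"
            )


def cds_sequences(contigs, models: Iterable[GeneModel]) -> dict[str, str]:
    """Locus tag -> CDS nucleotide string for every model with a CDS."""
    cmap = as_contig_map(contigs)
    return {
        m.locus_tag: extract_cds(cmap, m).seq for m in models if m.cds
    }
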