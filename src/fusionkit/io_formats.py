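"""Readers/writers for external formats and the shared coordinate-bearing domain types.

Coordinate convention: 1-based inclusive throughout (GFF3 style).  For a
fusion call, ``bp5`` is the genomic coordinate of the *last* transcribed base
of the 5' segment and ``bp3`` the *first* transcribed base of the 3' segment.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALPHABET = set("ACGTN")
STRANDS = ("+", "-")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class Genome:
    """Chromosome name -> uppercase nucleotide string over {A,C,G,T,N}."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not name:
                raise ValueError("chromosome name must be nonempty")
            if not seq:
                raise ValueError(f"chromosome {name!r} has empty sequence")

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive slice, clipped to the chromosome."""
        seq = self.sequences[chrom]
        if end < start:
            return ""
        return seq[max(start, 1) - 1 : min(end, len(seq))]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])


@dataclass
class Transcript:
    """A gene model: ordered exon (and optionally CDS) intervals, 1-based inclusive."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"transcript {self.transcript_id}: bad strand {self.strand!r}")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for name, ivs in (("exon", self.exons), ("CDS", self.cds)):
            prev_end = 0
            for s, e in ivs:
                if s > e:
                    raise ValueError(
                        f"transcript {self.transcript_id}: {name} interval {s}-{e} inverted"
                    )
                if s <= prev_end:
                    raise ValueError(
                        f"transcript {self.transcript_id}: overlapping {name} intervals"
                    )
                prev_end = e
        for s, e in self.cds:
            if not any(es <= s and e <= ee for es, ee in self.exons):
                raise ValueError(
                    f"transcript {self.transcript_id}: CDS {s}-{e} outside exons"
                )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def exon_order_transcription(self) -> list[tuple[int, int]]:
        """Exons in transcription order (reversed for minus strand)."""
        return self.exons if self.strand == "+" else self.exons[::-1]


@dataclass
class Annotation:
    """gene_id -> (chrom, strand, transcripts)."""

    genes: dict[str, tuple[str, str, list[Transcript]]]

    def transcripts_of(self, gene_id: str) -> list[Transcript]:
        if gene_id not in self.genes:
            raise KeyError(f"unknown gene id: {gene_id}")
        return self.genes[gene_id][2]

    def validate_against(self, genome: Genome) -> None:
        for gene_id, (chrom, _strand, txs) in self.genes.items():
            if chrom not in genome:
                raise ValueError(f"gene {gene_id}: chromosome {chrom} not in genome")
            clen = genome.length(chrom)
            for tx in txs:
                for s, e in tx.exons:
                    if s < 1 or e > clen:
                        raise ValueError(
                            f"transcript {tx.transcript_id}: exon {s}-{e} outside {chrom}"
                        )


@dataclass
class FusionCall:
    """One caller record for a candidate fusion junction."""

    sample_id: str
    tool: str
    gene5: str
    gene3: str
    chrom5: str
    bp5: int
    strand5: str
    chrom3: str
    bp3: int
    strand3: str
    junction_reads: int = 0

    def __post_init__(self) -> None:
        if self.bp5 < 1 or self.bp3 < 1:
            raise ValueError("breakpoints must be >= 1")
        if not self.gene5 or not self.gene3:
            raise ValueError("gene ids must be nonempty")
        if self.strand5 not in STRANDS or self.strand3 not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}")
        if self.junction_reads < 0:
            raise ValueError("junction_reads must be nonnegative")


@dataclass
class AlignmentHit:
    """One row of BLAST tabular outfmt-6 output (optional 13th slen column)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    subject_len: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.pct_identity <= 100:
            raise ValueError(f"pct_identity {self.pct_identity} outside [0, 100]")
        if self.aln_len < 1:
            raise ValueError("alignment length must be >= 1")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Sequences are uppercased; characters outside {A,C,G,T,N} are replaced by
    N (count logged).  Duplicate record names and empty sequences are errors.
    """
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    n_replaced = 0

    def _flush() -> None:
        nonlocal n_replaced
        if name is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise FormatError(f"record {name!r} has empty sequence")
        cleaned = re.sub("[^ACGTN]", "N", seq)
        n_replaced += sum(a != b for a, b in zip(seq, cleaned))
        sequences[name] = cleaned

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                _flush()
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError("FASTA header with empty name")
                if name in sequences:
                    raise FormatError(f"duplicate FASTA record name: {name!r}")
                chunks = []
            elif line:
                if name is None:
                    raise FormatError("sequence data before first FASTA header")
                chunks.append(line.strip())
        _flush()
    if not sequences:
        raise FormatError(f"{path}: no FASTA records found")
    if n_replaced:
        logger.info("read_fasta: replaced %d non-ACGTN characters by N", n_replaced)
    return Genome(sequences)


def write_fasta(path, genome: Genome, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def _gff3_attributes(col: str) -> dict[str, str]:
    out = {}
    for item in col.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gff3(path) -> Annotation:
    """Read gene/mRNA/exon/CDS rows of a GFF3 file into an :class:`Annotation`.

    Exon and CDS rows attach to their mRNA via ``Parent``; orphan parents and
    missing IDs are errors.
    """
    genes: dict[str, tuple[str, str]] = {}  # gene_id -> (chrom, strand)
    mrnas: dict[str, tuple[str, str, str]] = {}  # mrna_id -> (gene_id, chrom, strand)
    exons: dict[str, list[tuple[int, int]]] = {}
    cdss: dict[str, list[tuple[int, int]]] = {}
    deferred: list[tuple[str, str, int, int, int]] = []  # ftype, parent, start, end, lineno

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in ("gene", "mRNA", "exon", "CDS"):
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad coordinates") from exc
            attr = _gff3_attributes(attrs)
            if ftype == "gene":
                if "ID" not in attr:
                    raise FormatError(f"{path}:{lineno}: gene row missing ID")
                genes[attr["ID"]] = (chrom, strand)
            elif ftype == "mRNA":
                if "ID" not in attr:
                    raise FormatError(f"{path}:{lineno}: mRNA row missing ID")
                parent = attr.get("Parent", "")
                if parent not in genes:
                    raise FormatError(
                        f"{path}:{lineno}: mRNA {attr['ID']} has unknown Parent {parent!r}"
                    )
                mrnas[attr["ID"]] = (parent, chrom, strand)
            else:  # exon / CDS, mRNA may appear later in file
                parent = attr.get("Parent", "")
                deferred.append((ftype, parent, start_i, end_i, lineno))

    for ftype, parent, start_i, end_i, lineno in deferred:
        if parent not in mrnas:
            raise FormatError(f"{path}:{lineno}: {ftype} has unknown Parent {parent!r}")
        (exons if ftype == "exon" else cdss).setdefault(parent, []).append((start_i, end_i))

    gene_map: dict[str, tuple[str, str, list[Transcript]]] = {}
    for mrna_id, (gene_id, chrom, strand) in mrnas.items():
        try:
            tx = Transcript(
                transcript_id=mrna_id,
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                exons=exons.get(mrna_id, []),
                cds=cdss.get(mrna_id, []),
            )
        except ValueError as exc:
            raise FormatError(str(exc)) from exc
        if not tx.exons:
            raise FormatError(f"mRNA {mrna_id} has no exon rows")
        if gene_id not in gene_map:
            gchrom, gstrand = genes[gene_id]
            gene_map[gene_id] = (gchrom, gstrand, [])
        gene_map[gene_id][2].append(tx)
    for gene_id, (chrom, strand) in genes.items():
        gene_map.setdefault(gene_id, (chrom, strand, []))
    return Annotation(gene_map)


def write_gff3(path, annotation: Annotation) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, (chrom, strand, txs) in annotation.genes.items():
            span = [(s, e) for tx in txs for s, e in tx.exons]
            gs = min(s for s, _ in span) if span else 1
            ge = max(e for _, e in span) if span else 1
            fh.write(f"{chrom}\tfusionkit\tgene\t{gs}\t{ge}\t.\t{strand}\t.\tID={gene_id}\n")
            for tx in txs:
                ts = min(s for s, _ in tx.exons)
                te = max(e for _, e in tx.exons)
                fh.write(
                    f"{chrom}\tfusionkit\tmRNA\t{ts}\t{te}\t.\t{strand}\t.\t"
                    f"ID={tx.transcript_id};Parent={gene_id}\n"
                )
                for s, e in tx.exons:
                    fh.write(
                        f"{chrom}\tfusionkit\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                        f"Parent={tx.transcript_id}\n"
                    )
                for s, e in tx.cds:
                    fh.write(
                        f"{chrom}\tfusionkit\tCDS\t{s}\t{e}\t.\t{strand}\t0\t"
                        f"Parent={tx.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# Fusion call TSVs

UNIFIED_COLUMNS = [
    "sample_id",
    "tool",
    "gene5",
    "gene3",
    "chrom5",
    "bp5",
    "strand5",
    "chrom3",
    "bp3",
    "strand3",
    "junction_reads",
]


def _parse_breakpoint(token: str, lineno: int) -> tuple[str, int, str]:
    """'chr1:100:+' -> (chr1, 100, +)."""
    parts = token.rsplit(":", 2)
    if len(parts) != 3:
        raise FormatError(f"line {lineno}: malformed breakpoint {token!r}")
    chrom, pos, strand = parts
    try:
        pos_i = int(pos)
    except ValueError as exc:
        raise FormatError(f"line {lineno}: unparseable coordinate {pos!r}") from exc
    if strand not in STRANDS:
        raise FormatError(f"line {lineno}: bad strand {strand!r}")
    return chrom, pos_i, strand


def read_fusion_calls(path, dialect: str = "unified") -> list[FusionCall]:
    """Read fusion calls from TSV in the ``unified`` or ``star_fusion`` dialect."""
    if dialect not in ("unified", "star_fusion"):
        raise ValueError(f"unknown dialect {dialect!r}")
    calls: list[FusionCall] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if dialect == "unified" and header[: len(UNIFIED_COLUMNS)] != UNIFIED_COLUMNS:
            raise FormatError(f"{path}: unexpected unified header {header!r}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                if dialect == "unified":
                    if len(fields) < 11:
                        raise FormatError(f"line {lineno}: expected 11 columns")
                    (sample, tool, g5, g3, c5, bp5, s5, c3, bp3, s3, jr) = fields[:11]
                    if s5 not in STRANDS or s3 not in STRANDS:
                        raise FormatError(f"line {lineno}: bad strand")
                    call = FusionCall(sample, tool, g5, g3, c5, int(bp5), s5, c3, int(bp3), s3, int(jr))
                else:  # star_fusion: fusion_name junction_reads ... LeftBreakpoint RightBreakpoint
                    row = dict(zip(header, fields))
                    g5, _, g3 = row["#FusionName"].partition("--")
                    c5, bp5, s5 = _parse_breakpoint(row["LeftBreakpoint"], lineno)
                    c3, bp3, s3 = _parse_breakpoint(row["RightBreakpoint"], lineno)
                    jr = int(row.get("JunctionReadCount", 0))
                    call = FusionCall(
                        row.get("sample_id", "sample"), "star_fusion",
                        g5, g3, c5, bp5, s5, c3, bp3, s3, jr,
                    )
            except (ValueError, KeyError) as exc:
                if isinstance(exc, FormatError):
                    raise
                raise FormatError(f"{path} line {lineno}: {exc}") from exc
            calls.append(call)
    return calls


def write_fusion_calls(path, calls: list[FusionCall]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(UNIFIED_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        c.sample_id, c.tool, c.gene5, c.gene3, c.chrom5, c.bp5,
                        c.strand5, c.chrom3, c.bp3, c.strand3, c.junction_reads,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BLAST tabular / expression matrix / annotated-fusion TSV


def read_blast_tab(path) -> list[AlignmentHit]:
    """Parse BLAST outfmt-6 tabular output (13th column = subject length if present)."""
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{lineno}: expected >=12 columns, got {len(f)}")
            try:
                hits.append(
                    AlignmentHit(
                        query_id=f[0],
                        subject_id=f[1],
                        pct_identity=float(f[2]),
                        aln_len=int(f[3]),
                        mismatches=int(f[4]),
                        gap_opens=int(f[5]),
                        qstart=int(f[6]),
                        qend=int(f[7]),
                        sstart=int(f[8]),
                        send=int(f[9]),
                        evalue=float(f[10]),
                        bitscore=float(f[11]),
                        subject_len=int(f[12]) if len(f) > 12 and f[12] != "" else None,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_blast_tab(path, hits: list[AlignmentHit]) -> None:
    with open(path, "w") as fh:
        for h in hits:
            row = [
                h.query_id, h.subject_id, f"{h.pct_identity:.2f}", h.aln_len,
                h.mismatches, h.gap_opens, h.qstart, h.qend, h.sstart, h.send,
                f"{h.evalue:.2g}", f"{h.bitscore:.1f}",
            ]
            if h.subject_len is not None:
                row.append(h.subject_len)
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_expression_matrix(path) -> pd.DataFrame:
    """Gene x sample TPM table: first column gene ids, remaining columns samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    if (df.values < 0).any():
        raise FormatError(f"{path}: negative TPM values")
    return df


def write_expression_matrix(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index_label="gene")
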