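"""Structural annotation of fusion junctions.

For each fusion call: locality, exon-boundary class, donor/acceptor splice
motifs, short-homologous-sequence (SHS) detection, reading-frame status,
mechanism category, and the junction query sequence used for long-read
validation.

All sequence windows are taken in the transcription direction of the
relevant parental gene; minus-strand windows are reverse-complemented
genomic slices.  N never matches anything in motif or homology comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import Annotation, FusionCall, Genome, Transcript, revcomp

INTERCHROMOSOMAL = "interchromosomal"
INTRACHROMOSOMAL = "intrachromosomal"

BOUNDARY_BOTH = "both"
BOUNDARY_ONE = "one"
BOUNDARY_NONE = "none"

MECHANISMS = ("canonical_splice", "shs", "both", "other")
FRAMES = ("in_frame", "frameshift", "not_applicable")

DEFAULT_K = 20
DEFAULT_L_MIN = 4
DEFAULT_FLANK = 100


@dataclass
class AnnotatedFusion:
    call: FusionCall
    locality: str
    boundary_class: str
    donor_motif: str
    acceptor_motif: str
    canonical: bool
    shs_len: int
    shs_seq: str
    mechanism: str
    frame: str
    junction_seq: str


@dataclass
class MechanismSummary:
    motif_counts: list[tuple[tuple[str, str], int]]  # sorted by count desc
    category_proportions: dict[str, float]
    locality_proportions: dict[str, float]
    boundary_proportions: dict[str, float]
    n: int


def classify_locality(call: FusionCall) -> str:
    """Interchromosomal iff the parental genes sit on different chromosomes."""
    return INTERCHROMOSOMAL if call.chrom5 != call.chrom3 else INTRACHROMOSOMAL


def _bp5_at_boundary(call: FusionCall, transcripts: list[Transcript]) -> bool:
    """bp5 coincides with the transcription-direction 3' end of some exon."""
    for tx in transcripts:
        for s, e in tx.exons:
            edge = e if tx.strand == "+" else s
            if call.bp5 == edge:
                return True
    return False


def _bp3_at_boundary(call: FusionCall, transcripts: list[Transcript]) -> bool:
    """bp3 coincides with the transcription-direction 5' start of some exon."""
    for tx in transcripts:
        for s, e in tx.exons:
            edge = s if tx.strand == "+" else e
            if call.bp3 == edge:
                return True
    return False


def breakpoint_boundary_class(call: FusionCall, annotation: Annotation) -> str:
    """Classify whether breakpoints lie at exon boundaries of both/one/none
    of the parental genes.  Any annotated isoform counts."""
    tx5 = annotation.transcripts_of(call.gene5)
    tx3 = annotation.transcripts_of(call.gene3)
    n = int(_bp5_at_boundary(call, tx5)) + int(_bp3_at_boundary(call, tx3))
    return (BOUNDARY_NONE, BOUNDARY_ONE, BOUNDARY_BOTH)[n]


def extract_junction_motifs(call: FusionCall, genome: Genome) -> tuple[str, str, bool]:
    """Donor dinucleotide after bp5 and acceptor dinucleotide before bp3,
    each read in the transcription direction of its gene."""
    chrom5_len = genome.length(call.chrom5)
    chrom3_len = genome.length(call.chrom3)
    if call.strand5 == "+":
        if call.bp5 + 2 > chrom5_len:
            raise ValueError("breakpoint too close to contig edge")
        donor = genome.fetch(call.chrom5, call.bp5 + 1, call.bp5 + 2)
    else:
        if call.bp5 - 2 < 1:
            raise ValueError("breakpoint too close to contig edge")
        donor = revcomp(genome.fetch(call.chrom5, call.bp5 - 2, call.bp5 - 1))
    if call.strand3 == "+":
        if call.bp3 - 2 < 1:
            raise ValueError("breakpoint too close to contig edge")
        acceptor = genome.fetch(call.chrom3, call.bp3 - 2, call.bp3 - 1)
    else:
        if call.bp3 + 2 > chrom3_len:
            raise ValueError("breakpoint too close to contig edge")
        acceptor = revcomp(genome.fetch(call.chrom3, call.bp3 + 1, call.bp3 + 2))
    canonical = donor == "GT" and acceptor == "AG"
    return donor, acceptor, canonical


# -- SHS windows -------------------------------------------------------------


def _after_bp5(call: FusionCall, genome: Genome, k: int) -> str:
    """k bases following bp5 in the 5' gene's transcription direction."""
    if call.strand5 == "+":
        return genome.fetch(call.chrom5, call.bp5 + 1, call.bp5 + k)
    return revcomp(genome.fetch(call.chrom5, call.bp5 - k, call.bp5 - 1))


def _last_of_5seg(call: FusionCall, genome: Genome, k: int) -> str:
    """Last k transcribed bases of the 5' segment, ending at bp5."""
    if call.strand5 == "+":
        return genome.fetch(call.chrom5, call.bp5 - k + 1, call.bp5)
    return revcomp(genome.fetch(call.chrom5, call.bp5, call.bp5 + k - 1))


def _first_of_3seg(call: FusionCall, genome: Genome, k: int) -> str:
    """First k transcribed bases of the 3' segment, starting at bp3."""
    if call.strand3 == "+":
        return genome.fetch(call.chrom3, call.bp3, call.bp3 + k - 1)
    return revcomp(genome.fetch(call.chrom3, call.bp3 - k + 1, call.bp3))


def _before_bp3(call: FusionCall, genome: Genome, k: int) -> str:
    """k bases preceding bp3 in the 3' gene's transcription direction."""
    if call.strand3 == "+":
        return genome.fetch(call.chrom3, call.bp3 - k, call.bp3 - 1)
    return revcomp(genome.fetch(call.chrom3, call.bp3 + 1, call.bp3 + k))


def _lcp(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            break
        n += 1
    return n


def detect_shs(
    call: FusionCall,
    genome: Genome,
    k: int = DEFAULT_K,
    l_min: int = DEFAULT_L_MIN,
) -> tuple[int, str]:
    """Short-homologous-sequence length and sequence at the junction.

    f = longest common prefix of (k bases after bp5) and (first k bases of
    the 3' segment); b = longest common suffix of (last k bases of the 5'
    segment) and (k bases before bp3).  Reported only when f + b >= l_min.
    """
    f = _lcp(_after_bp5(call, genome, k), _first_of_3seg(call, genome, k))
    b = _lcp(_last_of_5seg(call, genome, k)[::-1], _before_bp3(call, genome, k)[::-1])
    total = f + b
    if total < l_min:
        return 0, ""
    seq = (_last_of_5seg(call, genome, b) if b else "") + (
        _first_of_3seg(call, genome, f) if f else ""
    )
    return total, seq


def build_junction_query(
    call: FusionCall, genome: Genome, flank: int = DEFAULT_FLANK
) -> str:
    """Junction query sequence: up to ``flank`` transcribed bases ending at
    bp5 followed by up to ``flank`` transcribed bases starting at bp3."""
    return _last_of_5seg(call, genome, flank) + _first_of_3seg(call, genome, flank)


# -- reading frame -----------------------------------------------------------


def _cds_bases_through(tx: Transcript, pos: int, inclusive: bool) -> int | None:
    """Number of CDS bases from the start codon through ``pos`` in
    transcription direction; None when pos is outside the CDS."""
    if not any(s <= pos <= e for s, e in tx.cds):
        return None
    total = 0
    if tx.strand == "+":
        for s, e in tx.cds:
            if e < pos:
                total += e - s + 1
            elif s <= pos:
                total += pos - s + 1 - (0 if inclusive else 1)
    else:
        for s, e in sorted(tx.cds, reverse=True):
            if s > pos:
                total += e - s + 1
            elif e >= pos:
                total += e - pos + 1 - (0 if inclusive else 1)
    return total


def _pick_transcript(
    transcripts: list[Transcript], bp: int, five_prime_side: bool
) -> Transcript | None:
    """Prefer a CDS-bearing transcript whose exon boundary matches the
    breakpoint; otherwise the one with the longest CDS."""
    with_cds = [tx for tx in transcripts if tx.cds]
    if not with_cds:
        return None
    for tx in with_cds:
        for s, e in tx.exons:
            edge = (e if tx.strand == "+" else s) if five_prime_side else (
                s if tx.strand == "+" else e
            )
            if bp == edge:
                return tx
    return max(with_cds, key=lambda tx: tx.cds_length)


def classify_frame(call: FusionCall, annotation: Annotation) -> str:
    """in_frame iff the 5' CDS contribution and the 3' CDS offset agree mod 3;
    not_applicable when either breakpoint falls outside coding sequence."""
    tx5 = _pick_transcript(annotation.transcripts_of(call.gene5), call.bp5, True)
    tx3 = _pick_transcript(annotation.transcripts_of(call.gene3), call.bp3, False)
    if tx5 is None or tx3 is None:
        return "not_applicable"
    l5 = _cds_bases_through(tx5, call.bp5, inclusive=True)
    o3 = _cds_bases_through(tx3, call.bp3, inclusive=False)
    if l5 is None or o3 is None:
        return "not_applicable"
    return "in_frame" if l5 % 3 == o3 % 3 else "frameshift"


# -- composition -------------------------------------------------------------


def _mechanism(canonical: bool, shs_len: int) -> str:
    if canonical and shs_len > 0:
        return "both"
    if canonical:
        return "canonical_splice"
    if shs_len > 0:
        return "shs"
    return "other"


def annotate(
    calls: list[FusionCall],
    genome: Genome,
    annotation: Annotation,
    k: int = DEFAULT_K,
    l_min: int = DEFAULT_L_MIN,
    flank: int = DEFAULT_FLANK,
) -> list[AnnotatedFusion]:
    """Run all junction operators over a list of calls."""
    out: list[AnnotatedFusion] = []
    for i, call in enumerate(calls):
        try:
            donor, acceptor, canonical = extract_junction_motifs(call, genome)
            shs_len, shs_seq = detect_shs(call, genome, k, l_min)
            out.append(
                AnnotatedFusion(
                    call=call,
                    locality=classify_locality(call),
                    boundary_class=breakpoint_boundary_class(call, annotation),
                    donor_motif=donor,
                    acceptor_motif=acceptor,
                    canonical=canonical,
                    shs_len=shs_len,
                    shs_seq=shs_seq,
                    mechanism=_mechanism(canonical, shs_len),
                    frame=classify_frame(call, annotation),
                    junction_seq=build_junction_query(call, genome, flank),
                )
            )
        except (KeyError, ValueError) as exc:
            raise type(exc)(f"row {i}: {exc}") from exc
    return out


def mechanism_summary(annotated: list[AnnotatedFusion]) -> MechanismSummary:
    if not annotated:
        raise ValueError("mechanism_summary requires a nonempty input")
    n = len(annotated)
    motif_counts: dict[tuple[str, str], int] = {}
    cat: dict[str, int] = {m: 0 for m in MECHANISMS}
    loc: dict[str, int] = {}
    bnd: dict[str, int] = {}
    for af in annotated:
        key = (af.donor_motif, af.acceptor_motif)
        motif_counts[key] = motif_counts.get(key, 0) + 1
        cat[af.mechanism] += 1
        loc[af.locality] = loc.get(af.locality, 0) + 1
        bnd[af.boundary_class] = bnd.get(af.boundary_class, 0) + 1
    return MechanismSummary(
        motif_counts=sorted(motif_counts.items(), key=lambda kv: (-kv[1], kv[0])),
        category_proportions={m: c / n for m, c in cat.items()},
        locality_proportions={m: c / n for m, c in loc.items()},
        boundary_proportions={m: c / n for m, c in bnd.items()},
        n=n,
    )


# -- TSV round trip ----------------------------------------------------------

ANNOTATED_COLUMNS = [
    "sample_id", "tool", "gene5", "gene3", "chrom5", "bp5", "strand5",
    "chrom3", "bp3", "strand3", "junction_reads", "locality", "boundary_class",
    "donor", "acceptor", "canonical", "shs_len", "shs_seq", "mechanism",
    "frame", "junction_seq",
]


def write_annotated_fusions(path, records: list[AnnotatedFusion]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATED_COLUMNS) + "\n")
        for r in records:
            c = r.call
            row = [
                c.sample_id, c.tool, c.gene5, c.gene3, c.chrom5, c.bp5,
                c.strand5, c.chrom3, c.bp3, c.strand3, c.junction_reads,
                r.locality, r.boundary_class, r.donor_motif, r.acceptor_motif,
                str(r.canonical).lower(), r.shs_len, r.shs_seq or ".",
                r.mechanism, r.frame, r.junction_seq,
            ]
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_annotated_fusions(path) -> list[AnnotatedFusion]:
    from .io_formats import FormatError

    out: list[AnnotatedFusion] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ANNOTATED_COLUMNS:
            raise FormatError(f"{path}: unexpected header")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != len(ANNOTATED_COLUMNS):
                raise FormatError(f"{path}:{lineno}: wrong column count")
            call = FusionCall(
                f[0], f[1], f[2], f[3], f[4], int(f[5]), f[6], f[7], int(f[8]),
                f[9], int(f[10]),
            )
            out.append(
                AnnotatedFusion(
                    call=call, locality=f[11], boundary_class=f[12],
                    donor_motif=f[13], acceptor_motif=f[14],
                    canonical=f[15] == "true", shs_len=int(f[16]),
                    shs_seq="" if f[17] == "." else f[17], mechanism=f[18],
                    frame=f[19], junction_seq=f[20],
                )
            )
    return out
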