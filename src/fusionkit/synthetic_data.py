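"""Seeded synthetic fixtures: toy genome + annotation, planted fusion events
of known mechanism, correlated expression, long-read hit tables and qPCR Ct
tables.  Every generator is a pure function of its seed.

Planted mechanism labels and what the junction annotator must recover:

==================  ==================  ===============  =================
label               mechanism           boundary_class   locality
==================  ==================  ===============  =================
canonical_boundary  canonical_splice    both             (either)
canonical_novel     canonical_splice    none             (either)
canonical_shs       both                none             (either)
shs                 shs                 none             (either)
noncanonical        other               none             (either)
readthrough         canonical_splice    both             intrachromosomal
==================  ==================  ===============  =================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import (
    AlignmentHit,
    Annotation,
    FusionCall,
    Genome,
    Transcript,
    revcomp,
)

MECHANISM_LABELS = (
    "canonical_boundary",
    "canonical_novel",
    "canonical_shs",
    "shs",
    "noncanonical",
    "readthrough",
)

_EXPECTED = {
    "canonical_boundary": ("canonical_splice", "both"),
    "canonical_novel": ("canonical_splice", "none"),
    "canonical_shs": ("both", "none"),
    "shs": ("shs", "none"),
    "noncanonical": ("other", "none"),
    "readthrough": ("canonical_splice", "both"),
}

_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PlantedFusion:
    """Ground truth for one planted fusion event."""

    mechanism_label: str
    call: FusionCall
    expected_mechanism: str
    expected_boundary: str
    expected_frame: str
    shs_len: int  # engineered homology length (0 when none planted)
    fused_seq: str  # contiguous fused-transcript context around the junction


# ---------------------------------------------------------------------------
# Genome + annotation


def generate_genome(
    n_chroms: int,
    chrom_len: int,
    n_genes: int,
    seed: int,
    with_n: bool = False,
) -> tuple[Genome, Annotation]:
    """Random multi-chromosome genome with non-overlapping multi-exon genes
    on both strands, canonical GT/AG (strand-aware) at every intron edge, and
    whole-exon CDS on roughly half the genes."""
    if chrom_len < 5000:
        raise ValueError("chrom_len must be >= 5000")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seqs = {
        f"chr{i + 1}": bytearray(
            rng.choice(bases, size=chrom_len).tobytes()
        )
        for i in range(n_chroms)
    }
    if with_n:
        for chrom in seqs.values():
            for _ in range(3):
                start = int(rng.integers(0, chrom_len - 20))
                chrom[start : start + int(rng.integers(5, 15))] = b"N" * 15

    chrom_names = list(seqs)
    genes: dict[str, tuple[str, str, list[Transcript]]] = {}
    cursors = {c: 200 for c in chrom_names}
    for gi in range(n_genes):
        chrom = chrom_names[gi % n_chroms]
        n_exons = int(rng.integers(2, 7))
        exon_lens = rng.integers(80, 201, size=n_exons)
        intron_lens = rng.integers(60, 151, size=n_exons - 1)
        start = cursors[chrom] + int(rng.integers(100, 301))
        exons: list[tuple[int, int]] = []
        pos = start
        for j in range(n_exons):
            exons.append((pos, pos + int(exon_lens[j]) - 1))
            pos = exons[-1][1] + 1
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        end = exons[-1][1]
        if end > chrom_len - 200:
            raise ValueError(
                f"infeasible packing: gene {gi + 1} does not fit on {chrom}"
            )
        cursors[chrom] = end
        strand = "+" if rng.random() < 0.5 else "-"
        # strand-aware canonical intron edges: +: GT...AG ; -: CT...AC
        seq = seqs[chrom]
        for (s1, e1), (s2, _e2) in zip(exons, exons[1:]):
            if strand == "+":
                seq[e1 : e1 + 2] = b"GT"
                seq[s2 - 3 : s2 - 1] = b"AG"
            else:
                seq[e1 : e1 + 2] = b"CT"
                seq[s2 - 3 : s2 - 1] = b"AC"
        gene_id = f"gene{gi + 1:04d}"
        has_cds = rng.random() < 0.5
        tx = Transcript(
            transcript_id=f"{gene_id}.1",
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            exons=exons,
            cds=list(exons) if has_cds else [],
        )
        genes[gene_id] = (chrom, strand, [tx])

    genome = Genome({c: s.decode() for c, s in seqs.items()})
    return genome, Annotation(genes)


# ---------------------------------------------------------------------------
# Fusion planting


def _ts_shift(pos: int, strand: str, d: int) -> int:
    """Genomic position d bases downstream (transcription direction)."""
    return pos + d if strand == "+" else pos - d


def _ts_read(seqs: dict[str, bytearray], chrom: str, strand: str, pos: int, n: int) -> str:
    """Read n bases starting at pos moving downstream in transcription
    direction (complemented for minus strand), clipped at contig edges."""
    out = []
    L = len(seqs[chrom])
    for i in range(n):
        p = _ts_shift(pos, strand, i)
        if not 1 <= p <= L:
            break
        ch = chr(seqs[chrom][p - 1])
        out.append(ch if strand == "+" else ch.translate(_COMP))
    return "".join(out)


def _ts_write(seqs: dict[str, bytearray], chrom: str, strand: str, pos: int, s: str) -> None:
    for i, ch in enumerate(s):
        p = _ts_shift(pos, strand, i)
        base = ch if strand == "+" else ch.translate(_COMP)
        seqs[chrom][p - 1] = ord(base)


def _other_base(rng: np.random.Generator, *avoid: str) -> str:
    choices = [b for b in "ACGT" if b not in avoid]
    return choices[int(rng.integers(0, len(choices)))]


def _mid_exon_position(tx: Transcript, rng: np.random.Generator, margin: int = 30) -> int:
    candidates = [(s, e) for s, e in tx.exons if e - s + 1 > 2 * margin + 2]
    s, e = candidates[int(rng.integers(0, len(candidates)))]
    return int(rng.integers(s + margin, e - margin + 1))


def _tx_bases_through(tx: Transcript, pos: int, inclusive: bool) -> int:
    """Transcribed (exonic) bases from transcript start through pos."""
    if tx.strand == "+":
        n = sum(min(e, pos) - s + 1 for s, e in tx.exons if s <= pos)
    else:
        n = sum(e - max(s, pos) + 1 for s, e in tx.exons if e >= pos)
    return n if inclusive else n - 1


def _expected_frame(tx5: Transcript, bp5: int, tx3: Transcript, bp3: int) -> str:
    if not tx5.cds or not tx3.cds:
        return "not_applicable"
    l5 = _tx_bases_through(tx5, bp5, inclusive=True)
    o3 = _tx_bases_through(tx3, bp3, inclusive=False)
    return "in_frame" if l5 % 3 == o3 % 3 else "frameshift"


def plant_fusions(
    genome: Genome,
    annotation: Annotation,
    counts: dict[str, int],
    seed: int,
    samples: tuple[str, ...] = ("S1", "S2", "S3", "S4"),
    tools: tuple[str, ...] = ("toolA", "toolB", "toolC"),
) -> tuple[list[FusionCall], list[PlantedFusion]]:
    """Plant fusion events of the requested mechanisms, editing the genome in
    place where an event requires engineered motifs or homology.

    Each event also emits duplicate calls attributed to 2-3 pseudo-tools so
    downstream deduplication has work to do.  Genes are never reused across
    events.
    """
    for label in counts:
        if label not in MECHANISM_LABELS:
            raise ValueError(f"unknown mechanism label {label!r}")
    rng = np.random.default_rng(seed)
    seqs = {c: bytearray(s, "ascii") for c, s in genome.sequences.items()}

    gene_ids = list(annotation.genes)
    order = [gene_ids[i] for i in rng.permutation(len(gene_ids))]
    free = iter(order)
    used: set[str] = set()

    def _next_gene() -> Transcript:
        for gid in free:
            if gid not in used:
                used.add(gid)
                return annotation.transcripts_of(gid)[0]
        raise ValueError("not enough free genes to plant all events")

    def _adjacent_pair() -> tuple[Transcript, Transcript]:
        # two genes adjacent on the same chromosome, neither used yet
        by_chrom: dict[str, list[str]] = {}
        for gid, (chrom, _s, _t) in annotation.genes.items():
            by_chrom.setdefault(chrom, []).append(gid)
        for chrom, gids in by_chrom.items():
            gids.sort(key=lambda g: annotation.transcripts_of(g)[0].exons[0][0])
            for a, b in zip(gids, gids[1:]):
                if a not in used and b not in used:
                    used.update((a, b))
                    return (
                        annotation.transcripts_of(a)[0],
                        annotation.transcripts_of(b)[0],
                    )
        raise ValueError("no free adjacent gene pair for readthrough event")

    def _scrub_homology(c5, bp5, s5, c3, bp3, s3) -> None:
        # force f = 0: first base of the 3' segment must differ from the
        # first base after bp5; force b = 0: the base at bp5 must differ
        # from the base just before bp3 (all in transcription direction)
        x = _ts_read(seqs, c5, s5, _ts_shift(bp5, s5, 1), 1)
        _ts_write(seqs, c3, s3, bp3, _other_base(rng, x, "N"))
        y = _ts_read(seqs, c3, s3, _ts_shift(bp3, s3, -1), 1)
        _ts_write(seqs, c5, s5, bp5, _other_base(rng, y, "N"))

    calls: list[FusionCall] = []
    planted: list[PlantedFusion] = []
    event_idx = 0

    for label, n_events in counts.items():
        for _ in range(n_events):
            event_idx += 1
            shs_k = 0
            if label == "readthrough":
                tx5, tx3 = _adjacent_pair()
            else:
                tx5, tx3 = _next_gene(), _next_gene()
            c5, s5 = tx5.chrom, tx5.strand
            c3, s3 = tx3.chrom, tx3.strand

            if label in ("canonical_boundary", "readthrough"):
                # donor/acceptor supplied by the genes' own intron motifs
                ex5 = tx5.exon_order_transcription()
                i = int(rng.integers(0, len(ex5) - 1))  # not the last exon
                bp5 = ex5[i][1] if s5 == "+" else ex5[i][0]
                ex3 = tx3.exon_order_transcription()
                j = int(rng.integers(1, len(ex3)))  # not the first exon
                bp3 = ex3[j][0] if s3 == "+" else ex3[j][1]
                _scrub_homology(c5, bp5, s5, c3, bp3, s3)
            elif label == "canonical_novel":
                bp5 = _mid_exon_position(tx5, rng)
                bp3 = _mid_exon_position(tx3, rng)
                _ts_write(seqs, c5, s5, _ts_shift(bp5, s5, 1), "GT")
                _ts_write(seqs, c3, s3, _ts_shift(bp3, s3, -2), "AG")
                _scrub_homology(c5, bp5, s5, c3, bp3, s3)
            elif label == "canonical_shs":
                bp5 = _mid_exon_position(tx5, rng)
                bp3 = _mid_exon_position(tx3, rng)
                shs_k = int(rng.integers(4, 10))
                kmer = "GT" + "".join(
                    "ACGT"[int(rng.integers(0, 4))] for _ in range(shs_k - 2)
                )
                _ts_write(seqs, c5, s5, _ts_shift(bp5, s5, 1), kmer)
                _ts_write(seqs, c3, s3, bp3, kmer)
                _ts_write(seqs, c3, s3, _ts_shift(bp3, s3, -2), "AG")
            elif label == "shs":
                bp5 = _mid_exon_position(tx5, rng)
                bp3 = _mid_exon_position(tx3, rng)
                shs_k = int(rng.integers(4, 10))
                first = _other_base(rng, "G")  # donor cannot start GT
                kmer = first + "".join(
                    "ACGT"[int(rng.integers(0, 4))] for _ in range(shs_k - 1)
                )
                _ts_write(seqs, c5, s5, _ts_shift(bp5, s5, 1), kmer)
                _ts_write(seqs, c3, s3, bp3, kmer)
            elif label == "noncanonical":
                bp5 = _mid_exon_position(tx5, rng)
                bp3 = _mid_exon_position(tx3, rng)
                donor = _ts_read(seqs, c5, s5, _ts_shift(bp5, s5, 1), 2)
                if donor == "GT":
                    _ts_write(seqs, c5, s5, _ts_shift(bp5, s5, 2), "C")
                acceptor = _ts_read(seqs, c3, s3, _ts_shift(bp3, s3, -2), 2)
                if acceptor == "AG":
                    _ts_write(seqs, c3, s3, _ts_shift(bp3, s3, -2), "C")
                _scrub_homology(c5, bp5, s5, c3, bp3, s3)
            else:  # pragma: no cover
                raise AssertionError(label)

            seg5 = _ts_read(seqs, c5, s5, _ts_shift(bp5, s5, -299), 300)
            seg3 = _ts_read(seqs, c3, s3, bp3, 300)
            n_dups = int(rng.integers(2, 4))
            tool_sel = [tools[t] for t in rng.permutation(len(tools))[:n_dups]]
            sample = samples[int(rng.integers(0, len(samples)))]
            event_calls = [
                FusionCall(
                    sample_id=sample,
                    tool=tool,
                    gene5=tx5.gene_id,
                    gene3=tx3.gene_id,
                    chrom5=c5,
                    bp5=bp5,
                    strand5=s5,
                    chrom3=c3,
                    bp3=bp3,
                    strand3=s3,
                    junction_reads=int(rng.integers(3, 60)),
                )
                for tool in tool_sel
            ]
            calls.extend(event_calls)
            mech, boundary = _EXPECTED[label]
            planted.append(
                PlantedFusion(
                    mechanism_label=label,
                    call=event_calls[0],
                    expected_mechanism=mech,
                    expected_boundary=boundary,
                    expected_frame=_expected_frame(tx5, bp5, tx3, bp3),
                    shs_len=shs_k,
                    fused_seq=seg5 + seg3,
                )
            )

    genome.sequences = {c: s.decode() for c, s in seqs.items()}
    return calls, planted


# ---------------------------------------------------------------------------
# Expression / long reads / qPCR


def simulate_expression(
    annotation: Annotation,
    fusions: list[FusionCall],
    n_samples: int,
    rho: float,
    fusion_effect: float,
    seed: int,
    base_log_tpm: float = np.log(50.0),
    gene_sd: float = 1.2,
    sample_sd: float = 0.25,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Log-normal TPM matrix with pairwise-correlated parental genes.

    Parental pairs share a latent gene-level factor giving log-scale
    correlation ~ ``rho`` across pairs; in designated fusion-present (F/P)
    samples both parents are scaled by ``fusion_effect``.  Returns the
    gene x sample TPM table and the fusion -> F/P-sample map.
    """
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    if fusion_effect <= 0:
        raise ValueError("fusion_effect must be > 0")
    rng = np.random.default_rng(seed)
    gene_ids = list(annotation.genes)
    sample_ids = [f"sample{i + 1}" for i in range(n_samples)]

    mu = {g: None for g in gene_ids}
    for call in fusions:
        if mu.get(call.gene5) is None and mu.get(call.gene3) is None:
            z = rng.normal()
            mu[call.gene5] = base_log_tpm + gene_sd * (
                np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.normal()
            )
            mu[call.gene3] = base_log_tpm + gene_sd * (
                np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.normal()
            )
    for g in gene_ids:
        if mu[g] is None:
            mu[g] = base_log_tpm + gene_sd * rng.normal()

    log_tpm = np.array(
        [[mu[g] + sample_sd * rng.normal() for _ in sample_ids] for g in gene_ids]
    )
    tpm = pd.DataFrame(np.exp(log_tpm), index=gene_ids, columns=sample_ids)

    presence: dict[str, set[str]] = {}
    for call in fusions:
        fusion_id = f"{call.gene5}_{call.gene3}"
        n_fp = max(1, min(n_samples - 1, n_samples // 2))
        fp = {sample_ids[i] for i in rng.permutation(n_samples)[:n_fp]}
        presence[fusion_id] = fp
        for g in (call.gene5, call.gene3):
            tpm.loc[g, sorted(fp)] *= fusion_effect
    return tpm, presence


def simulate_longread_hits(
    fusion_ids: list[str],
    n_true: int,
    n_decoy: int,
    seed: int,
    min_identity: float = 80.0,
    min_len: int = 150,
) -> tuple[list[AlignmentHit], dict[str, bool]]:
    """True hits clear both validation thresholds; decoys straddle exactly
    one threshold each (alternating identity-fail / length-fail).  Returns
    hits (with the slen column populated) plus query -> expected-validated."""
    rng = np.random.default_rng(seed)
    hits: list[AlignmentHit] = []
    truth: dict[str, bool] = {}

    def _hit(qid: str, ident: float, length: int) -> AlignmentHit:
        slen = int(rng.integers(400, 1500))
        sstart = int(rng.integers(1, max(2, slen - length)))
        return AlignmentHit(
            query_id=qid,
            subject_id=f"read{rng.integers(1, 10**6):06d}",
            pct_identity=round(float(ident), 2),
            aln_len=length,
            mismatches=int(round(length * (100 - ident) / 100)),
            gap_opens=0,
            qstart=1,
            qend=length,
            sstart=sstart,
            send=sstart + length - 1,
            evalue=1e-30,
            bitscore=round(2.0 * length * ident / 100, 1),
            subject_len=slen,
        )

    for i in range(n_true):
        qid = fusion_ids[i % len(fusion_ids)]
        ident = float(rng.uniform(min_identity + 1, 100))
        length = int(rng.integers(min_len + 2, min_len + 51))
        hits.append(_hit(qid, ident, length))
        truth[qid] = True
    for i in range(n_decoy):
        qid = f"decoy{i + 1:03d}"
        if i % 2 == 0:  # fails identity only
            ident = float(rng.uniform(50, min_identity))
            length = int(rng.integers(min_len + 2, min_len + 51))
        else:  # fails length only (boundary value included)
            ident = float(rng.uniform(min_identity + 1, 100))
            length = int(rng.integers(50, min_len + 1))
        hits.append(_hit(qid, ident, length))
        truth[qid] = False
    return hits, truth


def simulate_qpcr(
    fold_change: float,
    n_reps: int,
    noise_sd: float,
    seed: int,
    target: str = "fusion1",
    reference: str = "EF1a",
    control_label: str = "control",
    treated_label: str = "treated",
) -> pd.DataFrame:
    """Replicated Ct table with a stable reference gene; the treated-group
    target Ct is shifted by -log2(fold_change)."""
    if fold_change <= 0:
        raise ValueError("fold_change must be > 0")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    for group in (control_label, treated_label):
        shift = -np.log2(fold_change) if group == treated_label else 0.0
        for rep in range(1, n_reps + 1):
            sample = f"{group}_{rep}"
            rows.append(
                (sample, group, reference, 20.0 + noise_sd * rng.normal(), rep)
            )
            rows.append(
                (sample, group, target, 25.0 + shift + noise_sd * rng.normal(), rep)
            )
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "gene", "ct", "replicate"]
    )


def make_benchmark_sets(
    truth_calls: list[FusionCall],
    tool_specs: dict[str, tuple[int, int]],
    seed: int,
) -> tuple[dict[str, list[FusionCall]], list[tuple[str, str]]]:
    """Per-tool prediction sets with exactly (n_tp, n_fp) planted: n_tp calls
    copied from the truth set plus n_fp calls on invented gene pairs."""
    rng = np.random.default_rng(seed)
    truth_pairs = sorted({(c.gene5, c.gene3) for c in truth_calls})
    by_pair = {(c.gene5, c.gene3): c for c in truth_calls}
    out: dict[str, list[FusionCall]] = {}
    for tool, (n_tp, n_fp) in tool_specs.items():
        if n_tp > len(truth_pairs):
            raise ValueError(f"{tool}: n_tp exceeds truth size")
        picks = [truth_pairs[i] for i in rng.permutation(len(truth_pairs))[:n_tp]]
        preds = []
        for pair in picks:
            c = by_pair[pair]
            preds.append(
                FusionCall(
                    c.sample_id, tool, c.gene5, c.gene3, c.chrom5, c.bp5,
                    c.strand5, c.chrom3, c.bp3, c.strand3, c.junction_reads,
                )
            )
        for i in range(n_fp):
            preds.append(
                FusionCall(
                    "S1", tool, f"fake{tool}{i}a", f"fake{tool}{i}b", "chr1",
                    int(rng.integers(1000, 40000)), "+", "chr1",
                    int(rng.integers(1000, 40000)), "+", 5,
                )
            )
        out[tool] = preds
    return out, truth_pairs
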