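"""Cross-tool/cross-sample deduplication into unique fusions and gene pairs,
plus coding-potential consensus voting."""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .io_formats import FusionCall


@dataclass
class UniqueFusion:
    """A merged fusion: one representative breakpoint pair plus provenance."""

    gene5: str
    gene3: str
    chrom5: str
    strand5: str
    chrom3: str
    strand3: str
    bp5: int
    bp3: int
    junction_reads: int
    tools: set[str] = field(default_factory=set)
    samples: set[str] = field(default_factory=set)
    members: list[FusionCall] = field(default_factory=list)

    @property
    def fusion_id(self) -> str:
        return f"{self.gene5}_{self.gene3}@{self.chrom5}:{self.bp5}-{self.chrom3}:{self.bp3}"


@dataclass
class FusionGenePair:
    """Ordered (5' gene, 3' gene) pair aggregated over unique fusions."""

    gene5: str
    gene3: str
    isoform_breakpoints: set[tuple[int, int]]
    tools: set[str]
    samples: set[str]

    @property
    def n_isoforms(self) -> int:
        return len(self.isoform_breakpoints)


@dataclass
class CodingVote:
    fusion_id: str
    votes: dict[str, str]  # tool -> {coding, noncoding}
    consensus: str  # coding | noncoding | undetermined


def deduplicate(calls: list[FusionCall], bp_tolerance: int = 0) -> list[UniqueFusion]:
    """Merge calls that agree on ordered gene pair, chromosomes, strands and
    breakpoints within ``bp_tolerance``.

    The representative breakpoint is that of the member call with the most
    junction reads (ties: smallest (bp5, bp3)).  Greedy in input order; with
    tolerance 0 this is an exact-key merge.
    """
    if bp_tolerance < 0:
        raise ValueError("bp_tolerance must be >= 0")
    clusters: dict[tuple, list[UniqueFusion]] = {}
    out: list[UniqueFusion] = []
    for call in calls:
        key = (call.gene5, call.gene3, call.chrom5, call.strand5, call.chrom3, call.strand3)
        hit = None
        for uf in clusters.get(key, []):
            if any(
                abs(m.bp5 - call.bp5) <= bp_tolerance
                and abs(m.bp3 - call.bp3) <= bp_tolerance
                for m in uf.members
            ):
                hit = uf
                break
        if hit is None:
            hit = UniqueFusion(
                gene5=call.gene5, gene3=call.gene3, chrom5=call.chrom5,
                strand5=call.strand5, chrom3=call.chrom3, strand3=call.strand3,
                bp5=call.bp5, bp3=call.bp3, junction_reads=call.junction_reads,
            )
            clusters.setdefault(key, []).append(hit)
            out.append(hit)
        hit.members.append(call)
        hit.tools.add(call.tool)
        hit.samples.add(call.sample_id)
        # representative breakpoint: most junction reads, ties by smallest coords
        best = min(
            hit.members, key=lambda m: (-m.junction_reads, m.bp5, m.bp3)
        )
        hit.bp5, hit.bp3, hit.junction_reads = best.bp5, best.bp3, best.junction_reads
    return out


def aggregate_pairs(
    unique_fusions: list[UniqueFusion],
) -> tuple[list[FusionGenePair], dict[str, int], int]:
    """Collapse unique fusions to ordered gene pairs.

    Returns (pairs, partner_degree, n_fusion_genes) where partner_degree maps
    each gene to its number of distinct partner genes (either side).
    """
    pairs: dict[tuple[str, str], FusionGenePair] = {}
    partners: dict[str, set[str]] = {}
    for uf in unique_fusions:
        key = (uf.gene5, uf.gene3)
        if key not in pairs:
            pairs[key] = FusionGenePair(uf.gene5, uf.gene3, set(), set(), set())
        p = pairs[key]
        p.isoform_breakpoints.add((uf.bp5, uf.bp3))
        p.tools |= uf.tools
        p.samples |= uf.samples
        partners.setdefault(uf.gene5, set()).add(uf.gene3)
        partners.setdefault(uf.gene3, set()).add(uf.gene5)
    degree = {g: len(ps) for g, ps in partners.items()}
    return list(pairs.values()), degree, len(partners)


def gene_fraction(n_fusion_genes: int, n_annotated_genes: int) -> float:
    """Percentage of annotated genes involved in fusions, rounded half-up to
    one decimal."""
    if n_annotated_genes <= 0:
        raise ValueError("n_annotated_genes must be > 0")
    pct = Decimal(100 * n_fusion_genes) / Decimal(n_annotated_genes)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


VOTE_LABELS = ("coding", "noncoding")


def coding_vote(vote_table: dict[str, dict[str, str]]) -> list[CodingVote]:
    """Consensus coding-potential call: a label wins with >= 2 concordant
    tool votes, otherwise undetermined.

    ``vote_table`` maps fusion_id -> {tool: label}.
    """
    out: list[CodingVote] = []
    for fusion_id, votes in vote_table.items():
        for tool, label in votes.items():
            if label not in VOTE_LABELS:
                raise ValueError(f"{fusion_id}/{tool}: unknown label {label!r}")
        if len(votes) > 3:
            raise ValueError(f"{fusion_id}: more than 3 votes")
        n_coding = sum(1 for v in votes.values() if v == "coding")
        n_noncoding = len(votes) - n_coding
        if n_coding >= 2:
            consensus = "coding"
        elif n_noncoding >= 2:
            consensus = "noncoding"
        else:
            consensus = "undetermined"
        out.append(CodingVote(fusion_id, dict(votes), consensus))
    return out


# -- TSV interfaces ----------------------------------------------------------


def write_pairs(path, pairs: list[FusionGenePair]) -> None:
    with open(path, "w") as fh:
        fh.write("gene5\tgene3\tn_isoforms\tbreakpoints\ttools\tsamples\n")
        for p in sorted(pairs, key=lambda p: (p.gene5, p.gene3)):
            bps = ";".join(f"{a}-{b}" for a, b in sorted(p.isoform_breakpoints))
            fh.write(
                f"{p.gene5}\t{p.gene3}\t{p.n_isoforms}\t{bps}\t"
                f"{','.join(sorted(p.tools))}\t{','.join(sorted(p.samples))}\n"
            )


def write_votes(path, votes: list[CodingVote]) -> None:
    tools = sorted({t for v in votes for t in v.votes})
    with open(path, "w") as fh:
        fh.write("fusion_id\t" + "\t".join(tools) + "\tconsensus\n")
        for v in votes:
            cols = [v.votes.get(t, ".") for t in tools]
            fh.write(v.fusion_id + "\t" + "\t".join(cols) + f"\t{v.consensus}\n")
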