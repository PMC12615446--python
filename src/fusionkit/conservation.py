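"""Presence/absence conservation of fusion gene pairs across genotypes, with
hierarchical clustering of genotypes and ortholog-mapped cross-species
conservation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist

Pair = tuple[str, str]


@dataclass
class PresenceMatrix:
    pair_ids: list[Pair]  # ordered (gene5, gene3)
    genotypes: list[str]
    cells: np.ndarray  # shape (len(pair_ids), len(genotypes)), values {0,1}

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.shape != (len(self.pair_ids), len(self.genotypes)):
            raise ValueError("matrix dimensions inconsistent with labels")
        if not np.isin(self.cells, (0, 1)).all():
            raise ValueError("cells must be binary")

    def row_sums(self) -> np.ndarray:
        return self.cells.sum(axis=1)


def build_presence_matrix(
    reference_pairs: list[Pair],
    per_genotype_pair_sets: dict[str, set[Pair]],
) -> PresenceMatrix:
    """cell = 1 iff the ordered pair was detected in >= 1 sample of the genotype."""
    genotypes = list(per_genotype_pair_sets)
    if len(genotypes) != len(set(genotypes)):
        raise ValueError("genotype names must be unique")
    cells = np.zeros((len(reference_pairs), len(genotypes)), dtype=np.int8)
    for j, g in enumerate(genotypes):
        pset = set(per_genotype_pair_sets[g])
        for i, pair in enumerate(reference_pairs):
            if pair in pset:
                cells[i, j] = 1
    return PresenceMatrix(list(reference_pairs), genotypes, cells)


def conserved_pairs(
    matrix: PresenceMatrix, min_genotypes: int = 10
) -> tuple[int, int, list[Pair]]:
    """Counts of pairs present in >= 2 genotypes ("conserved") and in
    >= ``min_genotypes`` genotypes; returns the latter list."""
    if min_genotypes < 1:
        raise ValueError("min_genotypes must be >= 1")
    sums = matrix.row_sums()
    n_ge2 = int((sums >= 2).sum())
    selected = [p for p, s in zip(matrix.pair_ids, sums) if s >= min_genotypes]
    return n_ge2, len(selected), selected


def cluster_genotypes(
    matrix: PresenceMatrix, metric: str = "jaccard", method: str = "average"
) -> np.ndarray:
    """Agglomerative clustering of genotype columns on their binary profiles.

    Returns the scipy linkage matrix; column order (ties included) is
    deterministic for a given input.
    """
    if len(matrix.genotypes) < 2:
        raise ValueError("need >= 2 genotypes to cluster")
    profiles = matrix.cells.T.astype(bool)
    dist = pdist(profiles, metric=metric)
    return linkage(dist, method=method)


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = to_tree(z)

    def _walk(node) -> tuple[str, float]:
        if node.is_leaf():
            return labels[node.id], node.dist
        left, _ = _walk(node.left)
        right, _ = _walk(node.right)
        ldist = node.dist - node.left.dist
        rdist = node.dist - node.right.dist
        return f"({left}:{ldist:.6g},{right}:{rdist:.6g})", node.dist

    body, _ = _walk(tree)
    return body + ";"


def map_orthologous_fusions(
    pairs: list[Pair],
    ortholog_table: list[Pair],
    foreign_fusion_pairs: list[Pair],
) -> list[Pair]:
    """Native pairs conserved in another species via orthology.

    (g5, g3) is conserved iff some foreign pair (h5, h3) exists with
    h5 orthologous to g5 and h3 orthologous to g3 (direction preserved;
    many-to-many orthology allowed).
    """
    orth: dict[str, set[str]] = {}
    for native, foreign in ortholog_table:
        orth.setdefault(native, set()).add(foreign)
    foreign_set = set(foreign_fusion_pairs)
    out: list[Pair] = []
    for g5, g3 in pairs:
        o5 = orth.get(g5, set())
        o3 = orth.get(g3, set())
        if any((h5, h3) in foreign_set for h5 in o5 for h3 in o3):
            out.append((g5, g3))
    return out


# -- TSV / Newick interfaces -------------------------------------------------


def read_genotype_pair_lists(path) -> dict[str, set[Pair]]:
    """TSV columns: genotype, gene5, gene3 (header optional)."""
    out: dict[str, set[Pair]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or (lineno == 1 and line.lower().startswith("genotype\t")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            out.setdefault(fields[0], set()).add((fields[1], fields[2]))
    return out


def read_pair_table(path) -> list[Pair]:
    """Two-column TSV of gene pairs (header optional)."""
    out: list[Pair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and fields[0].lower() in ("gene5", "gene_a", "native"):
                continue
            out.append((fields[0], fields[1]))
    return out


def write_presence_matrix(path, matrix: PresenceMatrix) -> None:
    with open(path, "w") as fh:
        fh.write("pair\t" + "\t".join(matrix.genotypes) + "\n")
        for (g5, g3), row in zip(matrix.pair_ids, matrix.cells):
            fh.write(f"{g5}_{g3}\t" + "\t".join(str(int(v)) for v in row) + "\n")
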