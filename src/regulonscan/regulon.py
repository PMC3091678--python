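"""Predicted regulons, cross-genome conservation and the regulon tree.

A genome's regulon at a p-value threshold is the union of member genes
of every TU whose best site passes the threshold.  Two regulons R_i, R_j
are compared through ortholog pairs:

    c_ij = |R_i ∩ R_j| / (|R_i| + |R_j| - |R_i ∩ R_j|)

where the intersection counts ortholog pairs with one member in each
regulon (a Jaccard index in ortholog space).  The tree-building distance
is d_ij = 1/c_ij with a finite cap for c = 0 pairs and a forced zero
diagonal; a neighbor-joining tree of the genomes is built from d.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .orthology import OrthologMap
from .scanner import ScanHit
from .sequence_model import InputError

logger = logging.getLogger(__name__)


@dataclass
class Regulon:
    genome_id: str
    genes: frozenset[str]
    threshold: float

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ConservationMatrix:
    genome_ids: tuple[str, ...]
    c: np.ndarray  # similarity, c(i,i) = 1
    d: np.ndarray  # distance, d(i,i) = 0

    def write_phylip(self, path: str | Path) -> None:
        """Square PHYLIP distance matrix (names padded to 10 characters)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.genome_ids)}\n")
            for name, row in zip(self.genome_ids, self.d):
                fh.write(f"{name[:10]:<10}" + " ".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def read_phylip(cls, path: str | Path) -> "ConservationMatrix":
        with open(path) as fh:
            ntax = int(fh.readline())
            names, rows = [], []
            for _ in range(ntax):
                line = fh.readline()
                names.append(line[:10].strip())
                rows.append([float(v) for v in line[10:].split()])
        d = np.array(rows)
        with np.errstate(divide="ignore"):
            c = np.where(d > 0, 1.0 / d, 1.0)
        return cls(tuple(names), c, d)


def predict_regulon(
    hits: Sequence[ScanHit],
    tus_by_id: Mapping[str, object],
    threshold: float = 0.01,
) -> Regulon:
    """All genes of every TU whose hit p-value is strictly below threshold."""
    genes: set[str] = set()
    genome_id = ""
    for h in hits:
        genome_id = genome_id or h.genome_id
        if not h.valid or h.pvalue is None or h.pvalue >= threshold:
            continue
        genes.update(tus_by_id[h.tu_id].gene_ids)
    return Regulon(genome_id=genome_id, genes=frozenset(genes), threshold=threshold)


def regulon_conservation(
    r_i: Regulon, r_j: Regulon, ortholog_map: OrthologMap
) -> float:
    """Jaccard-style conservation c in [0, 1] between two regulons.

    Returns NaN (with a warning) when both regulons are empty.
    """
    if len(r_i) == 0 and len(r_j) == 0:
        warnings.warn(
            f"conservation undefined: regulons of {r_i.genome_id} and "
            f"{r_j.genome_id} are both empty",
            stacklevel=2,
        )
        return float("nan")
    shared = 0
    for gene in r_i.genes:
        partner = ortholog_map.orthologs_of(r_i.genome_id, gene).get(r_j.genome_id)
        if partner is not None and partner in r_j.genes:
            shared += 1
    return shared / (len(r_i) + len(r_j) - shared)


def conservation_distance_matrix(
    regulons: Sequence[Regulon],
    ortholog_map: OrthologMap,
    zero_cap: float | None = None,
) -> ConservationMatrix:
    """Pairwise c and d = 1/c with c = 0 mapped to a finite capped distance.

    ``zero_cap`` defaults to 10x the largest finite off-diagonal distance.
    The diagonal is forced to 0 (NJ needs it), reading the reciprocal rule
    as off-diagonal only.
    """
    ngen = len(regulons)
    ids = tuple(r.genome_id for r in regulons)
    c = np.eye(ngen)
    undefined = []
    for i in range(ngen):
        for j in range(i + 1, ngen):
            cij = regulon_conservation(regulons[i], regulons[j], ortholog_map)
            if np.isnan(cij):
                undefined.append((ids[i], ids[j]))
            c[i, j] = c[j, i] = cij
    if undefined:
        raise InputError(f"conservation undefined for genome pairs: {undefined}")
    with np.errstate(divide="ignore"):
        d = np.where(c > 0, 1.0 / np.where(c > 0, c, 1.0), np.inf)
    finite_off = d[np.isfinite(d) & ~np.eye(ngen, dtype=bool)]
    if zero_cap is None:
        zero_cap = 10.0 * float(finite_off.max()) if finite_off.size else 10.0
    logger.info("zero-conservation distance cap: %g", zero_cap)
    d[~np.isfinite(d)] = zero_cap
    np.fill_diagonal(d, 0.0)
    return ConservationMatrix(ids, c, d)


def neighbor_joining(matrix: ConservationMatrix) -> TreeNode:
    """Unrooted NJ tree from the regulon distance matrix.

    Negative branch lengths are clamped to zero with the deficit moved to
    the adjacent branch (standard practice).
    """
    if len(matrix.genome_ids) < 3:
        raise InputError("neighbor joining needs at least 3 genomes")
    dm = DistanceMatrix(matrix.d, ids=list(matrix.genome_ids))
    return nj(dm, neg_as_zero=True)


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def write_regulons_tsv(regulons: Sequence[Regulon], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tthreshold\tn_genes\tgenes\n")
        for r in regulons:
            fh.write(
                f"{r.genome_id}\t{r.threshold:g}\t{len(r)}\t{','.join(sorted(r.genes))}\n"
            )
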