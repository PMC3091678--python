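"""Bidirectional-best-hit (BDBH) orthology from precomputed hit tables.

Two cross-genome proteins are called orthologs when each is the other's
best hit (minimum E-value) and both E-values pass the cutoff (default
1e-10).  BLASTP itself is external; this module consumes its tabular
output (outfmt 6: qseqid sseqid ... evalue bitscore).

Ties in best-hit E-values are broken by higher bitscore, then by
lexicographic subject id, so the resulting map is independent of input
row order.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

if TYPE_CHECKING:
    from .sequence_model import GenomeBundle, UpstreamRegion

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrthologPair:
    genome_a: str
    gene_a: str
    genome_b: str
    gene_b: str
    evalue_ab: float = 0.0
    evalue_ba: float = 0.0


@dataclass
class OrthologMap:
    """Symmetric store of ortholog pairs, queryable from either side."""

    pairs: list[OrthologPair] = field(default_factory=list)

    def __post_init__(self):
        self._index: dict[tuple[str, str], dict[str, str]] = {}
        for p in self.pairs:
            self._register(p)

    def _register(self, p: OrthologPair) -> None:
        self._index.setdefault((p.genome_a, p.gene_a), {})[p.genome_b] = p.gene_b
        self._index.setdefault((p.genome_b, p.gene_b), {})[p.genome_a] = p.gene_a

    def add(self, p: OrthologPair) -> None:
        self.pairs.append(p)
        self._register(p)

    def orthologs_of(self, genome_id: str, gene_id: str) -> dict[str, str]:
        """genome_k -> ortholog gene id, for every genome with an ortholog."""
        return dict(self._index.get((genome_id, gene_id), {}))

    def __len__(self) -> int:
        return len(self.pairs)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("genome_a\tgene_a\tgenome_b\tgene_b\tevalue_ab\tevalue_ba\n")
            for p in self.pairs:
                fh.write(
                    f"{p.genome_a}\t{p.gene_a}\t{p.genome_b}\t{p.gene_b}"
                    f"\t{p.evalue_ab:g}\t{p.evalue_ba:g}\n"
                )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "OrthologMap":
        pairs = []
        with open(path) as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader, None)
            for row in reader:
                if not row:
                    continue
                pairs.append(
                    OrthologPair(row[0], row[1], row[2], row[3], float(row[4]), float(row[5]))
                )
        return cls(pairs)


def read_hit_table(path: str | Path) -> list[tuple[str, str, float, float]]:
    """Read a BLAST outfmt-6-like table as (query, subject, evalue, bitscore).

    Accepts either the full 12-column format (evalue and bitscore in the
    last two columns) or a minimal 4-column one.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 columns")
            try:
                evalue, bitscore = float(cols[-2]), float(cols[-1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad evalue/bitscore") from exc
            hits.append((cols[0], cols[1], evalue, bitscore))
    return hits


def _best_hits(
    hits: Iterable[tuple[str, str, float, float]]
) -> dict[str, tuple[str, float]]:
    """Best (min E-value) hit per query; ties by higher bitscore then
    lexicographic subject id; self-hits ignored."""
    best: dict[str, tuple[float, float, str]] = {}  # query -> (evalue, -bit, subject)
    for q, s, ev, bit in hits:
        if q == s:
            continue
        key = (ev, -bit, s)
        if q not in best or key < best[q]:
            best[q] = key
    return {q: (s, ev) for q, (ev, _nb, s) in best.items()}


def reciprocal_best_hits(
    hits_ab: Iterable[tuple[str, str, float, float]],
    hits_ba: Iterable[tuple[str, str, float, float]],
    genome_a: str = "A",
    genome_b: str = "B",
    evalue_cutoff: float = 1e-10,
) -> OrthologMap:
    """BDBH ortholog pairs between two genomes from the two hit tables.

    A pair (a, b) is kept iff b is a's best hit, a is b's best hit, and
    both E-values are <= ``evalue_cutoff``.
    """
    hits_ab, hits_ba = list(hits_ab), list(hits_ba)
    if not hits_ab or not hits_ba:
        logger.warning("empty hit table for %s/%s; ortholog map is empty", genome_a, genome_b)
        return OrthologMap([])
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    pairs = []
    for a, (b, ev_ab) in sorted(best_ab.items()):
        back = best_ba.get(b)
        if back is None or back[0] != a:
            continue
        ev_ba = back[1]
        if ev_ab <= evalue_cutoff and ev_ba <= evalue_cutoff:
            pairs.append(OrthologPair(genome_a, a, genome_b, b, ev_ab, ev_ba))
    return OrthologMap(pairs)


def ortholog_upstreams(
    gene_id: str,
    genome_id: str,
    ortholog_map: OrthologMap,
    bundles: Mapping[str, "GenomeBundle"],
) -> list[tuple[str, "UpstreamRegion"]]:
    """Upstream regions of the TUs holding each ortholog of ``gene_id``.

    One region per genome holding an ortholog (two orthologs in the same
    TU of a genome resolve to that genome's single region).  Genomes whose
    ortholog TU has no extractable region are skipped with a warning.
    """
    out = []
    for genome_k, gene_k in sorted(ortholog_map.orthologs_of(genome_id, gene_id).items()):
        bundle = bundles.get(genome_k)
        if bundle is None:
            continue
        tu_id = bundle.tu_of_gene.get(gene_k)
        region = bundle.regions.get(tu_id) if tu_id else None
        if region is None:
            logger.warning(
                "ortholog %s/%s of %s has no extractable upstream region; skipped",
                genome_k, gene_k, gene_id,
            )
            continue
        out.append((genome_k, region))
    return out
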