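"""Genome sequences, transcription units, upstream regions, background model.

The scanned search space is the *upstream inter-TU region* of each
transcription unit (TU): the genomic sequence between the TU's first gene
and the adjacent upstream gene body (any strand), truncated to the
immediate upstream ``cap`` bases when longer, plus the first
``coding_extension`` bases of the TU's leading gene.  All sequences are
reported 5'->3' on the TU's coding strand.

Coordinates are 1-based inclusive internally (GFF3 convention); BED output
is 0-based half-open.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from ._alphabet import BASES, encode, revcomp

logger = logging.getLogger(__name__)


class InputError(ValueError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Gene:
    gene_id: str
    genome_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # '+' or '-'
    replicon_id: str

    def __post_init__(self):
        if self.start > self.end:
            raise InputError(
                f"gene {self.gene_id}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in "+-":
            raise InputError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TranscriptionUnit:
    tu_id: str
    genome_id: str
    gene_ids: tuple[str, ...]  # ordered 5'->3' on the coding strand
    strand: str


@dataclass
class UpstreamRegion:
    region_id: str
    tu_id: str | None
    genome_id: str
    sequence: str  # 5'->3' on the TU's coding strand
    replicon_id: str | None = None
    start: int | None = None  # genomic interval, 1-based inclusive
    end: int | None = None
    strand: str = "+"
    kind: str = "interTU"  # or "null_coding"
    intertu_length: int | None = None  # bases of the region that are inter-TU
    flagged: bool = False

    def __post_init__(self):
        if self.intertu_length is None:
            self.intertu_length = len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BackgroundModel:
    genome_id: str
    q: np.ndarray  # frequencies over A,C,G,T

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        if q.shape != (4,) or not np.all(q > 0) or abs(q.sum() - 1.0) > 1e-9:
            raise InputError(f"invalid background frequencies {q!r}")
        object.__setattr__(self, "q", q)

    def freq(self, base: str) -> float:
        return float(self.q[BASES.index(base)])


@dataclass
class GenomeBundle:
    """One genome's sequence, annotation, TUs and derived artifacts."""

    genome_id: str
    sequences: dict[str, str]  # replicon_id -> sequence
    genes: list[Gene]
    tus: list[TranscriptionUnit] = field(default_factory=list)
    regions: dict[str, UpstreamRegion] = field(default_factory=dict)  # tu_id ->
    background: BackgroundModel | None = None

    def __post_init__(self):
        self.genes_by_id = {g.gene_id: g for g in self.genes}
        if len(self.genes_by_id) != len(self.genes):
            raise InputError(f"duplicate gene ids in genome {self.genome_id}")

    @property
    def tu_of_gene(self) -> dict[str, str]:
        try:
            return self._tu_of_gene
        except AttributeError:
            self._tu_of_gene = {
                gid: tu.tu_id for tu in self.tus for gid in tu.gene_ids
            }
            return self._tu_of_gene

    def invalidate_caches(self) -> None:
        for attr in ("_tu_of_gene", "_coding_pool"):
            if hasattr(self, attr):
                delattr(self, attr)

    @property
    def coding_pool(self):
        """Encoded coding-strand CDS sequences for null sampling.

        Returns (pool, offsets, lengths): one concatenated int8 array and,
        per gene, its slice offset and length within it.
        """
        try:
            return self._coding_pool
        except AttributeError:
            parts, offsets, lengths = [], [], []
            pos = 0
            for g in self.genes:
                seq = self.sequences[g.replicon_id][g.start - 1 : g.end]
                if g.strand == "-":
                    seq = revcomp(seq)
                parts.append(encode(seq))
                offsets.append(pos)
                lengths.append(len(seq))
                pos += len(seq)
            pool = (
                np.concatenate(parts) if parts else np.empty(0, dtype=np.int8)
            )
            self._coding_pool = (
                pool,
                np.array(offsets, dtype=np.int64),
                np.array(lengths, dtype=np.int64),
            )
            return self._coding_pool


# ---------------------------------------------------------------------------
# loading


def _parse_gene_tsv(path: Path, genome_id: str, replicons: Sequence[str]) -> list[Gene]:
    genes = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[1:2] and not row[1].lstrip("-").isdigit():
                continue  # header row
            if len(row) < 4:
                raise InputError(f"{path}:{lineno}: expected >=4 columns, got {len(row)}")
            gene_id, start, end, strand = row[:4]
            replicon = row[4] if len(row) > 4 else None
            if replicon is None:
                if len(replicons) != 1:
                    raise InputError(
                        f"{path}:{lineno}: no replicon column but FASTA has "
                        f"{len(replicons)} replicons"
                    )
                replicon = replicons[0]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: bad coordinates {start!r}/{end!r}") from exc
            genes.append(Gene(gene_id, genome_id, start_i, end_i, strand, replicon))
    return genes


def _parse_gff3(path: Path, genome_id: str) -> list[Gene]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    feature_types = ["gene"] if "gene" in set(db.featuretypes()) else ["CDS"]
    genes = []
    for ft in feature_types:
        for feat in db.features_of_type(ft):
            gid = feat.attributes.get("ID", feat.attributes.get("locus_tag", [feat.id]))[0]
            genes.append(Gene(gid, genome_id, feat.start, feat.end, feat.strand, feat.seqid))
    return genes


def load_genome(
    fasta_path: str | Path,
    annotation_path: str | Path,
    genome_id: str | None = None,
) -> GenomeBundle:
    """Read a genome FASTA plus gene annotation (GFF3 or 4/5-column TSV).

    Genes are returned sorted by (replicon, start).  Every gene must lie on
    a replicon present in the FASTA.
    """
    fasta_path, annotation_path = Path(fasta_path), Path(annotation_path)
    if genome_id is None:
        genome_id = fasta_path.stem
    sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not sequences:
        raise InputError(f"{fasta_path}: no FASTA records")
    if annotation_path.suffix.lower() in {".gff", ".gff3"}:
        genes = _parse_gff3(annotation_path, genome_id)
    else:
        genes = _parse_gene_tsv(annotation_path, genome_id, list(sequences))
    for g in genes:
        if g.replicon_id not in sequences:
            raise InputError(
                f"gene {g.gene_id} references replicon {g.replicon_id!r} "
                f"absent from {fasta_path.name}"
            )
        if g.end > len(sequences[g.replicon_id]):
            raise InputError(
                f"gene {g.gene_id} extends past end of replicon {g.replicon_id}"
            )
    genes.sort(key=lambda g: (g.replicon_id, g.start, g.end))
    return GenomeBundle(genome_id, sequences, genes)


# ---------------------------------------------------------------------------
# transcription units


def assemble_tus(
    genes: Sequence[Gene],
    tu_table: Mapping[str, Sequence[str]] | None = None,
    gap_threshold: int = 50,
) -> list[TranscriptionUnit]:
    """Group genes into transcription units.

    With ``tu_table`` (tu_id -> gene ids) the table is authoritative and must
    cover every gene exactly once.  Without it, a fallback heuristic groups
    consecutive same-strand genes whose intergenic gap is <= ``gap_threshold``
    bp.  The heuristic is a stand-in for a proper operon predictor and is
    labelled as such in the docs.
    """
    if not genes:
        return []
    genome_id = genes[0].genome_id
    by_id = {g.gene_id: g for g in genes}

    def _orient(member_ids: Sequence[str], strand: str) -> tuple[str, ...]:
        ordered = sorted(member_ids, key=lambda gid: by_id[gid].start)
        if strand == "-":
            ordered.reverse()
        return tuple(ordered)

    if tu_table is not None:
        seen: set[str] = set()
        tus = []
        for tu_id, member_ids in tu_table.items():
            for gid in member_ids:
                if gid not in by_id:
                    raise InputError(f"TU table references unknown gene {gid!r}")
                if gid in seen:
                    raise InputError(f"TU table lists gene {gid!r} more than once")
                seen.add(gid)
            strands = {by_id[g].strand for g in member_ids}
            replicons = {by_id[g].replicon_id for g in member_ids}
            if len(strands) != 1 or len(replicons) != 1:
                raise InputError(f"TU {tu_id}: members mix strands or replicons")
            strand = strands.pop()
            tus.append(TranscriptionUnit(tu_id, genome_id, _orient(member_ids, strand), strand))
        missing = set(by_id) - seen
        if missing:
            raise InputError(f"TU table does not cover genes: {sorted(missing)[:5]} ...")
        return tus

    tus = []
    counter = 0
    ordered = sorted(genes, key=lambda g: (g.replicon_id, g.start))
    block: list[Gene] = []

    def _flush():
        nonlocal counter
        if block:
            counter += 1
            strand = block[0].strand
            tus.append(
                TranscriptionUnit(
                    f"TU{counter:05d}",
                    genome_id,
                    _orient([g.gene_id for g in block], strand),
                    strand,
                )
            )

    for g in ordered:
        if (
            block
            and g.replicon_id == block[-1].replicon_id
            and g.strand == block[-1].strand
            and g.start - block[-1].end - 1 <= gap_threshold
        ):
            block.append(g)
        else:
            _flush()
            block = [g]
    _flush()
    return tus


# ---------------------------------------------------------------------------
# upstream regions


def extract_upstream(
    tu: TranscriptionUnit,
    bundle: GenomeBundle,
    cap: int = 800,
    coding_extension: int = 40,
) -> UpstreamRegion:
    """Extract the upstream inter-TU region (+ leading coding bases) of a TU.

    The inter-TU portion runs from the TU's first gene to the nearest gene
    body of another TU, irrespective of the neighbour's strand; when longer
    than ``cap`` only the immediate upstream ``cap`` bases are kept.  The
    first ``coding_extension`` bases of the leading gene are appended.  A TU
    with zero upstream inter-TU sequence yields only the coding extension
    and is flagged.
    """
    first = bundle.genes_by_id[tu.gene_ids[0]]
    seq = bundle.sequences[first.replicon_id]
    tu_gene_ids = set(tu.gene_ids)
    others = [
        g
        for g in bundle.genes
        if g.replicon_id == first.replicon_id and g.gene_id not in tu_gene_ids
    ]
    ext = min(coding_extension, first.length)

    if tu.strand == "+":
        prev_end = max((g.end for g in others if g.end < first.start), default=0)
        inter_start, inter_end = prev_end + 1, first.start - 1
        inter_len = max(0, inter_end - inter_start + 1)
        if inter_len > cap:
            inter_start = inter_end - cap + 1
            inter_len = cap
        block_start = inter_start if inter_len else first.start
        block_end = first.start + ext - 1
        region_seq = seq[block_start - 1 : block_end]
    else:
        next_start = min(
            (g.start for g in others if g.start > first.end), default=len(seq) + 1
        )
        inter_start, inter_end = first.end + 1, next_start - 1
        inter_len = max(0, inter_end - inter_start + 1)
        if inter_len > cap:
            inter_end = inter_start + cap - 1
            inter_len = cap
        block_start = first.end - ext + 1
        block_end = inter_end if inter_len else first.end
        region_seq = revcomp(seq[block_start - 1 : block_end])

    flagged = inter_len == 0
    if flagged:
        logger.warning("TU %s has no upstream inter-TU sequence", tu.tu_id)
    return UpstreamRegion(
        region_id=f"{tu.tu_id}:upstream",
        tu_id=tu.tu_id,
        genome_id=bundle.genome_id,
        sequence=region_seq,
        replicon_id=first.replicon_id,
        start=block_start,
        end=block_end,
        strand=tu.strand,
        kind="interTU",
        intertu_length=inter_len,
        flagged=flagged,
    )


def extract_all_upstreams(
    bundle: GenomeBundle, cap: int = 800, coding_extension: int = 40
) -> dict[str, UpstreamRegion]:
    bundle.regions = {
        tu.tu_id: extract_upstream(tu, bundle, cap, coding_extension)
        for tu in bundle.tus
    }
    return bundle.regions


def compute_background(
    regions: Iterable[UpstreamRegion], genome_id: str = ""
) -> BackgroundModel:
    """Base frequencies over the aggregated inter-TU sequence.

    Only the inter-TU portion of each region counts (the appended coding
    bases are excluded), N's are ignored, and one pseudocount per base
    keeps every frequency strictly positive.
    """
    counts = np.ones(4, dtype=float)  # +1 pseudocount per base
    informative = 0
    regions = list(regions)
    if not regions:
        raise InputError("compute_background: no regions supplied")
    for r in regions:
        if r.kind != "interTU":
            continue
        codes = encode(r.sequence[: r.intertu_length])
        hist = np.bincount(codes[codes < 4], minlength=4)
        counts += hist
        informative += int(hist.sum())
        if not genome_id:
            genome_id = r.genome_id
    if informative == 0:
        raise InputError("compute_background: no informative (A/C/G/T) bases")
    return BackgroundModel(genome_id, counts / counts.sum())


# ---------------------------------------------------------------------------
# BED I/O


def write_regions_bed(regions: Iterable[UpstreamRegion], path: str | Path) -> None:
    """Write regions as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            if r.replicon_id is None:
                continue
            fh.write(
                f"{r.replicon_id}\t{r.start - 1}\t{r.end}\t{r.region_id}\t0\t{r.strand}\n"
            )


def read_regions_bed(path: str | Path) -> list[tuple[str, int, int, str, str]]:
    """Read BED6 back as (replicon, start_1based, end, name, strand)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            out.append((chrom, int(start) + 1, int(end), name, strand))
    return out
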