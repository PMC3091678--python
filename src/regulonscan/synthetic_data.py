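"""Multi-genome synthetic fixtures with known ortholog structure and
planted motif instances.

Each simulated genome is one replicon of TU-structured gene layouts:
gene counts per TU slot are shared across genomes (so slot j of TU t is
an ortholog family), while strands, gene lengths and intergenic gaps are
drawn per genome.  Coding sequence is codon-structured random sequence
(uniform over the 61 non-stop codons — deliberately no codon bias) so
the coding null model is non-degenerate; intergenic sequence follows the
configured GC content, or the same codon model when a
composition-matched null calibration genome is wanted.

Ortholog families are labels, not sequences: a family is either linked
across all genomes (probability ``ortholog_coverage``) or absent from
the map.  A toy protein-hit-table writer exists solely to exercise the
reciprocal-best-hit reader.

Planted TUs receive one site sampled per TU from the ground-truth PWM
(the empirical column frequencies of the supplied site list), mutated
per genome at ``planting_fidelity`` per base, and written into the
upstream intergenic gap of the same TU slot in every genome carrying it
— emulating a conserved regulon.  ``planted_groups`` restricts planting
of disjoint TU sets to subsets of genomes, emulating habitat-specific
regulon divergence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._alphabet import decode, encode, revcomp_codes
from .motif_profile import load_reference_sites
from .orthology import OrthologMap, OrthologPair
from .scanner import ScanHit
from .sequence_model import (
    Gene,
    GenomeBundle,
    assemble_tus,
    compute_background,
    extract_all_upstreams,
)

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = np.array(
    [
        encode(a + b + c)
        for a, b, c in itertools.product("ACGT", repeat=3)
        if a + b + c not in _STOPS
    ],
    dtype=np.int8,
)  # (61, 3)


@dataclass
class SimulationConfig:
    seed: int
    n_genomes: int = 4
    n_tus_per_genome: int = 1000
    genes_per_tu_probs: tuple[float, ...] = (0.6, 0.25, 0.1, 0.05)  # P(1..4 genes)
    gene_length_range: tuple[int, int] = (300, 900)
    intergenic_length_range: tuple[int, int] = (80, 400)
    intra_tu_gap_range: tuple[int, int] = (5, 30)
    gc_content: float = 0.5
    truth_sites: tuple[str, ...] | None = None  # default: packaged reference sites
    n_planted_tus: int = 20
    planting_fidelity: float = 0.02  # per-base mutation rate of planted sites
    ortholog_coverage: float = 0.75
    intergenic_from_coding_model: bool = False
    planted_groups: tuple[tuple[int, ...], ...] | None = None

    def __post_init__(self):
        if not (0.0 <= self.planting_fidelity <= 1.0):
            raise ValueError("planting_fidelity must be in [0, 1]")
        if not (0.0 <= self.ortholog_coverage <= 1.0):
            raise ValueError("ortholog_coverage must be in [0, 1]")
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must be in (0, 1)")
        if abs(sum(self.genes_per_tu_probs) - 1.0) > 1e-9:
            raise ValueError("genes_per_tu_probs must sum to 1")


@dataclass(frozen=True)
class TruthRow:
    genome_id: str
    tu_id: str
    site: str  # planted spelling, 5'->3' on the TU's coding strand
    offset: int  # 0-based within the extracted upstream region
    strand: str  # TU strand
    replicon_id: str = "chr"
    genomic_start: int = 0  # 1-based


@dataclass
class TruthTable:
    rows: list[TruthRow] = field(default_factory=list)

    def for_genome(self, genome_id: str) -> list[TruthRow]:
        return [r for r in self.rows if r.genome_id == genome_id]

    def write_bed(self, path: str | Path, length: int) -> None:
        with open(path, "w") as fh:
            for r in self.rows:
                fh.write(
                    f"{r.replicon_id}\t{r.genomic_start - 1}\t"
                    f"{r.genomic_start - 1 + length}\t{r.genome_id}:{r.tu_id}\t0\t"
                    f"{r.strand}\n"
                )


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    bundles: dict[str, GenomeBundle]
    ortholog_map: OrthologMap
    truth: TruthTable
    tu_tables: dict[str, dict[str, tuple[str, ...]]]
    families: dict[tuple[int, int], bool]  # (tu_slot, gene_slot) -> covered

    @property
    def target_genome(self) -> str:
        return sorted(self.bundles)[0]


def _truth_pwm(sites: Sequence[str]) -> np.ndarray:
    length = len(sites[0])
    counts = np.zeros((length, 4))
    for s in sites:
        counts[np.arange(length), encode(s)] += 1
    return counts / counts.sum(axis=1, keepdims=True)


def _sample_site(pwm: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(pwm, axis=1)
    u = rng.random(pwm.shape[0])
    return np.argmax(u[:, None] < cum, axis=1).astype(np.int8)


def _mutate(site: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = site.copy()
    hit = rng.random(len(site)) < rate
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 4
    return out


def simulate_genomes(config: SimulationConfig) -> SimulatedDataset:
    """Generate genomes, ortholog map and planted-site truth table.

    Deterministic for a fixed config (seed included): same seed, same
    bytes.  Raises if a planted site cannot be placed inside the
    extractable upstream window (a config bug, e.g. gaps shorter than
    the site).
    """
    rng = np.random.default_rng(config.seed)
    truth_sites = config.truth_sites or tuple(
        s.sequence for s in load_reference_sites()
    )
    pwm = _truth_pwm(truth_sites)
    l = pwm.shape[0]
    n_tus = config.n_tus_per_genome

    # shared skeleton: gene count per TU slot, ortholog coverage per family
    gene_counts = rng.choice(
        np.arange(1, len(config.genes_per_tu_probs) + 1),
        size=n_tus,
        p=config.genes_per_tu_probs,
    )
    families = {
        (t, j): bool(rng.random() < config.ortholog_coverage)
        for t in range(n_tus)
        for j in range(int(gene_counts[t]))
    }

    # planted TU slots: non-adjacent so no two sites share an intergenic gap
    groups = config.planted_groups or (
        (tuple(range(config.n_genomes)),) if config.n_planted_tus else ()
    )
    planted_by_group: list[tuple[tuple[int, ...], np.ndarray]] = []
    taken: set[int] = set()
    for group in groups:
        chosen: list[int] = []
        candidates = rng.permutation(n_tus)
        for t in candidates:
            t = int(t)
            if {t - 1, t, t + 1} & taken:
                continue
            chosen.append(t)
            taken.add(t)
            if len(chosen) == config.n_planted_tus:
                break
        if len(chosen) < config.n_planted_tus:
            raise ValueError("cannot place planted TUs without shared gaps; "
                             "reduce n_planted_tus or raise n_tus_per_genome")
        planted_by_group.append((tuple(group), np.array(sorted(chosen))))
        for t in chosen:  # planted TUs must be linkable across genomes
            families[(t, 0)] = True
    base_sites = {
        int(t): _sample_site(pwm, rng)
        for _grp, slots in planted_by_group
        for t in slots
    }

    genome_ids = [f"G{i:02d}" for i in range(config.n_genomes)]
    bundles: dict[str, GenomeBundle] = {}
    tu_tables: dict[str, dict[str, tuple[str, ...]]] = {}
    truth = TruthTable()

    gc = config.gc_content
    intergenic_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    def _coding(n_bases: int, rng: np.random.Generator) -> np.ndarray:
        return _CODONS[rng.integers(0, len(_CODONS), size=n_bases // 3)].reshape(-1)

    def _intergenic(n_bases: int, rng: np.random.Generator) -> np.ndarray:
        if config.intergenic_from_coding_model:
            n_cod = -(-n_bases // 3) * 3
            return _coding(n_cod, rng)[:n_bases]
        return rng.choice(4, size=n_bases, p=intergenic_p).astype(np.int8)

    for gi, genome_id in enumerate(genome_ids):
        planted_here = {
            int(t): base_sites[int(t)]
            for grp, slots in planted_by_group
            if gi in grp
            for t in slots
        }
        parts: list[np.ndarray] = []
        pos = 0  # 0-based running genomic position
        genes: list[Gene] = []
        tu_table: dict[str, tuple[str, ...]] = {}
        gap_bounds: list[tuple[int, int]] = []  # 0-based [start, end) of each gap
        tu_span: list[tuple[int, int]] = []

        glo, ghi = config.intergenic_length_range
        for t in range(n_tus + 1):
            gap_len = int(rng.integers(glo, ghi + 1))
            parts.append(_intergenic(gap_len, rng))
            gap_bounds.append((pos, pos + gap_len))
            pos += gap_len
            if t == n_tus:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            count = int(gene_counts[t])
            # transcription order j=0..count-1; '-' TUs are laid right-to-left
            layout = list(range(count)) if strand == "+" else list(range(count))[::-1]
            tu_start = pos
            members: dict[int, str] = {}
            for idx, j in enumerate(layout):
                if idx > 0:
                    gap = int(rng.integers(*config.intra_tu_gap_range))
                    parts.append(_intergenic(gap, rng))
                    pos += gap
                lo, hi = config.gene_length_range
                length_bp = int(rng.integers(lo // 3, hi // 3 + 1)) * 3
                coding = _coding(length_bp, rng)
                if strand == "-":
                    coding = revcomp_codes(coding)
                parts.append(coding)
                gene_id = f"{genome_id}_t{t:05d}_{j}"
                genes.append(
                    Gene(gene_id, genome_id, pos + 1, pos + length_bp, strand, "chr")
                )
                members[j] = gene_id
                pos += length_bp
            tu_span.append((tu_start, pos))
            tu_table[f"TU{t:05d}"] = tuple(members[j] for j in range(count))

        seq_codes = np.concatenate(parts)
        assert len(seq_codes) == pos

        # plant sites: '+' TU t uses gap t; '-' TU t uses gap t+1
        for t, site in sorted(planted_here.items()):
            tu_id = f"TU{t:05d}"
            first_gene = tu_table[tu_id][0]
            strand = next(g.strand for g in genes if g.gene_id == first_gene)
            gap_i = t if strand == "+" else t + 1
            gstart, gend = gap_bounds[gap_i]
            gap_len = gend - gstart
            if gap_len < l:
                raise ValueError(
                    f"planted site does not fit the {gap_len}-bp gap of {tu_id}"
                )
            u = int(rng.integers(0, gap_len - l + 1))
            mutated = _mutate(site, config.planting_fidelity, rng)
            if strand == "+":
                a = gstart + u  # 0-based genomic start
                seq_codes[a : a + l] = mutated
                offset = a - gstart
            else:
                a = gend - u - l
                seq_codes[a : a + l] = revcomp_codes(mutated)
                offset = gend - (a + l)
            truth.rows.append(
                TruthRow(
                    genome_id=genome_id,
                    tu_id=tu_id,
                    site=decode(mutated),
                    offset=offset,
                    strand=strand,
                    genomic_start=a + 1,
                )
            )

        bundle = GenomeBundle(genome_id, {"chr": decode(seq_codes)}, genes)
        bundle.tus = assemble_tus(genes, tu_table)
        extract_all_upstreams(bundle)
        bundle.background = compute_background(bundle.regions.values(), genome_id)
        bundles[genome_id] = bundle
        tu_tables[genome_id] = tu_table

    # planted offsets must fall inside the extracted upstream window
    for row in truth.rows:
        region = bundles[row.genome_id].regions[row.tu_id]
        got = region.sequence[row.offset : row.offset + l]
        if got != row.site:
            raise AssertionError(
                f"planted site bookkeeping broken for {row.genome_id}/{row.tu_id}"
            )

    # ortholog map from shared family labels
    pairs = []
    for (t, j), covered in sorted(families.items()):
        if not covered:
            continue
        for a in range(config.n_genomes):
            for b in range(a + 1, config.n_genomes):
                ga, gb = genome_ids[a], genome_ids[b]
                gene_a = tu_tables[ga].get(f"TU{t:05d}", ())
                gene_b = tu_tables[gb].get(f"TU{t:05d}", ())
                if j < len(gene_a) and j < len(gene_b):
                    pairs.append(
                        OrthologPair(ga, gene_a[j], gb, gene_b[j], 1e-50, 1e-50)
                    )
    return SimulatedDataset(
        config=config,
        bundles=bundles,
        ortholog_map=OrthologMap(pairs),
        truth=truth,
        tu_tables=tu_tables,
        families=families,
    )


# ---------------------------------------------------------------------------
# recovery evaluation


@dataclass
class RecoveryResult:
    recall: float
    precision: float
    ranks: dict[str, int]  # planted tu_id -> rank (1 = best) in the hit list
    n_truth: int
    n_called: int

    @property
    def mean_rank(self) -> float:
        return float(np.mean(list(self.ranks.values()))) if self.ranks else float("nan")


def evaluate_recovery(
    truth: TruthTable,
    hits: Sequence[ScanHit],
    threshold: float = 0.01,
    length: int = 14,
) -> RecoveryResult:
    """Score recovery of planted sites in the genome the hits belong to.

    A planted site counts as recovered when its TU's hit passes the
    p-value threshold and the reported window overlaps the planted
    interval by at least half the site length.
    """
    if not hits:
        return RecoveryResult(0.0, 0.0, {}, 0, 0)
    genome_id = hits[0].genome_id
    rows = truth.for_genome(genome_id)
    hit_by_tu = {h.tu_id: h for h in hits}
    rank_by_tu = {h.tu_id: i + 1 for i, h in enumerate(hits)}
    recovered_tus = set()
    for row in rows:
        h = hit_by_tu.get(row.tu_id)
        if h is None or not h.valid or h.pvalue is None or h.pvalue >= threshold:
            continue
        if abs(h.offset - row.offset) <= length // 2:
            recovered_tus.add(row.tu_id)
    called = {
        h.tu_id
        for h in hits
        if h.valid and h.pvalue is not None and h.pvalue < threshold
    }
    recall = len(recovered_tus) / len(rows) if rows else 0.0
    precision = (
        len(recovered_tus & called) / len(called) if called else 0.0
    )
    ranks = {row.tu_id: rank_by_tu[row.tu_id] for row in rows if row.tu_id in rank_by_tu}
    return RecoveryResult(recall, precision, ranks, len(rows), len(called))


# ---------------------------------------------------------------------------
# file output (same formats the pipeline reads)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for genome_id, bundle in ds.bundles.items():
        with open(outdir / f"{genome_id}.fasta", "w") as fh:
            for rep, seq in bundle.sequences.items():
                fh.write(f">{rep}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        with open(outdir / f"{genome_id}.genes.tsv", "w") as fh:
            fh.write("gene_id\tstart\tend\tstrand\treplicon\n")
            for g in bundle.genes:
                fh.write(f"{g.gene_id}\t{g.start}\t{g.end}\t{g.strand}\t{g.replicon_id}\n")
        with open(outdir / f"{genome_id}.tus.tsv", "w") as fh:
            for tu_id, gene_ids in ds.tu_tables[genome_id].items():
                fh.write(f"{tu_id}\t{','.join(gene_ids)}\n")
    ds.ortholog_map.write_tsv(outdir / "orthologs.tsv")
    if ds.truth.rows:
        length = len(ds.truth.rows[0].site)
        ds.truth.write_bed(outdir / "truth.bed", length)


def write_toy_hit_tables(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Synthetic BLAST-like tables reproducing the ortholog map through RBH."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_pair: dict[tuple[str, str], list[str]] = {}
    for p in ds.ortholog_map.pairs:
        fwd = by_pair.setdefault((p.genome_a, p.genome_b), [])
        rev = by_pair.setdefault((p.genome_b, p.genome_a), [])
        fwd.append(f"{p.gene_a}\t{p.gene_b}\t{p.evalue_ab:g}\t500.0")
        rev.append(f"{p.gene_b}\t{p.gene_a}\t{p.evalue_ba:g}\t500.0")
    for (ga, gb), lines in by_pair.items():
        with open(outdir / f"hits_{ga}_vs_{gb}.tsv", "w") as fh:
            fh.write("\n".join(lines) + "\n")
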