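"""End-to-end orchestration: load -> TUs -> regions -> background ->
orthologs -> profile -> scan -> null -> p-values/LOR -> regulons ->
conservation tree.

Every run echoes its configuration, writes a manifest of produced
artifacts and logs the seed and per-genome summary (TU and gene counts,
score/LOR cutoffs and site counts at each threshold)."""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .motif_profile import (
    build_profile,
    consensus,
    load_reference_sites,
    load_sites_fasta,
    load_sites_tsv,
    write_meme_motif,
)
from .null_stats import (
    DEFAULT_NULL_COUNT,
    DEFAULT_SEED,
    annotate_hits,
    lor_at,
    lor_curve,
    null_distribution,
    score_cutoff,
)
from .orthology import OrthologMap
from .regulon import (
    conservation_distance_matrix,
    neighbor_joining,
    predict_regulon,
    write_newick,
    write_regulons_tsv,
)
from .scanner import scan_genome, write_hits_tsv, write_sites_bed
from .sequence_model import (
    assemble_tus,
    compute_background,
    extract_all_upstreams,
    load_genome,
    write_regions_bed,
)

logger = logging.getLogger(__name__)


@dataclass
class GenomeInput:
    genome_id: str
    fasta: str
    genes: str
    tus: str | None = None  # TU table TSV; fallback heuristic when absent


@dataclass
class RunConfig:
    genomes: list[GenomeInput]
    outdir: str
    sites: str | None = None  # site list TSV/FASTA; packaged reference when None
    orthologs: str | None = None  # ortholog map TSV
    cap: int = 800
    coding_extension: int = 40
    gap_threshold: int = 50
    null_count: int = DEFAULT_NULL_COUNT
    pvalue: float = 0.01
    pvalue_secondary: float = 0.05
    seed: int = DEFAULT_SEED
    both_strands: bool = True
    evalue_cutoff: float = 1e-10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        genomes = [GenomeInput(**g) for g in raw.pop("genomes")]
        return cls(genomes=genomes, **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _read_tu_table(path: str | Path) -> dict[str, tuple[str, ...]]:
    table: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "tu_id":
                continue
            table[row[0]] = tuple(row[1].split(","))
    return table


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the output directory.

    A stage failure aborts with the stage name and offending input in
    the raised exception.  Missing ortholog input degrades gracefully to
    a pure profile scan (bonus 0 everywhere) with a warning.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("regulonscan")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    manifest: dict[str, str] = {}
    try:
        logger.info("regulonscan %s  seed=%d", __version__, config.seed)
        config.to_yaml(outdir / "config.yaml")
        manifest["config"] = "config.yaml"

        stage = "load"
        bundles = {}
        for gi in config.genomes:
            try:
                bundle = load_genome(gi.fasta, gi.genes, gi.genome_id)
                tu_table = _read_tu_table(gi.tus) if gi.tus else None
                bundle.tus = assemble_tus(bundle.genes, tu_table, config.gap_threshold)
                extract_all_upstreams(bundle, config.cap, config.coding_extension)
                bundle.background = compute_background(
                    bundle.regions.values(), bundle.genome_id
                )
                bundles[bundle.genome_id] = bundle
            except Exception as exc:
                raise RuntimeError(
                    f"stage {stage!r} failed for genome input {gi.fasta}: {exc}"
                ) from exc
            logger.info(
                "genome %s: %d genes, %d TUs", bundle.genome_id,
                len(bundle.genes), len(bundle.tus),
            )

        stage = "orthologs"
        if config.orthologs:
            ortholog_map = OrthologMap.read_tsv(config.orthologs)
            logger.info("ortholog map: %d pairs", len(ortholog_map))
        else:
            ortholog_map = None
            logger.warning("no ortholog input; scanning without conservation bonus")

        stage = "profile"
        if config.sites is None:
            sites = load_reference_sites()
        elif str(config.sites).endswith((".fa", ".fasta", ".fna")):
            sites = load_sites_fasta(config.sites)
        else:
            sites = load_sites_tsv(config.sites)
        # profile built against the pooled background of all input genomes
        pooled_regions = [r for b in bundles.values() for r in b.regions.values()]
        pooled_bg = compute_background(pooled_regions, "pooled")
        profile = build_profile(sites, pooled_bg)
        logger.info(
            "profile: %d sites, length %d, consensus %s",
            profile.n_sites, profile.length, consensus(profile),
        )
        write_meme_motif(profile, outdir / "profile.meme")
        manifest["profile"] = "profile.meme"

        summary_rows = []
        regulons = []
        for genome_id, bundle in sorted(bundles.items()):
            gdir = outdir / genome_id
            gdir.mkdir(exist_ok=True)
            stage = f"scan:{genome_id}"
            others = {g: b for g, b in bundles.items() if g != genome_id}
            hits = scan_genome(
                bundle, profile, ortholog_map, others, config.both_strands
            )
            stage = f"null:{genome_id}"
            null = null_distribution(
                bundle, profile, ortholog_map, others,
                count=config.null_count, seed=config.seed,
                both_strands=config.both_strands,
            )
            annotate_hits(hits, null)
            null.write_tsv(gdir / "null.tsv")
            stage = f"lor:{genome_id}"
            observed = [h.s for h in hits if h.valid]
            curve = lor_curve(observed, null)
            curve.write_tsv(gdir / "lor.tsv")
            tus_by_id = {tu.tu_id: tu for tu in bundle.tus}
            write_hits_tsv(hits, gdir / "hits.tsv", tus_by_id)
            write_sites_bed(hits, bundle.regions, profile.length, gdir / "sites.bed")
            write_regions_bed(bundle.regions.values(), gdir / "regions.bed")
            for key in ("hits.tsv", "null.tsv", "lor.tsv", "sites.bed", "regions.bed"):
                manifest[f"{genome_id}/{key}"] = f"{genome_id}/{key}"

            stage = f"regulon:{genome_id}"
            regulon = predict_regulon(hits, tus_by_id, config.pvalue)
            regulons.append(regulon)

            row = {"genome": genome_id, "n_tus": len(bundle.tus),
                   "n_genes": len(bundle.genes)}
            for label, p in (("p05", config.pvalue_secondary), ("p01", config.pvalue)):
                cut = score_cutoff(null, p)
                n_sites = sum(
                    1 for h in hits if h.valid and h.pvalue is not None and h.pvalue < p
                )
                row[f"score_{label}"] = round(cut.score, 3)
                row[f"lor_{label}"] = round(lor_at(curve, cut.score), 3)
                row[f"sites_{label}"] = n_sites
            summary_rows.append(row)

        stage = "summary"
        with open(outdir / "summary.tsv", "w") as fh:
            cols = ["genome", "n_tus", "n_genes", "score_p05", "lor_p05",
                    "sites_p05", "score_p01", "lor_p01", "sites_p01"]
            fh.write("\t".join(cols) + "\n")
            for row in summary_rows:
                fh.write("\t".join(str(row[c]) for c in cols) + "\n")
        manifest["summary"] = "summary.tsv"

        write_regulons_tsv(regulons, outdir / "regulons.tsv")
        manifest["regulons"] = "regulons.tsv"

        if ortholog_map is not None and len(regulons) >= 3:
            stage = "tree"
            matrix = conservation_distance_matrix(regulons, ortholog_map)
            matrix.write_phylip(outdir / "dist.phylip")
            tree = neighbor_joining(matrix)
            write_newick(tree, outdir / "tree.nwk")
            manifest["distance_matrix"] = "dist.phylip"
            manifest["tree"] = "tree.nwk"

        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return outdir
    finally:
        root.removeHandler(handler)
        handler.close()
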