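"""Profile scanning with cross-genome orthology reinforcement.

For a sequence t scanned with profile M against an organism's background
q, the best-site score is

    s_M(t) = max_h  sum_i I_i * ln( p(i, h(i)) / q(h(i)) )      (nats)

over every l-mer h of t (both orientations by default; the near-
palindromic motif makes the orientation max the safe reading).  The
refined score adds a bonus rewarding conservation upstream of orthologs:
for each gene g_i of the TU with orthologs in m_i genomes,

    A(g_i) = (1/m_i) sum_k [(l - d_ik)/l] * s_M(o_k(g_i))

where o_k(g_i) is the upstream region of the ortholog's TU in genome
G_k (scored against G_k's own background) and d_ik the Hamming distance
between the two best sites, and

    s(t) = s_M(t) + max_i A(g_i)

with genes lacking orthologs contributing 0 to the max.

The profile's information weights I_i are fixed at build time; only the
ln q(h(i)) denominator is re-derived from each genome's own background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._alphabet import RC_CODE, decode, encode
from .motif_profile import MotifProfile
from .orthology import OrthologMap
from .sequence_model import BackgroundModel, GenomeBundle, UpstreamRegion

logger = logging.getLogger(__name__)

_NEG = -1e30  # poison score for windows containing N


@dataclass
class ScanHit:
    tu_id: str | None
    region_id: str | None
    genome_id: str
    site: str | None  # best l-mer, spelled in profile orientation
    offset: int | None  # 0-based within the region (coding strand)
    strand_of_window: str | None  # '+'/'-' relative to the region
    s_M: float | None
    A_max: float = 0.0
    bonus_gene: str | None = None
    per_ortholog: list[tuple[str, str, float, int]] = field(default_factory=list)
    pvalue: float | None = None
    pvalue_below_floor: bool = False

    @property
    def valid(self) -> bool:
        return self.s_M is not None

    @property
    def s(self) -> float | None:
        """Refined score s = s_M + A_max."""
        return None if self.s_M is None else self.s_M + self.A_max


class GenomeScorer:
    """Per-genome scoring matrix W[i,b] = I_i * (ln p(i,b) - ln q(b)).

    Column 4 (N) carries a large negative sentinel so any window touching
    an ambiguous base can never win.
    """

    def __init__(self, profile: MotifProfile, background: BackgroundModel):
        self.profile = profile
        self.background = background
        W = profile.information[:, None] * (
            np.log(profile.p) - np.log(background.q)[None, :]
        )
        self.W = np.concatenate([W, np.full((profile.length, 1), _NEG)], axis=1)
        self.length = profile.length


def score_window(
    profile: MotifProfile, lmer: str, background: BackgroundModel
) -> float:
    """Score a single l-mer (no sliding, no reverse complement)."""
    codes = encode(lmer)
    if len(codes) != profile.length:
        raise ValueError(f"window length {len(codes)} != profile length {profile.length}")
    if (codes > 3).any():
        raise ValueError("window contains N; caller must skip such windows")
    W = GenomeScorer(profile, background).W
    return float(W[np.arange(profile.length), codes].sum())


def _window_scores(W: np.ndarray, X: np.ndarray) -> np.ndarray:
    """All-window scores.  X is (m, L) int8; returns (m, L-l+1) float."""
    l = W.shape[0]
    nwin = X.shape[1] - l + 1
    scores = np.zeros((X.shape[0], nwin))
    for i in range(l):
        scores += W[i][X[:, i : i + nwin]]
    return scores


def batch_best_sites(
    scorer: GenomeScorer, X: np.ndarray, both_strands: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Best site per row of X (m, L): scores, offsets, strands, site codes.

    Offsets are 0-based forward-strand positions of the window; the site
    codes spell the window in profile orientation.  Ties break to the
    lower offset, then the '+' orientation.  Rows with no valid window
    get score -inf and offset -1.
    """
    l = scorer.length
    m, L = X.shape
    if L < l:
        return (
            np.full(m, -np.inf),
            np.full(m, -1, dtype=np.int64),
            np.zeros(m, dtype=np.int8),
            np.full((m, l), 4, dtype=np.int8),
        )
    fwd = _window_scores(scorer.W, X)
    best_off = np.argmax(fwd, axis=1)
    best_score = fwd[np.arange(m), best_off]
    strands = np.zeros(m, dtype=np.int8)  # 0='+', 1='-'
    if both_strands:
        Xrc = RC_CODE[X[:, ::-1]]
        rev = _window_scores(scorer.W, Xrc)[:, ::-1]  # indexed by forward offset
        rev_off = np.argmax(rev, axis=1)
        rev_score = rev[np.arange(m), rev_off]
        take_rev = (rev_score > best_score) | (
            (rev_score == best_score) & (rev_off < best_off)
        )
        best_score = np.where(take_rev, rev_score, best_score)
        best_off = np.where(take_rev, rev_off, best_off)
        strands = take_rev.astype(np.int8)
    invalid = best_score < _NEG / 2
    best_score = np.where(invalid, -np.inf, best_score)
    best_off = np.where(invalid, -1, best_off)
    # gather site codes in profile orientation
    idx = np.clip(best_off, 0, None)[:, None] + np.arange(l)[None, :]
    sites = np.take_along_axis(X, idx, axis=1)
    rc = RC_CODE[sites[:, ::-1]]
    sites = np.where(strands[:, None] == 1, rc, sites)
    sites[invalid] = 4
    return best_score, best_off, strands, sites


def best_site(
    profile: MotifProfile,
    region: UpstreamRegion | str,
    background: BackgroundModel,
    both_strands: bool = True,
) -> ScanHit:
    """Best-scoring window of one region (the s_M part of a hit).

    Returns a no-hit sentinel (``hit.valid`` false) when the region is
    shorter than l or every window contains an N.
    """
    if isinstance(region, str):
        region = UpstreamRegion("adhoc", None, background.genome_id, region)
    scorer = GenomeScorer(profile, background)
    X = encode(region.sequence)[None, :]
    score, off, strand, site = batch_best_sites(scorer, X, both_strands)
    if not np.isfinite(score[0]):
        return ScanHit(region.tu_id, region.region_id, region.genome_id,
                       None, None, None, None)
    return ScanHit(
        tu_id=region.tu_id,
        region_id=region.region_id,
        genome_id=region.genome_id,
        site=decode(site[0]),
        offset=int(off[0]),
        strand_of_window="-" if strand[0] else "+",
        s_M=float(score[0]),
    )


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("Hamming distance needs equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def orthology_bonus(
    tu_gene_ids: Sequence[str],
    hit: ScanHit,
    ortholog_hits_by_gene: Mapping[str, Sequence[tuple[str, ScanHit]]],
    length: int,
) -> tuple[float, str | None, list[tuple[str, str, float, int]]]:
    """Conservation bonus A_max for a hit.

    ``ortholog_hits_by_gene`` maps each TU gene to its resolved per-genome
    ortholog best hits [(genome_k, ScanHit)].  Genes with no orthologs
    contribute 0 to the max; negative per-ortholog scores enter the
    average as-is.  Returns (A_max, winning gene id, per-ortholog detail).
    """
    best_val = None
    best_gene = None
    best_detail: list[tuple[str, str, float, int]] = []
    any_without = False
    for gene_id in tu_gene_ids:
        ortho_hits = [
            (gk, oh) for gk, oh in ortholog_hits_by_gene.get(gene_id, []) if oh.valid
        ]
        if not ortho_hits:
            any_without = True
            continue
        terms = []
        detail = []
        for genome_k, oh in ortho_hits:
            d = hamming(hit.site, oh.site)
            terms.append((length - d) / length * oh.s_M)
            detail.append((genome_k, oh.site, oh.s_M, d))
        val = float(np.mean(terms))
        if best_val is None or val > best_val:
            best_val, best_gene, best_detail = val, gene_id, detail
    if best_val is None:
        return 0.0, None, []
    if any_without and best_val < 0.0:
        return 0.0, None, []
    return best_val, best_gene, best_detail


def refined_score(hit: ScanHit) -> float:
    """s = s_M + A_max (also available as ``hit.s``)."""
    if not hit.valid:
        raise ValueError("refined_score on a no-hit sentinel")
    return hit.s_M + hit.A_max


def _resolve_ortholog_hits(
    bundle: GenomeBundle,
    tu_gene_ids: Sequence[str],
    ortholog_map: OrthologMap,
    other_hits: Mapping[str, Mapping[str, ScanHit]],
    other_bundles: Mapping[str, GenomeBundle],
) -> dict[str, list[tuple[str, ScanHit]]]:
    out: dict[str, list[tuple[str, ScanHit]]] = {}
    for gene_id in tu_gene_ids:
        entries = []
        for genome_k, gene_k in sorted(
            ortholog_map.orthologs_of(bundle.genome_id, gene_id).items()
        ):
            bk = other_bundles.get(genome_k)
            if bk is None:
                continue
            tu_k = bk.tu_of_gene.get(gene_k)
            oh = other_hits.get(genome_k, {}).get(tu_k) if tu_k else None
            if oh is None or not oh.valid:
                continue
            entries.append((genome_k, oh))
        out[gene_id] = entries
    return out


def scan_genome(
    bundle: GenomeBundle,
    profile: MotifProfile,
    ortholog_map: OrthologMap | None = None,
    other_bundles: Mapping[str, GenomeBundle] | None = None,
    both_strands: bool = True,
) -> list[ScanHit]:
    """One hit (or no-hit sentinel) per TU, sorted by descending refined score.

    Reference genomes are scanned once (each against its own background)
    to resolve the per-ortholog best sites that feed the bonus.  Without an
    ortholog map every hit has A_max = 0.
    """
    other_bundles = other_bundles or {}
    other_hits: dict[str, dict[str, ScanHit]] = {}
    if ortholog_map is not None:
        for gid, bk in other_bundles.items():
            if gid == bundle.genome_id:
                continue
            other_hits[gid] = {
                tu_id: best_site(profile, region, bk.background, both_strands)
                for tu_id, region in bk.regions.items()
            }
    hits = []
    tus_by_id = {tu.tu_id: tu for tu in bundle.tus}
    for tu_id, region in bundle.regions.items():
        hit = best_site(profile, region, bundle.background, both_strands)
        if hit.valid and ortholog_map is not None:
            tu = tus_by_id[tu_id]
            resolved = _resolve_ortholog_hits(
                bundle, tu.gene_ids, ortholog_map, other_hits, other_bundles
            )
            a_max, gene, detail = orthology_bonus(tu.gene_ids, hit, resolved, profile.length)
            hit.A_max, hit.bonus_gene, hit.per_ortholog = a_max, gene, detail
        hits.append(hit)
    hits.sort(key=lambda h: (-(h.s if h.valid else -np.inf), h.tu_id or ""))
    return hits


# ---------------------------------------------------------------------------
# output


def write_hits_tsv(
    hits: Iterable[ScanHit],
    path: str | Path,
    tus_by_id: Mapping[str, object] | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "tu_id\tgenes\tsite\toffset\tstrand\ts_M\tA_max\ts\tbonus_gene\tpvalue\n"
        )
        for h in hits:
            genes = ""
            if tus_by_id and h.tu_id in tus_by_id:
                genes = ",".join(tus_by_id[h.tu_id].gene_ids)
            if not h.valid:
                fh.write(f"{h.tu_id}\t{genes}\tNA\tNA\tNA\tNA\tNA\tNA\tNA\tNA\n")
                continue
            pv = "NA" if h.pvalue is None else (
                f"<{h.pvalue:g}" if h.pvalue_below_floor else f"{h.pvalue:g}"
            )
            fh.write(
                f"{h.tu_id}\t{genes}\t{h.site}\t{h.offset}\t{h.strand_of_window}"
                f"\t{h.s_M:.4f}\t{h.A_max:.4f}\t{h.s:.4f}"
                f"\t{h.bonus_gene or 'NA'}\t{pv}\n"
            )


def read_hits_tsv(path: str | Path, genome_id: str = "") -> list[ScanHit]:
    """Read back a hits table written by :func:`write_hits_tsv`."""
    hits = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            c = line.rstrip("\n").split("\t")
            if c[2] == "NA":
                hits.append(ScanHit(c[0], None, genome_id, None, None, None, None))
                continue
            pv_raw = c[9]
            below = pv_raw.startswith("<")
            pv = None if pv_raw == "NA" else float(pv_raw.lstrip("<"))
            h = ScanHit(
                tu_id=c[0], region_id=None, genome_id=genome_id, site=c[2],
                offset=int(c[3]), strand_of_window=c[4], s_M=float(c[5]),
                A_max=float(c[6]), bonus_gene=None if c[8] == "NA" else c[8],
                pvalue=pv, pvalue_below_floor=below,
            )
            hits.append(h)
    return hits


def hit_genomic_interval(hit: ScanHit, region: UpstreamRegion, length: int):
    """Map a hit's region offset to a genomic interval (replicon, start, end, strand)."""
    if not hit.valid or region.start is None:
        return None
    if region.strand == "+":
        start = region.start + hit.offset
    else:
        start = region.end - hit.offset - length + 1
    window_strand = region.strand
    if hit.strand_of_window == "-":
        window_strand = "-" if window_strand == "+" else "+"
    return (region.replicon_id, start, start + length - 1, window_strand)


def write_sites_bed(
    hits: Iterable[ScanHit],
    regions: Mapping[str, UpstreamRegion],
    length: int,
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        for h in hits:
            if not h.valid or h.tu_id not in regions:
                continue
            iv = hit_genomic_interval(h, regions[h.tu_id], length)
            if iv is None:
                continue
            replicon, start, end, strand = iv
            fh.write(f"{replicon}\t{start - 1}\t{end}\t{h.tu_id}\t{h.s:.3f}\t{strand}\n")
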