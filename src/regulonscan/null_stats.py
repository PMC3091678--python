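"""Empirical coding-sequence null model, p-values, cutoffs and LOR curves.

For each TU upstream region of length L we draw ``count`` (default 300)
length-L contiguous substrings of the genome's coding sequence and score
them exactly as the real region is scored — including the orthology
bonus, where each real ortholog slot (genome G_k, ortholog region length
L_k) is filled with a random length-L_k coding substring from G_k.  The
pooled scores per genome form the null; the empirical p-value of a score
s is the fraction of null sequences whose best site scores strictly
higher.

The genome-level log-odds ratio

    LOR(s) = ln( p(S_IU > s) / p(S_CU > s) )

compares the fraction of real inter-TU regions exceeding s with the
null fraction; positive, rising LOR indicates genuine sites genome-wide.
Inside the log both fractions are smoothed as (count+1)/(N+1) to stay
finite; raw fractions are reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .motif_profile import MotifProfile
from .orthology import OrthologMap
from .scanner import GenomeScorer, ScanHit, batch_best_sites
from .sequence_model import GenomeBundle, InputError, UpstreamRegion

logger = logging.getLogger(__name__)

DEFAULT_NULL_COUNT = 300
DEFAULT_SEED = 1729


@dataclass
class NullDistribution:
    genome_id: str
    scores: np.ndarray  # sorted ascending
    n_samples_per_region: int
    seed: int
    n_regions: int = 0

    def __post_init__(self):
        self.scores = np.sort(np.asarray(self.scores, dtype=float))

    @property
    def n(self) -> int:
        return len(self.scores)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# genome={self.genome_id} count={self.n_samples_per_region} "
                     f"seed={self.seed} regions={self.n_regions}\n")
            for s in self.scores:
                fh.write(f"{s:.6f}\n")


def read_null_tsv(path: str | Path) -> NullDistribution:
    """Read back a null score file written by ``NullDistribution.write_tsv``."""
    meta = {"genome": "", "count": 0, "seed": 0, "regions": 0}
    scores = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                for tok in line[1:].split():
                    k, _, v = tok.partition("=")
                    if k in meta:
                        meta[k] = v if k == "genome" else int(v)
                continue
            if line.strip():
                scores.append(float(line))
    return NullDistribution(
        genome_id=str(meta["genome"]), scores=np.array(scores),
        n_samples_per_region=int(meta["count"]), seed=int(meta["seed"]),
        n_regions=int(meta["regions"]),
    )


@dataclass
class CutoffResult:
    score: float
    pvalue: float
    achieved: bool  # False when p_target is below the 1/N resolution


@dataclass
class LorCurve:
    grid: np.ndarray  # sorted unique observed scores
    p_iu: np.ndarray  # raw fraction of regions with score > s
    p_cu: np.ndarray  # raw null fraction
    lor: np.ndarray  # ln of smoothed fractions ratio
    n_iu: np.ndarray  # raw counts N(S_IU > s)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("s\tp_iu\tp_cu\tlor\tn_iu\n")
            for s, a, b, c, d in zip(self.grid, self.p_iu, self.p_cu, self.lor, self.n_iu):
                fh.write(f"{s:.6f}\t{a:.6g}\t{b:.6g}\t{c:.6g}\t{d}\n")


# ---------------------------------------------------------------------------
# coding-sequence sampling


def _sample_coding_batch(
    bundle: GenomeBundle, length: int, count: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """``count`` encoded length-``length`` coding substrings.

    Substrings are drawn uniformly over all positions of single CDSs long
    enough to contain them; genomes with no such CDS fall back to the
    concatenated coding pool (flagged).
    """
    pool, offsets, lengths = bundle.coding_pool
    if pool.size == 0:
        raise InputError(f"genome {bundle.genome_id}: no coding sequence to sample")
    npos = np.clip(lengths - length + 1, 0, None)
    total = int(npos.sum())
    if total > 0:
        cum = np.cumsum(npos)
        u = rng.integers(0, total, size=count)
        gene_idx = np.searchsorted(cum, u, side="right")
        within = u - (cum[gene_idx] - npos[gene_idx])
        starts = offsets[gene_idx] + within
        pooled = False
    else:
        if pool.size < length:
            raise InputError(
                f"genome {bundle.genome_id}: coding pool shorter than {length} bp"
            )
        starts = rng.integers(0, pool.size - length + 1, size=count)
        pooled = True
    X = pool[starts[:, None] + np.arange(length)[None, :]]
    return X, pooled


def sample_null_regions(
    bundle: GenomeBundle,
    region: UpstreamRegion,
    count: int = DEFAULT_NULL_COUNT,
    seed: int = DEFAULT_SEED,
) -> list[UpstreamRegion]:
    """Length-matched random coding regions for one real region."""
    rng = np.random.default_rng(seed)
    X, pooled = _sample_coding_batch(bundle, region.length, count, rng)
    if pooled:
        logger.warning(
            "genome %s: no single CDS >= %d bp; null drawn from concatenated pool",
            bundle.genome_id, region.length,
        )
    from ._alphabet import decode

    return [
        UpstreamRegion(
            region_id=f"{region.region_id}:null{i}",
            tu_id=region.tu_id,
            genome_id=bundle.genome_id,
            sequence=decode(row),
            kind="null_coding",
            flagged=pooled,
        )
        for i, row in enumerate(X)
    ]


# ---------------------------------------------------------------------------
# null distribution


def _tu_ortholog_slots(
    bundle: GenomeBundle,
    tu,
    ortholog_map: OrthologMap,
    other_bundles: Mapping[str, GenomeBundle],
) -> tuple[list[list[tuple[str, int]]], bool]:
    """Per-gene ortholog slots [(genome_k, region_length)], plus whether any
    TU gene has no usable slot (it then contributes 0 to the bonus max)."""
    slots = []
    any_without = False
    for gene_id in tu.gene_ids:
        entries = []
        for genome_k, gene_k in sorted(
            ortholog_map.orthologs_of(bundle.genome_id, gene_id).items()
        ):
            bk = other_bundles.get(genome_k)
            if bk is None:
                continue
            tu_k = bk.tu_of_gene.get(gene_k)
            region_k = bk.regions.get(tu_k) if tu_k else None
            if region_k is None or region_k.length < 1:
                continue
            entries.append((genome_k, region_k.length))
        if entries:
            slots.append(entries)
        else:
            any_without = True
    return slots, any_without


def null_distribution(
    bundle: GenomeBundle,
    profile: MotifProfile,
    ortholog_map: OrthologMap | None = None,
    other_bundles: Mapping[str, GenomeBundle] | None = None,
    count: int = DEFAULT_NULL_COUNT,
    seed: int = DEFAULT_SEED,
    both_strands: bool = True,
) -> NullDistribution:
    """Pooled refined scores of length-matched random coding sequences.

    Every real region contributes ``count`` null scores; each null score
    carries the same ortholog slot structure as the real TU, with slot
    sequences drawn at random from the slot genome's coding sequence.
    """
    other_bundles = other_bundles or {}
    rng = np.random.default_rng(seed)
    scorer = GenomeScorer(profile, bundle.background)
    scorers_k = {
        gid: GenomeScorer(profile, bk.background)
        for gid, bk in other_bundles.items()
        if gid != bundle.genome_id
    }
    l = profile.length
    tus_by_id = {tu.tu_id: tu for tu in bundle.tus}
    pooled: list[np.ndarray] = []
    n_regions = 0
    for tu_id, region in bundle.regions.items():
        if region.length < l:
            continue
        n_regions += 1
        X, _ = _sample_coding_batch(bundle, region.length, count, rng)
        s0, _off, _str, sites0 = batch_best_sites(scorer, X, both_strands)
        valid = np.isfinite(s0)
        if ortholog_map is not None:
            slots, any_without = _tu_ortholog_slots(
                bundle, tus_by_id[tu_id], ortholog_map, other_bundles
            )
            if slots:
                a_genes = []
                for entries in slots:
                    terms = np.zeros(count)
                    for genome_k, L_k in entries:
                        bk = other_bundles[genome_k]
                        Xk, _ = _sample_coding_batch(bk, L_k, count, rng)
                        sk, _o, _s, sites_k = batch_best_sites(
                            scorers_k[genome_k], Xk, both_strands
                        )
                        d = (sites0 != sites_k).sum(axis=1)
                        term = (l - d) / l * sk
                        terms += np.where(np.isfinite(term), term, 0.0)
                    a_genes.append(terms / len(entries))
                a_max = np.max(a_genes, axis=0)
                if any_without:
                    a_max = np.maximum(a_max, 0.0)
                s0 = s0 + np.where(valid, a_max, 0.0)
        pooled.append(s0[valid])
    if not pooled:
        raise InputError(f"genome {bundle.genome_id}: no scannable regions for null")
    return NullDistribution(
        genome_id=bundle.genome_id,
        scores=np.concatenate(pooled),
        n_samples_per_region=count,
        seed=seed,
        n_regions=n_regions,
    )


# ---------------------------------------------------------------------------
# p-values, cutoffs, LOR


def empirical_pvalue(null: NullDistribution, s: float) -> float:
    """Fraction of null scores strictly greater than s."""
    if null.n == 0:
        raise InputError("empty null distribution")
    greater = null.n - np.searchsorted(null.scores, s, side="right")
    return float(greater) / null.n


def annotate_hits(hits: Sequence[ScanHit], null: NullDistribution) -> None:
    """Attach empirical p-values to valid hits in place."""
    for h in hits:
        if h.valid:
            h.pvalue = empirical_pvalue(null, h.s)
            h.pvalue_below_floor = h.pvalue == 0.0


def score_cutoff(null: NullDistribution, p_target: float) -> CutoffResult:
    """Smallest observed null score whose empirical p-value is < p_target."""
    if null.n == 0:
        raise InputError("empty null distribution")
    # p-value of each sorted score, tie-aware: fraction strictly greater
    n = null.n
    pvals = (n - np.searchsorted(null.scores, null.scores, side="right")) / n
    ok = pvals < p_target
    if not ok.any():  # cannot happen: the max always has p = 0
        raise AssertionError
    k = int(np.argmax(ok))
    achieved = p_target > 1.0 / n
    if not achieved:
        logger.warning(
            "p-target %g below the 1/N = %g resolution of the null", p_target, 1.0 / n
        )
    return CutoffResult(score=float(null.scores[k]), pvalue=float(pvals[k]), achieved=achieved)


def lor_curve(observed_scores: Sequence[float], null: NullDistribution) -> LorCurve:
    """LOR(s) over the sorted unique observed scores."""
    obs = np.sort(np.asarray([s for s in observed_scores if np.isfinite(s)], dtype=float))
    if obs.size == 0:
        raise InputError("lor_curve: no observed scores")
    grid = np.unique(obs)
    n_obs, n_null = obs.size, null.n
    n_iu = n_obs - np.searchsorted(obs, grid, side="right")
    n_cu = n_null - np.searchsorted(null.scores, grid, side="right")
    p_iu = n_iu / n_obs
    p_cu = n_cu / n_null
    lor = np.log((n_iu + 1.0) / (n_obs + 1.0)) - np.log((n_cu + 1.0) / (n_null + 1.0))
    return LorCurve(grid=grid, p_iu=p_iu, p_cu=p_cu, lor=lor, n_iu=n_iu)


def lor_at(curve: LorCurve, s: float) -> float:
    """LOR evaluated at the largest grid score <= s (step function)."""
    idx = int(np.searchsorted(curve.grid, s, side="right")) - 1
    idx = max(0, min(idx, len(curve.grid) - 1))
    return float(curve.lor[idx])
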