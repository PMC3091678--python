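import math

import numpy as np
import pytest

from regulonscan._alphabet import revcomp
from regulonscan.motif_profile import build_profile, load_reference_sites
from regulonscan.scanner import (
    ScanHit,
    best_site,
    hamming,
    orthology_bonus,
    refined_score,
    scan_genome,
    score_window,
    write_hits_tsv,
)

SITE = "AGTACTAATGTTCT"


@pytest.fixture
def single_site_profile(uniform_bg):
    return build_profile([SITE], uniform_bg)


class TestScoreWindow:
    def test_perfect_match_closed_form(self, single_site_profile, uniform_bg):
        s = score_window(single_site_profile, SITE, uniform_bg)
        assert s == pytest.approx(14 * math.log(1.6), abs=1e-9)

    def test_single_mismatch_closed_form(self, single_site_profile, uniform_bg):
        mutated = "C" + SITE[1:]
        s = score_window(single_site_profile, mutated, uniform_bg)
        assert s == pytest.approx(13 * math.log(1.6) + math.log(0.8), abs=1e-9)

    def test_zero_information_column_contributes_nothing(self, uniform_bg):
        # a uniform column has I = 0; changing its base must not move the score
        sites = ["AAAA", "CAAA", "GAAA", "TAAA"]  # column 0 uniform, rest all-A
        prof = build_profile(sites, uniform_bg)
        assert prof.information[0] == pytest.approx(0.0, abs=1e-12)
        scores = {score_window(prof, b + "AAA", uniform_bg) for b in "ACGT"}
        assert max(scores) - min(scores) < 1e-12

    def test_n_in_window_rejected(self, single_site_profile, uniform_bg):
        with pytest.raises(ValueError, match="N"):
            score_window(single_site_profile, "N" + SITE[1:], uniform_bg)


class TestBestSite:
    def test_recovers_planted_site(self, single_site_profile, uniform_bg):
        rng = np.random.default_rng(5)
        bg_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        region = bg_seq[:40] + SITE + bg_seq[40:]
        hit = best_site(single_site_profile, region, uniform_bg)
        assert hit.offset == 40 and hit.site == SITE
        assert hit.s_M == pytest.approx(14 * math.log(1.6))

    def test_reverse_complement_same_score_minus_orientation(
        self, single_site_profile, uniform_bg
    ):
        rng = np.random.default_rng(6)
        bg_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        fwd = bg_seq[:30] + SITE + bg_seq[30:]
        rev = revcomp(fwd)
        h_f = best_site(single_site_profile, fwd, uniform_bg)
        h_r = best_site(single_site_profile, rev, uniform_bg)
        assert h_r.s_M == pytest.approx(h_f.s_M)
        assert h_r.strand_of_window == "-" and h_r.site == SITE

    def test_short_region_gives_sentinel(self, single_site_profile, uniform_bg):
        hit = best_site(single_site_profile, "ACGTACGTACGTA", uniform_bg)  # 13 bp
        assert not hit.valid

    def test_all_n_windows_give_sentinel(self, single_site_profile, uniform_bg):
        hit = best_site(single_site_profile, "ACGTACG" + "N" + "ACGTACGTAC", uniform_bg)
        assert not hit.valid

    def test_single_strand_mode_misses_reverse_site(
        self, single_site_profile, uniform_bg
    ):
        region = revcomp("ACGT" * 10 + SITE + "ACGT" * 10)
        h_both = best_site(single_site_profile, region, uniform_bg, both_strands=True)
        h_fwd = best_site(single_site_profile, region, uniform_bg, both_strands=False)
        assert h_both.s_M > h_fwd.s_M

    def test_matches_brute_force_enumeration(self, ref_profile, uniform_bg):
        # independent oracle: hand-summed score of every l-mer, both strands
        rng = np.random.default_rng(11)
        l = ref_profile.length
        logw = ref_profile.information[:, None] * (
            np.log(ref_profile.p) - np.log(uniform_bg.q)[None, :]
        )
        idx = {b: i for i, b in enumerate("ACGT")}
        for _ in range(200):
            region = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
            best = -np.inf
            for strand_seq in (region, revcomp(region)):
                for off in range(len(region) - l + 1):
                    w = strand_seq[off : off + l]
                    s = sum(logw[i, idx[c]] for i, c in enumerate(w))
                    best = max(best, s)
            hit = best_site(ref_profile, region, uniform_bg)
            assert hit.s_M == pytest.approx(best, abs=1e-9)

    def test_score_monotone_toward_column_argmax(self, ref_profile, uniform_bg):
        # mutating any best-window base to the column's argmax cannot lower s_M
        rng = np.random.default_rng(23)
        region = "".join("ACGT"[i] for i in rng.integers(0, 4, 80))
        hit = best_site(ref_profile, region, uniform_bg, both_strands=False)
        argmax = [int(np.argmax(ref_profile.p[i])) for i in range(ref_profile.length)]
        seq = list(region)
        for i in range(ref_profile.length):
            if hit.strand_of_window == "+":
                seq[hit.offset + i] = "ACGT"[argmax[i]]
            improved = best_site(
                ref_profile, "".join(seq), uniform_bg, both_strands=False
            )
            assert improved.s_M >= hit.s_M - 1e-12


class TestOrthologyBonus:
    def _hit(self, site=SITE, s_m=5.0):
        return ScanHit("TU1", "r", "G", site, 0, "+", s_m)

    def _ortho(self, site, s_m):
        return ScanHit("TUk", "rk", "K", site, 0, "+", s_m)

    def test_identical_site_full_weight(self):
        a, gene, detail = orthology_bonus(
            ["g1"], self._hit(), {"g1": [("K", self._ortho(SITE, 6.0))]}, 14
        )
        assert a == pytest.approx(6.0) and gene == "g1"
        assert detail == [("K", SITE, 6.0, 0)]

    def test_one_mismatch_scales_by_13_14(self):
        other = "C" + SITE[1:]
        a, _gene, _d = orthology_bonus(
            ["g1"], self._hit(), {"g1": [("K", self._ortho(other, 6.0))]}, 14
        )
        assert a == pytest.approx(13 / 14 * 6.0)

    def test_max_over_genes(self):
        hits = {
            "g1": [("K1", self._ortho(SITE, 2.0)), ("K2", self._ortho(SITE, 2.0))],
            "g2": [("K1", self._ortho(SITE, 3.5))],
        }
        a, gene, _d = orthology_bonus(["g1", "g2"], self._hit(), hits, 14)
        assert a == pytest.approx(3.5) and gene == "g2"

    def test_no_orthologs_zero_bonus(self):
        a, gene, detail = orthology_bonus(["g1"], self._hit(), {}, 14)
        assert a == 0.0 and gene is None and detail == []

    def test_negative_average_floored_by_orthologless_gene(self):
        hits = {"g1": [("K", self._ortho(SITE, -2.0))]}
        a, _g, _d = orthology_bonus(["g1", "g2"], self._hit(), hits, 14)
        assert a == 0.0  # g2 has no orthologs and contributes 0 to the max

    def test_negative_average_kept_when_every_gene_has_orthologs(self):
        hits = {"g1": [("K", self._ortho(SITE, -2.0))]}
        a, _g, _d = orthology_bonus(["g1"], self._hit(), hits, 14)
        assert a == pytest.approx(-2.0)


class TestRefinedScore:
    def test_additivity(self):
        hit = ScanHit("TU1", "r", "G", SITE, 0, "+", 4.2, A_max=6.0)
        assert refined_score(hit) == pytest.approx(10.2)
        assert hit.s - hit.s_M == pytest.approx(hit.A_max)

    def test_no_orthologs_score_is_s_m(self):
        hit = ScanHit("TU1", "r", "G", SITE, 0, "+", 4.2)
        assert refined_score(hit) == pytest.approx(4.2)


class TestScanGenome:
    def test_planted_tus_top_ranked(self, small_dataset, ref_profile):
        ds = small_dataset
        target = ds.target_genome
        prof = build_profile(load_reference_sites(), ds.bundles[target].background)
        hits = scan_genome(ds.bundles[target], prof, ds.ortholog_map, ds.bundles)
        planted = {r.tu_id for r in ds.truth.for_genome(target)}
        top = {h.tu_id for h in hits[: len(planted)]}
        assert len(top & planted) >= len(planted) - 1

    def test_no_reference_genomes_leaves_pure_profile_scores(
        self, small_dataset, ref_profile
    ):
        ds = small_dataset
        target = ds.target_genome
        hits = scan_genome(ds.bundles[target], ref_profile)
        assert all(h.A_max == 0.0 for h in hits)

    def test_empty_genome_gives_empty_list(self, ref_profile):
        from regulonscan.sequence_model import GenomeBundle

        bundle = GenomeBundle("E", {"c": "ACGT" * 100}, [])
        bundle.background = ref_profile.background
        assert scan_genome(bundle, ref_profile) == []

    def test_reproducible_hit_tables(self, small_dataset, ref_profile, tmp_path):
        ds = small_dataset
        target = ds.target_genome
        paths = []
        for i in range(2):
            hits = scan_genome(ds.bundles[target], ref_profile, ds.ortholog_map, ds.bundles)
            p = tmp_path / f"hits{i}.tsv"
            write_hits_tsv(hits, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]


def test_hamming_requires_equal_length():
    with pytest.raises(ValueError):
        hamming("ACGT", "ACG")
    assert hamming(SITE, SITE) == 0
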