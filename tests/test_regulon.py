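import itertools

import numpy as np
import pytest

from regulonscan.orthology import OrthologMap, OrthologPair
from regulonscan.regulon import (
    ConservationMatrix,
    Regulon,
    conservation_distance_matrix,
    neighbor_joining,
    predict_regulon,
    regulon_conservation,
)
from regulonscan.scanner import ScanHit
from regulonscan.sequence_model import InputError, TranscriptionUnit


def _hit(tu_id, pvalue, s_m=5.0):
    return ScanHit(tu_id, "r", "G", "A" * 14, 0, "+", s_m, pvalue=pvalue)


def _tus(spec):
    return {
        tu_id: TranscriptionUnit(tu_id, "G", tuple(genes), "+")
        for tu_id, genes in spec.items()
    }


def _map_identity(genome_a, genome_b, genes):
    return OrthologMap([OrthologPair(genome_a, g, genome_b, g) for g in genes])


class TestPredictRegulon:
    def test_union_of_member_genes(self):
        tus = _tus({"T1": ["a", "b"], "T2": ["c", "d", "e"], "T3": ["f"]})
        hits = [_hit("T1", 0.001), _hit("T2", 0.005), _hit("T3", 0.5)]
        reg = predict_regulon(hits, tus, threshold=0.01)
        assert reg.genes == frozenset("abcde")

    def test_no_passing_tu_gives_empty_regulon(self):
        tus = _tus({"T1": ["a"]})
        reg = predict_regulon([_hit("T1", 0.9)], tus, threshold=0.01)
        assert len(reg) == 0

    def test_looser_threshold_is_superset(self):
        tus = _tus({"T1": ["a"], "T2": ["b"], "T3": ["c"]})
        hits = [_hit("T1", 0.001), _hit("T2", 0.03), _hit("T3", 0.2)]
        strict = predict_regulon(hits, tus, 0.01)
        loose = predict_regulon(hits, tus, 0.05)
        assert strict.genes <= loose.genes


class TestConservation:
    def test_jaccard_arithmetic(self):
        r_i = Regulon("Gi", frozenset("abcd"), 0.01)
        r_j = Regulon("Gj", frozenset("abx"), 0.01)
        omap = _map_identity("Gi", "Gj", "ab")
        assert regulon_conservation(r_i, r_j, omap) == pytest.approx(0.4)  # 2/5

    def test_identical_fully_orthologous_is_one(self):
        r_i = Regulon("Gi", frozenset("abc"), 0.01)
        r_j = Regulon("Gj", frozenset("abc"), 0.01)
        omap = _map_identity("Gi", "Gj", "abc")
        assert regulon_conservation(r_i, r_j, omap) == 1.0

    def test_disjoint_is_zero(self):
        r_i = Regulon("Gi", frozenset("ab"), 0.01)
        r_j = Regulon("Gj", frozenset("cd"), 0.01)
        omap = _map_identity("Gi", "Gj", "abcd")
        assert regulon_conservation(r_i, r_j, omap) == 0.0

    def test_both_empty_undefined(self):
        r_i = Regulon("Gi", frozenset(), 0.01)
        r_j = Regulon("Gj", frozenset(), 0.01)
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(regulon_conservation(r_i, r_j, OrthologMap([])))

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(20)]
        r_i = Regulon("Gi", frozenset(rng.choice(genes, 8, replace=False)), 0.01)
        r_j = Regulon("Gj", frozenset(rng.choice(genes, 11, replace=False)), 0.01)
        omap = _map_identity("Gi", "Gj", genes)
        c_ij = regulon_conservation(r_i, r_j, omap)
        c_ji = regulon_conservation(r_j, r_i, omap)
        assert c_ij == c_ji and 0 <= c_ij <= 1


class TestDistanceMatrix:
    def _three(self, c_ab):
        regs = [
            Regulon("Ga", frozenset("abcd"), 0.01),
            Regulon("Gb", frozenset("abx"), 0.01),
            Regulon("Gc", frozenset("zz2"), 0.01),
        ]
        pairs = [OrthologPair("Ga", g, "Gb", g) for g in c_ab]
        return regs, OrthologMap(pairs)

    def test_reciprocal_rule(self):
        regs, omap = self._three("ab")  # c(Ga,Gb) = 2/5 = 0.4
        m = conservation_distance_matrix(regs, omap)
        i, j = m.genome_ids.index("Ga"), m.genome_ids.index("Gb")
        assert m.d[i, j] == pytest.approx(2.5)

    def test_diagonal_forced_zero(self):
        regs, omap = self._three("ab")
        m = conservation_distance_matrix(regs, omap)
        assert np.all(np.diag(m.d) == 0) and np.all(np.diag(m.c) == 1)

    def test_zero_conservation_capped(self):
        regs, omap = self._three("ab")
        m = conservation_distance_matrix(regs, omap)
        # Gc shares nothing: its distances are 10x the largest finite one (2.5)
        k = m.genome_ids.index("Gc")
        others = [i for i in range(3) if i != k]
        assert all(m.d[k, i] == pytest.approx(25.0) for i in others)

    def test_explicit_cap_honoured(self):
        regs, omap = self._three("ab")
        m = conservation_distance_matrix(regs, omap, zero_cap=99.0)
        k = m.genome_ids.index("Gc")
        assert m.d[k, (k + 1) % 3] == 99.0

    def test_full_similarity_distance_one(self):
        regs = [
            Regulon("Ga", frozenset("ab"), 0.01),
            Regulon("Gb", frozenset("ab"), 0.01),
            Regulon("Gc", frozenset("ab"), 0.01),
        ]
        pairs = [
            OrthologPair(x, g, y, g)
            for x, y in itertools.combinations(["Ga", "Gb", "Gc"], 2)
            for g in "ab"
        ]
        m = conservation_distance_matrix(regs, OrthologMap(pairs))
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(m.d[off], 1.0)


def _ls_fit_four_taxa(D):
    """Least-squares branch lengths for each unrooted 4-taxon topology.

    Returns (best_split, lengths dict, residual) by brute force over the
    three topologies; the independent oracle for NJ on additive input.
    """
    taxa = list(D.keys())
    results = []
    for split in [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]:
        cherry = {i: grp for grp in split for i in grp}
        rows, y = [], []
        for i, j in itertools.combinations(range(4), 2):
            x = np.zeros(5)
            x[i] = x[j] = 1.0
            if cherry[i] is not cherry[j]:
                x[4] = 1.0
            rows.append(x)
            y.append(D[taxa[i]][taxa[j]])
        sol, *_ = np.linalg.lstsq(np.array(rows), np.array(y), rcond=None)
        resid = float(np.sum((np.array(rows) @ sol - np.array(y)) ** 2))
        results.append((split, sol, resid))
    split, sol, resid = min(results, key=lambda r: r[2])
    lengths = {taxa[i]: sol[i] for i in range(4)}
    lengths["internal"] = sol[4]
    return split, lengths, resid


class TestNeighborJoining:
    # additive distances from tree ((A:1,B:2):1,(C:3,D:1))
    D4 = {
        "A": {"B": 3.0, "C": 5.0, "D": 3.0},
        "B": {"A": 3.0, "C": 6.0, "D": 4.0},
        "C": {"A": 5.0, "B": 6.0, "D": 4.0},
        "D": {"A": 3.0, "B": 4.0, "C": 4.0},
    }

    def _matrix(self, D, names):
        n = len(names)
        d = np.zeros((n, n))
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if a != b:
                    d[i, j] = D[a][b]
        c = np.where(d > 0, 1.0 / np.where(d > 0, d, 1.0), 1.0)
        return ConservationMatrix(tuple(names), c, d)

    def test_recovers_additive_four_taxon_tree(self):
        split, lengths, resid = _ls_fit_four_taxa(self.D4)
        assert resid < 1e-18 and set("AB") == {"ABCD"[i] for i in split[0]}
        tree = neighbor_joining(self._matrix(self.D4, ["A", "B", "C", "D"]))
        tip_sets = [
            frozenset(t.name for t in node.tips())
            for node in tree.non_tips(include_self=False)
        ]
        assert frozenset("AB") in tip_sets or frozenset("CD") in tip_sets
        got = {t.name: t.length for t in tree.tips()}
        for taxon in "ABCD":
            assert got[taxon] == pytest.approx(lengths[taxon], abs=1e-9)
        total = sum(n.length or 0 for n in tree.traverse() if n.length)
        assert total == pytest.approx(sum(lengths.values()), abs=1e-9)

    def test_three_taxon_closed_form(self):
        D = {"A": {"B": 3.0, "C": 4.0}, "B": {"A": 3.0, "C": 5.0}, "C": {"A": 4.0, "B": 5.0}}
        tree = neighbor_joining(self._matrix(D, ["A", "B", "C"]))
        got = {t.name: t.length for t in tree.tips()}
        assert got == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_taxon_order_invariance(self):
        t1 = neighbor_joining(self._matrix(self.D4, ["A", "B", "C", "D"]))
        t2 = neighbor_joining(self._matrix(self.D4, ["D", "B", "A", "C"]))
        assert t1.compare_rfd(t2) == 0.0

    def test_fewer_than_three_taxa_rejected(self):
        m = ConservationMatrix(("A", "B"), np.eye(2), np.array([[0.0, 1], [1, 0]]))
        with pytest.raises(InputError):
            neighbor_joining(m)


def test_phylip_round_trip(tmp_path):
    rng = np.random.default_rng(12)
    n = 5
    d = rng.uniform(1, 9, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    names = tuple(f"G{i:02d}" for i in range(n))
    m = ConservationMatrix(names, np.ones((n, n)), d)
    path = tmp_path / "dist.phylip"
    m.write_phylip(path)
    back = ConservationMatrix.read_phylip(path)
    assert back.genome_ids == names
    assert np.allclose(back.d, d, atol=1e-6)
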