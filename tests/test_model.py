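"""Neighborhood extraction, orientation, hit filtering and search semantics."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from genectx import (
    AnchorNotFoundError,
    DuplicateGeneIdError,
    Gene,
    GenomeRecord,
    HitFilterConfig,
    HitRecord,
    Neighborhood,
    NeighborhoodConfig,
    NeighborhoodSet,
    SourceRef,
    extract_neighborhood,
    filter_hits,
    flip,
    normalize_orientation,
    search_term,
    select_by_taxonomy,
    select_top_by_evalue,
)

from ._oracles import brute_force_window
from .conftest import random_genome


def _gene(gid, start, end, strand="+", product="", labels=None):
    return Gene(gid, "ctg", start, end, strand, product, labels or {})


def _genome(genes, length=6000):
    return GenomeRecord("ctg", length, "genomeX", genes=genes)


class TestExtractNeighborhood:
    def test_single_gene_genome(self):
        g = _genome([_gene("g1", 100, 400)])
        n = extract_neighborhood(g, "g1")
        assert [x.gene_id for x in n.genes] == ["g1"]
        assert n.anchor_id == "g1" and not n.flipped

    def test_window_bounds_and_membership(self):
        g = _genome(
            [_gene("g1", 100, 400), _gene("g2", 900, 1200), _gene("g3", 5000, 5300)]
        )
        n = extract_neighborhood(g, "g2", NeighborhoodConfig(window_bp=1000))
        assert (n.window_start, n.window_end) == (1, 2200)
        assert [x.gene_id for x in n.genes] == ["g1", "g2"]

    def test_edge_spanning_gene_excluded(self):
        g = _genome(
            [
                _gene("g1", 100, 400),
                _gene("g2", 900, 1200),
                _gene("g3", 5000, 5300),
                _gene("g4", 2100, 2400),  # crosses the window edge at 2200
            ]
        )
        n = extract_neighborhood(g, "g2", NeighborhoodConfig(window_bp=1000))
        assert "g4" not in [x.gene_id for x in n.genes]

    def test_default_window_is_10kb(self):
        assert NeighborhoodConfig().window_bp == 10_000

    def test_unknown_anchor(self):
        with pytest.raises(AnchorNotFoundError, match="anchor not found.*nope"):
            extract_neighborhood(_genome([_gene("g1", 100, 400)]), "nope")

    def test_duplicate_anchor_id(self):
        g = _genome([_gene("dup", 100, 400), _gene("dup", 900, 1200)])
        with pytest.raises(DuplicateGeneIdError, match="duplicate gene id"):
            extract_neighborhood(g, "dup")

    @given(seed=st.integers(0, 10_000), window=st.sampled_from([500, 2000, 10_000]))
    def test_matches_brute_force_on_random_genomes(self, seed, window):
        genome = random_genome(seed)
        for anchor in genome.genes[:: max(1, len(genome.genes) // 3)]:
            n = extract_neighborhood(
                genome, anchor.gene_id, NeighborhoodConfig(window_bp=window)
            )
            ws, we, expected = brute_force_window(genome, anchor, window)
            assert (n.window_start, n.window_end) == (ws, we)
            assert {g.gene_id for g in n.genes} == expected
            assert anchor.gene_id in {g.gene_id for g in n.genes}
            starts = [g.start for g in n.genes]
            assert starts == sorted(starts)


class TestFlip:
    def _nbh(self):
        genes = [_gene("a", 100, 400, "+"), _gene("b", 900, 1200, "+")]
        return Neighborhood("n1", "b", genes, 1, 2200)

    def test_reflection_formula(self):
        flipped = flip(self._nbh())
        b = next(g for g in flipped.genes if g.gene_id == "b")
        # independent check: reflect both endpoints around the window
        assert (b.start, b.end, b.strand) == (1 + 2200 - 1200, 1 + 2200 - 900, "-")
        assert (b.start, b.end) == (1001, 1301)

    def test_involution_and_order_reversal(self):
        n = self._nbh()
        assert flip(flip(n)) == n
        assert [g.gene_id for g in flip(n).genes] == ["b", "a"]

    def test_strand_toggle_single_gene(self):
        n = Neighborhood("n1", "a", [_gene("a", 10, 40, "-")], 1, 100)
        assert flip(n).anchor.strand == "+"

    @given(seed=st.integers(0, 5000))
    def test_involution_on_random_neighborhoods(self, seed):
        genome = random_genome(seed)
        anchor = genome.genes[len(genome.genes) // 2]
        n = extract_neighborhood(genome, anchor.gene_id)
        assert flip(flip(n)) == n
        assert [g.gene_id for g in flip(n).genes] == [
            g.gene_id for g in reversed(n.genes)
        ]


class TestNormalizeOrientation:
    def _set(self, strands):
        nbhs = []
        for i, s in enumerate(strands):
            g = _gene("a", 100, 400, s)
            nbhs.append(Neighborhood(f"n{i}", "a", [g], 1, 500))
        return NeighborhoodSet(nbhs, active_namespace="pfam")

    def test_all_plus_unchanged(self):
        s = self._set(["+", "+"])
        assert normalize_orientation(s).neighborhoods == s.neighborhoods

    def test_mixed_set_all_anchors_plus_and_idempotent(self):
        s = self._set(["+", "-", "-", "+"])
        out = normalize_orientation(s)
        assert all(n.anchor.strand == "+" for n in out)
        assert [n.neighborhood_id for n in out] == [n.neighborhood_id for n in s]
        assert normalize_orientation(out).neighborhoods == out.neighborhoods


class TestHitOperations:
    def _hit(self, evalue=1e-6, ident=45.0, q=80.0, s=75.0, bits=100.0, tax=()):
        return HitRecord("q", "s", ident, evalue, bits, q, s, tax)

    def test_defaults_retain_passing_hit(self):
        assert filter_hits([self._hit()]) == [self._hit()]

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"evalue": 1e-4},
            {"ident": 29.9},
            {"q": 69.0},
            {"s": 50.0},
        ],
    )
    def test_each_threshold_is_enforced(self, kwargs):
        assert filter_hits([self._hit(**kwargs)]) == []

    def test_empty_list_and_purity(self):
        assert filter_hits([]) == []
        hits = [self._hit(evalue=10.0 ** -e) for e in range(3, 12)]
        kept = filter_hits(hits)
        assert all(h in hits for h in kept)
        assert filter_hits(kept) == kept  # idempotent

    def test_top_by_evalue_order_and_ties(self):
        h1 = self._hit(evalue=1e-10)
        h2 = self._hit(evalue=1e-3)
        h3 = self._hit(evalue=1e-7)
        assert select_top_by_evalue([h1, h2, h3], 2) == [h1, h3]
        assert select_top_by_evalue([h1, h2, h3], 99) == [h1, h3, h2]
        tie_a = self._hit(evalue=1e-5, bits=200.0)
        tie_b = self._hit(evalue=1e-5, bits=150.0)
        assert select_top_by_evalue([tie_b, tie_a], 1) == [tie_a]

    def test_top_n_monotone_prefix(self):
        import numpy as np

        rng = np.random.default_rng(3)
        hits = [self._hit(evalue=float(10.0 ** rng.uniform(-40, 0))) for _ in range(30)]
        for n in range(1, 30):
            assert set(
                id(h) for h in select_top_by_evalue(hits, n)
            ) <= set(id(h) for h in select_top_by_evalue(hits, n + 1))

    def test_select_by_taxonomy_case_insensitive(self):
        tax = (("domain", "Archaea"), ("genus", "methanosarcina"))
        inside, outside = self._hit(tax=tax), self._hit(tax=(("genus", "Bacillus"),))
        assert select_by_taxonomy([inside, outside], "genus", "Methanosarcina") == [
            inside
        ]
        assert select_by_taxonomy([outside], "genus", "Methanosarcina") == []


class TestSearchTerm:
    def _set(self):
        genes = [
            _gene("f1", 100, 400, product="flagellar M-ring protein FliF"),
            _gene("f2", 500, 800, product="flagellar motor switch protein FliG"),
            _gene("h1", 900, 1000, product="hypothetical protein",
                  labels={"pfam": {"PF18765"}}),
        ]
        return NeighborhoodSet(
            [Neighborhood("n1", "f1", genes, 1, 1100)], active_namespace="pfam"
        )

    def test_product_substring(self):
        assert [g for _, g in search_term(self._set(), "flagellar")] == ["f1", "f2"]

    def test_empty_term_matches_nothing(self):
        assert search_term(self._set(), "") == []

    def test_label_search_case_insensitive(self):
        assert search_term(self._set(), "pf18765") == [("n1", "h1")]
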