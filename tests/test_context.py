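"""Neighborhood windows and the three over-representation summaries."""

import pytest
from hypothesis import given, settings, strategies as st

from funcdisc.context import (AnalysisConfig, extract_neighborhood,
                              run_analysis, summarize_enzymes,
                              summarize_metabolites, summarize_pathways)
from funcdisc.datastore import Datastore, MetabolicReference
from funcdisc.homology import HomologQuery
from tests.conftest import make_genome, make_reference
from tests.oracles import neighborhood_members_oracle, recount_tables_oracle


def window_indices(genome, anchor, n):
    nb = extract_neighborhood(genome, anchor, n)
    return [g.index for g in nb.genes]


class TestExtractNeighborhood:
    def test_zero_neighbors_returns_anchor_only(self):
        genome = make_genome("aa", [{} for _ in range(5)])
        nb = extract_neighborhood(genome, "aa:b0003", 0)
        assert [g.gene_id for g in nb.genes] == ["aa:b0003"]

    def test_linear_window_truncates_at_ends(self):
        genome = make_genome("aa", [{} for _ in range(8)])
        assert window_indices(genome, "aa:b0006", 10) == list(range(8))

    def test_circular_window_wraps(self):
        genome = make_genome("aa", [{} for _ in range(10)],
                             topology="circular")
        assert window_indices(genome, "aa:b0001", 3) == [0, 1, 2, 3, 7, 8, 9]

    def test_circular_window_never_duplicates_genes(self):
        genome = make_genome("aa", [{} for _ in range(6)],
                             topology="circular")
        idx = window_indices(genome, "aa:b0002", 10)
        assert idx == list(range(6))

    def test_missing_anchor_is_error(self):
        genome = make_genome("aa", [{}])
        with pytest.raises(KeyError):
            extract_neighborhood(genome, "aa:nope", 2)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(size=st.integers(1, 25), anchor=st.integers(0, 24),
           n=st.integers(0, 30), circular=st.booleans())
    def test_membership_matches_distance_oracle(self, size, anchor, n,
                                                circular):
        anchor = anchor % size
        genome = make_genome("aa", [{} for _ in range(size)],
                             topology="circular" if circular else "linear")
        got = set(window_indices(genome, f"aa:b{anchor + 1:04d}", n))
        assert got == neighborhood_members_oracle(size, anchor, n, circular)


def nb_of(genome, anchor, n=2):
    return extract_neighborhood(genome, anchor, n)


class TestEnzymeSummary:
    def test_frequency_counts_distinct_neighborhoods(self):
        g1 = make_genome("aa", [{"ec": ["1.1.1.103"]}, {"ec": ["1.1.1.103"]},
                                {}])
        g2 = make_genome("bb", [{"ec": ["1.1.1.103"]}, {}, {}])
        g3 = make_genome("cc", [{}, {}, {}])
        nbs = [nb_of(g1, "aa:b0001"), nb_of(g2, "bb:b0001"),
               nb_of(g3, "cc:b0001")]
        rows = summarize_enzymes(nbs)
        assert [(r.ec, r.frequency) for r in rows] == [("1.1.1.103", 2)]
        assert rows[0].neighborhoods == ("aa:b0001", "bb:b0001")

    def test_no_ecs_yields_empty_table(self):
        g = make_genome("aa", [{}, {}, {}])
        assert summarize_enzymes([nb_of(g, "aa:b0002")]) == []

    def test_planted_ec_outranks_sparse_decoys(self):
        # the planted EC appears in 4 of 5 neighborhoods, each decoy in 1
        genomes = []
        for i in range(5):
            ec = ["1.1.1.101"] if i < 4 else []
            decoy = [f"9.9.9.{i + 1}"]
            genomes.append(make_genome(f"g{i}", [{"ec": ec}, {}, {"ec": decoy}]))
        nbs = [nb_of(g, f"g{i}:b0002") for i, g in enumerate(genomes)]
        rows = summarize_enzymes(nbs)
        assert rows[0].ec == "1.1.1.101" and rows[0].frequency == 4
        assert all(r.frequency == 1 for r in rows[1:])


REF = make_reference(
    {"1.1.1.1": {"R1": (["CA", "CB"], ["CC"])}},
    ec_pathways={"1.1.1.1": ["P1"]},
    compound_pathways={"CA": ["P1"], "CB": ["P1"], "CC": ["P1"]})


class TestMetaboliteSummary:
    def test_reaction_compounds_inherit_neighborhood_frequency(self):
        genomes = [make_genome(f"g{i}", [{"ec": ["1.1.1.1"]}, {}, {}])
                   for i in range(4)]
        nbs = [nb_of(g, f"g{i}:b0001") for i, g in enumerate(genomes)]
        enz = summarize_enzymes(nbs)
        rows = summarize_metabolites(enz, nbs, REF)
        assert {(r.compound_id, r.frequency) for r in rows} == \
            {("CA", 4), ("CB", 4), ("CC", 4)}

    def test_exclusion_list_removes_currency_compounds(self):
        g = make_genome("aa", [{"ec": ["1.1.1.1"]}])
        nbs = [nb_of(g, "aa:b0001")]
        cfg = AnalysisConfig(exclude_compounds=frozenset({"CA"}))
        rows = summarize_metabolites(summarize_enzymes(nbs), nbs, REF, cfg)
        assert {r.compound_id for r in rows} == {"CB", "CC"}

    def test_shared_compound_counts_neighborhoods_not_ec_sum(self):
        # two different ECs whose reactions share compound CX; a
        # neighborhood containing both must count once
        ref = make_reference(
            {"1.1.1.1": {"R1": (["CX"], ["CY"])},
             "2.2.2.2": {"R2": (["CX"], ["CZ"])}})
        loci = [{"ec": ["1.1.1.1"]}, {"ec": ["2.2.2.2"]}, {}]
        genomes = [make_genome(f"g{i}", loci) for i in range(5)]
        nbs = [nb_of(g, f"g{i}:b0002") for i, g in enumerate(genomes)]
        rows = summarize_metabolites(summarize_enzymes(nbs), nbs, ref)
        freq = {r.compound_id: r.frequency for r in rows}
        assert freq["CX"] == 5          # not 10
        ec_freq, cpd_freq, _ = recount_tables_oracle(nbs, ref)
        assert freq == cpd_freq


class TestPathwaySummary:
    def test_unmapped_ecs_yield_empty_pathway_table(self):
        # mirrors a transport ATPase with an EC but no pathway membership
        ref = make_reference({"3.6.3.29": {"R1": (["CM"], [])}})
        g = make_genome("aa", [{"ec": ["3.6.3.29"]}])
        nbs = [nb_of(g, "aa:b0001")]
        enz = summarize_enzymes(nbs)
        met = summarize_metabolites(enz, nbs, ref)
        assert enz and summarize_pathways(enz, met, ref) == []

    def test_weighted_hits_sum_enzyme_and_compound_frequencies(self):
        genomes = [make_genome(f"g{i}", [{"ec": ["1.1.1.1"]}])
                   for i in range(3)]
        nbs = [nb_of(g, f"g{i}:b0001") for i, g in enumerate(genomes)]
        enz = summarize_enzymes(nbs)
        met = summarize_metabolites(enz, nbs, REF)
        rows = summarize_pathways(enz, met, REF)
        # EC freq 3 plus three compounds at freq 3 each
        assert [(r.pathway_id, r.hits) for r in rows] == [("P1", 12)]
        assert rows[0].ecs == ("1.1.1.1",)
        assert rows[0].compounds == ("CA", "CB", "CC")

    def test_distinct_mode_counts_entities_once(self):
        genomes = [make_genome(f"g{i}", [{"ec": ["1.1.1.1"]}])
                   for i in range(3)]
        nbs = [nb_of(g, f"g{i}:b0001") for i, g in enumerate(genomes)]
        enz = summarize_enzymes(nbs)
        met = summarize_metabolites(enz, nbs, REF)
        cfg = AnalysisConfig(score_mode="distinct")
        rows = summarize_pathways(enz, met, REF, cfg)
        assert [(r.pathway_id, r.hits) for r in rows] == [("P1", 4)]


class TestRunAnalysis:
    def test_end_to_end_defaults_on_fixture(self, small_pangenome, small_store):
        query = HomologQuery(small_pangenome.query_gene_id)
        res = run_analysis(query, small_store)
        assert len(res.homologs) == small_pangenome.config.n_genomes
        assert res.enzyme_summary and res.metabolite_summary
        assert res.top_pathway == small_pangenome.planted_pathway_id.upper()
        for row in res.enzyme_summary:
            assert 1 <= row.frequency <= len(res.neighborhoods)

    def test_tables_match_brute_force_recount(self, small_pangenome,
                                              small_store):
        res = run_analysis(HomologQuery(small_pangenome.query_gene_id),
                           small_store)
        ec_freq, cpd_freq, pw_hits = recount_tables_oracle(
            res.neighborhoods, small_store.reference)
        assert {r.ec: r.frequency for r in res.enzyme_summary} == ec_freq
        assert {r.compound_id: r.frequency
                for r in res.metabolite_summary} == cpd_freq
        assert {r.pathway_id: r.hits for r in res.pathway_summary} == pw_hits

    def test_window_growth_never_decreases_frequencies(self, small_pangenome,
                                                       small_store):
        qid = small_pangenome.query_gene_id
        res5 = run_analysis(HomologQuery(qid, n_neighbors=5), small_store)
        res20 = run_analysis(HomologQuery(qid, n_neighbors=14), small_store)
        f5 = {r.ec: r.frequency for r in res5.enzyme_summary}
        f20 = {r.ec: r.frequency for r in res20.enzyme_summary}
        assert all(f20.get(ec, 0) >= freq for ec, freq in f5.items())

    def test_single_genome_store_analyzes_query_only(self):
        g = make_genome("aa", [{"ec": ["1.1.1.1"]}, {}, {}])
        store = Datastore(reference=MetabolicReference())
        store.add_genome(g)
        res = run_analysis(HomologQuery("aa:b0002", n_neighbors=1), store)
        assert res.homologs == ["aa:b0002"]
        assert len(res.neighborhoods) == 1

    def test_missing_query_gene_is_error(self, small_store):
        with pytest.raises(KeyError):
            run_analysis(HomologQuery("zz:none"), small_store)

    def test_identical_runs_identical_results(self, small_pangenome,
                                              small_store):
        q = HomologQuery(small_pangenome.query_gene_id)
        a, b = run_analysis(q, small_store), run_analysis(q, small_store)
        assert a.homologs == b.homologs
        assert a.enzyme_summary == b.enzyme_summary
        assert a.pathway_summary == b.pathway_summary
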