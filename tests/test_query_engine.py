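import pytest

from cdamesh import (
    GeneratorSpec,
    LocalBackend,
    Query,
    add_term,
    annotate_counts,
    attach_qualifier,
    default_config,
    identify_keywords,
    initial_query,
    make_cda_set,
    make_corpus,
    make_mini_mesh,
    relevance,
    render_query,
)
from cdamesh.configuration import SectionRule
from cdamesh.keyword_identifier import IdentifiedKeyword, TokenSpan
from cdamesh.mesh_model import Qualifier
from cdamesh.query_engine import AdmissibilityError, QueryError

from oracles import brute_force_corpus_count

EP = Qualifier("epidemiology", "EP")
DI = Qualifier("diagnosis", "DI")
TH = Qualifier("therapy", "TH")


@pytest.fixture
def descriptors(clinical_thesaurus):
    d = clinical_thesaurus.descriptors
    return d["D003922"], d["D001249"], d["D006973"]  # disease, asthma, hypertension


def test_initial_query_single_clause(descriptors):
    disease, asthma, _ = descriptors
    q = initial_query(disease, asthma)
    assert q.iteration == 1
    assert render_query(q) == "(Asthma[mh]) AND (Diabetes Mellitus, Type 1[mh])"


def test_worked_example_three_mesh_keywords(descriptors):
    """Disease + two selected keywords render as three [mh] conjuncts."""
    disease, asthma, hypertension = descriptors
    q = add_term(initial_query(disease, asthma), hypertension)
    rendered = render_query(q)
    assert rendered == (
        "(Asthma[mh]) AND (Hypertension[mh]) AND (Diabetes Mellitus, Type 1[mh])"
    )
    assert q.iteration == 2
    assert rendered.count("[mh]") == 3  # 3 MeSH keywords incl. the disease


def test_duplicate_term_is_noop(descriptors):
    disease, asthma, _ = descriptors
    q = initial_query(disease, asthma)
    assert add_term(q, asthma) == q


def test_query_values_are_immutable(descriptors):
    disease, asthma, hypertension = descriptors
    q1 = initial_query(disease, asthma)
    q2 = add_term(q1, hypertension)
    assert q1.iteration == 1 and q2.iteration == 2


def test_negated_keyword_rejected(clinical_thesaurus, descriptors):
    disease, _, _ = descriptors
    negated = IdentifiedKeyword(
        descriptor_id="D001249",
        surface="Asthma",
        section_index=0,
        span=TokenSpan("Asthma", 0, 6),
        negated=True,
    )
    with pytest.raises(QueryError):
        initial_query(disease, negated, clinical_thesaurus)


def test_non_c_disease_rejected_unless_lax(clinical_thesaurus):
    penicillins = clinical_thesaurus.descriptors["D010406"]  # branch D only
    asthma = clinical_thesaurus.descriptors["D001249"]
    with pytest.raises(QueryError):
        initial_query(penicillins, asthma)
    q = initial_query(penicillins, asthma, strict=False)
    assert q.iteration == 1


def test_attach_qualifier_renders_per_qualifier_conjunct(clinical_thesaurus, descriptors):
    disease, asthma, _ = descriptors
    q = initial_query(disease, asthma)
    q = attach_qualifier(q, "D001249", EP, None, clinical_thesaurus)
    q = attach_qualifier(q, "D001249", DI, None, clinical_thesaurus)
    assert render_query(q) == (
        "(Asthma/epidemiology[mh]) AND (Asthma/diagnosis[mh]) "
        "AND (Diabetes Mellitus, Type 1[mh])"
    )


def test_attach_qualifier_idempotent(clinical_thesaurus, descriptors):
    disease, asthma, _ = descriptors
    q = attach_qualifier(
        initial_query(disease, asthma), "D001249", EP, None, clinical_thesaurus
    )
    assert attach_qualifier(q, "D001249", EP, None, clinical_thesaurus) == q


def test_qualifier_inadmissible_for_descriptor(clinical_thesaurus, descriptors):
    disease, _, hypertension = descriptors
    q = initial_query(disease, hypertension)
    with pytest.raises(AdmissibilityError, match="allowable"):
        attach_qualifier(q, "D006973", TH, None, clinical_thesaurus)


def test_qualifier_excluded_by_section_rule(clinical_thesaurus, descriptors):
    disease, asthma, _ = descriptors
    rule = SectionRule(titles=frozenset({"Allergies"}), qualifiers=frozenset({"DI"}))
    q = initial_query(disease, asthma)
    with pytest.raises(AdmissibilityError, match="section rule"):
        attach_qualifier(q, "D001249", EP, rule, clinical_thesaurus)


def test_general_query_renders_disease_only(descriptors):
    disease, _, _ = descriptors
    assert render_query(Query(disease=disease)) == "(Diabetes Mellitus, Type 1[mh])"


def test_rendering_injective_on_distinct_queries(descriptors):
    disease, asthma, hypertension = descriptors
    queries = [
        Query(disease=disease),
        initial_query(disease, asthma),
        initial_query(disease, hypertension),
        add_term(initial_query(disease, asthma), hypertension),
        add_term(initial_query(disease, hypertension), asthma),
    ]
    rendered = [render_query(q) for q in queries]
    assert len(set(rendered)) == len(rendered)


# -- relevance --------------------------------------------------------------

def test_relevance_set_arithmetic():
    assert relevance({"A", "B", "DM1"}, {"A", "B"}, "DM1") == 3
    assert relevance({"X", "Y"}, {"A", "B"}, "DM1") == 0
    assert relevance({"A", "DM1"}, set(), "DM1") == 1


@pytest.mark.parametrize("seed", range(5))
def test_nth_query_retrieves_relevance_at_least_n_plus_1(seed):
    """Citations matched by the n-th query share >= n+1 MeSH terms with the
    record (the AND chain makes every conjunct an index term)."""
    spec = GeneratorSpec(seed=seed, n_descriptors=40, n_docs=1, n_citations=150)
    th = make_mini_mesh(spec)
    docs, gold = make_cda_set(spec, th)
    ehr_terms = sorted({g.descriptor_id for g in gold})
    disease = sorted(
        d for d, de in th.descriptors.items()
        if "C" in de.branches and d not in ehr_terms
    )[0]
    corpus = make_corpus(spec, th, [disease] + ehr_terms)
    backend = LocalBackend(corpus)

    query = Query(disease=th.descriptors[disease])
    for n, term in enumerate(ehr_terms[:4], start=1):
        query = add_term(query, th.descriptors[term])
        assert query.iteration == n
        for citation in backend.search(query):
            assert relevance(citation.descriptor_ids, ehr_terms, disease) >= n + 1


# -- candidate counts -------------------------------------------------------

@pytest.fixture
def corpus_setup():
    spec = GeneratorSpec(seed=3, n_descriptors=40, n_docs=2, n_citations=120)
    th = make_mini_mesh(spec)
    docs, gold = make_cda_set(spec, th)
    focus = sorted({g.descriptor_id for g in gold if g.doc_id == "doc001"})
    disease = sorted(
        d for d, de in th.descriptors.items()
        if "C" in de.branches and d not in focus
    )[0]
    corpus = make_corpus(spec, th, [disease] + focus)
    return spec, th, docs, disease, corpus


def test_annotate_counts_equal_brute_force(corpus_setup):
    spec, th, docs, disease, corpus = corpus_setup
    backend = LocalBackend(corpus)
    keywords = identify_keywords(docs[0], th, default_config())
    query = Query(disease=th.descriptors[disease])
    annotated = annotate_counts(keywords, query, backend, th)
    for kw in annotated:
        if kw.negated:
            assert kw.candidate_count is None
            continue
        expected = brute_force_corpus_count(
            corpus, [(kw.descriptor_id, ()), (disease, ())]
        )
        assert kw.candidate_count == expected


def test_already_present_keyword_gets_no_count(corpus_setup):
    spec, th, docs, disease, corpus = corpus_setup
    backend = LocalBackend(corpus)
    keywords = [k for k in identify_keywords(docs[0], th, default_config()) if not k.negated]
    query = add_term(
        Query(disease=th.descriptors[disease]),
        th.descriptors[keywords[0].descriptor_id],
    )
    annotated = annotate_counts(keywords, query, backend, th)
    assert annotated[0].candidate_count is None


def test_and_monotonicity_of_candidate_counts(corpus_setup):
    spec, th, docs, disease, corpus = corpus_setup
    backend = LocalBackend(corpus)
    keywords = identify_keywords(docs[0], th, default_config())
    query = Query(disease=th.descriptors[disease])
    base_count = backend.count(query)
    for kw in annotate_counts(keywords, query, backend, th):
        if kw.candidate_count is not None:
            assert kw.candidate_count <= base_count


def test_backend_failure_marks_count_unavailable(corpus_setup, descriptors=None):
    spec, th, docs, disease, corpus = corpus_setup

    class Flaky:
        def count(self, query):
            raise RuntimeError("down")

    keywords = identify_keywords(docs[0], th, default_config())
    annotated = annotate_counts(keywords, Query(disease=th.descriptors[disease]), Flaky(), th)
    assert all(k.candidate_count is None for k in annotated)
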