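import pytest

from cdamesh import (
    AppConfig,
    GeneratorSpec,
    SectionRule,
    default_config,
    descriptors_in_branches,
    identify_baseline,
    identify_keywords,
    is_negated,
    make_cda_set,
    make_mini_mesh,
    match_terms,
    split_sentences,
    tokenize,
)
from cdamesh.cda_reader import CdaDocument, CdaSection
from cdamesh.mesh_model import BRANCH_LETTERS

from oracles import brute_force_allowed, brute_force_matches, oracle_identify


def make_doc(sections):
    return CdaDocument(
        doc_id="t",
        title="t",
        sections=tuple(
            CdaSection(title=title, codes=frozenset(), text=text, order_index=i)
            for i, (title, text) in enumerate(sections)
        ),
    )


# -- sentences and tokens ---------------------------------------------------

def test_sentence_split_counts():
    assert len(split_sentences("No pain. Asthma persists.")) == 2
    assert split_sentences("") == []


def test_token_spans_reconstruct_text():
    text = "Asthma persists, daily."
    (sent,) = split_sentences(text)
    tokens = tokenize(sent)
    assert [t.text for t in tokens] == ["Asthma", "persists", ",", "daily", "."]
    for t in tokens:
        assert text[t.start : t.end] == t.text


def test_spans_ordered_and_in_bounds(cda_set):
    docs, _ = cda_set
    for doc in docs:
        for section in doc.sections:
            last = 0
            for sent in split_sentences(section.text):
                assert last <= sent.start < sent.end <= len(section.text)
                last = sent.end
                assert section.text[sent.start : sent.end] == sent.text


# -- matching ---------------------------------------------------------------

def test_longest_match_wins(clinical_thesaurus):
    (sent,) = split_sentences("History of Diabetes Mellitus, Type 1 today.")
    tokens = tokenize(sent)
    allowed = frozenset(clinical_thesaurus.descriptors)
    matches = match_terms(tokens, clinical_thesaurus, allowed)
    assert [d for d, _ in matches] == ["D003922"]
    (did, span) = matches[0]
    assert sent.text[span.start - sent.start : span.end - sent.start].startswith(
        "Diabetes Mellitus, Type 1"[:16]
    )


def test_branch_restriction_blocks_match(clinical_thesaurus):
    (sent,) = split_sentences("Allergic to Penicillin since childhood.")
    tokens = tokenize(sent)
    c_only = descriptors_in_branches(clinical_thesaurus, {"C"})
    assert match_terms(tokens, clinical_thesaurus, c_only) == []
    with_d = descriptors_in_branches(clinical_thesaurus, {"C", "D"})
    assert [d for d, _ in match_terms(tokens, clinical_thesaurus, with_d)] == ["D010406"]


def test_synonym_matches_to_descriptor(clinical_thesaurus):
    (sent,) = split_sentences("Noted high blood pressure at rest.")
    tokens = tokenize(sent)
    matches = match_terms(
        tokens, clinical_thesaurus, frozenset(clinical_thesaurus.descriptors)
    )
    assert [d for d, _ in matches] == ["D006973"]


def test_matches_do_not_cross_sentences(clinical_thesaurus):
    # "Bronchial" ends one sentence, "Asthma" opens the next: no 2-gram match.
    text = "Something bronchial. Asthma follows."
    spans = split_sentences(text)
    all_matches = []
    for sent in spans:
        all_matches += match_terms(
            tokenize(sent), clinical_thesaurus, frozenset(clinical_thesaurus.descriptors)
        )
    assert [d for d, _ in all_matches] == ["D001249"]


@pytest.mark.parametrize("seed", range(8))
def test_match_equals_brute_force_ngram_oracle(seed):
    spec = GeneratorSpec(seed=seed, n_descriptors=40, n_docs=3)
    th = make_mini_mesh(spec)
    docs, _ = make_cda_set(spec, th)
    allowed = brute_force_allowed(th, BRANCH_LETTERS)
    for doc in docs:
        for section in doc.sections:
            got = []
            for sent in split_sentences(section.text):
                for did, span in match_terms(tokenize(sent), th, allowed):
                    got.append((did, (span.start, span.end)))
            assert got == brute_force_matches(section.text, th, allowed)


# -- negation ---------------------------------------------------------------

@pytest.mark.parametrize(
    "text,negated",
    [
        ("no Pain", True),
        ("Pain in chest", False),
        ("denies Pain today", True),
        ("without any Pain", True),
        ("No family history of asthma", False),  # trigger 4 tokens back
    ],
)
def test_negation_window_rule(clinical_thesaurus, text, negated):
    (sent,) = split_sentences(text)
    tokens = tokenize(sent)
    matches = match_terms(
        tokens, clinical_thesaurus, frozenset(clinical_thesaurus.descriptors)
    )
    assert len(matches) == 1
    assert is_negated(tokens, matches[0][1], window=3) is negated


def test_negation_window_must_be_positive(clinical_thesaurus):
    (sent,) = split_sentences("no Pain")
    tokens = tokenize(sent)
    (_, span), = match_terms(
        tokens, clinical_thesaurus, frozenset(clinical_thesaurus.descriptors)
    )
    with pytest.raises(ValueError):
        is_negated(tokens, span, window=0)


# -- full identification ----------------------------------------------------

def test_identify_recovers_planted_gold(cda_set, mini_mesh, shipped_config):
    docs, gold = cda_set
    for doc in docs:
        keywords = identify_keywords(doc, mini_mesh, shipped_config)
        found = {k.descriptor_id for k in keywords if not k.negated}
        expected = {g.descriptor_id for g in gold if g.doc_id == doc.doc_id}
        assert found == expected


def test_irrelevant_section_contributes_nothing(mini_mesh, shipped_config, cda_set):
    docs, _ = cda_set
    for doc in docs:
        keywords = identify_keywords(doc, mini_mesh, shipped_config)
        appointment = [s.order_index for s in doc.sections if s.title == "Appointment"]
        assert all(k.section_index not in appointment for k in keywords)


def test_negated_mention_flagged(clinical_thesaurus):
    doc = make_doc([("Allergies", "No Pain today. Asthma persists.")])
    keywords = identify_keywords(doc, clinical_thesaurus, default_config())
    by_id = {k.descriptor_id: k for k in keywords}
    assert by_id["D010146"].negated is True
    assert by_id["D001249"].negated is False


def test_candidate_qualifiers_intersection(clinical_thesaurus):
    cfg = AppConfig(
        rules=(
            SectionRule(
                titles=frozenset({"Allergies"}),
                branches=frozenset("ABCDEFG"),
                qualifiers=frozenset({"EP"}),
            ),
        )
    )
    doc = make_doc([("Allergies", "Asthma persists.")])
    (kw,) = identify_keywords(doc, clinical_thesaurus, cfg)
    assert {q.abbreviation for q in kw.candidate_qualifiers} == {"EP"}


def test_identify_matches_independent_filter_composition(cda_set, mini_mesh, shipped_config):
    docs, _ = cda_set
    for doc in docs:
        got = [
            (k.section_index, k.descriptor_id, k.span.start, k.span.end, k.negated)
            for k in identify_keywords(doc, mini_mesh, shipped_config)
        ]
        assert got == oracle_identify(doc, mini_mesh, shipped_config)


def test_shrinking_branches_never_adds_keywords(cda_set, mini_mesh, shipped_config):
    docs, _ = cda_set
    narrow = AppConfig(
        rules=tuple(
            SectionRule(titles=r.titles, codes=r.codes, branches=frozenset("AC"))
            for r in shipped_config.rules
        )
    )
    for doc in docs:
        wide = {
            (k.descriptor_id, k.span.start)
            for k in identify_keywords(doc, mini_mesh, shipped_config)
        }
        small = {
            (k.descriptor_id, k.span.start)
            for k in identify_keywords(doc, mini_mesh, narrow)
        }
        assert small <= wide


def test_baseline_is_concept_superset(cda_set, mini_mesh, shipped_config):
    docs, _ = cda_set
    for doc in docs:
        base = {k.descriptor_id for k in identify_baseline(doc, mini_mesh)}
        configured = {
            k.descriptor_id for k in identify_keywords(doc, mini_mesh, shipped_config)
        }
        assert configured <= base


def test_baseline_keeps_negated_occurrences(clinical_thesaurus):
    doc = make_doc([("Whatever", "No Pain today.")])
    base = identify_baseline(doc, clinical_thesaurus)
    assert [(k.descriptor_id, k.negated) for k in base] == [("D010146", True)]
    # the configured method sees nothing: section irrelevant
    assert identify_keywords(doc, clinical_thesaurus, default_config()) == []


def test_output_ordering_deterministic(cda_set, mini_mesh, shipped_config):
    docs, _ = cda_set
    for doc in docs:
        kws = identify_keywords(doc, mini_mesh, shipped_config)
        keys = [(k.section_index, k.span.start) for k in kws]
        assert keys == sorted(keys)
        assert kws == identify_keywords(doc, mini_mesh, shipped_config)
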