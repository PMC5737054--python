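import pytest

from meshir import (ExpansionConfig, SynthConfig, build_index, build_query,
                    generate_collection, load_corpus, load_synonyms,
                    read_queries, search)


@pytest.fixture(scope="session")
def small_collection(tmp_path_factory):
    """An 80-doc synthetic collection with heavy vocabulary mismatch."""
    cfg = SynthConfig(n_docs=80, n_queries=5, mismatch_rate=0.8, seed=11)
    return generate_collection(cfg, tmp_path_factory.mktemp("coll"))


@pytest.fixture(scope="session")
def small_index(small_collection):
    return build_index(load_corpus(small_collection.corpus_dir))


@pytest.fixture(scope="session")
def small_table(small_collection):
    return load_synonyms(small_collection.synonyms_path)


@pytest.fixture(scope="session")
def small_queries(small_collection):
    return read_queries(small_collection.queries_path)


@pytest.fixture(scope="session")
def small_runs(small_index, small_table, small_queries):
    """Baseline and expanded (5 terms, 1:5) ranked lists per query."""
    base_cfg = ExpansionConfig(max_terms=0, mesh_weight=1, baseline_weight=1)
    exp_cfg = ExpansionConfig(max_terms=5, mesh_weight=1, baseline_weight=5)
    base = {q: search(small_index, build_query(q, t, small_table, base_cfg))
            for q, t in small_queries}
    exp = {q: search(small_index, build_query(q, t, small_table, exp_cfg))
           for q, t in small_queries}
    return base, exp
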