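import pytest
from hypothesis import settings

from coiminer import fixtures, pipeline

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_spec():
    return fixtures.FixtureSpec(seed=11)


@pytest.fixture(scope="session")
def default_corpus(default_spec):
    return fixtures.generate_corpus(default_spec)


@pytest.fixture(scope="session")
def corpus_paths(default_corpus, tmp_path_factory):
    out = tmp_path_factory.mktemp("corpus")
    return fixtures.write_corpus(default_corpus, out)


@pytest.fixture(scope="session")
def run_config_factory(corpus_paths, tmp_path_factory):
    def make(thresholds, **kwargs):
        out = tmp_path_factory.mktemp("run")
        return pipeline.RunConfig(
            corpus_genbank=corpus_paths["genbank"],
            hit_table=corpus_paths["hits"],
            domain_hits=corpus_paths["domain_hits"],
            class_map=corpus_paths["class_map"],
            out_dir=out,
            thresholds=thresholds,
            **kwargs,
        )
    return make
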