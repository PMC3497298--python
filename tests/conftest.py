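import random
from types import SimpleNamespace

import pytest
from hypothesis import HealthCheck, settings

from pdbtriage import (
    generate_corpus,
    printed_funnel_spec,
    random_corpus_spec,
    run_pipeline,
)

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def printed(tmp_path_factory):
    """The published-funnel fixture corpus, generated and fully triaged once."""
    base = tmp_path_factory.mktemp("printed_funnel")
    paths = generate_corpus(printed_funnel_spec(), base / "fixtures")
    out_dir = base / "out"
    result = run_pipeline(
        paths["entries"],
        paths["annotations"],
        paths["sequence_hits"],
        paths["structure_hits"],
        out_dir=out_dir,
    )
    return SimpleNamespace(paths=paths, result=result, out_dir=out_dir)


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """A modest random corpus (fixed seed) for I/O and perturbation tests."""
    spec = random_corpus_spec(random.Random(5), n_entries=60)
    base = tmp_path_factory.mktemp("small_corpus")
    paths = generate_corpus(spec, base)
    return SimpleNamespace(spec=spec, paths=paths, base=base)
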