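import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from annozipf import parse_flatfile, strip_structure
from annozipf.synthetic import SyntheticSpec, generate_corpus

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


def zeta_series_oracle(alpha: float, q: float, n_terms: int = 1_000_000) -> float:
    """Independent Hurwitz-zeta oracle: direct partial summation plus an
    Euler-Maclaurin tail remainder (leading correction terms); the neglected
    remainder is bounded well below 1e-12 for alpha > 1 and 10^6 terms."""
    import math
    k = np.arange(n_terms, dtype=float) + q
    partial = math.fsum((k ** (-alpha)).tolist())
    x = q + n_terms
    tail = x ** (1 - alpha) / (alpha - 1) + 0.5 * x ** (-alpha) \
        + alpha * x ** (-alpha - 1) / 12.0
    return partial + tail


@pytest.fixture(scope="session")
def plain_spec() -> SyntheticSpec:
    return SyntheticSpec(seed=42, n_entries=30, alpha_true=2.0,
                         n_tail_types=200, n_head_types=100)


@pytest.fixture(scope="session")
def plain_corpus(plain_spec):
    text, ledger = generate_corpus(plain_spec)
    return plain_spec, text, ledger


@pytest.fixture(scope="session")
def copyright_corpus():
    spec = SyntheticSpec(seed=42, n_entries=30, alpha_true=2.0,
                         n_tail_types=200, n_head_types=100,
                         copyright="swissprot37")
    text, ledger = generate_corpus(spec)
    return spec, text, ledger


@pytest.fixture(scope="session")
def parsed_entries(plain_corpus):
    _, text, _ = plain_corpus
    return list(parse_flatfile(text, "syn"))


@pytest.fixture(scope="session")
def cleaned_entries(parsed_entries):
    return [strip_structure(e) for e in parsed_entries]
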