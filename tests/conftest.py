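import numpy as np
import pytest

from vowelspace import (
    CohortConfig,
    FormantToken,
    VowelLabel,
    generate_tokens,
    load_change_scores_fixture,
    load_group_means_fixture,
    simulate_gains,
)


@pytest.fixture(scope="session")
def change_records():
    """The 13-speaker published change-score table."""
    return load_change_scores_fixture()


@pytest.fixture(scope="session")
def ds_means():
    return load_group_means_fixture("DS")


@pytest.fixture(scope="session")
def td_means():
    return load_group_means_fixture("TD")


def make_session_tokens(points, speaker="S01", session="baseline"):
    """Tokens from (vowel, f1, f2) triples, repetitions auto-numbered."""
    counts: dict = {}
    tokens = []
    for vowel, f1, f2 in points:
        v = vowel if isinstance(vowel, VowelLabel) else VowelLabel.from_string(vowel)
        counts[v] = counts.get(v, 0) + 1
        tokens.append(FormantToken(speaker, session, v, counts[v], float(f1), float(f2)))
    return tokens


@pytest.fixture
def small_cohort():
    """A seeded 6-speaker synthetic cohort with simulated gains."""
    config = CohortConfig(n_speakers=6, seed=42)
    return simulate_gains(generate_tokens(config))


@pytest.fixture
def rng():
    return np.random.default_rng(20251002)
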