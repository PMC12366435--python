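import numpy as np
import pytest

from tagdisc import (
    SpeakerRecord,
    SyntheticConfig,
    default_scheme,
    generate_corpus,
    normalize_features,
)
from tagdisc.scheme import TagScheme


@pytest.fixture(scope="session")
def scheme():
    """The packaged 135-tag default scheme (read-only)."""
    return default_scheme()


@pytest.fixture(scope="session")
def toy_scheme_factory():
    """Build a minimal m-tag scheme with anonymous synthetic tags."""

    def _make(m: int, level: dict[str, str] | None = None) -> TagScheme:
        tags = tuple(f"tag{j:02d}" for j in range(m))
        return TagScheme(tags, {t: "Synthetic" for t in tags}, {}, level or {})

    return _make


@pytest.fixture
def two_tag_scheme(toy_scheme_factory):
    return toy_scheme_factory(2)


@pytest.fixture(scope="session")
def small_features(toy_scheme_factory):
    """A 40-speaker, 5-tag feature matrix with a real group signal."""
    sch = toy_scheme_factory(5)
    d = np.array([0.8, -0.8, 0.0, 0.0, 0.4])
    cfg = SyntheticConfig(scheme=sch, n_pos=20, n_neg=20, effect=d, seed=11)
    records = generate_corpus(cfg)
    return normalize_features(records, sch)


def make_records(scheme, counts_rows, word_counts, groups=None, ids=None):
    """Handy constructor for explicit small record lists."""
    n = len(counts_rows)
    groups = groups or ["ASD"] * (n // 2) + ["non-ASD"] * (n - n // 2)
    ids = ids or [f"s{i}" for i in range(n)]
    return [
        SpeakerRecord(ids[i], groups[i], word_counts[i],
                      np.asarray(counts_rows[i], dtype=np.int64))
        for i in range(n)
    ]
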