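"""Synthetic speaker-by-tag corpus generator.

No clinical corpus is distributed with the package, so every downstream
stage is exercised on generated count tables with the statistical
structure the analysis assumes:

* two diagnostic groups (defaults 64 ASD / 71 non-ASD speakers);
* per-speaker word counts drawn log-normally (no length restriction was
  placed on the source interviews, so a heavy right skew is realistic);
* per-tag counts drawn Poisson (or negative-binomial for overdispersion)
  with mean ``w_i * exp(b_j + y_i * d_j)`` — a log-linear rate per word
  with a group offset ``d_j`` for positive-class speakers.

Tags are generated independently within speaker; real tag counts are
surely correlated, but no covariance information is available to emulate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .corpus import NEGATIVE_LABEL, POSITIVE_LABEL, SpeakerRecord
from .reference import positive_mean_items, reference_items
from .scheme import TagScheme

#: Default per-word baseline rate: one tag occurrence per 100 words.
DEFAULT_BASE_RATE = 0.01
#: Default |group log-rate offset| used by the published-signs preset.
DEFAULT_PRESET_EFFECT = 0.5


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the generative model.

    Attributes
    ----------
    n_pos, n_neg
        Group sizes (positive = ASD). Defaults match the study design.
    scheme
        Tag inventory; one count column is generated per tag.
    word_count_median, word_count_sigma
        Log-normal word-count model: ``w ~ exp(N(log median, sigma^2))``,
        rounded and clipped to >= 1.
    base_log_rate
        Per-tag baseline log rate per word, scalar or length-m array.
    effect
        Per-tag group log-rate offset ``d_j`` added for positive-class
        speakers, scalar or length-m array.
    overdispersion
        Negative-binomial shape ``theta``; ``None`` means Poisson
        (variance = mean). Finite ``theta`` gives variance
        ``mu + mu^2 / theta``.
    seed
        Generator seed; identical seed gives identical corpora.
    """

    scheme: TagScheme
    n_pos: int = 64
    n_neg: int = 71
    word_count_median: float = 1000.0
    word_count_sigma: float = 0.6
    base_log_rate: float | np.ndarray = math.log(DEFAULT_BASE_RATE)
    effect: float | np.ndarray = 0.0
    overdispersion: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("group sizes must be >= 1")
        if self.word_count_median < 1:
            raise ValueError("word-count median must be >= 1")
        if self.word_count_sigma < 0:
            raise ValueError("word-count sigma must be >= 0")
        if self.overdispersion is not None and not self.overdispersion > 0:
            raise ValueError("overdispersion shape must be > 0 (or None for Poisson)")
        b = np.broadcast_to(np.asarray(self.base_log_rate, float), (self.scheme.n_tags,))
        d = np.broadcast_to(np.asarray(self.effect, float), (self.scheme.n_tags,))
        with np.errstate(over="ignore"):
            rates_ok = (np.isfinite(np.exp(b)).all()
                        and np.isfinite(np.exp(b + d)).all())
        if not rates_ok:
            raise ValueError("per-word rates exp(b) and exp(b+d) must be finite")
        object.__setattr__(self, "base_log_rate", np.array(b))
        object.__setattr__(self, "effect", np.array(d))

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


def generate_corpus(config: SyntheticConfig) -> list[SpeakerRecord]:
    """Draw one corpus: positive-group speakers first, then negative."""
    rng = np.random.default_rng(config.seed)
    scheme = config.scheme
    n = config.n_pos + config.n_neg
    groups = [POSITIVE_LABEL] * config.n_pos + [NEGATIVE_LABEL] * config.n_neg
    y = np.array([1] * config.n_pos + [0] * config.n_neg)

    w = rng.lognormal(
        mean=math.log(config.word_count_median),
        sigma=config.word_count_sigma,
        size=n,
    )
    w = np.maximum(1, np.rint(w)).astype(np.int64)

    log_rate = config.base_log_rate[None, :] + y[:, None] * config.effect[None, :]
    mu = w[:, None] * np.exp(log_rate)
    if config.overdispersion is None:
        counts = rng.poisson(mu)
    else:
        theta = config.overdispersion
        # NB as Poisson-gamma mixture: mean mu, variance mu + mu^2/theta
        lam = rng.gamma(shape=theta, scale=mu / theta)
        counts = rng.poisson(lam)

    width = len(str(n))
    return [
        SpeakerRecord(
            speaker_id=f"s{i + 1:0{width}d}",
            group=groups[i],
            word_count=int(w[i]),
            counts=counts[i],
        )
        for i in range(n)
    ]


def table1_preset(
    scheme: TagScheme,
    *,
    effect_size: float = DEFAULT_PRESET_EFFECT,
    seed: int = 0,
    **overrides,
) -> SyntheticConfig:
    """Config whose effect signs follow the published discriminator table.

    ``d_j = +effect_size`` for the items printed with a positive
    coefficient mean (parallel clauses, exemplifying elaboration,
    existential process, filler *unto*), ``-effect_size`` for the items
    printed negative, and 0 for every other tag. The magnitude is a
    documented default — the printed coefficients are not rate-scale
    effect sizes and are not reused as such.
    """
    missing = [t for t in reference_items() if t not in scheme.category_of]
    if missing:
        raise ValueError(
            f"scheme is missing published discriminator item(s): {missing[:5]}"
        )
    positive = set(positive_mean_items())
    d = np.zeros(scheme.n_tags)
    for item in reference_items():
        d[scheme.index_of(item)] = effect_size if item in positive else -effect_size
    return SyntheticConfig(scheme=scheme, effect=d, seed=seed, **overrides)


def null_preset(scheme: TagScheme, *, seed: int = 0, **overrides) -> SyntheticConfig:
    """No group effect anywhere (d_j = 0): the type-I-error condition."""
    return SyntheticConfig(scheme=scheme, effect=0.0, seed=seed, **overrides)
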