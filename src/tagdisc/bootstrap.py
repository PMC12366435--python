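"""Bootstrap coefficient inference and discriminator selection.

With 135 speakers and a comparable number of features, single-fit standard
errors for the logistic coefficients are unreliable, so inference is by
bootstrap: resample speakers with replacement, refit the penalized logistic
model on each resample, and summarize each coefficient by its mean and
standard deviation over the resamples. A two-sided p-value for the null
"coefficient = 0" is then obtained from a normal approximation,

    z_j = mean_j / sd_j,      p_j = 2 * (1 - Phi(|z_j|)),

and a tag is a discriminator when ``p_j < alpha`` (strict, no
multiple-testing adjustment by default; Benjamini-Hochberg is available as
an explicit extension).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, norm

from .corpus import FeatureMatrix
from .model import fit_logistic
from .scheme import LEVEL_CLAUSE_PHRASE, TagScheme

DEFAULT_B = 10_000
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class BootstrapResult:
    """Per-tag coefficient moments over ``B`` bootstrap refits."""

    tag_names: tuple[str, ...]
    mean: np.ndarray          # bootstrap mean of beta_j
    sd: np.ndarray            # bootstrap SD (B-1 denominator)
    z: np.ndarray             # mean / sd (NaN where sd == 0)
    p_value: np.ndarray       # two-sided normal tail (NaN where undefined)
    significant: np.ndarray   # p < alpha
    alpha: float
    B: int
    n_failed: int             # single-class resamples that were redrawn
    seed: int
    penalty: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lexicogrammar": list(self.tag_names),
                "mean": self.mean,
                "SD": self.sd,
                "p_value": self.p_value,
                "significant": self.significant,
            }
        )


class SelectedTag(NamedTuple):
    tag: str
    mean: float
    sd: float
    p_value: float


def pvalue_from_moments(mean: float, sd: float) -> float:
    """Two-sided normal-tail p-value from a bootstrap mean and SD.

    ``p = 2 * (1 - Phi(|mean| / sd))``; requires ``sd > 0``.
    """
    if not sd > 0:
        raise ValueError(f"sd must be positive, got {sd}")
    return float(2.0 * norm.sf(abs(mean) / sd))


def bootstrap_coefficients(
    features: FeatureMatrix,
    B: int = DEFAULT_B,
    penalty: float = 1.0,
    seed: int = 0,
    *,
    alpha: float = DEFAULT_ALPHA,
    stratified: bool = False,
    progress: Callable[[int, int], None] | None = None,
) -> BootstrapResult:
    """Resample speakers with replacement ``B`` times and refit each time.

    Draws are non-stratified by default: each resample takes ``n`` speakers
    uniformly with replacement from all ``n`` rows. A resample containing a
    single class cannot be fit and is redrawn; the number of such redraws is
    reported as ``n_failed``, and a redraw rate above 50% aborts. With
    ``stratified=True``, draws resample within each class (never degenerate).

    Deterministic given ``(seed, B, penalty, stratified)``.

    Parameters
    ----------
    progress
        Optional callback ``progress(done, B)`` invoked at every 10% tick.
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    y = features.y
    n = features.n_speakers
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)

    betas = np.empty((B, features.n_tags))
    n_failed = 0
    n_draws = 0
    tick = max(1, B // 10)
    for b in range(B):
        while True:
            n_draws += 1
            if stratified:
                idx = np.concatenate(
                    [rng.choice(pos_idx, size=pos_idx.size, replace=True),
                     rng.choice(neg_idx, size=neg_idx.size, replace=True)]
                )
            else:
                idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2:
                break
            n_failed += 1
            if n_draws >= 20 and n_failed / n_draws > 0.5:
                raise RuntimeError(
                    f"bootstrap aborted: {n_failed}/{n_draws} resamples were "
                    "single-class (>50%); the design is too unbalanced to "
                    "resample non-stratified — consider stratified=True"
                )
        resample = FeatureMatrix(
            x=features.x[idx],
            y=y[idx],
            tag_names=features.tag_names,
            speaker_ids=tuple(f"b{b}_{i}" for i in range(n)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # per-resample convergence noise
            model = fit_logistic(resample, penalty)
        betas[b] = model.coef
        if progress is not None and (b + 1) % tick == 0:
            progress(b + 1, B)

    mean = betas.mean(axis=0)
    if B > 1:
        sd = betas.std(axis=0, ddof=1)
    else:
        sd = np.zeros(features.n_tags)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, mean / sd, np.nan)
    p = np.where(np.isfinite(z), 2.0 * norm.sf(np.abs(z)), np.nan)
    if B == 1:
        warnings.warn(
            "B=1: bootstrap SD is zero and p-values are not computable",
            stacklevel=2,
        )
    sig = (p < alpha) & np.isfinite(p)
    return BootstrapResult(
        tag_names=features.tag_names,
        mean=mean,
        sd=sd,
        z=z,
        p_value=p,
        significant=sig,
        alpha=alpha,
        B=B,
        n_failed=n_failed,
        seed=seed,
        penalty=penalty,
    )


def select_discriminators(
    result: BootstrapResult,
    alpha: float = DEFAULT_ALPHA,
    *,
    adjust: str | None = None,
) -> list[SelectedTag]:
    """Tags with ``p < alpha`` (strict), sorted by p then scheme order.

    ``adjust="bh"`` applies Benjamini-Hochberg to the p-values first — an
    extension beyond the default raw-p selection.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    p = result.p_value
    if adjust == "bh":
        finite = np.isfinite(p)
        p = p.copy()
        p[finite] = false_discovery_control(p[finite], method="bh")
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    order = np.argsort(p, kind="stable")  # stable => ties keep scheme order
    out: list[SelectedTag] = []
    for j in order:
        if np.isfinite(p[j]) and p[j] < alpha:
            out.append(
                SelectedTag(
                    tag=result.tag_names[j],
                    mean=float(result.mean[j]),
                    sd=float(result.sd[j]),
                    p_value=float(p[j]),
                )
            )
    return out


@dataclass(frozen=True)
class LevelFilterResult:
    """Outcome of a structural-level filter over a selection."""

    selected: tuple[SelectedTag, ...]
    unclassified: tuple[SelectedTag, ...]  # tags the scheme does not annotate


def filter_structural_level(
    selected: Sequence[SelectedTag],
    scheme: TagScheme,
    level: str = "all",
) -> LevelFilterResult:
    """Restrict a discriminator list to one structural level.

    ``level="all"`` is the identity. ``level="clause_phrase"`` keeps tags
    the scheme annotates as clause/phrase level; tags with no level
    annotation are returned separately as ``unclassified`` rather than
    silently dropped.
    """
    if level == "all":
        return LevelFilterResult(tuple(selected), ())
    if level != LEVEL_CLAUSE_PHRASE:
        raise ValueError(f"unknown level {level!r}")
    keep: list[SelectedTag] = []
    unclassified: list[SelectedTag] = []
    for item in selected:
        tag_level = scheme.level(item.tag)
        if tag_level is None:
            unclassified.append(item)
        elif tag_level == level:
            keep.append(item)
    return LevelFilterResult(tuple(keep), tuple(unclassified))


# ---------------------------------------------------------------------------
# results-table I/O (the published-table column layout)


def write_results_table(result: BootstrapResult, path: str | Path) -> None:
    """CSV with columns lexicogrammar, mean, SD, p_value, significant.

    Floats are printed to 4 decimals, mirroring the published layout; rows
    follow scheme tag order.
    """
    if not (np.isfinite(result.mean).all() and np.isfinite(result.sd).all()):
        raise ValueError("result contains non-finite moments")
    df = result.to_frame()
    df["significant"] = np.where(df["significant"], "true", "false")
    df.to_csv(path, index=False, float_format="%.4f")


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back the CSV written by :func:`write_results_table`."""
    df = pd.read_csv(path)
    expected = ["lexicogrammar", "mean", "SD", "p_value", "significant"]
    if list(df.columns) != expected:
        raise ValueError(f"expected columns {expected}, got {list(df.columns)}")
    df["significant"] = df["significant"].map(
        lambda v: bool(v) if isinstance(v, (bool, np.bool_))
        else str(v).lower() == "true"
    )
    return df
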