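"""Do lost introns cluster at adjacent positions?

For a gene with ``l`` lost and ``r`` conserved introns, the null hypothesis
of independent random loss places the ``l`` lost introns uniformly among the
``r + l`` ordered positions.  The number of adjacent lost pairs ``d`` then
has the exact distribution

    Pr{d | l, r} = C(l-1, d) * C(r+1, l-d) / C(r+l, l)

Aggregate significance over genes is computed two ways: exactly, by
convolving the per-gene mass functions and reading the upper tail at the
observed total; and by Monte-Carlo resampling of loss positions (the
100,000-round default), counting how often the resampled total reaches the
observed one.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class GeneLossProfile:
    """Loss layout of one gene: r conserved + l lost ordered intron sites."""

    gene_id: str
    r: int
    lost_ordinals: tuple[int, ...]   # 1-based positions among the r+l sites

    def __post_init__(self) -> None:
        object.__setattr__(self, "lost_ordinals", tuple(sorted(self.lost_ordinals)))
        if self.r < 0:
            raise ValueError("conserved count must be >= 0")
        n = self.n_sites
        if len(set(self.lost_ordinals)) != len(self.lost_ordinals):
            raise ValueError(f"{self.gene_id}: duplicate ordinals")
        for o in self.lost_ordinals:
            if not 1 <= o <= n:
                raise ValueError(f"{self.gene_id}: ordinal {o} outside 1..{n}")

    @property
    def l(self) -> int:  # noqa: E743  - the field's conventional name
        return len(self.lost_ordinals)

    @property
    def n_sites(self) -> int:
        return self.r + self.l

    @property
    def d(self) -> int:
        return count_adjacent(self.lost_ordinals, self.n_sites)


def count_adjacent(lost_ordinals: Sequence[int], n_sites: int) -> int:
    """Number of consecutive ordinal pairs that are both lost."""
    ordinals = sorted(set(lost_ordinals))
    if len(ordinals) != len(list(lost_ordinals)):
        raise ValueError("ordinals must be distinct")
    if ordinals and (ordinals[0] < 1 or ordinals[-1] > n_sites):
        raise ValueError("ordinal outside the site range")
    return sum(1 for a, b in zip(ordinals, ordinals[1:]) if b == a + 1)


def prob_adjacent(d: int, l: int, r: int) -> float:  # noqa: E741
    """Exact null probability of exactly ``d`` adjacent lost pairs."""
    if l < 1:
        raise ValueError("l must be >= 1")
    if r < 0:
        raise ValueError("r must be >= 0")
    if d < 0 or d > l - 1 or l - d > r + 1:
        return 0.0
    return comb(l - 1, d) * comb(r + 1, l - d) / comb(r + l, l)


def _gene_pmf(l: int, r: int) -> np.ndarray:  # noqa: E741
    """Mass function of d for one gene; genes with l <= 1 are a point mass at 0."""
    if l <= 1:
        return np.array([1.0])
    return np.array([prob_adjacent(d, l, r) for d in range(l)])


def total_pmf(profiles: Sequence[GeneLossProfile]) -> np.ndarray:
    """Distribution of the summed adjacent-pair count across independent genes."""
    if not profiles:
        raise ValueError("no gene profiles given")
    pmf = np.array([1.0])
    for p in profiles:
        pmf = np.convolve(pmf, _gene_pmf(p.l, p.r))
    return pmf


def exact_tail(
    profiles: Sequence[GeneLossProfile], observed_total: int | None = None
) -> float:
    """P(total adjacent pairs >= observed) under the independent-gene null."""
    if not profiles:
        raise ValueError("no gene profiles given")
    if observed_total is None:
        observed_total = sum(p.d for p in profiles)
    if observed_total <= 0:
        return 1.0
    pmf = total_pmf(profiles)
    if observed_total >= len(pmf):
        return 0.0
    return float(pmf[observed_total:].sum())


def resample_totals(
    profiles: Sequence[GeneLossProfile],
    n_resamples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null totals of adjacent lost pairs over ``n_resamples`` redraws."""
    totals = np.zeros(n_resamples, dtype=np.int64)
    for p in profiles:
        if p.l <= 1:
            continue
        n = p.n_sites
        keys = rng.random((n_resamples, n))
        picks = np.argpartition(keys, p.l - 1, axis=1)[:, : p.l]
        mask = np.zeros((n_resamples, n), dtype=bool)
        np.put_along_axis(mask, picks, True, axis=1)
        totals += (mask[:, :-1] & mask[:, 1:]).sum(axis=1)
    return totals


def resample_tail(
    profiles: Sequence[GeneLossProfile],
    n_resamples: int = 100_000,
    seed: int = 0,
    observed_total: int | None = None,
) -> float:
    """Resampling estimate of the exact tail; seeded and reproducible."""
    if not profiles:
        raise ValueError("no gene profiles given")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if observed_total is None:
        observed_total = sum(p.d for p in profiles)
    if observed_total <= 0:
        return 1.0
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    totals = resample_totals(profiles, n_resamples, rng)
    return float((totals >= observed_total).sum() / n_resamples)
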