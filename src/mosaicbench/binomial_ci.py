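"""Binomial confidence intervals on allele read counts.

The decision-tree heuristics rest on one-sided binomial confidence bounds
for the variant allele fraction, computed from quality-filtered read
counts.  Per-technology bounds use a one-sided confidence coefficient of
0.95; the bound on counts pooled across technologies uses 0.99.  A
"one-sided coefficient L" is realized as the relevant bound of the
two-sided interval at level 2L - 1, the standard equivalence.

The default interval family is the Wilson score interval without
continuity correction (the default of the R ``binconf`` routine); exact
Clopper-Pearson intervals are available for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Callable, Iterable, Mapping

from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .read_support import MosaicCandidate

__all__ = [
    "BinomialCI",
    "CombinedSupport",
    "wilson_interval",
    "clopper_pearson_interval",
    "per_tech_cis",
    "combined_ci",
]


@dataclass(frozen=True)
class BinomialCI:
    """A binomial interval record: x successes out of n trials.

    ``level`` is the one-sided confidence coefficient attached to each
    bound individually (so the two bounds jointly form a two-sided
    interval at level ``2*level - 1``).
    """

    x: int
    n: int
    level: float
    lower: float
    upper: float

    @property
    def point(self) -> float:
        return self.x / self.n

    def __post_init__(self) -> None:
        if self.n < 1 or not (0 <= self.x <= self.n):
            raise ValueError(f"invalid counts x={self.x}, n={self.n}")
        if not (0.5 < self.level < 1):
            raise ValueError(f"one-sided level must be in (0.5, 1), got {self.level}")
        if not (0 <= self.lower <= self.point <= self.upper <= 1):
            raise ValueError("interval does not bracket the point estimate")


def wilson_interval(x: int, n: int, one_sided_level: float = 0.95) -> BinomialCI:
    """Wilson score interval, no continuity correction.

    With z the normal quantile at ``one_sided_level`` and p = x/n::

        (p + z^2/2n +- z*sqrt(p(1-p)/n + z^2/4n^2)) / (1 + z^2/n)

    Each bound is a one-sided bound at ``one_sided_level``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= x <= n):
        raise ValueError(f"x must be in [0, n], got x={x}, n={n}")
    if not (0.5 < one_sided_level < 1):
        raise ValueError("one_sided_level must be in (0.5, 1)")
    z = stats.norm.ppf(one_sided_level)
    z2 = z * z
    denom = n + z2
    center = (x + z2 / 2.0) / denom
    half = z * math.sqrt(x * (n - x) / n + z2 / 4.0) / denom
    # clamp to [0,1] and guard the point estimate against float rounding
    lower = min(max(0.0, center - half), x / n)
    upper = max(min(1.0, center + half), x / n)
    return BinomialCI(x=int(x), n=int(n), level=one_sided_level, lower=lower, upper=upper)


def clopper_pearson_interval(x: int, n: int, one_sided_level: float = 0.95) -> BinomialCI:
    """Exact (Clopper-Pearson) interval, one-sided level per bound."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= x <= n):
        raise ValueError(f"x must be in [0, n], got x={x}, n={n}")
    alpha = 1.0 - one_sided_level
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(one_sided_level, x + 1, n - x))
    return BinomialCI(x=int(x), n=int(n), level=one_sided_level, lower=lower, upper=upper)


_METHODS: dict[str, Callable[[int, int, float], BinomialCI]] = {
    "wilson": wilson_interval,
    "clopper-pearson": clopper_pearson_interval,
}


def binomial_interval(x: int, n: int, one_sided_level: float, method: str = "wilson") -> BinomialCI:
    try:
        return _METHODS[method](x, n, one_sided_level)
    except KeyError:
        raise ValueError(f"unknown interval method {method!r}; choose from {sorted(_METHODS)}")


@dataclass(frozen=True)
class CombinedSupport:
    """Pooled allele counts across technologies with their combined interval.

    ``x_ci``/``n_ci`` are plain sums of alternate counts and depths over
    the included technologies; pooling deliberately ignores
    between-technology heterogeneity.
    """

    x_ci: int
    n_ci: int
    ci: BinomialCI
    technologies: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.x_ci > self.n_ci:
            raise ValueError("x_ci cannot exceed n_ci")

    @property
    def point(self) -> float:
        return self.x_ci / self.n_ci


def per_tech_cis(
    candidate: "MosaicCandidate",
    level: float = 0.95,
    method: str = "wilson",
) -> dict[str, BinomialCI]:
    """One interval per technology with positive filtered depth."""
    out = {}
    for tech, sup in candidate.support.items():
        if sup.depth >= 1:
            out[tech] = binomial_interval(sup.alt_count, sup.depth, level, method)
    if not out:
        raise ValueError(f"candidate {candidate.key} has no technology with depth >= 1")
    return out


def combined_ci(
    candidate: "MosaicCandidate",
    level: float = 0.99,
    include: Iterable[str] | None = None,
    method: str = "wilson",
) -> CombinedSupport:
    """Pooled interval over the included technologies (default: all present).

    Raises if the inclusion filter leaves no technology with depth >= 1.
    """
    chosen = candidate.support if include is None else {
        t: s for t, s in candidate.support.items() if t in set(include)
    }
    chosen = {t: s for t, s in chosen.items() if s.depth >= 1}
    if not chosen:
        raise ValueError(
            f"candidate {candidate.key}: no included technology with depth >= 1"
        )
    x_ci = sum(s.alt_count for s in chosen.values())
    n_ci = sum(s.depth for s in chosen.values())
    return CombinedSupport(
        x_ci=x_ci,
        n_ci=n_ci,
        ci=binomial_interval(x_ci, n_ci, level, method),
        technologies=tuple(sorted(chosen)),
    )
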