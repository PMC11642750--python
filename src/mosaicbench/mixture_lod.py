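"""In-silico mixture limit-of-detection experiment.

Two-sample mixtures are simulated across a ladder of expected allele
fractions (mixing fraction f of the carrier sample gives AF = f/2 at
carrier-unique heterozygous sites), a pluggable detector is run per
site, and recall is reported per AF.  The default detector is a
transparent binomial test — detect when the alternate count is at least
``min_alt`` and improbable under the sequencing-error rate — so its
acceptance region can be enumerated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import simulate_mixture, _alt_probability

__all__ = [
    "MixtureSpec",
    "LodReport",
    "DEFAULT_MIXTURE_FRACTIONS",
    "default_detector",
    "detection_threshold",
    "expected_recall",
    "run_lod",
]

#: carrier fractions of the study's mixture ladder: expected AFs
#: 50%, 25%, 10%, 5%, 1% and 0%
DEFAULT_MIXTURE_FRACTIONS: tuple[float, ...] = (1.0, 0.5, 0.2, 0.1, 0.02, 0.0)


@dataclass(frozen=True)
class MixtureSpec:
    """One mixture condition."""

    hg002_fraction: float
    depth: int = 300
    n_sites: int = 1000
    seed: int = 0
    fixed_depth: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.hg002_fraction <= 1):
            raise ValueError("hg002_fraction must be in [0, 1]")
        if self.depth < 1 or self.n_sites < 1:
            raise ValueError("depth and n_sites must be >= 1")

    @property
    def expected_af(self) -> float:
        return self.hg002_fraction * 0.5


def default_detector(
    alt: np.ndarray | int,
    depth: np.ndarray | int,
    error_rate: float,
    min_alt: int = 3,
    alpha: float = 1e-4,
) -> np.ndarray | bool:
    """Detect when alt >= min_alt and P(X >= alt | Bin(depth, error)) < alpha.

    Vectorized over sites; the tail probability is the exact binomial
    survival function at the error-model rate.
    """
    alt = np.asarray(alt)
    depth = np.asarray(depth)
    tail = stats.binom.sf(alt - 1, depth, error_rate)
    detected = (alt >= min_alt) & (tail < alpha)
    return bool(detected) if detected.ndim == 0 else detected


def detection_threshold(
    depth: int, error_rate: float, min_alt: int = 3, alpha: float = 1e-4
) -> int:
    """Smallest alt count the default detector accepts at this depth.

    The detector's acceptance region is an upper tail {alt >= t}; returns
    t (``depth + 1`` when nothing is detectable).
    """
    alts = np.arange(depth + 1)
    det = default_detector(alts, np.full(depth + 1, depth), error_rate, min_alt, alpha)
    hits = np.nonzero(det)[0]
    return int(hits[0]) if len(hits) else depth + 1


def expected_recall(
    expected_af: float,
    depth: int,
    error_rate: float,
    min_alt: int = 3,
    alpha: float = 1e-4,
) -> float:
    """Exact P(detected) by enumeration of the detector's acceptance region."""
    p_alt = float(_alt_probability(np.array([expected_af]), error_rate)[0])
    t = detection_threshold(depth, error_rate, min_alt, alpha)
    if t > depth:
        return 0.0
    return float(stats.binom.sf(t - 1, depth, p_alt))


@dataclass
class LodReport:
    """Per-AF recall table with the detector provenance."""

    rows: pd.DataFrame  # columns: expected_af, n_sites, detected, recall
    detector: str
    params: dict = field(default_factory=dict)

    def recall_at(self, expected_af: float) -> float:
        match = self.rows[np.isclose(self.rows["expected_af"], expected_af)]
        if match.empty:
            raise KeyError(f"no mixture at expected AF {expected_af}")
        return float(match["recall"].iloc[0])


def run_lod(
    specs: Sequence[MixtureSpec],
    detector: Callable = default_detector,
    error_rate: float = 0.001,
    detector_params: dict | None = None,
) -> LodReport:
    """Simulate each mixture, apply the detector, and tabulate recall.

    Rows are ordered by expected AF descending.  Deterministic given each
    spec's seed.
    """
    detector_params = dict(detector_params or {})
    rows = []
    for spec in specs:
        sim = simulate_mixture(
            sites=spec.n_sites,
            hg002_fraction=spec.hg002_fraction,
            depth=spec.depth,
            error_rate=error_rate,
            seed=spec.seed,
            fixed_depth=spec.fixed_depth,
        )
        detected = detector(
            sim["alt"].to_numpy(), sim["depth"].to_numpy(), error_rate, **detector_params
        )
        n_det = int(np.asarray(detected).sum())
        rows.append(
            dict(
                expected_af=spec.expected_af,
                n_sites=spec.n_sites,
                detected=n_det,
                recall=n_det / spec.n_sites,
            )
        )
    df = pd.DataFrame(rows).sort_values("expected_af", ascending=False, kind="stable")
    return LodReport(
        rows=df.reset_index(drop=True),
        detector=getattr(detector, "__name__", str(detector)),
        params={"error_rate": error_rate, **detector_params},
    )
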