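"""The 0–10 authentication score.

Eight alignment summaries are each tested against a pass/fail criterion and
contribute fixed points when they pass: evenness of coverage +2 (the
decisive evidence of genuine presence), terminal deamination +1 per end
(5′ C→T and 3′ G→A count independently, so up to +2 — the decisive
evidence of ancient origin), and +1 each for the all-read and damaged-read
edit-distance shapes, short read lengths, PMD-positive fraction, assigned
read count, and ANI. The total therefore ranges from 0 (absent or modern)
to 10 (present and ancient).

The per-criterion thresholds are this package's documented defaults; every
one is configurable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .authmetrics import AuthMetrics

__all__ = [
    "ScoreWeights",
    "ScoreCriteria",
    "AuthScore",
    "score_taxon",
    "score_matrix",
    "plot_heatmap",
    "COMPONENTS",
]

log = logging.getLogger(__name__)

COMPONENTS = ("deam5", "deam3", "evenness", "edit_all", "edit_damaged",
              "read_length", "pmd", "n_reads", "identity")


@dataclass(frozen=True)
class ScoreWeights:
    """Points awarded per passing component; defaults sum to 10."""

    deam5: int = 1
    deam3: int = 1
    evenness: int = 2
    edit_all: int = 1
    edit_damaged: int = 1
    read_length: int = 1
    pmd: int = 1
    n_reads: int = 1
    identity: int = 1

    @property
    def total(self) -> int:
        return sum(getattr(self, c) for c in COMPONENTS)


@dataclass(frozen=True)
class ScoreCriteria:
    """Pure pass/fail predicates on :class:`AuthMetrics`.

    deam5 / deam3
        Terminal rate ≥ ``deam_min_rate``, at least ``deam_fold``-fold over
        the interior baseline (positions 8–12), and ≥ ``deam_min_sites``
        informative terminal sites.
    evenness
        Breadth within ``evenness_ratio`` of the Lander–Waterman expectation
        1 − e^(−depth) (random placement normalizes breadth for depth), and
        ≥ ``evenness_nonzero_frac`` of bins covered.
    edit_all / edit_damaged
        Histogram mode at edit distance ≤ ``edit_mode_max`` and counts
        non-increasing over bins 0→3 allowing ``edit_allowed_inversions``;
        the damaged-read version additionally requires
        ``min_damaged_reads`` reads as a statistical floor.
    read_length
        Median aligned length ≤ ``max_median_read_length`` (fragmentation).
    pmd
        ≥ ``pmd_min_fraction`` of reads with PMD score > ``pmd_threshold``.
    n_reads
        ≥ ``min_assigned`` assigned reads (the depth default).
    identity
        Mean percent identity ≥ ``min_ani``.
    """

    deam_min_rate: float = 0.05
    deam_fold: float = 2.0
    deam_min_sites: int = 10
    deam_baseline: tuple[int, int] = (8, 12)  # 1-based inclusive positions
    evenness_ratio: float = 0.8
    evenness_nonzero_frac: float = 0.4
    edit_mode_max: int = 1
    edit_allowed_inversions: int = 1
    min_damaged_reads: int = 20
    max_median_read_length: float = 100.0
    pmd_threshold: float = 3.0
    pmd_min_fraction: float = 0.10
    min_assigned: int = 200
    min_ani: float = 90.0

    # -- individual predicates -------------------------------------------

    def _deam(self, rate: np.ndarray, n_sites: np.ndarray) -> bool:
        terminal = rate[0]
        if not np.isfinite(terminal) or n_sites[0] < self.deam_min_sites:
            return False
        lo, hi = self.deam_baseline
        baseline = rate[lo - 1:hi]
        base = float(np.nanmean(baseline)) if np.any(np.isfinite(baseline)) else 0.0
        return terminal >= self.deam_min_rate and terminal >= self.deam_fold * base

    def deam5(self, m: AuthMetrics) -> bool:
        return self._deam(m.deamination.p5_ct, m.deamination.n5_informative)

    def deam3(self, m: AuthMetrics) -> bool:
        return self._deam(m.deamination.p3_ga, m.deamination.n3_informative)

    def evenness(self, m: AuthMetrics) -> bool:
        depth = m.coverage.depth_mean
        if depth <= 0:
            return False
        expected = 1.0 - np.exp(-depth)
        ratio = m.coverage.breadth / expected
        return (ratio >= self.evenness_ratio
                and m.coverage.fraction_nonzero_bins >= self.evenness_nonzero_frac)

    def _edit_shape(self, hist: np.ndarray) -> bool:
        if hist.sum() == 0:
            return False
        mode = int(np.argmax(hist))  # ties resolve to the lowest bin
        inversions = sum(1 for i in range(3) if hist[i + 1] > hist[i])
        return mode <= self.edit_mode_max and inversions <= self.edit_allowed_inversions

    def edit_all(self, m: AuthMetrics) -> bool:
        return self._edit_shape(m.edit_all)

    def edit_damaged(self, m: AuthMetrics) -> bool:
        return (m.edit_damaged.sum() >= self.min_damaged_reads
                and self._edit_shape(m.edit_damaged))

    def read_length(self, m: AuthMetrics) -> bool:
        med = m.median_read_length
        return np.isfinite(med) and med <= self.max_median_read_length

    def pmd(self, m: AuthMetrics) -> bool:
        if len(m.pmd_scores) == 0:
            return False
        frac = float(np.mean(m.pmd_scores > self.pmd_threshold))
        return frac >= self.pmd_min_fraction

    def n_reads(self, m: AuthMetrics) -> bool:
        return m.n_assigned >= self.min_assigned

    def identity(self, m: AuthMetrics) -> bool:
        return np.isfinite(m.ani_mean) and m.ani_mean >= self.min_ani

    def evaluate(self, m: AuthMetrics) -> dict[str, bool]:
        return {c: bool(getattr(self, c)(m)) for c in COMPONENTS}


@dataclass
class AuthScore:
    """Component points awarded and their total (0–10 with default weights)."""

    components: dict[str, int]
    total: int


def score_taxon(metrics: AuthMetrics, criteria: ScoreCriteria | None = None,
                weights: ScoreWeights | None = None) -> AuthScore:
    """Score one taxon in one sample: each component contributes its weight
    iff its criterion passes."""
    criteria = criteria or ScoreCriteria()
    weights = weights or ScoreWeights()
    passed = criteria.evaluate(metrics)
    components = {c: (getattr(weights, c) if passed[c] else 0) for c in COMPONENTS}
    return AuthScore(components=components, total=sum(components.values()))


def score_matrix(metrics: Mapping[tuple[str, str], AuthMetrics],
                 criteria: ScoreCriteria | None = None,
                 weights: ScoreWeights | None = None) -> pd.DataFrame:
    """Taxa × samples table of total scores; (sample, taxon) pairs without
    metrics render as 0."""
    if not metrics:
        warnings.warn("score_matrix called with no (sample, taxon) metrics",
                      stacklevel=2)
        return pd.DataFrame()
    samples = sorted({s for s, _ in metrics})
    taxa = sorted({t for _, t in metrics})
    df = pd.DataFrame(0, index=taxa, columns=samples, dtype=int)
    for (sample, taxon), m in metrics.items():
        df.loc[taxon, sample] = score_taxon(m, criteria, weights).total
    df.index.name = "taxon"
    df.columns.name = "sample"
    return df


def component_table(metrics: Mapping[tuple[str, str], AuthMetrics],
                    criteria: ScoreCriteria | None = None,
                    weights: ScoreWeights | None = None) -> pd.DataFrame:
    """Per-(sample, taxon) component breakdown, one row each."""
    rows = []
    for (sample, taxon), m in sorted(metrics.items()):
        score = score_taxon(m, criteria, weights)
        row = {"sample": sample, "taxon": taxon, **score.components,
               "total": score.total}
        rows.append(row)
    return pd.DataFrame(rows)


def plot_heatmap(scores: pd.DataFrame, path, max_score: int = 10) -> None:
    """Authentication-score heatmap, color scale fixed to [0, max_score]."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if scores.empty:
        log.warning("empty score matrix: no heatmap written to %s", path)
        return
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.6 * scores.shape[1], 1.0 + 0.35 * scores.shape[0]))
    im = ax.imshow(scores.values, cmap="YlOrRd", vmin=0, vmax=max_score,
                   aspect="auto")
    ax.set_xticks(range(scores.shape[1]), scores.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(scores.shape[0]), scores.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="authentication score")
    fig.tight_layout()
    fig.savefig(path, dpi=110, metadata={"Software": None})
    plt.close(fig)
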