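"""Alignment-based validation and authentication summaries.

From SAM-style alignments against a candidate reference this module derives
the eight per-taxon summaries used to judge microbial presence and ancient
status: depth and breadth of coverage, the 100-bin evenness profile,
terminal deamination (C→T at 5′ / G→A at 3′) profiles, edit-distance
histograms for all and for damaged reads, read-length distribution,
per-read post-mortem-damage (PMD) log-likelihood scores, assigned-read
counts, and percent identity / ANI.

All coordinates are 0-based half-open internally; SAM input is converted
from 1-based by pysam. "Molecule orientation" below means the read's own
5′→3′ direction: reverse-strand records are flipped and complemented before
damage tallying, so a C→T lesion is counted at its distance from the
molecule's 5′ terminus regardless of mapping strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .simdata import revcomp

__all__ = [
    "AlignmentRecord",
    "DeaminationProfile",
    "CoverageProfile",
    "PmdParams",
    "AuthMetrics",
    "read_sam",
    "compute_depth",
    "compute_breadth",
    "compute_evenness_profile",
    "compute_deamination_profile",
    "is_damaged",
    "edit_distance_histograms",
    "percent_identity",
    "identity_histogram",
    "pmd_score",
    "count_assigned",
    "compute_auth_metrics",
    "metrics_by_reference",
    "plot_panels",
]

EDIT_BINS = 11  # edit distances 0..9, with >= 10 pooled in the last bin
IDENTITY_EDGES = (80.0, 85.0, 90.0, 95.0, 100.0)


@dataclass
class AlignmentRecord:
    """One aligned read.

    ``read_seq`` and ``ref_seq`` are the aligned query and reference bases in
    reference orientation (substitution columns only; insertions are dropped
    and deletions skipped, NM kept as reported). ``mismatches`` lists
    (offset, ref_base, read_base) into those strings.
    """

    read_id: str
    ref_id: str
    pos: int
    strand: str
    read_seq: str
    edit_distance: int
    mapq: int = 60
    ref_seq: str | None = None
    mismatches: list[tuple[int, str, str]] = field(default_factory=list)
    is_primary: bool = True

    @property
    def aligned_length(self) -> int:
        return len(self.read_seq)

    def molecule_pairs(self) -> list[tuple[str, str]]:
        """(ref_base, read_base) columns in molecule 5′→3′ orientation."""
        if self.ref_seq is None:
            raise ValueError(
                f"read {self.read_id}: reference bases unavailable "
                "(no MD tag and no reference sequence supplied)"
            )
        ref, qry = self.ref_seq.upper(), self.read_seq.upper()
        if self.strand == "-":
            ref, qry = revcomp(ref), revcomp(qry)
        return list(zip(ref, qry))


@dataclass
class DeaminationProfile:
    """Per-position terminal mismatch frequencies over a window of P
    positions from each read end (index 0 = terminal base). Frequencies are
    NaN where no informative (reference C resp. G) site was seen."""

    p5_ct: np.ndarray
    p3_ga: np.ndarray
    n5_informative: np.ndarray
    n3_informative: np.ndarray

    @property
    def window(self) -> int:
        return len(self.p5_ct)


@dataclass
class CoverageProfile:
    """Depth, breadth and per-bin local breadth over equal genome bins
    (remainder absorbed by the last bin)."""

    depth_mean: float
    breadth: float
    bin_breadth: np.ndarray
    bin_sizes: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.bin_breadth)

    @property
    def fraction_nonzero_bins(self) -> float:
        if self.n_bins == 0:
            return 0.0
        return float(np.mean(self.bin_breadth > 0))


@dataclass(frozen=True)
class PmdParams:
    """Damage/null model constants for the per-read PMD log-likelihood ratio.

    Deamination probability at distance z from the relevant end is
    p_base + (p_max − p_base)·exp(−decay_rate·z); the null model explains
    every mismatch as a sequencing error at rate ``err``. Defaults mirror
    the simulator's Briggs defaults so end-to-end recovery is testable.
    """

    decay_rate: float = 0.5
    p_max: float = 0.3
    p_base: float = 0.01
    err: float = 0.001

    def __post_init__(self):
        if not 0.0 <= self.p_base <= self.p_max <= 1.0:
            raise ValueError("need 0 <= p_base <= p_max <= 1")
        if self.decay_rate <= 0:
            raise ValueError("decay_rate must be > 0")

    def damage_prob(self, z: int) -> float:
        return self.p_base + (self.p_max - self.p_base) * math.exp(-self.decay_rate * z)


@dataclass
class AuthMetrics:
    """The eight per-taxon per-sample authentication summaries."""

    deamination: DeaminationProfile
    coverage: CoverageProfile
    edit_all: np.ndarray
    edit_damaged: np.ndarray
    read_lengths: np.ndarray
    pmd_scores: np.ndarray
    n_assigned: int
    identity_hist: np.ndarray
    ani_mean: float

    @property
    def median_read_length(self) -> float:
        if len(self.read_lengths) == 0:
            return float("nan")
        return float(np.median(self.read_lengths))

    @property
    def pmd_positive_fraction(self) -> float:
        """Fraction of reads with PMD score above the conventional +3 cut."""
        if len(self.pmd_scores) == 0:
            return 0.0
        return float(np.mean(self.pmd_scores > 3.0))


def read_sam(path, reference: Mapping[str, str] | None = None,
             keep_unmapped: bool = False) -> list[AlignmentRecord]:
    """Parse a SAM/BAM file into :class:`AlignmentRecord` objects.

    Reference bases are recovered from the MD tag when present, otherwise
    from ``reference`` (a mapping ref_id → sequence). Secondary and
    supplementary records are skipped.
    """
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for idx, seg in enumerate(sam):
            if seg.is_secondary or seg.is_supplementary:
                continue
            if seg.is_unmapped:
                if keep_unmapped:
                    records.append(AlignmentRecord(
                        read_id=seg.query_name, ref_id="*", pos=-1, strand="+",
                        read_seq=seg.query_sequence or "", edit_distance=0,
                        mapq=seg.mapping_quality, is_primary=False))
                continue
            if seg.query_sequence is None:
                raise ValueError(f"record {idx} ({seg.query_name}): missing SEQ")
            ref_bases, qry_bases = _aligned_columns(seg, reference)
            nm = int(seg.get_tag("NM")) if seg.has_tag("NM") else _count_mismatches(
                ref_bases, qry_bases)
            if ref_bases is not None:
                mismatches = [(i, r, q)
                              for i, (r, q) in enumerate(zip(ref_bases, qry_bases))
                              if r != q]
            else:
                mismatches = []
            records.append(AlignmentRecord(
                read_id=seg.query_name,
                ref_id=seg.reference_name,
                pos=seg.reference_start,
                strand="-" if seg.is_reverse else "+",
                read_seq=qry_bases,
                edit_distance=nm,
                mapq=seg.mapping_quality,
                ref_seq=ref_bases,
                mismatches=mismatches,
            ))
    return records


def _aligned_columns(seg: pysam.AlignedSegment,
                     reference: Mapping[str, str] | None) -> tuple[str | None, str]:
    """Substitution columns (ref, query) of an alignment, both in reference
    orientation; insertions dropped, deletions skipped."""
    qseq = seg.query_sequence.upper()
    has_md = seg.has_tag("MD")
    if reference is not None and seg.reference_name in reference:
        refseq = reference[seg.reference_name]
    else:
        refseq = None
    if not has_md and refseq is None:
        # matched query bases only; mismatch identities unrecoverable
        qry = "".join(qseq[q] for q, r in seg.get_aligned_pairs(matches_only=True))
        return None, qry
    ref_parts: list[str] = []
    qry_parts: list[str] = []
    if has_md:
        for q, r, rb in seg.get_aligned_pairs(matches_only=True, with_seq=True):
            ref_parts.append(rb.upper())
            qry_parts.append(qseq[q])
    else:
        for q, r in seg.get_aligned_pairs(matches_only=True):
            ref_parts.append(refseq[r].upper())
            qry_parts.append(qseq[q])
    return "".join(ref_parts), "".join(qry_parts)


def _count_mismatches(ref: str | None, qry: str) -> int:
    if ref is None:
        return 0
    return sum(1 for r, q in zip(ref, qry) if r != q)


def compute_depth(alignments: Sequence[AlignmentRecord], ref_length: int) -> float:
    """Mean depth of coverage: total aligned bases / reference length (X)."""
    if ref_length <= 0:
        raise ValueError("ref_length must be positive")
    return sum(a.aligned_length for a in alignments) / ref_length


def _coverage_mask(alignments: Sequence[AlignmentRecord], ref_length: int) -> np.ndarray:
    delta = np.zeros(ref_length + 1, dtype=np.int64)
    for a in alignments:
        start = max(a.pos, 0)
        end = min(a.pos + a.aligned_length, ref_length)
        if start < end:
            delta[start] += 1
            delta[end] -= 1
    return np.cumsum(delta[:-1]) > 0


def compute_breadth(alignments: Sequence[AlignmentRecord], ref_length: int) -> float:
    """Breadth of coverage: fraction of reference positions covered ≥ 1×."""
    if ref_length <= 0:
        raise ValueError("ref_length must be positive")
    return float(_coverage_mask(alignments, ref_length).mean())


def compute_evenness_profile(alignments: Sequence[AlignmentRecord], ref_length: int,
                             n_bins: int = 100) -> CoverageProfile:
    """Local breadth per bin: split the reference into ``n_bins`` equal bins
    (the last absorbs the remainder) and report, per bin, the fraction of
    positions covered by at least one aligned read."""
    if ref_length <= 0:
        raise ValueError("ref_length must be positive")
    if ref_length < n_bins:
        raise ValueError(
            f"reference length {ref_length} shorter than n_bins={n_bins}; "
            "use a smaller n_bins"
        )
    covered = _coverage_mask(alignments, ref_length)
    size = ref_length // n_bins
    edges = [i * size for i in range(n_bins)] + [ref_length]
    bin_breadth = np.empty(n_bins)
    bin_sizes = np.empty(n_bins, dtype=int)
    for i in range(n_bins):
        lo, hi = edges[i], edges[i + 1]
        bin_sizes[i] = hi - lo
        bin_breadth[i] = covered[lo:hi].mean()
    depth = compute_depth(alignments, ref_length)
    return CoverageProfile(depth_mean=depth, breadth=float(covered.mean()),
                           bin_breadth=bin_breadth, bin_sizes=bin_sizes)


def compute_deamination_profile(alignments: Iterable[AlignmentRecord],
                                window: int = 15) -> DeaminationProfile:
    """Terminal damage profile: per 5′ position, the C→T mismatch frequency
    among reference-C sites; per 3′ position, the G→A frequency among
    reference-G sites. Strand-corrected via molecule orientation."""
    c5 = np.zeros(window)
    n5 = np.zeros(window)
    c3 = np.zeros(window)
    n3 = np.zeros(window)
    for rec in alignments:
        pairs = rec.molecule_pairs()
        L = len(pairs)
        for z in range(min(window, L)):
            ref5, read5 = pairs[z]
            if ref5 == "C":
                n5[z] += 1
                if read5 == "T":
                    c5[z] += 1
            ref3, read3 = pairs[L - 1 - z]
            if ref3 == "G":
                n3[z] += 1
                if read3 == "A":
                    c3[z] += 1
    with np.errstate(invalid="ignore"):
        p5 = np.where(n5 > 0, c5 / np.maximum(n5, 1), np.nan)
        p3 = np.where(n3 > 0, c3 / np.maximum(n3, 1), np.nan)
    return DeaminationProfile(p5_ct=p5, p3_ga=p3,
                              n5_informative=n5.astype(int),
                              n3_informative=n3.astype(int))


def is_damaged(rec: AlignmentRecord, terminal_window: int = 5) -> bool:
    """True iff the read shows ≥ 1 C→T within the first ``terminal_window``
    5′ positions or ≥ 1 G→A within the last ``terminal_window`` 3′ positions
    (molecule orientation)."""
    pairs = rec.molecule_pairs()
    L = len(pairs)
    w = min(terminal_window, L)
    for z in range(w):
        ref5, read5 = pairs[z]
        if ref5 == "C" and read5 == "T":
            return True
        ref3, read3 = pairs[L - 1 - z]
        if ref3 == "G" and read3 == "A":
            return True
    return False


def edit_distance_histograms(alignments: Sequence[AlignmentRecord],
                             terminal_window: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Edit-distance counts over 0..10 (≥10 pooled) for all reads and for
    the damaged subset."""
    edit_all = np.zeros(EDIT_BINS, dtype=int)
    edit_damaged = np.zeros(EDIT_BINS, dtype=int)
    for rec in alignments:
        b = min(rec.edit_distance, EDIT_BINS - 1)
        edit_all[b] += 1
        if is_damaged(rec, terminal_window):
            edit_damaged[b] += 1
    return edit_all, edit_damaged


def percent_identity(rec: AlignmentRecord) -> float:
    """100·(aligned length − edit distance)/aligned length."""
    if rec.aligned_length <= 0:
        raise ValueError(f"read {rec.read_id}: empty alignment")
    return 100.0 * (rec.aligned_length - rec.edit_distance) / rec.aligned_length


def identity_histogram(alignments: Sequence[AlignmentRecord]) -> np.ndarray:
    """Counts over identity bins [80,85), [85,90), [90,95), [95,100];
    identities below 80% fall outside the displayed range and are dropped."""
    vals = [percent_identity(a) for a in alignments]
    hist, _ = np.histogram(vals, bins=IDENTITY_EDGES)
    return hist


def pmd_score(rec: AlignmentRecord, params: PmdParams | None = None) -> float:
    """Per-read PMD log-likelihood ratio of the damage model vs. the null.

    Reference-C sites contribute from the 5′ side (distance z from the 5′
    terminus) and reference-G sites from the 3′ side; observing the
    deaminated base adds log(D(z)/err), observing the intact base adds
    log((1−D(z))/(1−err)); any other observation, and sites that are neither
    reference C nor G, contribute 0.
    """
    params = params or PmdParams()
    pairs = rec.molecule_pairs()
    L = len(pairs)
    score = 0.0
    for z, (ref, read) in enumerate(pairs):
        if ref == "C":
            d = params.damage_prob(z)
            if read == "T":
                score += math.log(d / params.err)
            elif read == "C":
                score += math.log((1.0 - d) / (1.0 - params.err))
        elif ref == "G":
            d = params.damage_prob(L - 1 - z)
            if read == "A":
                score += math.log(d / params.err)
            elif read == "G":
                score += math.log((1.0 - d) / (1.0 - params.err))
    return score


def count_assigned(alignments: Iterable[AlignmentRecord],
                   min_mapq: int = 0) -> dict[str, int]:
    """Primary alignments per reference with MAPQ strictly above
    ``min_mapq`` (min_mapq=0 counts uniquely mapped reads, MAPQ > 0)."""
    counts: dict[str, int] = {}
    for rec in alignments:
        if not rec.is_primary or rec.mapq <= min_mapq:
            continue
        counts[rec.ref_id] = counts.get(rec.ref_id, 0) + 1
    return counts


def compute_auth_metrics(alignments: Sequence[AlignmentRecord], ref_length: int,
                         n_bins: int = 100, deam_window: int = 15,
                         terminal_window: int = 5,
                         pmd_params: PmdParams | None = None) -> AuthMetrics:
    """Assemble the full eight-summary panel for one taxon."""
    coverage = compute_evenness_profile(alignments, ref_length, n_bins)
    deam = compute_deamination_profile(alignments, deam_window)
    edit_all, edit_damaged = edit_distance_histograms(alignments, terminal_window)
    lengths = np.array([a.aligned_length for a in alignments], dtype=int)
    pmds = np.array([pmd_score(a, pmd_params) for a in alignments])
    ident = identity_histogram(alignments)
    ani = float(np.mean([percent_identity(a) for a in alignments])) if alignments else float("nan")
    return AuthMetrics(
        deamination=deam,
        coverage=coverage,
        edit_all=edit_all,
        edit_damaged=edit_damaged,
        read_lengths=lengths,
        pmd_scores=pmds,
        n_assigned=len(alignments),
        identity_hist=ident,
        ani_mean=ani,
    )


def metrics_by_reference(alignments: Iterable[AlignmentRecord],
                         ref_lengths: Mapping[str, int],
                         **kwargs) -> dict[str, AuthMetrics]:
    """Group alignments by reference and compute a metrics panel each.

    References shorter than the bin count are skipped (desk-scale guard).
    """
    grouped: dict[str, list[AlignmentRecord]] = {}
    for rec in alignments:
        grouped.setdefault(rec.ref_id, []).append(rec)
    out: dict[str, AuthMetrics] = {}
    n_bins = kwargs.get("n_bins", 100)
    for ref_id in sorted(grouped):
        if ref_id not in ref_lengths or ref_lengths[ref_id] < n_bins:
            continue
        out[ref_id] = compute_auth_metrics(grouped[ref_id], ref_lengths[ref_id],
                                           **kwargs)
    return out


def metrics_to_frame(metrics: Mapping[str, AuthMetrics]):
    """Flat per-taxon summary table of the headline numbers."""
    import pandas as pd

    rows = []
    for ref_id, m in metrics.items():
        rows.append({
            "taxon": ref_id,
            "n_assigned": m.n_assigned,
            "depth_mean": m.coverage.depth_mean,
            "breadth": m.coverage.breadth,
            "fraction_nonzero_bins": m.coverage.fraction_nonzero_bins,
            "p5_ct_pos1": m.deamination.p5_ct[0],
            "p3_ga_pos1": m.deamination.p3_ga[0],
            "median_read_length": m.median_read_length,
            "pmd_positive_fraction": m.pmd_positive_fraction,
            "ani_mean": m.ani_mean,
            "n_damaged": int(m.edit_damaged.sum()),
        })
    return pd.DataFrame(rows)


def metrics_to_dict(m: AuthMetrics) -> dict:
    """JSON-serializable form of a metrics panel (NaN encoded as None)."""

    def _list(a):
        return [None if isinstance(x, float) and math.isnan(x) else float(x)
                for x in np.asarray(a, dtype=float)]

    return {
        "deamination": {
            "p5_ct": _list(m.deamination.p5_ct),
            "p3_ga": _list(m.deamination.p3_ga),
            "n5_informative": [int(x) for x in m.deamination.n5_informative],
            "n3_informative": [int(x) for x in m.deamination.n3_informative],
        },
        "coverage": {
            "depth_mean": m.coverage.depth_mean,
            "breadth": m.coverage.breadth,
            "bin_breadth": _list(m.coverage.bin_breadth),
            "bin_sizes": [int(x) for x in m.coverage.bin_sizes],
        },
        "edit_all": [int(x) for x in m.edit_all],
        "edit_damaged": [int(x) for x in m.edit_damaged],
        "read_lengths": [int(x) for x in m.read_lengths],
        "pmd_scores": _list(m.pmd_scores),
        "n_assigned": int(m.n_assigned),
        "identity_hist": [int(x) for x in m.identity_hist],
        "ani_mean": None if math.isnan(m.ani_mean) else float(m.ani_mean),
    }


def metrics_from_dict(d: dict) -> AuthMetrics:
    def _arr(xs):
        return np.array([np.nan if x is None else x for x in xs], dtype=float)

    deam = DeaminationProfile(
        p5_ct=_arr(d["deamination"]["p5_ct"]),
        p3_ga=_arr(d["deamination"]["p3_ga"]),
        n5_informative=np.array(d["deamination"]["n5_informative"], dtype=int),
        n3_informative=np.array(d["deamination"]["n3_informative"], dtype=int),
    )
    cov = CoverageProfile(
        depth_mean=d["coverage"]["depth_mean"],
        breadth=d["coverage"]["breadth"],
        bin_breadth=_arr(d["coverage"]["bin_breadth"]),
        bin_sizes=np.array(d["coverage"]["bin_sizes"], dtype=int),
    )
    return AuthMetrics(
        deamination=deam,
        coverage=cov,
        edit_all=np.array(d["edit_all"], dtype=int),
        edit_damaged=np.array(d["edit_damaged"], dtype=int),
        read_lengths=np.array(d["read_lengths"], dtype=int),
        pmd_scores=_arr(d["pmd_scores"]),
        n_assigned=int(d["n_assigned"]),
        identity_hist=np.array(d["identity_hist"], dtype=int),
        ani_mean=float("nan") if d["ani_mean"] is None else float(d["ani_mean"]),
    )


def save_metrics(metrics: Mapping[str, AuthMetrics], path) -> None:
    """Write a taxon → metrics mapping as JSON."""
    import json

    with open(path, "w") as fh:
        json.dump({k: metrics_to_dict(m) for k, m in sorted(metrics.items())},
                  fh, indent=1, sort_keys=True)


def load_metrics(path) -> dict[str, AuthMetrics]:
    import json

    with open(path) as fh:
        raw = json.load(fh)
    return {k: metrics_from_dict(d) for k, d in raw.items()}


def plot_panels(metrics: AuthMetrics, path, title: str = "") -> None:
    """Nine-panel authentication figure: edit distances (all / damaged),
    evenness profile, deamination pattern, read lengths, PMD scores,
    identity histogram, coverage summary, counts summary."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 3, figsize=(12, 10))
    (ax_a, ax_b, ax_c), (ax_d, ax_e, ax_f), (ax_g, ax_h, ax_i) = axes

    x = np.arange(EDIT_BINS)
    ax_a.bar(x, metrics.edit_all, color="steelblue")
    ax_a.set_title("a  edit distance (all reads)")
    ax_b.bar(x, metrics.edit_damaged, color="firebrick")
    ax_b.set_title("b  edit distance (damaged reads)")

    ax_c.plot(metrics.coverage.bin_breadth, lw=1)
    ax_c.set_ylim(0, 1.05)
    ax_c.set_title("c  evenness (local breadth per bin)")

    w = metrics.deamination.window
    ax_d.plot(np.arange(1, w + 1), metrics.deamination.p5_ct, "r-", label="5' C>T")
    ax_d.plot(np.arange(1, w + 1), metrics.deamination.p3_ga, "b-", label="3' G>A")
    ax_d.legend(frameon=False, fontsize=8)
    ax_d.set_title("d  deamination pattern")

    if len(metrics.read_lengths):
        ax_e.hist(metrics.read_lengths, bins=30, color="grey")
    ax_e.set_title("e  read length")

    if len(metrics.pmd_scores):
        ax_f.hist(metrics.pmd_scores, bins=30, color="darkgreen")
    ax_f.axvline(3.0, color="k", ls="--", lw=0.8)
    ax_f.set_title("f  PMD scores")

    labels = ["80-85", "85-90", "90-95", "95-100"]
    ax_g.bar(labels, metrics.identity_hist, color="goldenrod")
    ax_g.set_title("g  percent identity")

    ax_h.axis("off")
    ax_h.text(0.05, 0.6,
              f"depth = {metrics.coverage.depth_mean:.3f}X\n"
              f"breadth = {metrics.coverage.breadth:.3f}\n"
              f"nonzero bins = {metrics.coverage.fraction_nonzero_bins:.2f}",
              fontsize=11)
    ax_h.set_title("h  coverage summary")

    ax_i.axis("off")
    ax_i.text(0.05, 0.6,
              f"assigned reads = {metrics.n_assigned}\n"
              f"damaged reads = {int(metrics.edit_damaged.sum())}\n"
              f"ANI = {metrics.ani_mean:.2f}%\n"
              f"median length = {metrics.median_read_length:.0f} bp",
              fontsize=11)
    ax_i.set_title("i  assignment summary")

    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=110, metadata={"Software": None})
    plt.close(fig)
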