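"""Synthetic ancient-metagenomic sample generation.

Emulates the classic aDNA library construction chain at desk scale:
toy reference genomes, log-normally fragmented molecules, Briggs-style
post-mortem damage (single-strand overhangs with elevated C→T deamination,
double-strand background deamination, nick-associated deamination),
adapter read-through, uniform sequencing errors, and ground-truth
bookkeeping (per-species fragment counts plus a truth SAM of fragment
origins) for downstream benchmarking of detection and authentication.

Coordinates are 0-based half-open internally; the truth SAM is written
1-based per the SAM standard via pysam.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "DamageParams",
    "FragmentLengthModel",
    "SpeciesSpec",
    "SampleDesign",
    "GroundTruth",
    "DamageEvent",
    "SampleResult",
    "DEFAULT_MICROBIAL_FRACTIONS",
    "ANCIENT_SPECIES_NAMES",
    "MODERN_SPECIES_NAMES",
    "MODERN_FRAGLEN",
    "generate_reference",
    "sample_fragment_lengths",
    "apply_briggs_damage",
    "terminal_ct_rate",
    "species_panel",
    "default_design",
    "build_genomes",
    "simulate_sample",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: default Illumina universal adapter (TruSeq), written on read-through
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"

#: microbial DNA fraction per sample in the default ten-sample design
DEFAULT_MICROBIAL_FRACTIONS = (0.7, 0.7, 0.7, 0.5, 0.5, 0.5, 0.4, 0.3, 0.3, 0.3)

# Species panel of the default design: 18 taxa carry ancient (damaged,
# heavily fragmented) molecules, 17 are modern contaminants. Names are
# taxa commonly reported in ancient metagenomic projects; the attached
# genomes and taxon IDs are synthetic.
ANCIENT_SPECIES_NAMES = (
    "Campylobacter rectus",
    "Clostridium botulinum",
    "Enterococcus faecalis",
    "Fusarium fujikuroi",
    "Mycobacterium avium",
    "Mycolicibacterium aurum",
    "Neisseria meningitidis",
    "Nocardia brasiliensis",
    "Parvimonas micra",
    "Prosthecobacter vanneervenii",
    "Ralstonia solanacearum",
    "Rothia dentocariosa",
    "Salmonella enterica",
    "Sorangium cellulosum",
    "Streptococcus pyogenes",
    "Streptosporangium roseum",
    "Yersinia pestis",
    "Bradyrhizobium erythrophlei",
)

MODERN_SPECIES_NAMES = (
    "Acanthamoeba castellanii",
    "Aspergillus flavus",
    "Brevibacterium aurantiacum",
    "Burkholderia mallei",
    "Lactococcus lactis",
    "Methylobacterium bullatum",
    "Micromonas commoda",
    "Micromonospora echinospora",
    "Nonomuraea gerenzanensis",
    "Pseudomonas caeni",
    "Pseudomonas psychrophila",
    "Pseudomonas thivervalensis",
    "Vermamoeba vermiformis",
    "Rhodococcus hoagii",
    "Rhodopseudomonas palustris",
    "Mycobacterium riyadhense",
    "Planobispora rosea",
)

HOST_NAME = "Homo sapiens"
HOST_TAXID = 9606


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class DamageParams:
    """Briggs-style post-mortem damage parameters.

    nick_rate
        Per-internal-position nick probability. Nicks do not split the
        fragment here; a nicked interior position gets an additional
        single-strand-rate C→T deamination opportunity.
    overhang_param
        Geometric parameter p of the single-strand overhang length at each
        fragment end, P(length = j) = p·(1−p)^j for j ≥ 0 (blunt ends
        allowed).
    ds_deam
        Double-strand (interior) per-site C→T deamination probability.
    ss_deam
        Single-strand (overhang) per-site C→T deamination probability;
        appears as G→A inside the 3′ overhang because the lesion sits on
        the complementary strand.
    """

    nick_rate: float = 0.03
    overhang_param: float = 0.4
    ds_deam: float = 0.01
    ss_deam: float = 0.3

    def __post_init__(self):
        for name in ("nick_rate", "overhang_param", "ds_deam", "ss_deam"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")


@dataclass(frozen=True)
class FragmentLengthModel:
    """Log-normal fragment length: exp(Normal(loc, scale)), floored at min_len.

    The defaults were fit to authentic ancient bacterial reads (median
    exp(loc) ≈ 42 bp).
    """

    loc: float = 3.7424069808
    scale: float = 0.2795148843
    min_len: int = 30

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError(f"scale must be > 0, got {self.scale!r}")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")

    @property
    def mean(self) -> float:
        """Closed-form log-normal mean exp(loc + scale²/2), ignoring the floor."""
        return float(np.exp(self.loc + self.scale**2 / 2.0))


#: moderately fragmented modern contaminant molecules (median ≈ 148 bp)
MODERN_FRAGLEN = FragmentLengthModel(loc=5.0, scale=0.25)


@dataclass(frozen=True)
class SpeciesSpec:
    """One taxon of a simulated community."""

    name: str
    taxid: int
    is_ancient: bool
    genome_length: int
    relative_abundance: float


@dataclass(frozen=True)
class SampleDesign:
    """Layout of one simulated metagenomic sample.

    ``microbial_fraction`` is the fraction of each fragment pool that is
    microbial; the remainder is host. Paired 125-bp reads are emitted from
    each fragment, padding short inserts with the adapter and random fill.
    """

    sample_id: str = "sample1"
    n_ancient_fragments: int = 500_000
    n_modern_fragments: int = 500_000
    microbial_fraction: float = 0.7
    read_length: int = 125
    paired: bool = True
    adapter_seq: str = DEFAULT_ADAPTER
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.microbial_fraction <= 1.0:
            raise ValueError("microbial_fraction must be in [0, 1]")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.n_ancient_fragments < 0 or self.n_modern_fragments < 0:
            raise ValueError("fragment counts must be non-negative")


@dataclass
class DamageEvent:
    """One deamination substitution: 0-based molecule position, base change,
    and the region that produced it (``5p_overhang``/``3p_overhang``/
    ``interior``/``nick``)."""

    pos: int
    change: str
    region: str


@dataclass
class GroundTruth:
    """Truth bookkeeping for a set of simulated samples.

    ``table`` has one row per (sample, taxon) with columns
    sample, taxid, species, is_ancient, n_fragments.
    """

    table: pd.DataFrame

    COLUMNS = ("sample", "taxid", "species", "is_ancient", "n_fragments")

    def fragment_counts(self) -> pd.DataFrame:
        """Sample × species fragment-count matrix."""
        return self.table.pivot_table(
            index="sample", columns="species", values="n_fragments",
            aggfunc="sum", fill_value=0,
        )

    def presence(self) -> pd.DataFrame:
        """Sample × species boolean presence matrix."""
        return self.fragment_counts() > 0

    def ancient_label(self) -> pd.Series:
        """species → is_ancient (host rows excluded: its pools differ)."""
        micro = self.table[self.table["taxid"] != HOST_TAXID]
        return micro.drop_duplicates("species").set_index("species")["is_ancient"]

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "GroundTruth":
        df = pd.read_csv(path, sep="\t")
        missing = set(cls.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"truth table missing columns: {sorted(missing)}")
        return cls(df)

    @classmethod
    def concat(cls, parts: Iterable["GroundTruth"]) -> "GroundTruth":
        return cls(pd.concat([p.table for p in parts], ignore_index=True))


@dataclass
class SampleResult:
    """Paths and truth slice produced by :func:`simulate_sample`."""

    fastq_r1: Path
    fastq_r2: Path | None
    truth_sam: Path
    truth: GroundTruth


def generate_reference(length: int, gc: float = 0.5, seed=0) -> str:
    """Random uppercase A/C/G/T sequence of the given length and GC content."""
    if length <= 0:
        raise ValueError(f"length must be positive, got {length!r}")
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must be in [0, 1], got {gc!r}")
    rng = _as_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=probs)
    return codes.tobytes().decode("ascii")


def sample_fragment_lengths(n: int, model: FragmentLengthModel | None = None,
                            seed=0) -> np.ndarray:
    """Draw n integer fragment lengths from the log-normal model."""
    if n < 0:
        raise ValueError("n must be >= 0")
    model = model or FragmentLengthModel()
    rng = _as_rng(seed)
    raw = rng.lognormal(mean=model.loc, sigma=model.scale, size=n)
    return np.maximum(np.rint(raw).astype(int), model.min_len)


def apply_briggs_damage(fragment: str, params: DamageParams | None = None,
                        seed=0) -> tuple[str, list[DamageEvent]]:
    """Apply Briggs-style damage to one fragment (molecule orientation).

    Draws a 5′ and a 3′ single-strand overhang length (geometric, support
    includes 0), deaminates C→T at ``ss_deam`` inside the 5′ overhang and
    G→A at ``ss_deam`` inside the 3′ overhang, C→T at ``ds_deam`` in the
    double-stranded interior, plus a nick-associated ``ss_deam``-rate C→T
    opportunity at interior positions nicked at ``nick_rate``. Length is
    unchanged; non-ACGT characters pass through.
    """
    if not fragment:
        raise ValueError("fragment must be non-empty")
    params = params or DamageParams()
    rng = _as_rng(seed)
    p = params.overhang_param
    # geometric with support {0, 1, ...}; p == 1 means always blunt
    o5 = int(rng.geometric(p)) - 1 if p < 1.0 else 0
    o3 = int(rng.geometric(p)) - 1 if p < 1.0 else 0

    n = len(fragment)
    arr = np.frombuffer(fragment.encode("ascii"), dtype=np.uint8).copy()
    idx = np.arange(n)
    in5 = idx < o5
    in3 = idx >= n - o3
    interior = ~in5 & ~in3
    is_c = arr == ord("C")
    is_g = arr == ord("G")

    u = rng.random(n)
    u_nick = rng.random(n)
    u_nick_deam = rng.random(n)

    ct5 = is_c & in5 & (u < params.ss_deam)
    ga3 = is_g & in3 & (u < params.ss_deam)
    ct_ds = is_c & interior & (u < params.ds_deam)
    ct_nick = (is_c & interior & ~ct_ds
               & (u_nick < params.nick_rate)
               & (u_nick_deam < params.ss_deam))

    events: list[DamageEvent] = []
    for pos in np.flatnonzero(ct5):
        events.append(DamageEvent(int(pos), "C>T", "5p_overhang"))
    for pos in np.flatnonzero(ct_ds):
        events.append(DamageEvent(int(pos), "C>T", "interior"))
    for pos in np.flatnonzero(ct_nick):
        events.append(DamageEvent(int(pos), "C>T", "nick"))
    for pos in np.flatnonzero(ga3):
        events.append(DamageEvent(int(pos), "G>A", "3p_overhang"))
    events.sort(key=lambda e: e.pos)

    arr[ct5 | ct_ds | ct_nick] = ord("T")
    arr[ga3] = ord("A")
    return arr.tobytes().decode("ascii"), events


def terminal_ct_rate(params: DamageParams, position: int = 0) -> float:
    """Analytic C→T deamination probability at a 5′ position (0-based).

    Mixture over the geometric overhang length: the site is single-stranded
    with probability (1−p)^(z+1) (rate ``ss_deam``), otherwise interior
    (rate ds + (1−ds)·nick·ss). Edge effects of the 3′ overhang are ignored
    (valid for fragments much longer than typical overhangs).
    """
    p_ss = (1.0 - params.overhang_param) ** (position + 1)
    interior = params.ds_deam + (1.0 - params.ds_deam) * params.nick_rate * params.ss_deam
    return p_ss * params.ss_deam + (1.0 - p_ss) * interior


def species_panel(microbial_fraction: float, seed=0, genome_length: int = 50_000,
                  n_ancient: int = 18, n_modern: int = 17,
                  abundance_concentration: float = 5.0) -> list[SpeciesSpec]:
    """Build a community of ancient + modern taxa with Dirichlet abundances.

    Abundances sum to ``microbial_fraction``; the host share (1 − fraction)
    is added implicitly by :func:`simulate_sample`. Taxon IDs are synthetic
    (1001... for ancient, 2001... for modern).
    """
    if n_ancient > len(ANCIENT_SPECIES_NAMES) or n_modern > len(MODERN_SPECIES_NAMES):
        raise ValueError("panel larger than the built-in species name lists")
    rng = _as_rng(seed)
    names = list(ANCIENT_SPECIES_NAMES[:n_ancient]) + list(MODERN_SPECIES_NAMES[:n_modern])
    flags = [True] * n_ancient + [False] * n_modern
    taxids = [1001 + i for i in range(n_ancient)] + [2001 + i for i in range(n_modern)]
    ab = rng.dirichlet(np.full(len(names), abundance_concentration))
    ab = ab * microbial_fraction
    return [
        SpeciesSpec(name=nm, taxid=tid, is_ancient=fl,
                    genome_length=genome_length, relative_abundance=float(a))
        for nm, tid, fl, a in zip(names, taxids, flags, ab)
    ]


def default_design(seed: int = 0, n_ancient_fragments: int = 500_000,
                   n_modern_fragments: int = 500_000) -> list[SampleDesign]:
    """The default ten-sample design with microbial fractions
    (0.7, 0.7, 0.7, 0.5, 0.5, 0.5, 0.4, 0.3, 0.3, 0.3)."""
    designs = []
    for i, frac in enumerate(DEFAULT_MICROBIAL_FRACTIONS, start=1):
        designs.append(SampleDesign(
            sample_id=f"sample{i}",
            n_ancient_fragments=n_ancient_fragments,
            n_modern_fragments=n_modern_fragments,
            microbial_fraction=frac,
            seed=seed * 1000 + i,
        ))
    return designs


def build_genomes(species: Sequence[SpeciesSpec], seed: int = 0,
                  host_genome_length: int = 200_000) -> dict[int, str]:
    """Generate one toy genome per taxon (plus host), keyed by taxid.

    Each genome's stream is seeded by (seed, taxid) so the sequences do not
    depend on species ordering.
    """
    genomes: dict[int, str] = {}
    for sp in species:
        ss = np.random.SeedSequence([seed, sp.taxid])
        genomes[sp.taxid] = generate_reference(sp.genome_length, 0.5, np.random.default_rng(ss))
    host_ss = np.random.SeedSequence([seed, HOST_TAXID])
    genomes[HOST_TAXID] = generate_reference(host_genome_length, 0.41,
                                             np.random.default_rng(host_ss))
    return genomes


def _species_substream(design: SampleDesign, taxid: int, pool: int) -> np.random.Generator:
    # hash of (sample_id, taxid) per pool, independent of iteration order
    sid = zlib.crc32(design.sample_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([design.seed, sid, taxid, pool]))


def _add_errors(arr: np.ndarray, error_rate: float, rng: np.random.Generator) -> int:
    """Uniform substitution errors in place; returns the number applied."""
    if error_rate <= 0:
        return 0
    hit = rng.random(arr.size) < error_rate
    n_hit = int(hit.sum())
    if n_hit == 0:
        return 0
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for pos in np.flatnonzero(hit):
        alternatives = bases[bases != arr[pos]]
        arr[pos] = rng.choice(alternatives)
    return n_hit


def _md_tag(ref: str, seq: str) -> tuple[str, int]:
    """MD tag and NM for a substitution-only, full-length alignment."""
    run = 0
    parts: list[str] = []
    nm = 0
    for r, s in zip(ref, seq):
        if r == s:
            run += 1
        else:
            parts.append(str(run))
            parts.append(r)
            run = 0
            nm += 1
    parts.append(str(run))
    return "".join(parts), nm


def _make_read(fragment: str, read_length: int, adapter: str,
               rng: np.random.Generator) -> str:
    """One raw read of exactly read_length bases from the fragment 5′ end,
    with adapter read-through then random fill on short inserts."""
    if len(fragment) >= read_length:
        return fragment[:read_length]
    read = fragment + adapter
    if len(read) < read_length:
        fill = generate_reference(read_length - len(read), 0.5, rng)
        read += fill
    return read[:read_length]


def simulate_sample(design: SampleDesign, species: Sequence[SpeciesSpec],
                    damage: DamageParams | None = None,
                    fraglen: FragmentLengthModel | None = None,
                    modern_fraglen: FragmentLengthModel | None = None,
                    outdir=".", genomes: dict[int, str] | None = None,
                    genome_seed: int = 0) -> SampleResult:
    """Simulate one metagenomic sample: FASTQ read pairs, truth table slice
    and a truth SAM of fragment origins.

    The ancient pool (``n_ancient_fragments``) draws from ancient-flagged
    taxa plus damaged host molecules; the modern pool draws from modern
    taxa plus undamaged, moderately fragmented host molecules. Within each
    pool the host carries weight (1 − microbial_fraction) and the pool's
    taxa their configured abundances. Fully reproducible under the design
    seed.
    """
    damage = damage or DamageParams()
    fraglen = fraglen or FragmentLengthModel()
    modern_fraglen = modern_fraglen or MODERN_FRAGLEN

    ab_sum = sum(sp.relative_abundance for sp in species)
    if abs(ab_sum - design.microbial_fraction) > 1e-6:
        raise ValueError(
            f"species abundances sum to {ab_sum:.6f}, expected the design's "
            f"microbial_fraction {design.microbial_fraction:.6f}"
        )
    if genomes is None:
        genomes = build_genomes(species, seed=genome_seed)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    r1_path = outdir / f"{design.sample_id}_R1.fastq"
    r2_path = (outdir / f"{design.sample_id}_R2.fastq") if design.paired else None
    sam_path = outdir / f"{design.sample_id}_truth.sam"

    master = np.random.default_rng(np.random.SeedSequence([design.seed]))

    ancient_taxa = sorted((sp for sp in species if sp.is_ancient), key=lambda s: s.taxid)
    modern_taxa = sorted((sp for sp in species if not sp.is_ancient), key=lambda s: s.taxid)
    host_weight = 1.0 - design.microbial_fraction

    def _pool_counts(taxa, n_total):
        weights = np.array([host_weight] + [sp.relative_abundance for sp in taxa])
        if weights.sum() == 0:
            weights = np.ones_like(weights)
        return master.multinomial(n_total, weights / weights.sum())

    counts_anc = _pool_counts(ancient_taxa, design.n_ancient_fragments)
    counts_mod = _pool_counts(modern_taxa, design.n_modern_fragments)

    # SAM header: @SQ for every genome, sorted by taxid for determinism
    taxid_order = sorted(genomes)
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": f"taxid|{tid}", "LN": len(genomes[tid])} for tid in taxid_order],
    })
    tid_index = {tid: i for i, tid in enumerate(taxid_order)}

    truth_rows = []
    qual = "I" * design.read_length

    with open(r1_path, "w") as fq1, \
         (open(r2_path, "w") if r2_path else _null_writer()) as fq2, \
         pysam.AlignmentFile(sam_path, "w", header=header) as sam:

        def _emit_species(sp_name, taxid, count, is_ancient_pool, damaged, flm):
            genome = genomes[taxid]
            glen = len(genome)
            rng = _species_substream(design, taxid, pool=int(is_ancient_pool))
            lengths = sample_fragment_lengths(count, flm, rng)
            np.minimum(lengths, glen, out=lengths)
            for i in range(count):
                flen = int(lengths[i])
                start = int(rng.integers(0, glen - flen + 1))
                minus = bool(rng.random() < 0.5)
                slab = genome[start:start + flen]
                frag = revcomp(slab) if minus else slab
                if damaged:
                    frag, _ = apply_briggs_damage(frag, damage, rng)
                arr = np.frombuffer(frag.encode("ascii"), dtype=np.uint8).copy()
                _add_errors(arr, design.error_rate, rng)
                frag = arr.tobytes().decode("ascii")

                ref_oriented = revcomp(frag) if minus else frag
                md, nm = _md_tag(slab, ref_oriented)

                qname = f"{design.sample_id}|{taxid}|{'a' if is_ancient_pool else 'm'}{i}"
                seg = pysam.AlignedSegment(header)
                seg.query_name = qname
                seg.flag = 16 if minus else 0
                seg.reference_id = tid_index[taxid]
                seg.reference_start = start
                seg.mapping_quality = 60
                seg.cigarstring = f"{flen}M"
                seg.query_sequence = ref_oriented
                seg.query_qualities = pysam.qualitystring_to_array("I" * flen)
                seg.set_tag("NM", nm)
                seg.set_tag("MD", md)
                sam.write(seg)

                r1 = _make_read(frag, design.read_length, design.adapter_seq, rng)
                fq1.write(f"@{qname}/1\n{r1}\n+\n{qual}\n")
                if design.paired:
                    r2 = _make_read(revcomp(frag), design.read_length,
                                    design.adapter_seq, rng)
                    fq2.write(f"@{qname}/2\n{r2}\n+\n{qual}\n")

        # ancient pool: host first (damaged), then ancient taxa
        _emit_species(HOST_NAME, HOST_TAXID, int(counts_anc[0]), True, True, fraglen)
        truth_rows.append((design.sample_id, HOST_TAXID, HOST_NAME, True,
                           int(counts_anc[0])))
        for sp, cnt in zip(ancient_taxa, counts_anc[1:]):
            _emit_species(sp.name, sp.taxid, int(cnt), True, True, fraglen)
            truth_rows.append((design.sample_id, sp.taxid, sp.name, True, int(cnt)))

        # modern pool: undamaged host and contaminants
        _emit_species(HOST_NAME, HOST_TAXID, int(counts_mod[0]), False, False,
                      modern_fraglen)
        truth_rows.append((design.sample_id, HOST_TAXID, HOST_NAME, False,
                           int(counts_mod[0])))
        for sp, cnt in zip(modern_taxa, counts_mod[1:]):
            _emit_species(sp.name, sp.taxid, int(cnt), False, False, modern_fraglen)
            truth_rows.append((design.sample_id, sp.taxid, sp.name, False, int(cnt)))

    truth = GroundTruth(pd.DataFrame(truth_rows, columns=list(GroundTruth.COLUMNS)))
    return SampleResult(fastq_r1=r1_path, fastq_r2=r2_path, truth_sam=sam_path,
                        truth=truth)


class _null_writer:
    """Context manager standing in for the absent R2 file in single-end mode."""

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        return False

    def write(self, _):
        pass
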