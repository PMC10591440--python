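import numpy as np
import pytest

from paleometa.authmetrics import (AlignmentRecord, AuthMetrics,
                                   CoverageProfile, DeaminationProfile)


def make_alignment(pos, read_seq, ref_seq=None, strand="+", nm=None,
                   read_id="r", ref_id="ref", mapq=60):
    """Alignment with mismatches derived from the ref/read base columns."""
    if ref_seq is None:
        ref_seq = read_seq
    if nm is None:
        nm = sum(1 for a, b in zip(ref_seq, read_seq) if a != b)
    mismatches = [(i, a, b) for i, (a, b) in enumerate(zip(ref_seq, read_seq))
                  if a != b]
    return AlignmentRecord(read_id=read_id, ref_id=ref_id, pos=pos,
                           strand=strand, read_seq=read_seq,
                           edit_distance=nm, mapq=mapq, ref_seq=ref_seq,
                           mismatches=mismatches)


def _deam_profile(terminal, window=15, n_sites=300, interior=0.01):
    rate = np.full(window, interior)
    rate[0] = terminal
    rate[1] = terminal / 2
    rate[2] = terminal / 4
    n = np.full(window, n_sites, dtype=int)
    return DeaminationProfile(p5_ct=rate.copy(), p3_ga=rate.copy(),
                              n5_informative=n.copy(), n3_informative=n.copy())


def _coverage(depth=2.0, breadth=0.9, nonzero_frac=1.0, n_bins=100):
    bins = np.zeros(n_bins)
    k = int(round(nonzero_frac * n_bins))
    bins[:k] = breadth / max(nonzero_frac, 1e-9) if k else 0.0
    np.clip(bins, 0, 1, out=bins)
    return CoverageProfile(depth_mean=depth, breadth=breadth,
                           bin_breadth=bins,
                           bin_sizes=np.full(n_bins, 500, dtype=int))


def all_pass_metrics():
    """Synthetic panel satisfying every default score criterion."""
    edit_all = np.array([520, 300, 120, 40, 15, 5, 0, 0, 0, 0, 0])
    edit_damaged = np.array([120, 60, 25, 8, 2, 0, 0, 0, 0, 0, 0])
    return AuthMetrics(
        deamination=_deam_profile(terminal=0.20),
        coverage=_coverage(depth=2.0, breadth=0.9, nonzero_frac=1.0),
        edit_all=edit_all,
        edit_damaged=edit_damaged,
        read_lengths=np.full(1000, 45, dtype=int),
        pmd_scores=np.concatenate([np.full(300, 6.0), np.full(700, -1.0)]),
        n_assigned=1000,
        identity_hist=np.array([0, 0, 40, 960]),
        ani_mean=98.5,
    )


def all_fail_metrics():
    """Synthetic panel failing every default score criterion."""
    edit_all = np.array([5, 20, 70, 40, 10, 5, 0, 0, 0, 0, 0])  # mode at 2
    return AuthMetrics(
        deamination=_deam_profile(terminal=0.0, interior=0.0),
        coverage=_coverage(depth=2.0, breadth=0.1, nonzero_frac=0.1),
        edit_all=edit_all,
        edit_damaged=np.zeros(11, dtype=int),
        read_lengths=np.full(150, 160, dtype=int),
        pmd_scores=np.full(150, -2.0),
        n_assigned=150,
        identity_hist=np.array([150, 0, 0, 0]),
        ani_mean=84.0,
    )


def evenness_only_metrics():
    """Only the evenness-of-coverage criterion passes."""
    m = all_fail_metrics()
    m.coverage = _coverage(depth=2.0, breadth=0.9, nonzero_frac=1.0)
    return m


@pytest.fixture(scope="session")
def small_sample(tmp_path_factory):
    """One simulated sample shared across tests: 5 ancient + 5 modern taxa,
    2,000 + 2,000 fragments, full microbial content."""
    from paleometa import simdata as sd

    outdir = tmp_path_factory.mktemp("smallsim")
    design = sd.SampleDesign(sample_id="s1", n_ancient_fragments=2000,
                             n_modern_fragments=2000, microbial_fraction=1.0,
                             seed=11)
    species = sd.species_panel(1.0, seed=1, genome_length=50_000,
                               n_ancient=5, n_modern=5)
    genomes = sd.build_genomes(species, seed=0)
    result = sd.simulate_sample(design, species, outdir=outdir, genomes=genomes)
    return design, species, genomes, result
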