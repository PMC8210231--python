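import numpy as np
import pytest

from ncrm.core import GenomicInterval, SomaticMutation
from ncrm.simulate import CohortConfig, generate_cohort


def make_mutation(
    chrom="chr1",
    pos=100,
    ref="C",
    alt="T",
    sample_id="S1",
    individual_id=None,
    cancer_type="BRCA",
    tissue_site="breast",
    somatic_confirmed=True,
    snp_flagged=False,
):
    return SomaticMutation(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        sample_id=sample_id,
        individual_id=individual_id if individual_id is not None else f"I_{sample_id}",
        cancer_type=cancer_type,
        tissue_site=tissue_site,
        somatic_confirmed=somatic_confirmed,
        snp_flagged=snp_flagged,
    )


def random_mutations(rng, n, chroms=("chr1", "chr2"), max_pos=10_000, n_samples=12,
                     cancer_types=("BRCA", "LUAD", "COAD")):
    bases = "ACGT"
    out = []
    for _ in range(n):
        ref = bases[rng.integers(0, 4)]
        alt = [b for b in bases if b != ref][rng.integers(0, 3)]
        sample = f"S{int(rng.integers(0, n_samples)):03d}"
        out.append(
            make_mutation(
                chrom=chroms[rng.integers(0, len(chroms))],
                pos=int(rng.integers(1, max_pos + 1)),
                ref=ref,
                alt=alt,
                sample_id=sample,
                cancer_type=cancer_types[rng.integers(0, len(cancer_types))],
            )
        )
    return out


def brute_force_containing(intervals, chrom, pos):
    """O(n) reference for 1-based point containment in half-open intervals."""
    return [
        iv for iv in intervals if iv.chrom == chrom and iv.start <= pos - 1 < iv.end
    ]


@pytest.fixture(scope="session")
def bundle():
    """One seeded synthetic cohort shared by read-only tests."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)
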