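import numpy as np
import pytest

from epihybrid.datamodel import CountMatrix, Locus, SampleInfo


def make_counts(counts, groups, library_sizes=None, sites=None):
    """Build a small CountMatrix from a 2-D array and per-sample group labels."""
    counts = np.asarray(counts)
    n_loci, n_samples = counts.shape
    if library_sizes is None:
        library_sizes = [1_000_000] * n_samples
    if sites is None:
        sites = ["GUA"] * n_samples
    tally: dict[str, int] = {}
    samples = []
    for g, lib, site in zip(groups, library_sizes, sites):
        tally[g] = tally.get(g, 0) + 1
        samples.append(
            SampleInfo(sample_id=f"{g}_{tally[g]}", group=g, site=site, library_size=int(lib))
        )
    loci = [Locus(scaffold="sc1", position=100 * (i + 1), strand="+") for i in range(n_loci)]
    return CountMatrix(loci=loci, samples=samples, counts=counts)


@pytest.fixture
def toy_matrix():
    """3 loci x 4 samples, two groups, equal library sizes."""
    return make_counts(
        [[10, 12, 50, 55], [0, 0, 0, 0], [5, 5, 5, 5]],
        groups=["parent1", "parent1", "parent2", "parent2"],
    )
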