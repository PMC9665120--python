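"""Shared simulator for pairwise-distance mixed-model recovery checks."""

import numpy as np
from skbio import DistanceMatrix

from epihybrid.datamodel import SampleInfo
from epihybrid.distances import euclidean_distances


def simulate_mlpe_dataset(seed, n=30, slope=0.5, id_sd=0.2, resid_sd=0.1):
    """Pairwise epigenetic distances generated from the MLPE model itself."""
    rng = np.random.default_rng(seed)
    ids = [f"i{k}" for k in range(n)]
    gen = euclidean_distances(rng.normal(size=(n, 2)), ids)
    a = rng.normal(0, id_sd, n)
    epi = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            epi[i, j] = epi[j, i] = abs(
                1.0 + slope * gen.data[i, j] + a[i] + a[j] + rng.normal(0, resid_sd)
            )
    groups = ["parent1", "parent2", "hybrid"]
    sinfo = [
        SampleInfo(ids[k], groups[k % 3], ["GUA", "FUN"][k % 2], 1_000_000)
        for k in range(n)
    ]
    return DistanceMatrix(epi, ids), gen, sinfo
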