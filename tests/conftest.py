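"""Shared fixtures: small simulated references, cohorts and libraries.

Everything is generated programmatically with fixed seeds; session scope
keeps the more expensive simulations to one run each.
"""

import numpy as np
import pytest

from mescan import demux, mapping, simulate

INDEXES = {"S1": "ACCAT", "S2": "TATTC", "S3": "GGTTA", "S4": "CGCTA"}
EQUAL_PROPS = {s: 0.25 for s in INDEXES}


@pytest.fixture(scope="session")
def small_ref():
    """50 kb reference: 6 targets, 2 decoys, 1 duplicated block."""
    return simulate.make_reference(
        {"chrA": 50_000}, n_target=6, n_decoy=2, n_duplications=1, seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_ref):
    return simulate.simulate_cohort(
        small_ref, 4, fixed_fraction=0.5, allele_freq_spec=0.5, n_novel=2, seed=12,
        individuals=list(INDEXES),
    )


@pytest.fixture(scope="session")
def small_library(small_ref, small_cohort):
    design = simulate.LibraryDesign(
        indexes=INDEXES,
        proportions=EQUAL_PROPS,
        total_read_pairs=3000,
        dispersion=10.0,
        error_rate=0.004,
        decoy_mean_pairs=4.0,
        seed=13,
    )
    return design, simulate.simulate_library(small_ref, small_cohort, design)


@pytest.fixture(scope="session")
def small_index(small_ref):
    return mapping.GenomeIndex(small_ref.sequences)


@pytest.fixture(scope="session")
def small_demux(small_library):
    design, lib = small_library
    pairs = (
        demux.ReadPairRecord(j[0], j[1], f[1], j[2], f[2])
        for j, f in zip(lib.junction_reads, lib.flank_reads)
    )
    return demux.demux_stream(pairs, {v: k for k, v in design.indexes.items()})


@pytest.fixture(scope="session")
def small_endpoints(small_demux, small_index):
    """Accepted pair endpoints from the small library, with rejection reasons."""
    from mescan import loci

    endpoints = []
    rejects = []
    for sample, recs in small_demux.by_sample.items():
        for rec in recs:
            res = mapping.dual_map(rec.junction_seq, rec.flank_seq, small_index, pair_id=rec.pair_id)
            if res.accepted is None:
                rejects.append((rec.pair_id, res.reason))
            else:
                endpoints.append(loci.junction_endpoint(res.accepted, sample))
    return endpoints, rejects


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
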