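from __future__ import annotations

import pytest

from trscout.params import Parameters
from trscout.simulate import SimParams, make_experiment


@pytest.fixture()
def params() -> Parameters:
    return Parameters()


SMALL_LOCI = [
    ("chr4", "HTT", "CAG", 57),
    ("chrX", "FMR1", "CGG", 60),
    ("chr21", "CSTB", "CGCGGGGCGGGG", 36),
]


@pytest.fixture(scope="session")
def small_het_bundle(tmp_path_factory):
    """Three-locus heterozygous sample (reference + 400 bp allele, ~24X),
    small enough to simulate once and reuse across tests."""
    outdir = tmp_path_factory.mktemp("small_het")
    sim = SimParams(flank_len=6000, depth=24.0, read_len_median=4000)
    return make_experiment("het17", str(outdir), seed=11, sim=sim,
                           allele_size=400, loci_spec=SMALL_LOCI)


@pytest.fixture(scope="session")
def clean_het_bundle(tmp_path_factory):
    """Error-free version of the small sample (exact round trips)."""
    outdir = tmp_path_factory.mktemp("clean_het")
    sim = SimParams(flank_len=6000, depth=15.0, read_len_median=4000,
                    sub_rate=0.0, ins_rate=0.0, del_rate=0.0)
    return make_experiment("het17", str(outdir), seed=12, sim=sim,
                           allele_size=400, loci_spec=SMALL_LOCI)
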