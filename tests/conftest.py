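import numpy as np
import pytest

from bsqc.records import MethylRecord, ReferenceSequence, TargetRegion
from bsqc.simulate import SimulationSpec, generate_methyl_table, generate_reference

SEED = 20131


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def sim_spec():
    return SimulationSpec(seed=SEED)


@pytest.fixture(scope="session")
def sim_reference(sim_spec):
    return generate_reference(sim_spec)


@pytest.fixture(scope="session")
def sim_table(sim_spec, sim_reference):
    """(records, ground_truth) for the session-wide synthetic dataset."""
    rng = np.random.default_rng(SEED)
    return generate_methyl_table(sim_reference, sim_spec, rng)


def make_record(pos=0, context="CHH", coverage=1, ratio=0.0, chrom="chr1", strand="+"):
    return MethylRecord(
        chrom=chrom,
        pos=pos,
        strand=strand,
        context=context,
        coverage=coverage,
        methyl_ratio=ratio if coverage else None,
    )


def random_records(rng, n_sites, chrom="chr1", span=10_000):
    """n_sites random cytosine records at distinct positions."""
    positions = rng.choice(span, size=n_sites, replace=False)
    records = []
    for pos in sorted(int(p) for p in positions):
        context = ("CG", "CHG", "CHH")[rng.integers(3)]
        covered = rng.random() < 0.6
        cov = int(rng.integers(1, 30)) if covered else 0
        ratio = float(rng.random()) if covered else None
        records.append(
            MethylRecord(chrom, pos, "+-"[rng.integers(2)], context, cov, ratio)
        )
    return records
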