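import math

import numpy as np
import pytest

from mutspect.filtering import VariantRecord
from mutspect.pipeline import RunConfig, analyze_cohort
from mutspect.simulate import MutationSpectrum, SimulationConfig

STRAINS = tuple(f"s{i}" for i in range(4))


def make_record(
    chrom="chr1", pos=100, ref="A", alt="G", qual=100.0, mq=60.0,
    strains=STRAINS, carriers=(0,), gq=99.0, dp=50.0, alt_frac=0.5, **kwargs,
) -> VariantRecord:
    """A hand-built variant record with idealised metrics unless overridden."""
    n = len(strains)
    gt = np.zeros(n, dtype=bool)
    gt[list(carriers)] = True
    dp_arr = np.full(n, float(dp))
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, qual=qual, mq=mq,
        strains=strains, gt=gt, gq=np.full(n, float(gq)), dp=dp_arr,
        alt_reads=np.where(gt, alt_frac * dp_arr, 0.0), **kwargs,
    )


@pytest.fixture(scope="session")
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def small_sim_config() -> SimulationConfig:
    """A small, fast population: two chromosomes, moderate mutational input."""
    return SimulationConfig(
        n_strains=10,
        chromosome_lengths=(60_000, 40_000),
        mutations_per_kb_total_depth=12.0,
        indel_rate_relative=0.15,
        seed=11,
    )


@pytest.fixture(scope="session")
def neutral_cohort(small_sim_config):
    """Small cohort simulated without selection (balanced 50% GC genome)."""
    sim = SimulationConfig(
        n_strains=10,
        chromosome_lengths=(60_000, 40_000),
        gc_content=0.50,
        mutations_per_kb_total_depth=60.0,
        indel_rate_relative=0.1,
        selection_halflife=math.inf,
        indel_selection_halflife=math.inf,
        seed=7,
    )
    return analyze_cohort(RunConfig(simulation=sim, n_boot=50))


@pytest.fixture(scope="session")
def selected_cohort(small_sim_config):
    """Small cohort with the default age-dependent purifying selection."""
    return analyze_cohort(RunConfig(simulation=small_sim_config, n_boot=50))


@pytest.fixture(scope="session")
def ma_spectrum() -> MutationSpectrum:
    return MutationSpectrum.ma_reference()
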