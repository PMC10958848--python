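import numpy as np
import pytest

from replicall import (
    CallAttributes,
    CallSet,
    Provenance,
    StudyConfig,
    VariantKey,
    simulate_study,
)
from replicall.simulate import CallerModel, CenterProfile


def vk(pos, chrom="chr1", ref="A", alt="C"):
    return VariantKey(chrom, pos, ref, alt)


def make_callset(positions, chrom="chr1", center="FD", replicate=1,
                 mapper="bwa", caller="mutect", attrs=None):
    keys = frozenset(vk(p, chrom=chrom) for p in positions)
    return CallSet(
        keys=keys,
        attrs=attrs or {},
        provenance=Provenance(center, replicate, mapper, caller),
    )


def random_callset(rng, n_keys, universe=500, **prov):
    positions = rng.choice(universe, size=min(n_keys, universe), replace=False)
    return make_callset((int(p) + 1 for p in positions), **prov)


@pytest.fixture
def rng():
    return np.random.default_rng(20240322)


def small_config(seed=0, **kw):
    """A scaled-down study for fast unit tests: 2 centers x 3 and 2
    replicates, one mapper, two callers."""
    defaults = dict(
        n_truth=150,
        chroms=tuple(f"chr{i}" for i in range(1, 7)),
        targets_per_chrom=50,
        target_length=500,
        target_spacing=2000,
        centers=(
            CenterProfile("AA", (60.0, 70.0, 65.0), center_artifact_sites=20),
            CenterProfile("BB", (90.0, 85.0), center_artifact_sites=15),
        ),
        mappers={"bwa": 1.0},
        callers={
            "mutect": CallerModel(slope=0.18, intercept=-0.3,
                                  private_fp_rate=25.0, shared_artifact_sites=10),
            "ss": CallerModel(slope=0.12, intercept=-0.5,
                              private_fp_rate=60.0, shared_artifact_sites=25),
        },
        seed=seed,
    )
    defaults.update(kw)
    return StudyConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_study(small_config(seed=7))


@pytest.fixture(scope="session")
def default_bundle():
    """One full-default study, shared across tests that need realism."""
    return simulate_study(StudyConfig(seed=11))


def attrs_for(keys, vaf=0.3, qual=30.0):
    return {k: CallAttributes(qual=qual, vaf=vaf, tumor_depth=50, normal_depth=48)
            for k in keys}
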