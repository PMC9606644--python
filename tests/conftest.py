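import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tsmr.gwas_io import AssociationSet, SummaryRecord
from tsmr.harmonize import HarmonizedDataset, harmonize

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_record(snp_id="rs1", chrom="1", pos=1000, ea="A", oa="G",
                beta=0.1, se=0.01, pval=1e-9, eaf=0.3, n=10000.0, trait="x"):
    return SummaryRecord(snp_id, chrom, pos, ea, oa, beta, se, pval, eaf, n, trait)


def make_set(records, role="exposure", trait_name="x"):
    return AssociationSet(tuple(records), role=role, trait_name=trait_name)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_dataset(rng):
    """20 harmonized pairs consistent with a causal effect of 0.25."""
    n = 20
    bx = rng.normal(0.08, 0.02, n)
    sx = np.full(n, 0.004)
    sy = rng.uniform(0.008, 0.02, n)
    by = 0.25 * bx + rng.normal(0, sy)
    return HarmonizedDataset.from_arrays(bx, sx, by, sy)


def dataset_from_arrays(bx, sx, by, sy):
    return HarmonizedDataset.from_arrays(
        np.asarray(bx, float), np.asarray(sx, float),
        np.asarray(by, float), np.asarray(sy, float),
    )


def simulate_harmonized(cfg, min_f=None):
    """Generate one study and harmonize it.

    Estimator-property tests run on the full generated panel so the
    panel's constructed properties (instrument count, strength, invalid
    fraction) are exactly the stated study conditions; pass ``min_f`` to
    interpose the weak-instrument filter instead.
    """
    from tsmr.instruments import filter_by_f
    from tsmr.simulate import simulate_two_sample

    exposure, outcome, truth = simulate_two_sample(cfg)
    instruments = exposure if min_f is None else filter_by_f(exposure, min_f)
    return harmonize(instruments, outcome), truth
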