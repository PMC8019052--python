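import numpy as np
import pytest

from charpop import simdata


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study shared across read-only tests."""
    cfg = simdata.default_config(seed=42, n_loci=2000)
    return simdata.simulate_study(cfg)


@pytest.fixture(scope="session")
def two_deme_cfg():
    """Flat two-deme design at F = 0.2 (one lake per group, no nesting)."""

    def make(seed, n_loci=2000, n=50, fst=0.2, missing=0.0, sex_loci=False):
        kwargs = {}
        if not sex_loci:
            kwargs = {"n_sex_loci_xy": 0, "n_sex_loci_female_only": 0}
        return simdata.default_config(
            seed=seed,
            n_loci=n_loci,
            fst_between_groups=fst,
            fst_within_group=0.0,
            missing_rate=missing,
            lakes=(
                simdata.LakeSpec("A", "G1", n, ((300, 30, 1.0),)),
                simdata.LakeSpec("B", "G2", n, ((300, 30, 1.0),)),
            ),
            **kwargs,
        )

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(0)
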