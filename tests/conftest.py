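import numpy as np
import pytest

import morphoerror as me


@pytest.fixture(scope="session")
def panel():
    return me.DEFAULT_PANEL


@pytest.fixture(scope="session")
def replica():
    """Default replica-design dataset (20 individuals x 3 operators) + truth."""
    return me.generate_replica_study(me.replica_spec(seed=11))


@pytest.fixture(scope="session")
def replica_fit(replica):
    ds, _ = replica
    return me.gpa_align(ds)


@pytest.fixture(scope="session")
def zero_noise_replica(panel):
    """Replica design with no digitizing noise and no operator bias."""
    spec = me.replica_spec(
        seed=5,
        noise_sd_bone=0.0,
        noise_sd_soft=0.0,
        operator_bias={op: np.zeros((15, 3)) for op in ("OP1", "OP2", "OP3")},
    )
    return me.generate_replica_study(spec)


@pytest.fixture(scope="session")
def small_study():
    """Scaled-down partition-design sample (~1/4 of the full cell counts)."""
    counts = {
        ("OP1", "F"): 26, ("OP1", "M"): 15,
        ("OP2", "F"): 27, ("OP2", "M"): 41,
        ("OP3", "F"): 63, ("OP3", "M"): 56,
    }
    spec = me.study_spec(
        seed=3, sex_counts=counts, n_individuals=sum(counts.values())
    )
    return me.generate_study_sample(spec)


def rigid_motion(coords, rng, scale=False):
    """Random rotation + translation (+ optional positive scaling) of (p,3)."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    s = rng.uniform(0.5, 2.0) if scale else 1.0
    t = rng.normal(scale=50.0, size=3)
    return s * coords @ q + t
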