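import numpy as np
import pytest

from rhizofit import AttachmentDecomposition, reference
from rhizofit.data import NormalizedSeries
from rhizofit.models import logistic_density
from rhizofit.simulate import TreatmentSpec, default_design


@pytest.fixture(scope="session")
def colonization():
    """Published logistic parameters of the total-colonization fit."""
    return reference.TOTAL_COLONIZATION


@pytest.fixture(scope="session")
def mu_p():
    """Published proliferation-only rate constant (h^-1)."""
    return reference.PROLIFERATION.mu


@pytest.fixture(scope="session")
def decomp(colonization, mu_p):
    return AttachmentDecomposition(colonization, mu_p)


@pytest.fixture()
def make_series():
    def _make(times, values, kind="normalized_density", treatment=""):
        return NormalizedSeries(np.asarray(times, float), np.asarray(values, float),
                                kind, treatment)

    return _make


@pytest.fixture()
def noiseless_design():
    """Factory for a fully deterministic design (no noise anywhere, including
    the per-treatment suspension noise overrides)."""
    import dataclasses

    def _make(seed=0, replicates=5, **overrides):
        base = default_design(seed=seed)
        treatments = overrides.pop(
            "treatments",
            {k: dataclasses.replace(v, noise_sd=None) for k, v in base.treatments.items()},
        )
        treatments = {k: dataclasses.replace(v, noise_sd=None) for k, v in treatments.items()}
        return default_design(
            seed=seed, replicates=replicates, noise_sd=0.0,
            inoculant_cv=0.0, root_weight_cv=0.0, treatments=treatments, **overrides,
        )

    return _make


@pytest.fixture()
def replicated_logistic_series(colonization, make_series):
    """Exact logistic responses replicated 5x at the colonization timepoints."""
    from rhizofit.simulate import TOTAL_TIMEPOINTS

    t = np.repeat(np.asarray(TOTAL_TIMEPOINTS), 5)
    return make_series(t, logistic_density(colonization, t))


@pytest.fixture()
def dense_total_design(noiseless_design):
    """Noiseless total-colonization design sampled every 2 h (no gaps), for
    spline checks where unsupported gaps would dominate the error."""
    dense = tuple(float(t) for t in range(2, 97, 2))
    base = noiseless_design()
    treatments = dict(base.treatments)
    treatments["total"] = TreatmentSpec(
        "logistic", reference.TOTAL_COLONIZATION, dense, "normalized_density"
    )
    return noiseless_design(treatments=treatments)
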