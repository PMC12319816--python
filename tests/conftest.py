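import numpy as np
import pytest

from amyconn import clustering, endpoints, phantom


@pytest.fixture(scope="session")
def two_group_spec():
    return phantom.preset("two_group", seed=11)


@pytest.fixture(scope="session")
def two_group_data(two_group_spec):
    """Phantom labels, endpoint maps, reference region, fitted null, and profiles."""
    labels, table = phantom.make_phantom_labels(two_group_spec)
    maps = phantom.simulate_endpoint_maps(labels, two_group_spec)
    pre = endpoints.profile_maps(maps, labels)
    reference = endpoints.select_reference_region(pre)
    lam = endpoints.fit_poisson_rate(
        endpoints.pooled_reference_counts(maps, labels, reference)
    )
    null = endpoints.build_null(lam, n_draws=100_000, alpha=0.05, seed=12)
    profiles = endpoints.profile_maps(maps, labels, null)
    return {
        "spec": two_group_spec,
        "labels": labels,
        "table": table,
        "maps": maps,
        "reference": reference,
        "null": null,
        "profiles": profiles,
    }


@pytest.fixture(scope="session")
def two_group_features(two_group_data):
    feats, names, cols = clustering.build_feature_matrix(two_group_data["profiles"])
    return feats, names, cols
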