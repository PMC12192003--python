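import pytest

from ipdrep import make_distribution

# every built-in society composition, with the exponential case at its
# default slope a=5
BUILTIN_SPECS = [
    ("uniform", {}),
    ("linear_increasing", {}),
    ("linear_decreasing", {}),
    ("exp_decreasing", {"a": 5.0}),
    ("hump", {}),
    ("ushape", {}),
]


@pytest.fixture(params=BUILTIN_SPECS, ids=lambda s: s[0])
def builtin_dist(request):
    name, params = request.param
    return make_distribution(name, **params)


@pytest.fixture
def all_builtin_dists():
    return [make_distribution(name, **params) for name, params in BUILTIN_SPECS]
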