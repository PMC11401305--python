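import numpy as np
import pytest

from bubbletree.synthetic import MixtureSpec, make_gaussian_mixture


@pytest.fixture(scope="session")
def blobs5():
    """Five well-separated isotropic blobs (10 sd apart), n=500, f=2."""
    means = np.array(
        [[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [10.0, 10.0], [5.0, 18.0]]
    )
    spec = MixtureSpec(sizes=[100] * 5, means=means, sd=1.0, seed=7)
    emb, attrs = make_gaussian_mixture(spec)
    return emb, attrs.data["label"]


@pytest.fixture(scope="session")
def blobs2():
    spec = MixtureSpec(sizes=[60, 40], means=[[0.0, 0.0], [12.0, 0.0]],
                       sd=1.0, seed=3)
    emb, attrs = make_gaussian_mixture(spec)
    return emb, attrs.data["label"]
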