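import numpy as np
import pytest

from mbcc import (
    DictionaryModel,
    class_support_masks,
    make_synthetic,
    normalize_atoms,
    separable_model_config,
    separable_preset,
)


@pytest.fixture(scope="session")
def preset_data():
    """Canonical well-separated synthetic benchmark (train, test, truth)."""
    return make_synthetic(separable_preset(seed=1))


@pytest.fixture(scope="session")
def preset_config():
    return separable_model_config(seed=1)


@pytest.fixture(scope="session")
def trained_model(preset_data, preset_config):
    from mbcc import fit_mbcc

    train, _, _ = preset_data
    return fit_mbcc(train, preset_config)


@pytest.fixture
def small_instance():
    """A random small coding/scatter instance shared by gradient tests."""
    rng = np.random.default_rng(42)
    d, Kc, M, C, n, p = 6, 3, 2, 2, 10, 4
    D = normalize_atoms(rng.standard_normal((d, C * Kc)))
    dic = DictionaryModel(D=D, class_offsets=np.arange(C + 1) * Kc)
    labels = np.array([1, 2] * (n // 2))
    delta, xi = class_support_masks(labels, dic)
    Z = [rng.standard_normal((d, n)) for _ in range(M)]
    A = [rng.standard_normal((C * Kc, n)) for _ in range(M)]
    G = [np.linalg.qr(rng.standard_normal((d, p)))[0] for _ in range(M)]
    return dict(dic=dic, labels=labels, delta=delta, xi=xi, Z=Z, A=A, G=G)
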