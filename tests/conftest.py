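import numpy as np
import pytest

from bmseg import PhantomSpec, easy_phantom_spec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One phantom at the default study conditions (64^3, 5 lesions)."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def easy_phantom():
    """One high-contrast low-noise phantom (3 lesions)."""
    return generate_phantom(easy_phantom_spec(seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def flood_fill_label(mask: np.ndarray, connectivity: int = 26):
    """Independent brute-force connected-components oracle (BFS)."""
    mask = np.asarray(mask).astype(bool)
    if connectivity == 26:
        offsets = [
            (i, j, k)
            for i in (-1, 0, 1)
            for j in (-1, 0, 1)
            for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
        ]
    else:
        offsets = [
            (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)
        ]
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            v = stack.pop()
            for off in offsets:
                w = tuple(a + o for a, o in zip(v, off))
                if all(0 <= x < s for x, s in zip(w, mask.shape)):
                    if mask[w] and not labels[w]:
                        labels[w] = current
                        stack.append(w)
    return labels, current
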