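import numpy as np
import pytest

from ageperf import IMAPShape


@pytest.fixture
def shape_100m() -> IMAPShape:
    """Published sprint-speed shape with a physical amplitude (~10 m/s)."""
    return IMAPShape(alpha0_star=34.26, alphar_star=21.40, betar_star=2.19,
                     td=124.13, scale_inf=10.0)


def random_interior_shapes(rng: np.random.Generator, n: int) -> list[IMAPShape]:
    """Random shapes guaranteed to have an interior performance peak.

    An interior maximum of the reduced curve exists iff the growth pull at
    birth exceeds the senescence drag there:
    alpha0* > betar* / (e^{betar*} - 1).  Rejection sampling over ranges
    spanning the published series (alpha0*/alphar* kept below ~50 so the
    asymptotic amplitude stays representable).
    """
    shapes: list[IMAPShape] = []
    while len(shapes) < n:
        a0s = rng.uniform(1.0, 500.0)
        ars = rng.uniform(2.0, 100.0)
        brs = rng.uniform(0.05, 20.0)
        td = rng.uniform(2.0, 200.0)
        if a0s / ars > 50.0:
            continue
        if a0s <= brs / np.expm1(brs):
            continue
        shapes.append(IMAPShape(a0s, ars, brs, td, scale_inf=rng.uniform(0.5, 50.0)))
    return shapes
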