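import numpy as np
import pytest

from fracvent import DerivativeSpec, VentParams
from fracvent.local_calculus import Family, truncated_mittag_leffler

# alpha / beta grids matching the shipped figure settings
ALPHA_GRID = (0.25, 0.45, 0.65, 0.7, 0.8, 0.9, 0.95, 1.0)
BETA_GRID = (0.5, 0.8, 1.0, 1.2, 1.5)


@pytest.fixture
def params():
    return VentParams()


def figure_specs():
    """Every (family, alpha, beta) combination of the figure grids."""
    specs = [DerivativeSpec(family=Family.CLASSICAL)]
    for a in ALPHA_GRID:
        specs.append(DerivativeSpec(family=Family.PROPORTIONAL, alpha=a))
        specs.append(DerivativeSpec(family=Family.CONFORMABLE, alpha=a))
        for b in BETA_GRID:
            specs.append(DerivativeSpec(family=Family.TRUNCATED_M, alpha=a, beta=b))
    return specs


def limit_quotient(f, spec, t, levels=8, eps0=1e-3):
    """Richardson-extrapolated epsilon-limit quotient of the local derivatives.

    Independent oracle: evaluates the raw limit definitions (difference
    quotients with the family's dilation of the time argument) on a geometric
    epsilon sequence and extrapolates the O(eps) error away. Never calls the
    equivalence forms.
    """
    fam = spec.family
    a = spec.alpha

    def quotient(eps):
        if fam is Family.CONFORMABLE:
            return (f(t + eps * t ** (1.0 - a)) - f(t)) / eps
        if fam is Family.TRUNCATED_M:
            dil = truncated_mittag_leffler(spec.beta, eps * t ** (-a), n_terms=60)
            return (f(t * dil) - f(t)) / eps
        raise ValueError("limit oracle defined for the dilation families only")

    seq = [quotient(eps0 / 2.0**k) for k in range(levels)]
    # Neville ladder for a full asymptotic expansion in eps (ratio 2):
    # T[j] eliminates the eps^j term with weight 2^j / (2^j - 1)
    for j in range(1, levels):
        seq = [
            (2.0**j * seq[i + 1] - seq[i]) / (2.0**j - 1.0)
            for i in range(len(seq) - 1)
        ]
    return seq[0]
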