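"""Print the proportional Laplace transform rules for repeated derivatives.

For the proportional derivative D^a f = (1-a) f + a f', the transform of the
n-fold derivative is a degree-n polynomial multiplier on Phi(s) minus
boundary polynomials on the classical derivatives at 0. In exact rational
arithmetic the direct rule equals the n-fold composition of the first-order
rule — the identity the solver relies on.
"""

from fractions import Fraction as F

from fracvent.prop_laplace import (
    compose_first_order_rules,
    expand_nth_prop_derivative,
    lt_nth_order_rule,
)


def poly_str(coeffs):
    terms = [f"{c} s^{k}" if k else f"{c}" for k, c in enumerate(coeffs) if c]
    return " + ".join(terms) or "0"


alpha = F(1, 2)
for n in (1, 2, 3):
    rule = lt_nth_order_rule(n, alpha)
    print(f"n = {n}, alpha = {alpha}:")
    print(f"  multiplier on Phi(s): {poly_str(rule.multiplier)}")
    for k, b in enumerate(rule.boundary_coeffs):
        print(f"  coefficient of phi^({k})(0): {poly_str(b)}")
    assert rule == compose_first_order_rules(n, alpha), "composition identity"
    w = expand_nth_prop_derivative(n, alpha).weights
    print(f"  binomial weights on (phi^(n) ... phi): {tuple(map(str, w))} (sum = {sum(w)})")
print("direct rules equal first-order compositions exactly (asserted above)")
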