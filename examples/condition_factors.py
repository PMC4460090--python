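"""Closed-form integrals of the condition-specific reduced ODEs.

Each physiological state collapses the focal metabolite's rate equation to
dY/dx = alpha·x + beta + Σ a·x/(K+x).  Integrating gives a quadratic +
linear + logarithmic closed form whose linear coefficient is the named
condition factor (for obesity, the common multiplier of x − log(x+1)).
"""

from kinemet import ReducedODE, antiderivative, extract_condition_factor
from kinemet.fixtures import CONSTANTS, KM

cases = [
    ("starvation", ReducedODE("Glucose", beta=CONSTANTS.starvation_beta,
                              sat_terms=((-1, KM["glucose"]),))),
    ("exercise", ReducedODE("AcetylCoA", beta=CONSTANTS.exercise_beta,
                            sat_terms=((-1, KM["acetyl_coa"]),))),
    ("obesity", ReducedODE("Triglyceride", sat_terms=((-2, KM["obesity_K"]),))),
]

for name, reduced in cases:
    closed = antiderivative(reduced)
    factor = extract_condition_factor(closed, name)
    print(f"{name:>10}: Y(x) = {closed}")
    print(f"{'':>10}  {name} factor = {float(factor.value):g}")

# the glycaemic glucose integral and the reduced ATP equation
gluc = antiderivative(ReducedODE("Glucose", beta=16282.5775,
                                 sat_terms=((-1, KM["glucose"]),)))
print(f"\n glycaemic: Y(x) = {gluc}   (linear coefficient {float(gluc.linear):.1f})")
atp = antiderivative(ReducedODE("ATP", alpha=CONSTANTS.atp_alpha, beta=-4.2068))
print(f"       ATP: Y(x) = {atp}")
print("\nNegative factors quantify the net drain on the focal metabolite in")
print("each condition; more negative = faster depletion per unit concentration.")
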