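"""Read binding stoichiometry off a continuous-variation (Job) plot.

A 1:1 complex peaks at host mole fraction 0.5; a single 1:2 host:guest
complex peaks at 1/3.  Both curves are generated from the exact
mass-balance equilibrium at constant total concentration.
"""

from hostguest import job_curve, job_maximum

one_to_one = job_curve(5e-5, ka=1.30e4)
one_to_two = job_curve(1e-4, ka=1e10, stoichiometry=(1, 2))

print(f"1:1 curve maximum at x = {job_maximum(one_to_one):.4f}")
print(f"1:2 curve maximum at x = {job_maximum(one_to_two):.4f}")
# x is the host mole fraction [H]0/([H]0+[G]0); 0.5 identifies 1:1
# binding, 1/3 a host:guest 1:2 complex.
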