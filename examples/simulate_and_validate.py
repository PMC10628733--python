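"""Generate a constrained synthetic network and inspect its structure.

The generator emulates the feasibility-study matrices: small integer
stoichiometry numbers, every reaction both-signed (something is consumed and
something produced), reaction count at least J + 2, and a controlled
nullity.  The same seed always yields the same matrix.
"""

from stoichdir import SimulatedNetworkSpec, generate_network, validate

spec = SimulatedNetworkSpec(J=5, I=7, target_nullity=2, seed=1)
S = generate_network(spec)

print("generated stoichiometry number matrix (reactants x reactions):")
print(S.to_dataframe())

report = validate(S)
print()
print(report.to_text())
print("\nnullity 2 means two independent steady-state flux directions: the "
      "smallest null space from which directionality can be inferred.")
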