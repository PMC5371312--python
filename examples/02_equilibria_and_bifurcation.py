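"""Equilibria and the pitchfork of the two-path system.

Enumerates the closed-form equilibria of the deterministic two-path
dynamics at eps = 0.2 (tristable) and eps = 0.3 (bistable), labels their
linear stability, and locates the sub-critical pitchfork where the
symmetric "use both paths" state loses stability.
"""

from physarum import classify_stability, critical_epsilon, equilibria

for eps in (0.2, 0.3):
    eq_set = classify_stability(equilibria(eps, delta=1.0))
    print(f"eps = {eps}:")
    for eq in eq_set.equilibria:
        eig = (
            f"eigenvalues ({eq.eigenvalues[0]:+.3f}, {eq.eigenvalues[1]:+.3f})"
            if eq.eigenvalues
            else "eigenvalues n/a (origin)"
        )
        print(f"  {eq.kind:<10} (D1, D2) = ({eq.D1:.4f}, {eq.D2:.4f})"
              f"  {eq.stability:<8} {eig}")
    print()

print(f"pitchfork threshold (bisection): eps* = {critical_epsilon():.6f}")
print("Below eps* the network can settle on either single path or on equal "
      "use of both; above it the shared state is an unstable saddle and the "
      "decision is always binary.")
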