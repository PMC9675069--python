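"""Locate and classify evolutionarily singular strategies for each trade-off.

At a singular strategy the selection gradient vanishes.  Second-order
conditions then separate continuously stable endpoints (ESS), branching
points (convergence-stable but invadable) and repellers (evolution diverges,
producing bistability between the boundary strategies).
"""

from mixoevolve import ModelParams, find_singular_points

T = 18.0
for name, z in (("specialist (z=-1)", -1.0), ("linear (z=0)", 0.0),
                ("generalist (z=+1)", 1.0)):
    points = find_singular_points(T, ModelParams(z=z))
    print(f"{name} at {T} degC:")
    for p in points:
        extra = "" if p.classification == "boundary_attractor" else \
            f" (d2 lambda/d theta_mut^2 = {p.second_derivative:+.3g})"
        print(f"  theta* = {p.theta_star:.4f}: {p.classification}{extra}")

print(
    "\n-> the concave trade-off puts a repeller between two attracting\n"
    "   boundaries (evolutionary bistability: pure phototroph or pure\n"
    "   phagotroph, depending on where evolution starts); the linear\n"
    "   trade-off sits on a neutral (perfectly flat) fitness landscape at\n"
    "   its interior singular point; the convex trade-off supports a true\n"
    "   intermediate ESS, i.e. stable mixotrophy.")
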