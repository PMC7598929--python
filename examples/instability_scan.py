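"""Locate the mechanobiological static instability in mechanosensing loss.

The parameter delta is the fraction of intramural stress that cells fail to
sense.  For a localized axisymmetric mechanosensing lesion at normotensive
pressure, equilibrated states exist only up to a critical delta: beyond it
the dilatation is unbounded (no equilibrium).  The scan marches delta upward
and bisects between the last converged and first failed solve.
"""

import equigr as eg

params = eg.fixture_table1()
out = eg.scan_delta_instability(params, delta_max=0.4, resolution=0.005)

print("probe history (delta, equilibrated?):")
for d, ok in out["history"]:
    print(f"  delta = {d:6.4f}  ->  {'converged' if ok else 'no equilibrium'}")
print()
print(f"critical mechanosensing loss: delta_crit = {out['delta_critical']:.3f}")
print()
print("Below delta_crit the lesion dilates monotonically with delta; above")
print("it no equilibrated wall exists -- a static instability of the")
print("growth-and-remodeling feedback, not a material failure.")
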