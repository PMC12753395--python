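"""One-way (tornado) and probabilistic sensitivity analyses with figures.

Perturbs every model parameter on its +/-20% range: one at a time for the
tornado ranking, jointly (1,000 Monte Carlo draws) for the CEAC.
Figures are written next to this script as PNG files.
"""

from pathlib import Path

import numpy as np

from markovcea import (
    ceac,
    icer,
    one_way_tornado,
    psa,
    reference_case,
    resolve_strategies,
    run_strategy,
)
from markovcea.plots import ce_plane, ceac_plot, tornado_plot

out = Path(__file__).parent
config = reference_case()
opd, lpd = resolve_strategies(config)
_, r = run_strategy(opd)
_, c = run_strategy(lpd)
baseline = icer(r, c, config.wtp)

entries = one_way_tornado(opd, lpd, config.wtp)
print("Tornado (widest ICER span first):")
for e in entries[:5]:
    print(f"  {e.parameter:25s} span {e.span:>12,.0f} RMB/QALY")
tornado_plot(entries, baseline.icer, out / "tornado.png")

draws = psa(opd, lpd, n_draws=1000, seed=20170301)
curve = ceac(draws)
for wtp in (50_000, 200_000, 268_074):
    p = curve.probability[np.searchsorted(curve.wtp, wtp, side="right") - 1]
    print(f"P(LPD cost-effective | WTP {wtp:>9,.0f}) = {p:.3f}")
ce_plane(draws, config.wtp, out / "ce_plane.png")
ceac_plot(curve, config.wtp, out / "ceac.png")

print(
    "\nThe tornado shows direct-cost parameters drive the ICER most; the"
    "\nCEAC gives the share of Monte Carlo draws in which LPD has positive"
    "\nincremental net monetary benefit at each willingness-to-pay."
)
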