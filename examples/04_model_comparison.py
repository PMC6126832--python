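"""Model selection: does the data want district-level spatial structure?

Fits the no-spatial (hospital random effects), district-level and
coarse-level struct+unstruct specifications on one synthetic panel with
a true district effect and compares DIC/WAIC. Lower is better; the
generating process has a genuine district-level structured effect, so
the district specification should win.
"""

from geosfa import MCMCSettings, SimConfig, prepare_panel, run_model_suite, \
    simulate_panel
from geosfa.presets import get_preset

panel, graph, _ = simulate_panel(
    SimConfig(lattice_size=6, coarse_block=3, hospitals_per_district=5.0,
              waves=(2006, 2008, 2010), seed=100))
prepared = prepare_panel(panel)
mc = MCMCSettings(iterations=12000, burn_in=3000, thinning=9, seed=0)
specs = [get_preset(n, mcmc=mc) for n in ("model1", "model2", "model5")]
table = run_model_suite(prepared, graph, specs)
print(table[["DIC", "pD", "WAIC", "p_waic", "best_dic"]].round(1))
# model1: no spatial terms, iid hospital effects; model2: district-level
# structured (GMRF) + unstructured effects; model5: both at the coarse
# (NUTS2-style) level.
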