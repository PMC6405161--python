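"""Simulate seizure onset and recruitment on a synthetic connectome.

Builds a planted-propagation network (one epileptogenic node with three
strong links), integrates the coupled Epileptor network from the healthy
fixed point, and prints the seizure raster: the EZ seizes autonomously,
then recruits exactly the strongly linked regions.
"""

from ictalnet import (
    ExcitabilityMap,
    detect_seizure_events,
    generate_planted,
    recruited_set,
    simulate,
)

scenario = generate_planted(n_nodes=30, n_strong=3, seed=7)
c = scenario.connectome
print(f"network: N={c.n}, EZ node {scenario.ez_node}, "
      f"planted PZ {sorted(scenario.planted_pz)}")

ex = ExcitabilityMap.from_ez(c.n, scenario.ez)  # EZ x0=-1.6, healthy -2.2
traj = simulate(c, ex, horizon=3 * 2857.0, dt_out=2.0)
raster = detect_seizure_events(traj)

print(f"\n{len(raster.events)} seizure events over {traj.horizon:g} time units:")
for e in raster.events[:8]:
    tag = "EZ" if e.node == scenario.ez_node else "recruited"
    print(f"  node {e.node:2d} ({tag:9s}) onset {e.onset:8.1f} offset {e.offset:8.1f}")

rec = recruited_set(raster, scenario.ez)
print(f"\nrecruited set {sorted(rec.nodes)} (order of onset: {rec.onset_order})")
print("-> matches the planted propagation zone:", rec.nodes == scenario.planted_pz)
# Onsets cluster just after each EZ seizure: recruitment is driven by the
# permittivity coupling pushing the neighbors' slow variable past its fold.
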