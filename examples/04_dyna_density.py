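"""Windowed correlation networks (DyNA) and the density trace.

Night-group mediators are given strong mutual noise correlation in the
first 8 h; the density statistic should separate the groups early and
converge later — the qualitative signature of a more coordinated early
inflammatory program after nighttime injury.
"""

import traumanet as tn

blocks = tuple(
    tn.CorrelationBlock(tn.MEDIATOR_PANEL[i:i + 8], rho=0.9,
                        group="Night", start_h=0.0, end_h=8.0)
    for i in range(0, 32, 8)
)
config = tn.SyntheticConfig(seed=23, correlation_blocks=blocks)
patients, samples = tn.generate_cohort(config)
groups = {p.patient_id: p.group for p in patients}

trace, networks = tn.density_trace(samples, groups, threshold=0.7)
print(trace.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
first_night = next(n for n in networks
                   if n.group == "Night" and n.window.start_h == 0.0)
print(f"\nnight 0-8 h network: {len(first_night.nodes)} nodes, "
      f"{first_night.n_edges} edges at |r| >= 0.7")
print("density = 2E/(N-1): edges per node pair scaled by network size; "
      "the night group is denser in the 0-8 h window because its "
      "mediators were simulated as strongly co-regulated there.")
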