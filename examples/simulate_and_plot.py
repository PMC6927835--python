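"""Simulate a Markov cohort, aggregate 12-month transitions, render diagrams.

Draws 2,000 women over 60 months from a four-state monthly chain (non-use,
injections, pill, implants), extracts new-use episodes, applies the
exclusion rules, and renders both the method-flow chord diagram and the
reasons-for-quitting diagram.
"""

from pathlib import Path

from contraflow import (
    CodeMap,
    build_flow_matrix,
    build_reason_matrix,
    compute_layout,
    demo_cohort_spec,
    method_palette,
    outcome_partition,
    pairs_from_records,
    render,
    render_reason_diagram,
    simulate_cohort,
)

out_dir = Path("scratch")
out_dir.mkdir(exist_ok=True)

codes = CodeMap()
spec = demo_cohort_spec(n_women=2000, seed=11, window_months=60)
records = simulate_cohort(spec, codes)
pairs, tally, _ = pairs_from_records(records, codes)
print(f"{len(records)} women -> {len(pairs)} retained 12-month transitions")
print("exclusions:", dict(tally))
# the tally counts episodes without a 12-month observation, never-users,
# and discontinuations because the woman wanted to become pregnant

part = outcome_partition(pairs)
print(f"continue/switch/quit (weighted): "
      f"{part['continue']:.0f}/{part['switch']:.0f}/{part['quit']:.0f}")

flow = build_flow_matrix(pairs, codes)
svg = render(compute_layout(flow), method_palette(codes))
(out_dir / "simulated_chord.svg").write_text(svg)

quitters = build_reason_matrix(pairs, "quitters", codes)
(out_dir / "simulated_reasons.svg").write_text(render_reason_diagram(quitters, codes))
print(f"wrote {out_dir / 'simulated_chord.svg'} and {out_dir / 'simulated_reasons.svg'}")
print(f"top quitting flow: injections -> side effects = "
      f"{quitters.cell('injections', 'side effects'):.0f} women (weighted)")
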