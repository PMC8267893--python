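"""Designed-winner recovery on synthetic effect tables.

Generates a synthetic table with realistic interval structure, plants one
treatment that dominates by construction (largest improvement odds, zero
QTc shift, tight intervals), and checks that both the deterministic tree
and the PSA identify it — an end-to-end correctness probe of the pipeline.
"""

from qtcda import PsaConfig, SyntheticTableSpec, generate_table, recovery_experiment

table = generate_table(SyntheticTableSpec(n_treatments=6, seed=42))
print("synthetic table:")
print(table.to_frame().round(3).to_string(index=False))

report = recovery_experiment(
    SyntheticTableSpec(n_treatments=6, seed=42),
    config=PsaConfig(n_draws=5_000, seed=42),
)
print(f"\nplanted winner: {report.winner}; recovered: {report.success}")
for baseline, (top, share) in report.psa_top_share.items():
    margin = report.deterministic_margin[baseline]
    print(f"  {baseline:g} ms: deterministic margin {margin:.2f} utility; "
          f"PSA top {top} ({share:.0f}% of draws)")
print(
    "\nA 100% recovery rate under designed dominance is what passing looks"
    "\nlike; real tables (overlapping intervals) legitimately split wins."
)
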