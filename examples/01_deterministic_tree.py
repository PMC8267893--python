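"""Deterministic decision-tree analysis on the packaged effect table.

Evaluates each antipsychotic's expected utility — improvement probability
weighting a QTc-dependent utility, with the drug's own QTc shift added to
the baseline — across four baseline QTc values, and ranks the options.
"""

from qtcda import default_pair, evaluate_grid, rank_treatments, reference_table

table = reference_table()  # six drugs; placebo improvement probability 0.5
matrix = evaluate_grid(table, pair=default_pair())

print("Expected utility by baseline QTc (ms):")
print(matrix.round(2).to_string())
print()
for baseline in matrix.columns:
    best, utility = rank_treatments(matrix, baseline)[0]
    print(f"  best option at {baseline:g} ms: {best} ({utility:.2f})")
print(
    "\nHigher is better (0-100 scale). Amisulpride's strong improvement odds"
    "\nwin at a normal baseline; from 450 ms its 14.1 ms QTc shift costs it"
    "\nthe lead and quetiapine, almost as effective but far gentler on QTc,"
    "\ntakes over."
)
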