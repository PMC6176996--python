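"""How stable is the network to the correlation threshold and to samples?

Sweeps the |r| threshold, recomputes metrics under leave-one-sample-out
jackknifing at each threshold, and recommends the smallest threshold at
which the jackknife CV of density has plateaued.
"""

from cartnet import SimConfig, quantify, simulate_dataset, stability_report

data = simulate_dataset(SimConfig(), seed=1)
matrix = quantify(data["peptide_table"], data["sample_sheet"])
matrix.values = matrix.values.drop(index="MDH1")  # constant reference row

grid = [0.5, 0.6, 0.7, 0.8, 0.9]
report = stability_report(matrix, grid, group="LFHS")

print("threshold  links  density  jackknife CV(density)")
for t in grid:
    print(f"   {t:.2f}    {int(report.sweep.loc[t, 'n_links']):5d}  "
          f"{report.sweep.loc[t, 'density']:.4f}   "
          f"{report.jackknife.loc[t, 'density_cv']:.3f}")
print(f"\nrecommended threshold: {report.recommended_threshold}")
print("criterion trace:")
for line in report.criterion_trace:
    print("  ", line)
print("\nLink counts shrink as the threshold rises; the recommendation "
      "picks the first threshold where removing any single sample no "
      "longer changes density much relative to the next grid point.")
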