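"""Per-protein differential testing across the three diet groups.

Each protein is log2-transformed, checked for homoscedasticity
(Brown-Forsythe), then tested by one-way ANOVA + Tukey HSD or, if
variances are unequal, Kruskal-Wallis + Dunn.  Benjamini-Hochberg FDR is
applied across proteins.
"""

from cartnet import SimConfig, diff_table, quantify, simulate_dataset

data = simulate_dataset(SimConfig(), seed=1)
matrix = quantify(data["peptide_table"], data["sample_sheet"])

result = diff_table(
    matrix.values.drop(index="MDH1"),  # the reference is constant by design
    matrix.samples["group"],
    transform="log2",
    alpha=0.05,
    fdr="features",
)

n_anova = (result["test_used"] == "anova").sum()
n_kw = (result["test_used"] == "kruskal").sum()
print(f"tested {result.shape[0]} proteins: {n_anova} by ANOVA, {n_kw} by "
      "Kruskal-Wallis (heteroscedastic)")
raw_hits = (result["p_value"] < 0.05).sum()
fdr_hits = result["significant"].sum()
print(f"{raw_hits} proteins with raw p < 0.05; {fdr_hits} survive BH-FDR")

top = result.nsmallest(5, "p_value")
print("\ntop 5 proteins by omnibus p:")
print(top[["test_used", "statistic", "p_value", "p_adjusted"]].round(4).to_string())
print("\nThe simulation plants lower antioxidant/glycolysis/TCA abundance "
      "in LFHS and higher beta-oxidation in HFLS, so hits concentrate there.")
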