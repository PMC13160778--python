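"""Generate a synthetic development cohort and summarize it.

The generator reproduces the marginal structure of a contemporary IMRT
lung-cancer cohort (truncated-normal dose metrics, log-normal inflammatory
markers, the MLD-V30 rank correlation of 0.768) with outcomes drawn from a
known true model tuned to a 30.7% event rate.
"""

from scipy.stats import spearmanr

from rpntcp import SyntheticConfig, generate, summarize

cohort = generate(SyntheticConfig(n=580, seed=1))
print(f"cohort: n={len(cohort)}, grade>=2 events={cohort.n_events} "
      f"({100 * cohort.n_events / len(cohort):.1f}%)")

rho = spearmanr(cohort.df["mld"], cohort.df["v30"]).statistic
print(f"Spearman(MLD, V30) = {rho:.3f}  (generator target 0.768)")

table = summarize(cohort)
cont = table[table.kind == "continuous"].set_index("variable")
for var in ("age", "mld", "v30", "nlr"):
    row = cont.loc[var]
    print(f"  {var:>4}: {row['mean']:.2f} +/- {row['sd']:.2f}")
print("  -> mean +/- SD per covariate, the baseline-characteristics view "
      "of the simulated population")
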