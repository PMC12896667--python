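"""Two-period enrichment statistics on daily behavior proportions.

Simulates a control/test study for three individuals with a planted
increase in scent-directed behavior during the test period, then runs
the non-parametric toolkit: Mann-Whitney on daily proportions,
chi-square on the categorical distribution, Fligner-Killeen on
dispersion.
"""

import ethopose as ep
from ethopose.ethogram_stats import daily_values

config = ep.StudySimConfig(seed=11).with_effect("Scenting", shift=6.0)
table = ep.simulate_study_table(config)

print("individual  behavior   MW-U      p  | FK-stat     p")
for ind in config.individuals:
    for cat in config.categories:
        x = daily_values(table, ind, "control", cat)
        y = daily_values(table, ind, "test", cat)
        u, p = ep.mann_whitney(x, y)
        fk, _, fkp = ep.fligner_killeen([x, y])
        flag = " *" if p < 0.05 else ""
        print(f"{ind:<10}  {cat:<9} {u:5.1f}  {p:5.3f} | {fk:7.3f} {fkp:5.3f}{flag}")

# full-distribution chi-square per individual (counts from mean daily
# proportions scaled to a nominal hour of observation)
print("\nchi-square on the full behavioral distribution (control vs test):")
for ind in config.individuals:
    counts = {
        period: [daily_values(table, ind, period, c).mean() * 3600 for c in config.categories]
        for period in ("control", "test")
    }
    res = ep.chi_square_counts(counts["control"], counts["test"])
    print(f"  {ind}: chi2({res.df}) = {res.chi2:.1f}, p = {res.p:.2g}")

print(
    "\nThe planted Scenting shift should surface as small Mann-Whitney"
    " p-values for Scenting (marked *) while other behaviors stay null."
)
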