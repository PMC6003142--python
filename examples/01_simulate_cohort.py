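"""Generate a synthetic case-control cohort and inspect its structure.

The generator plants three high-LD haplotype blocks (4 + 4 + 2 SNPs) among
equilibrium SNPs and a rare risk haplotype whose allelic odds ratio is 9,
then samples retrospectively until the case/control quotas fill.
"""

from haplorisk import SimulationConfig, simulate_cohort

cfg = SimulationConfig(n_cases=829, n_controls=765, seed=1)
genotypes, phenotypes, truth = simulate_cohort(cfg)

print(f"cohort: {phenotypes.n_cases} cases / {phenotypes.n_controls} controls, "
      f"{genotypes.n_snps} SNPs")
print(f"risk haplotype frequency  cases: {truth['case_risk_freq']:.4f}  "
      f"controls: {truth['control_risk_freq']:.4f}")
# The case frequency sits near 0.05 and the control frequency near 0.006 --
# the regime of a rare haplotype with a strong effect; the gap between the
# two is what every downstream association statistic quantifies.
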