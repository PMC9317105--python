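"""Instrument strength, weak-instrument filtering, LD pruning, harmonisation.

Builds two-sample GWAS summary statistics from a synthetic cohort, computes
per-variant R^2 and F, removes weak instruments (F < 10), prunes variants in
LD (r^2 >= 0.1) and harmonises exposure and outcome records to a shared
effect allele.
"""

from mrpath import SimulationConfig, harmonize, make_two_sample_sumstats, simulate_cohort, simulate_genotypes
from mrpath.instruments import instrument_strength, ld_prune

cfg = SimulationConfig(n_individuals=12_000, exclusion_fraction=0.0, seed=2)
geno = simulate_genotypes(cfg)
cohort, truth = simulate_cohort(cfg, geno)
exp_stats, med_stats = make_two_sample_sumstats(cohort, geno, outcome="mediator", seed=2)

stats = instrument_strength(exp_stats, f_min=10.0)
print(f"{stats['kept'].sum()} of {len(stats)} variants pass F >= 10 "
      f"(max F = {stats['f_stat'].max():.1f})")

ld = geno.empirical_ld()
pruned = ld_prune(stats[stats["kept"]].copy(), ld, threshold=0.1)
kept = pruned.loc[pruned["kept"], "SNP"]
print(f"{len(kept)} variants remain after LD pruning at r^2 < 0.1")

pairs, dropped = harmonize(exp_stats[exp_stats["SNP"].isin(kept)], med_stats)
print(f"{len(pairs)} harmonised exposure/outcome pairs "
      f"({int(pairs['flipped'].sum())} allele-flipped, {len(dropped)} dropped)")
print(pairs.head(5).round(4).to_string(index=False))
print("\nbeta_exp/beta_out are per-effect-allele effects on exposure and outcome,")
print("aligned to the exposure minor allele; these pairs feed the MR estimators.")
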