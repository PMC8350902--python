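"""Generate a synthetic memory-clinic cohort and inspect its structure.

The generator draws a latent disease stage per participant; amyloid burden
rises early along that stage, aggregated (PET) tau late, and soluble
(CSF/plasma) tau responds to amyloid and age. The printed correlations show
the resulting raw-scale coupling between modalities.
"""

from taucompare import GeneratorConfig, generate_cohort, censor_plasma

cfg = GeneratorConfig(n_participants=400, seed=0)
table, truth = generate_cohort(cfg)

print(f"cohort: {len(table)} participants, "
      f"{(table.group == 'IMPAIRED').mean():.0%} impaired, "
      f"{(table.abeta_status == 'POS').mean():.0%} amyloid-positive")
for a, b in [("taupet_meta", "csf_ptau181"),
             ("csf_ptau181", "csf_ab4240"),
             ("taupet_meta", "mem_z")]:
    print(f"  r({a}, {b}) = {table[a].corr(table[b]):+.2f}")

censored = censor_plasma(table, cfg)
n = censored.attrs["plasma_censored_n"]
ids = set(censored.attrs["plasma_censored_ids"])
neg = censored[censored.id.isin(ids)].abeta_status.eq("NEG").mean()
print(f"plasma p-tau217 below detection limit: {n} samples "
      f"({neg:.0%} of them amyloid-negative)")
print("ground-truth effects:", truth.effects)
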