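"""Rank AD features by bagged regression-tree variable importance.

One bagged ensemble (25 pruned CART trees) per imputed table; the VIM of a
predictor is its mean summed SSE decrease normalized by the root SSE. The
amyloid measure should dominate the fluid-tau outcome while memory outranks
age for the PET outcome in the impaired stratum.
"""

from taucompare import (GeneratorConfig, generate_cohort, censor_plasma,
                        apply_missingness, ImputationConfig, impute,
                        vim_across_imputations)

predictors = ["age", "education", "apoe4", "csf_ab4240", "mmse", "mem_z",
              "lang_z", "exec_z", "visuo_z", "hippo_tiv", "ad_sig_thickness"]

cfg = GeneratorConfig(n_participants=400, seed=0)
table, _ = generate_cohort(cfg)
table = apply_missingness(censor_plasma(table, cfg), cfg)
imputed = impute(table, ImputationConfig(m=5, seed=1))

vim_fluid = vim_across_imputations(imputed, "csf_ptau181", predictors, seed=0)
print("top predictors of CSF p-tau181 (whole cohort):")
print(vim_fluid[["median", "lo", "hi", "rank"]].head(4).round(3))

impaired = (imputed.tables[0]["group"] == "IMPAIRED").to_numpy()
vim_pet = vim_across_imputations(imputed, "taupet_meta", predictors,
                                 seed=50, rows=impaired)
print("\ntop predictors of tau-PET meta-ROI (impaired stratum):")
print(vim_pet[["median", "lo", "hi", "rank"]].head(4).round(3))
print(f"\nmemory rank {int(vim_pet.loc['mem_z', 'rank'])} vs "
      f"age rank {int(vim_pet.loc['age', 'rank'])} for the PET outcome")
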