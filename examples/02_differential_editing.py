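"""Two-stage differential-editing detection with trend clustering.

Simulates the three-group longitudinal design with 20% truly shifted sites
(+0.10 on the editing-proportion scale), runs the binomial GLM + LRT with
pooled-count Fisher confirmation, and compares the calls with the ground
truth. Covariate (age / sex) p-values are then computed for the called sites.
"""

import numpy as np

from aied import io as aio
from aied.catalog import SubgroupScheme
from aied.differential import call_dre, covariate_effects
from aied.simulate import SimConfig, generate_study

cfg = SimConfig(n_sites=300, seed=7, frac_dre=0.2, effect_size=0.10,
                coverage_mean=50, dispersion=0.01)
study = generate_study(cfg)
oriented, _ = aio.orient_to_sense(study.allele_counts)
scheme = SubgroupScheme.from_metadata(study.metadata)

res = call_dre(oriented, study.metadata, groups=("control", "D1", "D4"),
               scheme=scheme, rng=np.random.default_rng(7)).set_index("site_id")
truth = study.truth.set_index("site_id")["is_dre"].reindex(res.index)

called = int(res["is_dre"].sum())
sens = res.loc[truth, "is_dre"].mean()
fpr = res.loc[~truth, "is_dre"].mean()
print(f"tested {len(res)} sites; called {called} DRE "
      f"(sensitivity {sens:.2f}, null call rate {fpr:.3f})")
print("a DRE call requires BH-FDR(P_GLM) < 0.05 AND pooled Fisher P < 0.05\n")

print("temporal trends among DRE calls:")
print(res.loc[res["is_dre"], "trend"].value_counts().to_string())
print("(early_up_then_down = up at day 1 then falling; late_up = highest at "
      "day 4; down = below control at both time points)\n")

# covariate effects at the five strongest calls
meta = study.metadata.set_index("sample_id")
top = res[res["is_dre"]].nsmallest(5, "p_glm").index
print("age / sex covariate p-values (GLM dropping one factor at a time):")
for sid in top:
    sub = oriented[oriented["site_id"] == sid]
    g = meta.loc[sub["sample_id"]]
    out = covariate_effects(
        sub["alt_count"].to_numpy(), sub["ref_count"].to_numpy(),
        g["group"].to_numpy(), g["age"].to_numpy(), g["sex"].to_numpy(),
    )
    print(f"  {sid}: P_age={out['p_age']:.4f}  P_sex={out['p_sex']:.4f}")
print("(small values would indicate age- or sex-dependent editing at the site)")
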