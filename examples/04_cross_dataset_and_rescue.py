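"""Cross-dataset DRE comparison and treatment-rescue calling.

Three independently simulated studies sharing a common set of true DRE
sites are compared by Venn overlap of their DRE calls (raw P_GLM < 0.05,
no FDR — over-correcting independent datasets would hide shared signal).
A separate three-arm study (control / insult / pre-treated insult) is then
screened for sites whose insult-induced editing change is rescued.
"""

import numpy as np

from aied import io as aio
from aied.catalog import SubgroupScheme
from aied.differential import call_dre
from aied.integrate import overlap_dre_sets, rescue_call
from aied.simulate import SimConfig, generate_rescue_study, generate_study


BASE_CFG = SimConfig(n_sites=150, seed=97, frac_dre=0.25, effect_size=0.12,
                     coverage_mean=60, dispersion=0.0)
BASE = generate_study(BASE_CFG)


def dre_sites(seed: int) -> set:
    """Re-draw counts for the shared sites/truth and call DRE without FDR."""
    from dataclasses import replace

    study = generate_study(
        replace(BASE_CFG, seed=seed),
        truth=BASE.truth.drop(columns=["is_known"]),
        sites=BASE.sites,
    )
    oriented, _ = aio.orient_to_sense(study.allele_counts)
    scheme = SubgroupScheme.from_metadata(study.metadata)
    res = call_dre(oriented, study.metadata, groups=("control", "D1", "D4"),
                   scheme=scheme, fdr_mode="off", rng=np.random.default_rng(seed))
    return set(res.loc[res["is_dre"], "site_id"])


sets = {"CLP": dre_sites(97), "LPS1": dre_sites(201), "LPS2": dre_sites(202)}
report = overlap_dre_sets(sets)
print("DRE sites per dataset:", {k: len(v) for k, v in report.sets.items()})
print("Venn cells:", {" & ".join(sorted(k)): len(v) for k, v in report.cells.items()})
print(f"shared by all three datasets: {len(report.shared_by_all)} sites")
print(f"in CLP and at least one LPS dataset: {len(report.in_and_any_other('CLP'))} sites")
print("(the same true effects drive every dataset, so shared calls mark the "
      "reproducible differential-editing signal)\n")

rescue_study = generate_rescue_study(n_rescued=15, n_unrescued=10, n_null=50,
                                     effect_size=0.15, coverage_mean=100, seed=5)
oriented, _ = aio.orient_to_sense(rescue_study.allele_counts)
res = rescue_call(oriented, rescue_study.metadata).set_index("site_id")
truth = rescue_study.truth.set_index("site_id").loc[res.index]
called = res["rescued"]
print(f"rescue screen over {len(res)} sites: {int(called.sum())} called rescued; "
      f"sensitivity {called[truth['is_rescued']].mean():.2f}, "
      f"specificity {(~called[~truth['is_rescued']]).mean():.2f}")
print("(rescued = insult shifts editing significantly, pre-treatment shifts it "
      "back significantly, and the treated mean ends closer to control)")
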