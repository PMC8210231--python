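"""Expression association of candidate binding sites with their target
genes, plus the FDR-threshold validation simulation.

Finding: every planted site-gene pair is recovered at FDR < 0.25 with a
negative direction (down-regulation in mutated samples), while random
pseudo-mutated splits of the same expression matrix yield well under one
discovery per repetition.
"""

from pathlib import Path

import pandas as pd

from ncrm.expression import fdr_null_simulation, zscore_by_cancer_type
from ncrm.pipeline import ScreenParams, run_bundle
from ncrm.simulate import CohortConfig, generate_cohort

SEED = 11
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    bundle = generate_cohort(CohortConfig(seed=SEED))
    result = run_bundle(bundle, ScreenParams())
    RESULTS.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame(
        [
            {
                "site_id": a.site_id,
                "gene_id": a.gene_id,
                "n_mutated": a.n_mutated,
                "n_wt": a.n_wt,
                "p_value": a.p_value,
                "fdr": a.fdr,
                "direction": a.direction,
            }
            for a in result.associations
        ]
    )
    table.to_csv(RESULTS / "associations.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print(f"significant at FDR < 0.25: {len(result.significant)}")

    z = zscore_by_cancer_type(bundle.expression)
    affected = {e["gene_id"] for e in bundle.truth.effects}
    eligible = [g for g in z.z.index if g not in affected]
    sim = fdr_null_simulation(z, eligible, n_genes=30, n_mut=12, n_reps=50, seed=SEED)
    print(
        f"FDR validation: {sim.mean_discoveries:.3f} mean discoveries per rep "
        f"over {sim.n_reps} random splits of {sim.n_genes} unaffected genes"
    )


if __name__ == "__main__":
    main()
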