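"""Generate the study's synthetic cohort bundle and write it to scratch/.

The bundle emulates the real inputs of the screen: a curated-catalog-like
mutation cohort, a WGS-like cohort with matched expression, open-chromatin
peaks, chromatin-interaction anchor pairs, motif models with located
binding sites, and gene models — with seven planted candidate positions
that satisfy all ten criteria and one decoy per criterion.
"""

from pathlib import Path

from ncrm.simulate import CohortConfig, generate_cohort

SEED = 11
OUT = Path(__file__).resolve().parents[1] / "scratch" / "bundle"


def main() -> None:
    bundle = generate_cohort(CohortConfig(seed=SEED))
    bundle.write(OUT)
    truth = bundle.truth
    print(f"bundle written to {OUT}")
    print(f"cohort 1: {len(bundle.cohort1)} records, cohort 2: {len(bundle.cohort2)}")
    print(f"planted candidate positions ({len(truth.planted)}):")
    for p in truth.planted:
        print(
            f"  {p['chrom']}:{p['pos']} {p['ref']}>{p['alt']} "
            f"site={p['site_id']} target={p['target_gene']}"
        )
    print(f"decoys ({len(truth.decoys)}):")
    for d in truth.decoys:
        print(f"  {d['chrom']}:{d['pos']}  fails at stage '{d['removed_at']}' ({d['name']})")


if __name__ == "__main__":
    main()
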