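"""Concordance and evolutionary-constraint filtering of the candidate
variants.

Every resequencing-panel variant is tested for perfect co-segregation
with the deduced QTL genotypes; survivors are screened against the
orthologous alleles of five other mammals, and surviving pairs are
checked for complete linkage disequilibrium.
"""

import pandas as pd

from analysis_common import OUT_DIR, RUN_DIR, ensure_run


def main() -> None:
    report = ensure_run()
    conc = pd.read_csv(RUN_DIR / "concordance.tsv", sep="\t", comment="#")
    cons = pd.read_csv(RUN_DIR / "constraint.tsv", sep="\t", comment="#")
    ld = pd.read_csv(RUN_DIR / "ld_pairs.tsv", sep="\t", comment="#")
    conc.to_csv(OUT_DIR / "05_concordance.tsv", sep="\t", index=False)
    cons.to_csv(OUT_DIR / "05_constraint.tsv", sep="\t", index=False)

    print(conc.to_string(index=False))
    print()
    print(cons.to_string(index=False))
    if len(ld):
        print()
        print(ld.to_string(index=False))
    print(
        f"\n{int(conc['passed'].sum())} of {len(conc)} variants concordant; "
        f"{int(cons['retained'].sum())} retained after the cross-species screen: "
        f"{', '.join(report['final_candidates'])}"
    )


if __name__ == "__main__":
    main()
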