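"""Mixed-model GWAS per population, meta-analysis and interval overlap.

Reads the cached pipeline run and reports each population's top SNP,
its genome-wide threshold, the LOD-drop-2 support intervals on the
consensus chromosome and their intersection.
"""

import pandas as pd

from analysis_common import OUT_DIR, RUN_DIR, ensure_run


def main() -> None:
    report = ensure_run()
    rows = []
    for pop in ("WE", "SU", "ET"):
        scan = pd.read_csv(RUN_DIR / f"scan_{pop}.tsv", sep="\t", comment="#")
        top = scan.loc[scan["lod"].idxmax()]
        rows.append((pop, top["marker"], top["chrom"], int(top["bp"]), round(top["lod"], 2)))
    meta = pd.read_csv(RUN_DIR / "scan_meta.tsv", sep="\t", comment="#")
    mtop = meta.loc[meta["lod"].idxmax()]
    rows.append(("meta", mtop["marker"], mtop["chrom"], int(mtop["bp"]), round(mtop["lod"], 2)))
    tops = pd.DataFrame(rows, columns=["population", "top_marker", "chrom", "bp", "lod"])
    tops.to_csv(OUT_DIR / "02_top_snps.tsv", sep="\t", index=False)

    intervals = pd.read_csv(RUN_DIR / "intervals.tsv", sep="\t", comment="#")
    intervals.to_csv(OUT_DIR / "02_support_intervals.tsv", sep="\t", index=False)

    print(tops.to_string(index=False))
    print()
    print(intervals.to_string(index=False))
    ov = report["ci_overlap"]
    print(
        f"\nconsensus region: chr{report['anchor']['chrom']}:"
        f"{ov['start_bp']}-{ov['end_bp']} "
        f"({(ov['end_bp'] - ov['start_bp']) / 1e3:.0f} kb)"
    )


if __name__ == "__main__":
    main()
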