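"""Progeny-test segregation analysis of every breeding sire.

Reports, per sire, the offspring counts and mean thoracic counts by
transmitted chromosome, the Z log10 likelihood ratio, and the deduced
QTL genotype (Qq when Z > 2, homozygous when Z < -2).
"""

import pandas as pd

from analysis_common import OUT_DIR, RUN_DIR, ensure_run


def main() -> None:
    ensure_run()
    seg = pd.read_csv(RUN_DIR / "segregation.tsv", sep="\t", comment="#")
    seg.to_csv(OUT_DIR / "03_sire_calls.tsv", sep="\t", index=False)
    print(seg.to_string(index=False))
    called = seg[seg["call"] != "unknown"]
    n_het = (called["call"] == "Qq").sum()
    print(
        f"\n{len(called)} of {len(seg)} sires called "
        f"({n_het} heterozygous Qq, {len(called) - n_het} homozygous)"
    )


if __name__ == "__main__":
    main()
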