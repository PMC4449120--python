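#!/usr/bin/env python
"""Binary cognate coding and inter-variant distances.

Reads results/data/lexicon.csv, codes one presence/absence character per
(meaning, cognate class) pair, and writes the NEXUS character matrix plus
Hamming and Jaccard distance tables under results/.
"""

from pathlib import Path

import pandas as pd

from lexevo import cognate

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    lex = cognate.read_lexicon(ROOT / "data" / "lexicon.csv")
    m = cognate.binarize(lex)
    cognate.write_nexus_characters(m, ROOT / "matrix.nex")
    print(f"binary matrix: {m.shape[0]} variants x {m.shape[1]} cognate classes")
    missing = (~m.observed()).mean()
    print(f"missing cells: {missing:.1%}")
    for name, fn in (("hamming", cognate.hamming_distance),
                     ("jaccard", cognate.jaccard_distance)):
        d = fn(m)
        pd.DataFrame(d.d, index=d.taxa, columns=d.taxa).to_csv(
            ROOT / f"dist_{name}.tsv", sep="\t")
        print(f"{name}: mean off-diagonal distance "
              f"{d.d[d.d > 0].mean():.3f}, written to dist_{name}.tsv")


if __name__ == "__main__":
    main()
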