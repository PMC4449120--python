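#!/usr/bin/env python
"""Admixture clustering of variants and Evanno DeltaK model choice.

Treats each variant as a haploid individual and each cognate class as a
biallelic locus; runs independent Gibbs chains for K = 1..6, selects K*
by the DeltaK second-difference statistic, and reports the variants with
more than 10% minority ancestry.
"""

import sys
from pathlib import Path

from lexevo import admixture, cognate

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 21
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    m = cognate.read_nexus_characters(ROOT / "matrix.nex")
    runs_by_k = {k: admixture.run_k(m, k, 10, 300, 700, seed=SEED + k)
                 for k in range(1, 7)}
    table = admixture.evanno_delta_k(runs_by_k)
    table.to_csv(ROOT / "delta_k.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    k_star = admixture.select_k(table)
    q = admixture.mean_q(runs_by_k[k_star])
    q.round(4).to_csv(ROOT / "q_matrix.tsv", sep="\t")
    print(f"selected K* = {k_star}")
    print(f"variants with >10% admixture: {admixture.admixed_taxa(q, 0.10)}")


if __name__ == "__main__":
    main()
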