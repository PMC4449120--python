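#!/usr/bin/env python
"""Geographic barrier detection and isolation-by-barrier tests.

Builds the Delaunay network over the 14 located sites with Jaccard edge
distances, extracts five Monmonier barriers, and applies the Mantel-r2
scree rule (with partial tests controlling geographic distance) to decide
how many barriers are meaningful.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from lexevo import cognate, korea_sites_path, synth
from lexevo.barrier import (barriers_to_geojson, build_network,
                            extract_barriers, read_sites)
from lexevo.mantel import (barrier_indicator, geo_distance_matrix, mantel,
                           partial_mantel, select_n_barriers)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 31
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    m = cognate.read_nexus_characters(ROOT / "matrix.nex")
    ids, lonlat = read_sites(korea_sites_path())
    located = [t for t in m.taxa if t != synth.ANCIENT_TIP]
    dj = cognate.jaccard_distance(m).submatrix(located)
    net = build_network(ids, lonlat, dj)
    barriers = extract_barriers(net, 5)
    (ROOT / "barriers.geojson").write_text(
        json.dumps(barriers_to_geojson(barriers, net), indent=1))
    for i, b in enumerate(barriers, 1):
        crossed = [f"{ids[e[0]]}-{ids[e[1]]}" for e in b.crossed]
        print(f"barrier {i}: {len(crossed)} edges ({b.termination}): "
              + ", ".join(crossed))
    geo = geo_distance_matrix(ids, lonlat)
    rows, pr2, kr2 = [], [], []
    for k in range(1, len(barriers) + 1):
        ind = barrier_indicator(barriers, net, k)
        for method in ("pearson", "kendall"):
            res = mantel(dj, ind, method, 999, SEED + k)
            part = partial_mantel(dj, ind, geo, method, 999, SEED + k)
            rows.append({"k": k, "method": method, "r2": round(res.r2, 4),
                         "p": res.p, "partial_r2": round(part.r2, 4),
                         "partial_p": part.p})
            (pr2 if method == "pearson" else kr2).append(res.r2)
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "mantel.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    k_star = select_n_barriers(pr2, kr2)
    print(f"scree rule retains {k_star} barriers")


if __name__ == "__main__":
    main()
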