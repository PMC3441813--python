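"""Integration of the RH map with the genetic linkage map.

Anchors each ordered RH group to a linkage group through shared
microsatellites, detects LG merges supported by two anchors on each side,
assembles each chromosome (group order by mean cM, orientation by anchor
rank correlation or end-marker LOD) and compares marker orders between
the maps. Writes results/assembly.tsv.
"""

import sys
from pathlib import Path

import pandas as pd  # noqa: F401

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import default_world, ensure_dirs, make_parser  # noqa: E402

from radmap import (anchor_groups,  # noqa: E402
                    assemble_chromosome, chromosome_partition,
                    compare_orders, detect_lg_merges)
from radmap.linkage import TwoPointEstimate  # noqa: E402
from radmap import io as rio  # noqa: E402


def main() -> None:
    args = make_parser(__doc__).parse_args()
    out, data = ensure_dirs(args.out)
    ds = default_world(args.seed)
    gmap = rio.read_genetic_map(data / "genetic_map.tsv")
    maps = rio.read_map_objects(out / "rh_map.tsv")
    tp = rio.read_two_point(out / "two_point.tsv")
    estimates = [TwoPointEstimate(r.marker_a, r.marker_b, r.theta,
                                  r.retention, r.lod, int(r.n), r.cr)
                 for r in tp.itertuples(index=False)]

    assignments = anchor_groups(maps, gmap)
    merges = detect_lg_merges(assignments)
    chromosomes, orphans = chromosome_partition(assignments, merges)
    print(f"{len(maps)} groups anchored to {len(chromosomes)} chromosomes; "
          f"{len(orphans)} orphan groups")
    for s in merges:
        print(f"  LG merge detected: {sorted(s)} behave as one chromosome")

    by_id = {m.group_id: m for m in maps}
    rows = []
    for chrom, gids in sorted(chromosomes.items()):
        lgs = sorted({assignments[i].lg for i, m in enumerate(maps)
                      if m.group_id in gids and assignments[i].lg})
        asm = assemble_chromosome(chrom, lgs, [by_id[g] for g in gids],
                                  gmap, estimates)
        rh_order = []
        for og in asm.groups:
            markers = by_id[og.group_id].markers
            rh_order.extend(reversed(markers) if og.flipped else markers)
            rows.append((chrom, og.group_id, og.flipped, og.oriented,
                         og.evidence))
        rep = compare_orders(rh_order, gmap, lgs)
        print(f"{chrom}: {len(asm.groups)} groups, shared markers "
              f"{rep['n_shared']}, LCS {rep['lcs']}, "
              f"{len(rep['inversions'])} locally inverted pairs")
        for c in asm.conflicts:
            print(f"  conflict: {c}")
    pd.DataFrame(rows, columns=["chromosome", "group", "flipped",
                                "oriented", "evidence"]).to_csv(
        out / "assembly.tsv", sep="\t", index=False)
    print(f"assembly written to {out / 'assembly.tsv'}")


if __name__ == "__main__":
    main()
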