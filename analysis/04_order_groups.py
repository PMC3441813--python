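"""Multipoint ordering of each RH group into a centiray map.

Reads groups.tsv and the vector file, searches the marker order of every
group under the retention-chain likelihood, merges co-localized markers,
and writes results/rh_map.tsv plus a GMOD CMap export. Reports order
correctness against the simulated truth (up to reversal and co-localized
permutations).
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import default_world, ensure_dirs, make_parser  # noqa: E402

from radmap import search_order  # noqa: E402
from radmap import io as rio  # noqa: E402
from radmap.evaluate import order_matches_truth  # noqa: E402


def main() -> None:
    args = make_parser(__doc__).parse_args()
    out, data = ensure_dirs(args.out)
    ds = default_world(args.seed)
    matrix = rio.read_vectors(data / "vectors.txt")
    gdf = pd.read_csv(out / "groups.tsv", sep="\t", comment="#")

    maps = []
    n_correct = n_checked = 0
    for gid, grp in gdf[gdf["group"] != "unlinked"].groupby("group",
                                                            sort=True):
        markers = grp["marker"].tolist()
        ogm = search_order(markers, matrix, group_id=gid, seed=args.seed,
                           n_restarts=10)
        maps.append(ogm)
        truth = next((order for order in ds.truth_order.values()
                      if set(markers) <= set(order)), None)
        verdict = ""
        if truth is not None:
            truth_sub = [m for m in truth if m in set(markers)]
            n_checked += 1
            ok = order_matches_truth(
                ogm.markers, truth_sub, matrix.subset_markers(markers))
            n_correct += ok
            verdict = " (true order recovered)" if ok else \
                " (differs from truth)"
        n_coloc = sum(1 for _, ms in ogm.positions if len(ms) > 1)
        print(f"{gid}: {len(ogm.markers)} markers, "
              f"{len(ogm.positions)} positions ({n_coloc} co-localized), "
              f"{ogm.length_cr:.1f} cR{verdict}")

    rio.write_map(maps, out / "rh_map.tsv")
    rio.write_cmap(maps, out / "cmap_export.tsv")
    if n_checked:
        print(f"{n_correct}/{n_checked} groups match the simulated order "
              "up to reversal and co-localized permutations")
        print("(mismatches are maximum-likelihood local flips of nearly "
              "co-retained markers -- at 190 clones such orders score at "
              "least as well as the truth; see docs/methods.md)")
    print(f"map written to {out / 'rh_map.tsv'}")


if __name__ == "__main__":
    main()
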