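"""Generate the synthetic RH world: panel vectors, genetic map, ortholog
hits and truth files.

Writes under results/data/: the RH vector file, the microsatellite genetic
map, aligner-style ortholog hit tables for four model species, and the
truth fragment intervals, all regenerable from the seed.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import default_world, ensure_dirs, make_parser  # noqa: E402

from radmap import io as rio  # noqa: E402


def main() -> None:
    args = make_parser(__doc__).parse_args()
    out, data = ensure_dirs(args.out)
    ds = default_world(args.seed)

    rio.write_vectors(ds.call_matrix, data / "vectors.txt")
    rio.write_genetic_map(ds.genetic_map, data / "genetic_map.tsv")
    rio.write_hits(ds.hit_tables, data / "hits.tsv")
    rio.write_fragments(ds.truth_fragments, data / "fragments.tsv")

    m = ds.call_matrix
    n_ms = int((ds.genome.marker_positions()["class"]
                == "microsatellite").sum())
    print(f"simulated {m.n_markers} markers ({n_ms} microsatellites) on "
          f"{ds.config.n_chromosomes} chromosomes, {m.n_clones} clones")
    print(f"panel presence fraction {m.presence_fraction():.3f} "
          f"(target retention {ds.config.retention_rate})")
    print(f"ortholog hits written for "
          f"{ds.hit_tables['species'].nunique()} model species "
          f"({len(ds.hit_tables)} hits)")
    print(f"outputs under {data}")


if __name__ == "__main__":
    main()
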