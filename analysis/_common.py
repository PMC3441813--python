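"""Shared plumbing for the numbered analysis scripts.

Every script regenerates the same deterministic synthetic world from the
run seed (cheap), then exchanges results with its neighbours through the
tab-delimited files under results/. The default world mirrors the mapped
panel this project models: 190 hybrid clones, 11.7% retention, 27.5 kb/cR,
840 kb/cM, one marker per ~800 kb, four model species with small
rearrangement recipes and realistic missing-ortholog rates.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from radmap import SimulationConfig, simulate_dataset

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"


def default_config(seed: int) -> SimulationConfig:
    return SimulationConfig(seed=seed)


def default_world(seed: int):
    return simulate_dataset(default_config(seed))


def make_parser(description: str) -> argparse.ArgumentParser:
    p = argparse.ArgumentParser(description=description)
    p.add_argument("--seed", type=int, default=0,
                   help="seed for the synthetic world (default 0)")
    p.add_argument("--out", type=Path, default=RESULTS,
                   help="results directory (default ./results)")
    return p


def ensure_dirs(out: Path) -> tuple[Path, Path]:
    data = out / "data"
    data.mkdir(parents=True, exist_ok=True)
    return out, data
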