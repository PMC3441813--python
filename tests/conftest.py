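import numpy as np
import pytest

from radmap import SimulationConfig, simulate_dataset, simulate_panel
from radmap.simulate import Chromosome, TrueGenome

NOISE_FREE = dict(false_positive_rate=0.0, false_negative_rate=0.0,
                  ambiguous_rate=0.0)


def controlled_genome(n_markers: int, gaps_cr, kb_per_cr: float = 27.5,
                      name: str = "chrA", offset_kb: float = 500.0
                      ) -> TrueGenome:
    """A single-chromosome genome with prescribed inter-marker gaps (cR)."""
    gaps_cr = np.asarray(gaps_cr, dtype=float)
    assert len(gaps_cr) == n_markers - 1
    pos = np.concatenate(([offset_kb],
                          offset_kb + np.cumsum(gaps_cr * kb_per_cr)))
    markers = [f"{name}_M{j + 1:02d}" for j in range(n_markers)]
    return TrueGenome([Chromosome(name, markers, pos, ["gene"] * n_markers)])


def controlled_panel(n_markers: int, gaps_cr, seed: int, n_clones: int = 190,
                     **noise):
    """Noise-free (unless overridden) panel over a controlled genome."""
    genome = controlled_genome(n_markers, gaps_cr)
    params = {**NOISE_FREE, **noise}
    cfg = SimulationConfig(
        n_chromosomes=1, markers_per_chromosome=n_markers,
        chromosome_length_kb=float(genome.chromosomes[0].positions_kb[-1]
                                   + 500.0),
        n_clones=n_clones, seed=seed, **params)
    matrix, fragments = simulate_panel(genome, cfg)
    return genome, matrix, fragments


def controlled_multi_panel(n_chromosomes: int, n_markers: int,
                           gap_range_cr: tuple[float, float], seed: int,
                           n_clones: int = 190, kb_per_cr: float = 27.5,
                           **noise):
    """Multi-chromosome panel with gaps drawn inside a prescribed cR range
    (the regime where grouping and ordering are statistically resolvable)."""
    rng = np.random.default_rng(100_000 + seed)
    chroms = []
    max_pos = 0.0
    for ci in range(n_chromosomes):
        gaps = rng.uniform(*gap_range_cr, size=n_markers - 1)
        pos = np.concatenate(([500.0], 500.0 + np.cumsum(gaps * kb_per_cr)))
        name = f"chr{ci + 1:02d}"
        chroms.append(Chromosome(
            name, [f"{name}_M{j + 1:02d}" for j in range(n_markers)], pos,
            ["gene"] * n_markers))
        max_pos = max(max_pos, float(pos[-1]))
    genome = TrueGenome(chroms)
    params = {**NOISE_FREE, **noise}
    cfg = SimulationConfig(
        n_chromosomes=n_chromosomes, markers_per_chromosome=n_markers,
        chromosome_length_kb=max_pos + 500.0, n_clones=n_clones,
        seed=seed, **params)
    matrix, fragments = simulate_panel(genome, cfg)
    return genome, matrix, fragments


@pytest.fixture(scope="session")
def clean_dataset():
    """Two chromosomes, 12 markers each, noise-free, 190 clones."""
    cfg = SimulationConfig(n_chromosomes=2, markers_per_chromosome=12,
                           chromosome_length_kb=8000.0, seed=3,
                           microsatellite_fraction=0.35, **NOISE_FREE)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default noise levels (fp 0.005, fn 0.01, ambiguous 0.02)."""
    cfg = SimulationConfig(n_chromosomes=2, markers_per_chromosome=12,
                           chromosome_length_kb=8000.0, seed=5,
                           microsatellite_fraction=0.35)
    return simulate_dataset(cfg)
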