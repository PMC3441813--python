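"""Synthetic radiation-hybrid worlds with known ground truth.

The generator emulates the construction of a whole-genome RH panel from a
gamma-irradiated donor genome: chromosome breakage is a homogeneous Poisson
process whose rate is calibrated so that the breakage probability between
two markers ``d`` kb apart is ``theta = 1 - exp(-d / (100 * kb_per_cr))``,
i.e. distances come out directly in centirays; each fragment is retained in
a hybrid clone independently with the panel retention probability. On top
of the true presence/absence lattice, genotyping noise flips calls and an
ambiguity process blanks them to the '2' code.

Alongside the panel the generator produces a meiotic (genetic) map over the
microsatellite subset, with cM proportional to physical kb, and model-species
"genomes" derived from the true marker order by chromosome fusions, fissions,
reciprocal translocations and segment inversions plus a per-species
missing-ortholog dropout, written as aligner-style ortholog hit tables.
Every stochastic choice draws from an independent seeded substream, so a
given (config, seed) pair reproduces byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .matrix import ABSENT, AMBIGUOUS, PRESENT, RHCallMatrix

# Fixed spawn keys for the independent random substreams.
_STREAM_GENOME = 0
_STREAM_BREAKS = 1
_STREAM_RETAIN = 2
_STREAM_FP = 3
_STREAM_FN = 4
_STREAM_AMB = 5
_STREAM_SPECIES = 6
_STREAM_GENMAP = 7
_STREAM_INTENSITY = 8

#: Class mix of the non-microsatellite markers (gene, BAC-end, SNP),
#: mirroring the composition of a typical RH marker panel.
_NON_MS_CLASSES = ("gene", "BAC-end", "SNP")
_NON_MS_PROBS = (0.706, 0.068, 0.226)


@dataclass(frozen=True)
class SpeciesSpec:
    """Rearrangement recipe for one model species.

    ``missing_ortholog_rate`` is the probability that a marker has no
    detectable ortholog in this species at all.
    """

    name: str
    n_fusions: int = 0
    n_fissions: int = 0
    n_translocations: int = 0
    n_inversions: int = 0
    missing_ortholog_rate: float = 0.0


def default_species_specs() -> list[SpeciesSpec]:
    """Four model species with small rearrangement recipes.

    Missing-ortholog rates mirror the per-species anchor recovery of
    percomorph comparative maps (a close relative like stickleback keeps
    ~78% of anchors, a distant outgroup like zebrafish ~53%).
    """
    return [
        SpeciesSpec("stickleback", n_fusions=1, n_fissions=1,
                    n_inversions=3, missing_ortholog_rate=0.22),
        SpeciesSpec("medaka", n_fissions=1, n_inversions=2,
                    missing_ortholog_rate=0.26),
        SpeciesSpec("pufferfish", n_translocations=1, n_inversions=2,
                    missing_ortholog_rate=0.31),
        SpeciesSpec("zebrafish", n_translocations=2, n_inversions=4,
                    missing_ortholog_rate=0.47),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated RH world.

    Defaults follow the panel this package models: 190 hybrid clones, a
    cumulative retention of 0.117, 27.5 kb per cR(3500) and 840 kb per cM.
    Marker density defaults to one marker per 800 kb (about 29 cR between
    neighbours), matching a ~1400-marker map of a ~1.1 Gb genome.
    """

    n_chromosomes: int = 4
    markers_per_chromosome: int | tuple[int, ...] = 40
    chromosome_length_kb: float = 32_000.0
    retention_rate: float = 0.117
    kb_per_cr: float = 27.5
    kb_per_cm: float = 840.0
    n_clones: int = 190
    false_positive_rate: float = 0.005
    false_negative_rate: float = 0.01
    ambiguous_rate: float = 0.02
    microsatellite_fraction: float = 0.11
    jitter_cm: float = 0.0
    split_chromosome: str | None = None
    species_specs: tuple[SpeciesSpec, ...] = field(
        default_factory=lambda: tuple(default_species_specs()))
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "species_specs", tuple(self.species_specs))
        if isinstance(self.markers_per_chromosome, (list, np.ndarray)):
            object.__setattr__(self, "markers_per_chromosome",
                               tuple(int(m) for m in self.markers_per_chromosome))

    def marker_counts(self) -> list[int]:
        m = self.markers_per_chromosome
        if isinstance(m, tuple):
            if len(m) != self.n_chromosomes:
                raise ConfigError("markers_per_chromosome list length must "
                                  "equal n_chromosomes")
            return [int(x) for x in m]
        return [int(m)] * self.n_chromosomes

    def validate(self) -> None:
        if self.n_chromosomes < 1:
            raise ConfigError("need at least one chromosome")
        if any(m < 1 for m in self.marker_counts()):
            raise ConfigError("need at least one marker per chromosome")
        if self.chromosome_length_kb <= 0:
            raise ConfigError("chromosome_length_kb must be positive")
        if self.kb_per_cr <= 0 or self.kb_per_cm <= 0:
            raise ConfigError("kb_per_cr and kb_per_cm must be positive")
        if self.n_clones < 1:
            raise ConfigError("n_clones must be at least 1")
        for name, p in (("retention_rate", self.retention_rate),
                        ("false_positive_rate", self.false_positive_rate),
                        ("false_negative_rate", self.false_negative_rate),
                        ("ambiguous_rate", self.ambiguous_rate),
                        ("microsatellite_fraction",
                         self.microsatellite_fraction)):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {p}")
        for spec in self.species_specs:
            if not 0.0 <= spec.missing_ortholog_rate <= 1.0:
                raise ConfigError(
                    f"missing_ortholog_rate for {spec.name} not in [0, 1]")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    ss = np.random.SeedSequence(config.seed, spawn_key=(stream,))
    return np.random.default_rng(ss)


@dataclass
class Chromosome:
    name: str
    markers: list[str]
    positions_kb: np.ndarray
    classes: list[str]


@dataclass
class TrueGenome:
    """The donor genome the simulated panel samples: ordered markers with
    kb positions and marker classes."""

    chromosomes: list[Chromosome]

    def marker_positions(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chromosomes:
            for m, pos, cls in zip(chrom.markers, chrom.positions_kb,
                                   chrom.classes):
                rows.append((chrom.name, m, float(pos), cls))
        return pd.DataFrame(rows, columns=["chrom", "marker", "pos_kb",
                                           "class"])

    def all_markers(self) -> list[str]:
        return [m for c in self.chromosomes for m in c.markers]

    def truth_order(self) -> dict[str, list[str]]:
        return {c.name: list(c.markers) for c in self.chromosomes}


@dataclass
class SimulatedDataset:
    """A full synthetic world: panel calls plus every layer of truth."""

    config: SimulationConfig
    genome: TrueGenome
    call_matrix: RHCallMatrix
    truth_fragments: pd.DataFrame        # chrom, start_kb, end_kb, clone
    genetic_map: pd.DataFrame            # lg, marker, cm
    hit_tables: pd.DataFrame             # aligner-style ortholog hits
    truth_synteny: dict                  # per-species truth (see below)
    truth_order: dict[str, list[str]]


def simulate_genome(config: SimulationConfig) -> TrueGenome:
    """Place markers uniformly at random along each chromosome.

    Positions are sorted and made strictly increasing; the configured
    fraction of markers (rounded per chromosome) is classed microsatellite,
    the rest split among gene / BAC-end / SNP classes.
    """
    config.validate()
    rng = _rng(config, _STREAM_GENOME)
    chromosomes = []
    for ci, n_markers in enumerate(config.marker_counts()):
        name = f"chr{ci + 1:02d}"
        pos = np.sort(rng.uniform(0.0, config.chromosome_length_kb,
                                  size=n_markers))
        # enforce strictly increasing positions (ties are measure-zero but
        # would break downstream ordering invariants)
        for j in range(1, n_markers):
            if pos[j] <= pos[j - 1]:
                pos[j] = pos[j - 1] + 1e-6
        markers = [f"{name}_M{j + 1:03d}" for j in range(n_markers)]
        n_ms = int(round(config.microsatellite_fraction * n_markers))
        ms_idx = set(rng.choice(n_markers, size=n_ms, replace=False).tolist())
        classes = []
        for j in range(n_markers):
            if j in ms_idx:
                classes.append("microsatellite")
            else:
                classes.append(str(rng.choice(_NON_MS_CLASSES,
                                              p=_NON_MS_PROBS)))
        chromosomes.append(Chromosome(name, markers, pos, classes))
    return TrueGenome(chromosomes)


def simulate_panel(genome: TrueGenome, config: SimulationConfig
                   ) -> tuple[RHCallMatrix, pd.DataFrame]:
    """Irradiate, retain, and genotype: the donor genome becomes a panel.

    Returns the noisy call matrix and the per-clone truth fragments
    (retained intervals in kb). Breakage is a Poisson process with rate
    ``1 / (100 * kb_per_cr)`` per kb; each fragment is retained
    independently with ``retention_rate``. The diploid donor is treated as
    haploid-equivalent (one fragment lattice per chromosome), the standard
    RH approximation for presence/absence genotyping.
    """
    config.validate()
    if not genome.chromosomes:
        raise ConfigError("genome has no chromosomes")
    rng_b = _rng(config, _STREAM_BREAKS)
    rng_r = _rng(config, _STREAM_RETAIN)
    rate = 1.0 / (100.0 * config.kb_per_cr)
    clones = [f"CL{i + 1:03d}" for i in range(config.n_clones)]
    calls_cols = []
    frag_rows = []
    for chrom in genome.chromosomes:
        L = config.chromosome_length_kb
        pos = chrom.positions_kb
        chrom_calls = np.zeros((config.n_clones, len(pos)), dtype=np.int8)
        n_breaks = rng_b.poisson(rate * L, size=config.n_clones)
        for i, clone in enumerate(clones):
            breaks = np.sort(rng_b.uniform(0.0, L, size=n_breaks[i]))
            bounds = np.concatenate(([0.0], breaks, [L]))
            retained = rng_r.random(len(bounds) - 1) < config.retention_rate
            # fragment index of each marker
            frag_of = np.searchsorted(bounds, pos, side="right") - 1
            frag_of = np.clip(frag_of, 0, len(retained) - 1)
            chrom_calls[i, :] = retained[frag_of]
            for k in np.nonzero(retained)[0]:
                frag_rows.append((chrom.name, float(bounds[k]),
                                  float(bounds[k + 1]), clone))
        calls_cols.append(chrom_calls)
    calls = np.concatenate(calls_cols, axis=1)
    markers = genome.all_markers()

    # noise: false negatives on true presents, false positives on true
    # absents, then uniform ambiguity blanking; independent substreams.
    true_calls = calls.copy()
    if config.false_negative_rate > 0:
        rng_fn = _rng(config, _STREAM_FN)
        flip = (true_calls == PRESENT) & (rng_fn.random(calls.shape)
                                          < config.false_negative_rate)
        calls[flip] = ABSENT
    if config.false_positive_rate > 0:
        rng_fp = _rng(config, _STREAM_FP)
        flip = (true_calls == ABSENT) & (rng_fp.random(calls.shape)
                                         < config.false_positive_rate)
        calls[flip] = PRESENT
    if config.ambiguous_rate > 0:
        rng_amb = _rng(config, _STREAM_AMB)
        blank = rng_amb.random(calls.shape) < config.ambiguous_rate
        calls[blank] = AMBIGUOUS

    fragments = pd.DataFrame(frag_rows, columns=["chrom", "start_kb",
                                                 "end_kb", "clone"])
    return RHCallMatrix(clones, markers, calls), fragments


def simulate_genetic_map(genome: TrueGenome, config: SimulationConfig
                         ) -> pd.DataFrame:
    """A meiotic map over the microsatellite subset.

    cM positions are kb / kb_per_cm plus optional Gaussian jitter; each
    chromosome becomes one linkage group, except ``split_chromosome`` whose
    microsatellites get two LG labels (split at the chromosome midpoint) to
    create a mergeable-LG test case.
    """
    config.validate()
    rng = _rng(config, _STREAM_GENMAP)
    rows = []
    for ci, chrom in enumerate(genome.chromosomes):
        lg = f"LG{ci + 1}"
        for m, pos, cls in zip(chrom.markers, chrom.positions_kb,
                               chrom.classes):
            if cls != "microsatellite":
                continue
            cm = pos / config.kb_per_cm
            if config.jitter_cm > 0:
                cm = max(0.0, cm + rng.normal(0.0, config.jitter_cm))
            if config.split_chromosome == chrom.name:
                half = config.chromosome_length_kb / 2.0
                label = f"{lg}a" if pos < half else f"{lg}b"
            else:
                label = lg
            rows.append((label, m, float(cm)))
    if not rows:
        warnings.warn("genome has no microsatellite markers; "
                      "genetic map is empty")
    return pd.DataFrame(rows, columns=["lg", "marker", "cm"])


# ---------------------------------------------------------------------------
# model-species rearrangement machinery
# ---------------------------------------------------------------------------

def _apply_rearrangements(order: list[list[str]], spec: SpeciesSpec,
                          rng: np.random.Generator):
    """Apply the recipe to a list of chromosomes (lists of marker ids).

    Returns the rearranged chromosome list and the event log. Events are
    drawn uniformly among feasible choices; infeasible recipes (e.g. more
    fusions than chromosome pairs) raise ConfigError.
    """
    chroms = [list(c) for c in order]
    events = []

    for _ in range(spec.n_fissions):
        eligible = [i for i, c in enumerate(chroms) if len(c) >= 2]
        if not eligible:
            raise ConfigError(f"{spec.name}: no chromosome left to fission")
        i = int(rng.choice(eligible))
        cut = int(rng.integers(1, len(chroms[i])))
        left, right = chroms[i][:cut], chroms[i][cut:]
        events.append(("fission", chroms[i][cut - 1], chroms[i][cut]))
        chroms[i] = left
        chroms.append(right)

    for _ in range(spec.n_fusions):
        if len(chroms) < 2:
            raise ConfigError(f"{spec.name}: fewer than 2 chromosomes, "
                              "cannot fuse")
        i, j = rng.choice(len(chroms), size=2, replace=False)
        i, j = int(i), int(j)
        events.append(("fusion", chroms[i][-1], chroms[j][0]))
        chroms[i] = chroms[i] + chroms[j]
        del chroms[j]

    for _ in range(spec.n_translocations):
        eligible = [i for i, c in enumerate(chroms) if len(c) >= 2]
        if len(eligible) < 2:
            raise ConfigError(f"{spec.name}: need two chromosomes of >= 2 "
                              "markers for a reciprocal translocation")
        i, j = rng.choice(eligible, size=2, replace=False)
        i, j = int(i), int(j)
        ci, cj = chroms[i], chroms[j]
        cut_i = int(rng.integers(1, len(ci)))
        cut_j = int(rng.integers(1, len(cj)))
        events.append(("translocation", ci[cut_i - 1], ci[cut_i],
                       cj[cut_j - 1], cj[cut_j]))
        chroms[i] = ci[:cut_i] + cj[cut_j:]
        chroms[j] = cj[:cut_j] + ci[cut_i:]

    for _ in range(spec.n_inversions):
        eligible = [i for i, c in enumerate(chroms) if len(c) >= 2]
        if not eligible:
            raise ConfigError(f"{spec.name}: no chromosome of >= 2 markers "
                              "for an inversion")
        i = int(rng.choice(eligible))
        c = chroms[i]
        start = int(rng.integers(0, len(c) - 1))
        stop = int(rng.integers(start + 2, len(c) + 1))  # at least 2 markers
        events.append(("inversion", tuple(c[start:stop])))
        chroms[i] = c[:start] + c[start:stop][::-1] + c[stop:]

    return chroms, events


def _species_prefix(name: str) -> str:
    return name[:3].upper()


def simulate_model_species(genome: TrueGenome, config: SimulationConfig
                           ) -> tuple[pd.DataFrame, dict]:
    """Derive model-species genomes and emit aligner-style hit tables.

    Each species starts from the true marker order, suffers the configured
    fusions / fissions / reciprocal translocations / inversions, then loses
    each ortholog independently with its missing rate. Hits carry scores and
    alignment lengths that pass the default comparative filters, so filter
    behaviour is exercised by dedicated tests, not by the simulator.

    The returned truth dict maps species name to a dict with:

    ``events``
        the event log (kind plus flanking/contained marker ids),
    ``location``
        marker -> (model chromosome, bp midpoint) after dropout,
    ``cs_truth``
        per donor chromosome, the expected conserved-segment decomposition:
        a list of (model chromosome, [marker ids]) runs in donor order,
    ``inversion_spans``
        the marker tuples that were reversed, for breakpoint checks.
    """
    config.validate()
    if not config.species_specs:
        raise ConfigError("species_specs is empty")
    rng = _rng(config, _STREAM_SPECIES)
    spacing_bp = 100_000
    hit_rows = []
    truth: dict[str, dict] = {}
    donor_order = [list(c.markers) for c in genome.chromosomes]
    donor_chrom_of = {m: c.name for c in genome.chromosomes
                      for m in c.markers}

    for spec in config.species_specs:
        chroms, events = _apply_rearrangements(donor_order, spec, rng)
        prefix = _species_prefix(spec.name)
        # assign model coordinates: evenly spaced with small jitter
        location = {}
        for k, markers in enumerate(chroms):
            mchrom = f"{prefix}{k + 1:02d}"
            for idx, m in enumerate(markers):
                start = (idx + 1) * spacing_bp + int(rng.integers(0, 1000))
                location[m] = (mchrom, start)
        # ortholog dropout
        kept = {}
        for m, loc in location.items():
            if rng.random() >= spec.missing_ortholog_rate:
                kept[m] = loc
        for m, (mchrom, start) in kept.items():
            length = int(rng.integers(80, 301))
            score = int(rng.integers(250, 600))
            hit_rows.append((m, spec.name, mchrom, start, start + length,
                             score, length, "+"))
        # conserved-segment truth: donor-order runs by model chromosome
        cs_truth = {}
        for chrom in genome.chromosomes:
            runs = []
            for m in chrom.markers:
                if m not in kept:
                    continue
                mchrom = kept[m][0]
                if runs and runs[-1][0] == mchrom:
                    runs[-1][1].append(m)
                else:
                    runs.append((mchrom, [m]))
            cs_truth[chrom.name] = [(mc, list(ms)) for mc, ms in runs]
        truth[spec.name] = {
            "events": events,
            "location": kept,
            "cs_truth": cs_truth,
            "inversion_spans": [ev[1] for ev in events
                                if ev[0] == "inversion"],
            "donor_chrom_of": donor_chrom_of,
        }

    hits = pd.DataFrame(hit_rows, columns=["marker", "species", "chromosome",
                                           "start", "end", "score", "length",
                                           "strand"])
    return hits, truth


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run every generator stage and bundle the results with their truth."""
    genome = simulate_genome(config)
    call_matrix, fragments = simulate_panel(genome, config)
    gmap = simulate_genetic_map(genome, config)
    hits, truth_synteny = simulate_model_species(genome, config)
    return SimulatedDataset(
        config=config, genome=genome, call_matrix=call_matrix,
        truth_fragments=fragments, genetic_map=gmap, hit_tables=hits,
        truth_synteny=truth_synteny, truth_order=genome.truth_order())


def simulate_intensities(matrix: RHCallMatrix, config: SimulationConfig,
                         threshold: float = 0.30,
                         present_mu: float = 0.75, present_sd: float = 0.08,
                         absent_mu: float = 0.07, absent_sd: float = 0.035,
                         x_axis_fraction: float = 0.1) -> pd.DataFrame:
    """Two-cluster fluorescence mixture consistent with a call matrix.

    Present calls emit high signal on the marker's scoring axis, absent
    calls low signal, and ambiguous calls signal right at the threshold.
    A fraction of markers score on the x axis (the rest on y), mirroring
    per-marker axis choice in bead-array genotyping. Returns a long table
    (marker, clone, x, y) plus a per-marker ``axis`` column.
    """
    rng = _rng(config, _STREAM_INTENSITY)
    rows = []
    for j, marker in enumerate(matrix.markers):
        axis = "x" if rng.random() < x_axis_fraction else "y"
        for i, clone in enumerate(matrix.clones):
            call = matrix.calls[i, j]
            if call == PRESENT:
                v = rng.normal(present_mu, present_sd)
            elif call == ABSENT:
                v = rng.normal(absent_mu, absent_sd)
            else:
                v = rng.normal(threshold, 0.01)
            v = max(0.0, v)
            off = abs(rng.normal(0.08, 0.04))
            x, y = (v, off) if axis == "x" else (off, v)
            rows.append((marker, clone, x, y, axis))
    return pd.DataFrame(rows, columns=["marker", "clone", "x", "y", "axis"])
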