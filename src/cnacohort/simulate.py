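"""Seeded synthetic SNP-array cohorts with known planted copy-number alterations.

The simulator emulates a ~10,000-probe genome-wide genotyping array applied
to a case cohort split into an exposed and an unexposed tumor group plus a
pool of germline reference arrays.  Probe signal is linear in underlying
copy number on the raw scale, with multiplicative probe-affinity, per-array
scale and measurement-noise factors, so that the downstream
``copies = 2 x tumor/reference`` convention inverts the forward model
exactly in the noise-free limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUP_EXPOSED = "exposed"
GROUP_UNEXPOSED = "unexposed"
GROUP_REFERENCE = "reference"
GROUPS = (GROUP_EXPOSED, GROUP_UNEXPOSED, GROUP_REFERENCE)

#: Approximate lengths (bp) of human chromosomes 1-22 and X, the genome the
#: 10K array tiles.  Rounded to the nearest Mb; used only to allocate probes.
DEFAULT_CHROM_LENGTHS: dict[str, int] = {
    "1": 245_000_000, "2": 243_000_000, "3": 199_000_000, "4": 191_000_000,
    "5": 181_000_000, "6": 171_000_000, "7": 158_000_000, "8": 146_000_000,
    "9": 138_000_000, "10": 135_000_000, "11": 134_000_000, "12": 132_000_000,
    "13": 114_000_000, "14": 106_000_000, "15": 100_000_000, "16": 89_000_000,
    "17": 79_000_000, "18": 76_000_000, "19": 64_000_000, "20": 62_000_000,
    "21": 47_000_000, "22": 49_000_000, "X": 155_000_000,
}

DEFAULT_N_PROBES = 10_000
DEFAULT_COHORT_SIZES = {GROUP_EXPOSED: 26, GROUP_UNEXPOSED: 17, GROUP_REFERENCE: 14}


@dataclass(frozen=True)
class PlantedSegment:
    """A ground-truth altered interval carried with group-specific frequency.

    ``true_copies`` is the integer copy number carriers receive over every
    probe inside ``[start_pos, end_pos]`` (1-based, closed); non-carriers and
    reference samples stay diploid.
    """

    chrom: str
    start_pos: int
    end_pos: int
    true_copies: int
    carrier_freq_exposed: float
    carrier_freq_unexposed: float

    def __post_init__(self) -> None:
        if self.start_pos > self.end_pos:
            raise ValueError(f"start_pos {self.start_pos} > end_pos {self.end_pos}")
        if not (0 <= self.true_copies <= 5) or self.true_copies == 2:
            raise ValueError("true_copies must be in 0..5 and not the diploid 2")
        for f in (self.carrier_freq_exposed, self.carrier_freq_unexposed):
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"carrier frequency {f} outside [0, 1]")


#: Default planted segments: four gain regions whose carrier frequencies
#: mirror the strongest exposure-differential contrasts of the motivating
#: betel-quid breast-cancer cohort (gains in 16/26 vs 3/17, 15/26 vs 3/17,
#: 3/26 vs 9/17 and 1/26 vs 8/17 of exposed vs unexposed tumors).
DEFAULT_SEGMENTS: tuple[PlantedSegment, ...] = (
    PlantedSegment("7", 133_281_372, 135_010_987, 3, 16 / 26, 3 / 17),
    PlantedSegment("21", 37_974_454, 40_484_883, 3, 15 / 26, 3 / 17),
    PlantedSegment("19", 3_542_590, 17_471_210, 3, 3 / 26, 9 / 17),
    PlantedSegment("20", 31_982_015, 35_933_409, 3, 1 / 26, 8 / 17),
)


@dataclass(frozen=True)
class NoiseParams:
    """Multiplicative noise model for simulated probe intensities.

    All three sigmas act on the log scale: probe affinities are
    log-normal(0, affinity_sigma^2), per-array scale factors
    log-normal(0, array_scale_sigma^2), and every measurement carries an
    independent log-normal(0, noise_sigma^2) error.
    """

    affinity_sigma: float = 0.25
    array_scale_sigma: float = 0.3
    noise_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for s in (self.affinity_sigma, self.array_scale_sigma, self.noise_sigma):
            if s < 0:
                raise ValueError(f"noise sigma must be >= 0, got {s}")


#: Relative emission level of a homozygously deleted locus (true copies 0).
#: Residual signal keeps intensities positive and the log domain regular.
ZERO_COPY_LEVEL = 0.05


def make_design(
    n_exposed: int = 26, n_unexposed: int = 17, n_reference: int = 14
) -> pd.DataFrame:
    """Build a cohort design table (sample_id, group)."""
    if n_exposed < 1 or n_unexposed < 1:
        raise ValueError("need at least one tumor sample per group")
    if n_reference < 2:
        raise ValueError("need at least two reference samples")
    rows = (
        [(f"EXP{i + 1:02d}", GROUP_EXPOSED) for i in range(n_exposed)]
        + [(f"UNX{i + 1:02d}", GROUP_UNEXPOSED) for i in range(n_unexposed)]
        + [(f"REF{i + 1:02d}", GROUP_REFERENCE) for i in range(n_reference)]
    )
    return pd.DataFrame(rows, columns=["sample_id", "group"])


def _sample_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """Draw ``n`` distinct 1-based positions uniformly from ``1..length``."""
    if n > length:
        raise ValueError(f"cannot place {n} distinct probes on {length} bp")
    seen: dict[int, None] = {}
    while len(seen) < n:
        draw = rng.integers(1, length + 1, size=max(2 * (n - len(seen)), 16))
        for v in draw.tolist():
            if v not in seen:
                seen[v] = None
                if len(seen) == n:
                    break
    return np.sort(np.fromiter(seen.keys(), dtype=np.int64, count=n))


def generate_probe_map(
    n_probes: int = DEFAULT_N_PROBES,
    chrom_lengths: dict[str, int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate an ordered probe map (probe_id, chrom, pos).

    Probes are allocated to chromosomes proportionally to length using
    largest-remainder rounding, then placed uniformly at random without
    replacement within each chromosome and sorted.  Deterministic for a
    given seed.
    """
    if chrom_lengths is None:
        chrom_lengths = DEFAULT_CHROM_LENGTHS
    if not chrom_lengths:
        raise ValueError("chrom_lengths must not be empty")
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    for c, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {c!r} has non-positive length {length}")

    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    quota = n_probes * lengths / lengths.sum()
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    # Largest-remainder rounding; ties broken by chromosome order.
    for i in np.argsort(-remainder, kind="stable")[: n_probes - counts.sum()]:
        counts[i] += 1

    rng = np.random.default_rng(seed)
    frames = []
    offset = 0
    for chrom, k in zip(chroms, counts):
        if k == 0:
            continue
        pos = _sample_positions(rng, chrom_lengths[chrom], int(k))
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": [f"SNP{offset + j + 1:06d}" for j in range(int(k))],
                    "chrom": chrom,
                    "pos": pos,
                }
            )
        )
        offset += int(k)
    return pd.concat(frames, ignore_index=True)


def _segment_probe_mask(probe_map: pd.DataFrame, seg: PlantedSegment) -> np.ndarray:
    return (
        (probe_map["chrom"].to_numpy() == seg.chrom)
        & (probe_map["pos"].to_numpy() >= seg.start_pos)
        & (probe_map["pos"].to_numpy() <= seg.end_pos)
    )


def plant_alterations(
    probe_map: pd.DataFrame,
    design: pd.DataFrame,
    segments: list[PlantedSegment] | tuple[PlantedSegment, ...] = DEFAULT_SEGMENTS,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw carriers and build the ground-truth copy-number matrix.

    Every tumor sample independently carries each segment with its group's
    frequency; carriers receive ``true_copies`` over all probes inside the
    segment.  Overlapping segments resolve last-writer-wins in list order.
    Reference samples stay diploid everywhere.

    Returns a probes x samples integer DataFrame (index probe_id, columns
    sample_id).
    """
    rng = np.random.default_rng(seed)
    n_probes = len(probe_map)
    truth = pd.DataFrame(
        np.full((n_probes, len(design)), 2, dtype=np.int8),
        index=probe_map["probe_id"].to_numpy(),
        columns=design["sample_id"].to_numpy(),
    )
    groups = design.set_index("sample_id")["group"]
    for seg in segments:
        mask = _segment_probe_mask(probe_map, seg)
        if not mask.any():
            raise ValueError(
                f"planted segment {seg.chrom}:{seg.start_pos}-{seg.end_pos} "
                "covers no probe in the map"
            )
        for sample_id, group in groups.items():
            if group == GROUP_REFERENCE:
                continue
            freq = (
                seg.carrier_freq_exposed
                if group == GROUP_EXPOSED
                else seg.carrier_freq_unexposed
            )
            if rng.random() < freq:
                truth.loc[mask, sample_id] = seg.true_copies
    return truth


def simulate_intensities(
    probe_map: pd.DataFrame,
    truth: pd.DataFrame,
    params: NoiseParams = NoiseParams(),
) -> pd.DataFrame:
    """Emit probe intensities from ground truth under the multiplicative model.

    ``intensity(p, s) = affinity(p) * scale(s) * level(copies) * exp(eps)``
    with ``level = copies/2`` (and the small positive floor
    :data:`ZERO_COPY_LEVEL` for zero copies) and
    ``eps ~ Normal(0, noise_sigma^2)``.
    """
    if list(truth.index) != list(probe_map["probe_id"]):
        raise ValueError("truth matrix rows do not match the probe map")
    rng = np.random.default_rng(params.seed)
    n_probes, n_samples = truth.shape
    affinity = np.exp(rng.normal(0.0, params.affinity_sigma, size=n_probes))
    scale = np.exp(rng.normal(0.0, params.array_scale_sigma, size=n_samples))
    noise = np.exp(rng.normal(0.0, params.noise_sigma, size=(n_probes, n_samples)))
    copies = truth.to_numpy(dtype=float)
    level = np.where(copies == 0, ZERO_COPY_LEVEL, copies / 2.0)
    values = affinity[:, None] * scale[None, :] * level * noise
    return pd.DataFrame(values, index=truth.index, columns=truth.columns)


@dataclass
class SimulatedCohort:
    """A complete simulated study: map, design, ground truth and intensities."""

    probe_map: pd.DataFrame
    design: pd.DataFrame
    truth: pd.DataFrame
    intensities: pd.DataFrame
    segments: tuple[PlantedSegment, ...] = field(default_factory=tuple)


def simulate_cohort(
    seed: int = 0,
    n_probes: int = DEFAULT_N_PROBES,
    chrom_lengths: dict[str, int] | None = None,
    cohort_sizes: dict[str, int] | None = None,
    segments: list[PlantedSegment] | tuple[PlantedSegment, ...] = DEFAULT_SEGMENTS,
    noise: NoiseParams | None = None,
) -> SimulatedCohort:
    """Simulate a full cohort with the default study conditions.

    The single ``seed`` fans out to fixed child seeds for the probe map,
    the carrier draws and the intensity noise so that each stage is
    individually reproducible.
    """
    sizes = dict(DEFAULT_COHORT_SIZES)
    if cohort_sizes:
        sizes.update(cohort_sizes)
    probe_map = generate_probe_map(n_probes, chrom_lengths, seed=seed)
    design = make_design(
        sizes[GROUP_EXPOSED], sizes[GROUP_UNEXPOSED], sizes[GROUP_REFERENCE]
    )
    truth = plant_alterations(probe_map, design, segments, seed=seed + 1)
    if noise is None:
        noise = NoiseParams(seed=seed + 2)
    intensities = simulate_intensities(probe_map, truth, noise)
    return SimulatedCohort(probe_map, design, truth, intensities, tuple(segments))
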