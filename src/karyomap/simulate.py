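"""Simulators for truth maps, rearranged genomes, meioses and pedigree genotypes.

The crossover process is Poisson without interference, so Haldane's mapping
function is exact for the simulated data.  Female crossovers are uniform along
a chromosome; male crossovers are drawn from a piecewise-uniform density that
concentrates a configurable share of probability mass in the two terminal
windows, emulating strongly telomeric male recombination.

Positions are kept on the female-cM axis, which doubles as the "physical"
coordinate: a marker's male position is the male map length times the male
crossover CDF evaluated at the marker's relative female position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .karyotype import (
    ACROCENTRIC,
    FISSION,
    METACENTRIC,
    ROBERTSONIAN_FUSION,
    TANDEM_FUSION,
    WHOLE_ARM_TRANSLOCATION,
    Karyotype,
    RearrangementEvent,
    UnknownParticipantError,
    _composite_name,
    build_european_reference,
    north_american_events,
)
from .maptable import COLUMNS, LinkageMapTable

__all__ = [
    "TruthChromosome",
    "TruthMap",
    "PedigreeGenotypes",
    "Family",
    "FishCounts",
    "male_crossover_position_density",
    "male_crossover_cdf",
    "draw_crossovers",
    "simulate_truth_maps",
    "simulate_meiosis",
    "simulate_pedigree_genotypes",
    "simulate_fish_counts",
    "truth_to_map_table",
    "demo_rearrangement_panel",
]

MISSING = -1


# ---------------------------------------------------------------------------
# crossover position model
# ---------------------------------------------------------------------------

def _check_telomere_params(telomere_window: float, telomere_mass: float) -> None:
    if not 0.0 < telomere_window < 0.5:
        raise ValueError(f"telomere_window must be in (0, 0.5), got {telomere_window}")
    if not 0.5 <= telomere_mass <= 1.0:
        raise ValueError(f"telomere_mass must be in [0.5, 1], got {telomere_mass}")


def male_crossover_position_density(
    relative_position, telomere_window: float = 0.1, telomere_mass: float = 0.9
):
    """Piecewise-uniform crossover density on [0, 1].

    A probability mass of ``telomere_mass`` is spread uniformly over the two
    terminal windows of width ``telomere_window``; the remainder is uniform
    over the interior.  With ``telomere_mass == 2 * telomere_window`` the
    density degenerates to the uniform density.
    """
    _check_telomere_params(telomere_window, telomere_mass)
    x = np.asarray(relative_position, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("relative_position must lie in [0, 1]")
    telo = telomere_mass / (2.0 * telomere_window)
    interior = (1.0 - telomere_mass) / (1.0 - 2.0 * telomere_window)
    dens = np.where((x <= telomere_window) | (x >= 1.0 - telomere_window), telo, interior)
    return dens if dens.ndim else float(dens)


def male_crossover_cdf(
    relative_position, telomere_window: float = 0.1, telomere_mass: float = 0.9
):
    """CDF of :func:`male_crossover_position_density`."""
    _check_telomere_params(telomere_window, telomere_mass)
    x = np.asarray(relative_position, dtype=float)
    w, m = telomere_window, telomere_mass
    telo = m / (2.0 * w)
    interior = (1.0 - m) / (1.0 - 2.0 * w)
    out = np.where(
        x <= w,
        x * telo,
        np.where(x < 1.0 - w, m / 2.0 + (x - w) * interior, 1.0 - (1.0 - x) * telo),
    )
    return np.clip(out, 0.0, 1.0)


def _male_cdf_inverse(u, telomere_window: float, telomere_mass: float):
    w, m = telomere_window, telomere_mass
    telo = m / (2.0 * w)
    interior = (1.0 - m) / (1.0 - 2.0 * w)
    u = np.asarray(u, dtype=float)
    lo, hi = m / 2.0, 1.0 - m / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        mid = np.where(interior > 0, w + (u - lo) / interior, w)
    return np.where(u <= lo, u / telo, np.where(u < hi, mid, 1.0 - (1.0 - u) / telo))


def draw_crossovers(
    rng: np.random.Generator,
    map_length_cM: float,
    sex: str,
    telomere_window: float = 0.1,
    telomere_mass: float = 0.9,
) -> np.ndarray:
    """Relative crossover positions for one meiosis of one chromosome.

    The count is Poisson with mean ``map_length_cM / 100``; positions are
    uniform for females and follow the telomere-concentrated density for
    males.  Returned sorted, in [0, 1].
    """
    if map_length_cM < 0:
        raise ValueError("map length must be >= 0")
    n = rng.poisson(map_length_cM / 100.0)
    if n == 0:
        return np.empty(0)
    u = rng.random(n)
    if sex == "male":
        pos = _male_cdf_inverse(u, telomere_window, telomere_mass)
    elif sex == "female":
        pos = u
    else:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    return np.sort(pos)


# ---------------------------------------------------------------------------
# truth maps
# ---------------------------------------------------------------------------

@dataclass
class TruthChromosome:
    """True marker placements for one chromosome of one population."""

    name: str
    markers: list[str]
    female_cM: np.ndarray
    male_length_cM: float
    centromere_frac: float = 0.0  # relative position of the centromere on the female axis
    male_cM: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def female_length(self) -> float:
        return float(self.female_cM[-1]) if len(self.female_cM) else 0.0

    def relative_positions(self) -> np.ndarray:
        length = self.female_length
        if length == 0:
            return np.zeros(len(self.female_cM))
        return self.female_cM / length

    def compute_male_positions(self, telomere_window: float, telomere_mass: float) -> None:
        cdf = male_crossover_cdf(self.relative_positions(), telomere_window, telomere_mass)
        self.male_cM = self.male_length_cM * cdf


@dataclass
class TruthMap:
    """Per-chromosome truth for one population, plus the crossover profile."""

    chromosomes: dict[str, TruthChromosome]
    telomere_window: float = 0.1
    telomere_mass: float = 0.9
    label: str = ""

    def marker_ids(self) -> list[str]:
        return [m for c in self.chromosomes.values() for m in c.markers]

    def shared_markers(self, other: "TruthMap") -> set[str]:
        return set(self.marker_ids()) & set(other.marker_ids())

    def marker_order(self) -> dict[str, int]:
        return {m: i for i, m in enumerate(self.marker_ids())}

    def chromosome_of(self) -> dict[str, str]:
        return {m: c.name for c in self.chromosomes.values() for m in c.markers}


def truth_to_map_table(truth: TruthMap, other: TruthMap | None = None) -> LinkageMapTable:
    """Render a truth map in the eight-column marker-table layout.

    If ``other`` is given, markers absent from it are flagged population
    specific.  Positions are re-based so each group starts at 0 cM.
    """
    import pandas as pd

    other_ids = set(other.marker_ids()) if other is not None else None
    rows = []
    for chrom in truth.chromosomes.values():
        f = chrom.female_cM - chrom.female_cM[0]
        m = chrom.male_cM - chrom.male_cM[0]
        for i, marker in enumerate(chrom.markers):
            rows.append(
                {
                    "marker": marker,
                    "group": chrom.name,
                    "order": i + 1,
                    "female_cM": float(f[i]),
                    "male_cM": float(m[i]),
                    "n_meioses": 0,
                    "accession": "",
                    "population_specific": other_ids is not None and marker not in other_ids,
                }
            )
    return LinkageMapTable(pd.DataFrame(rows, columns=COLUMNS))


def _broadcast(value, n: int, name: str) -> list[float]:
    if np.isscalar(value):
        return [float(value)] * n
    vals = [float(v) for v in value]
    if len(vals) != n:
        raise ValueError(f"{name}: expected {n} values, got {len(vals)}")
    return vals


def simulate_truth_maps(
    n_chromosomes: int = 6,
    female_lengths_cM=80.0,
    male_lengths_cM=20.0,
    markers_per_chromosome: int = 20,
    shared_fraction: float = 1.0,
    seed: int = 0,
    events: Sequence[RearrangementEvent] = (),
    karyotype: Karyotype | None = None,
    telomere_window: float = 0.1,
    telomere_mass: float = 0.9,
) -> tuple[TruthMap, TruthMap]:
    """Simulate a (reference, query) pair of truth maps.

    Markers are evenly spaced.  Each query marker is shared with the
    reference with probability ``shared_fraction``; the reference map holds
    exactly the shared markers (in untransformed coordinates), the query map
    holds every marker and is then transformed by ``events``.

    When a ``karyotype`` is supplied, chromosomes take its pair names, the
    per-chromosome lengths and marker counts are scaled by the pair's arm
    mass (so a two-arm metacentric is twice as long as a unit acrocentric)
    and metacentric centromere positions follow the arm-length split.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError(f"shared_fraction must be in [0, 1], got {shared_fraction}")
    if markers_per_chromosome < 2:
        raise ValueError("markers_per_chromosome must be >= 2")
    _check_telomere_params(telomere_window, telomere_mass)
    rng = np.random.default_rng(seed)

    if karyotype is not None:
        names = [p.name for p in karyotype.pairs]
        masses = [p.mass for p in karyotype.pairs]
        cen_fracs = [
            p.arms[0].length / p.mass if p.centromere_class == METACENTRIC else 0.0
            for p in karyotype.pairs
        ]
        n_chromosomes = len(names)
        f_len = [float(female_lengths_cM) * m for m in masses] if np.isscalar(
            female_lengths_cM
        ) else _broadcast(female_lengths_cM, n_chromosomes, "female_lengths_cM")
        m_len = [float(male_lengths_cM) * m for m in masses] if np.isscalar(
            male_lengths_cM
        ) else _broadcast(male_lengths_cM, n_chromosomes, "male_lengths_cM")
        counts = [max(2, round(markers_per_chromosome * m)) for m in masses]
    else:
        names = [f"chr{i + 1:02d}" for i in range(n_chromosomes)]
        cen_fracs = [0.0] * n_chromosomes
        f_len = _broadcast(female_lengths_cM, n_chromosomes, "female_lengths_cM")
        m_len = _broadcast(male_lengths_cM, n_chromosomes, "male_lengths_cM")
        counts = [markers_per_chromosome] * n_chromosomes

    if any(v <= 0 for v in f_len) or any(v < 0 for v in m_len):
        raise ValueError("map lengths must be positive (female) / non-negative (male)")

    query: dict[str, TruthChromosome] = {}
    ref: dict[str, TruthChromosome] = {}
    for name, lf, lm, k, cf in zip(names, f_len, m_len, counts, cen_fracs):
        positions = np.linspace(0.0, lf, k)
        markers = [f"{name}_m{i + 1:03d}" for i in range(k)]
        shared = rng.random(k) < shared_fraction
        query[name] = TruthChromosome(name, markers, positions, lm, cf)
        if shared.any():
            ref[name] = TruthChromosome(
                name,
                [m for m, s in zip(markers, shared) if s],
                positions[shared],
                lm,
                cf,
            )

    if events:
        query = _apply_events_to_truth(query, events, karyotype)

    ref_map = TruthMap(ref, telomere_window, telomere_mass, label="reference")
    query_map = TruthMap(query, telomere_window, telomere_mass, label="query")
    for tm in (ref_map, query_map):
        for chrom in tm.chromosomes.values():
            chrom.compute_male_positions(telomere_window, telomere_mass)
    return ref_map, query_map


def _apply_events_to_truth(
    chroms: dict[str, TruthChromosome],
    events: Sequence[RearrangementEvent],
    karyotype: Karyotype | None,
) -> dict[str, TruthChromosome]:
    """Rearrange truth chromosomes.  Male positions are recomputed afterwards."""
    chroms = dict(chroms)

    def pop(name: str) -> TruthChromosome:
        if name not in chroms:
            raise UnknownParticipantError(f"unknown chromosome {name!r} in truth map")
        return chroms.pop(name)

    def insert_after(ordered: dict, key_removed: str, new_items: list[TruthChromosome]):
        # preserve rough ordering: append at end is fine for analysis purposes
        for item in new_items:
            ordered[item.name] = item

    for event in events:
        if event.event_type == ROBERTSONIAN_FUSION:
            a, b = pop(event.participants[0]), pop(event.participants[1])
            la = a.female_length
            # head-to-head: the two proximal (position-0, centromeric) ends meet
            markers = a.markers[::-1] + b.markers
            female = np.concatenate([la - a.female_cM[::-1], la + b.female_cM])
            fused = TruthChromosome(
                _composite_name(a.name, b.name),
                markers,
                female,
                a.male_length_cM + b.male_length_cM,
                centromere_frac=la / (la + b.female_length),
            )
            insert_after(chroms, a.name, [fused])
        elif event.event_type == TANDEM_FUSION:
            donor, other = pop(event.participants[0]), pop(event.participants[1])
            ld = donor.female_length
            markers = donor.markers + other.markers
            female = np.concatenate([donor.female_cM, ld + other.female_cM])
            fused = TruthChromosome(
                _composite_name(donor.name, other.name),
                markers,
                female,
                donor.male_length_cM + other.male_length_cM,
                centromere_frac=donor.centromere_frac * ld / (ld + other.female_length),
            )
            insert_after(chroms, donor.name, [fused])
        elif event.event_type == WHOLE_ARM_TRANSLOCATION:
            if karyotype is None:
                raise ValueError("whole_arm_translocation in a truth map requires a karyotype")
            arm_name, dest_name = event.participants
            source_pair = karyotype.pair_with_arm(arm_name)
            if source_pair.arms[0].name != arm_name:
                raise ValueError(
                    "truth-map translocation supports moving the first (p) arm only"
                )
            src = pop(source_pair.name)
            dest = pop(dest_name)
            cut = src.centromere_frac * src.female_length
            in_p = src.female_cM <= cut + 1e-9
            p_f = src.female_cM[in_p]
            q_f = src.female_cM[~in_p] - cut
            p_markers = [m for m, s in zip(src.markers, in_p) if s]
            q_markers = [m for m, s in zip(src.markers, in_p) if not s]
            frac_p = cut / src.female_length
            fused = TruthChromosome(
                _composite_name(arm_name, dest.name),
                p_markers + dest.markers,
                np.concatenate([p_f, cut + dest.female_cM]),
                src.male_length_cM * frac_p + dest.male_length_cM,
                centromere_frac=cut / (cut + dest.female_length),
            )
            residue = TruthChromosome(
                source_pair.arms[1].name,
                q_markers,
                q_f,
                src.male_length_cM * (1.0 - frac_p),
                centromere_frac=0.0,
            )
            insert_after(chroms, src.name, [fused, residue])
        elif event.event_type == FISSION:
            if karyotype is None:
                raise ValueError("fission in a truth map requires a karyotype")
            pair = karyotype.pair(event.participants[0])
            src = pop(pair.name)
            cut = src.centromere_frac * src.female_length
            in_p = src.female_cM <= cut + 1e-9
            parts = []
            for arm, mask, offset in (
                (pair.arms[0], in_p, 0.0),
                (pair.arms[1], ~in_p, cut),
            ):
                parts.append(
                    TruthChromosome(
                        arm.name,
                        [m for m, s in zip(src.markers, mask) if s],
                        src.female_cM[mask] - offset,
                        src.male_length_cM / 2.0,
                        centromere_frac=0.0,
                    )
                )
            insert_after(chroms, src.name, parts)
        else:
            raise ValueError(f"unsupported truth-map event {event.event_type!r}")
    return chroms


# ---------------------------------------------------------------------------
# meiosis and pedigrees
# ---------------------------------------------------------------------------

def simulate_meiosis(
    parent_haplotypes: Mapping[str, np.ndarray],
    truth_map: TruthMap,
    parent_sex: str,
    rng,
    return_strands: bool = False,
):
    """One gamete from a phased parent.

    ``parent_haplotypes`` maps chromosome name -> (2, n_markers) allele array.
    Crossover counts are Poisson with the sex-specific map length; positions
    are uniform (female) or telomere-concentrated (male) without
    interference.  With ``return_strands`` the per-marker source strand (0/1)
    is returned alongside the allele array.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    gamete: dict[str, np.ndarray] = {}
    strands: dict[str, np.ndarray] = {}
    for name, chrom in truth_map.chromosomes.items():
        haps = np.asarray(parent_haplotypes[name])
        if haps.shape != (2, len(chrom.markers)):
            raise ValueError(
                f"chromosome {name!r}: haplotypes shape {haps.shape} does not match "
                f"{len(chrom.markers)} markers"
            )
        length = chrom.male_length_cM if parent_sex == "male" else chrom.female_length
        xovers = draw_crossovers(
            rng, length, parent_sex, truth_map.telomere_window, truth_map.telomere_mass
        )
        rel = chrom.relative_positions()
        strand = (int(rng.integers(2)) + np.searchsorted(xovers, rel, side="right")) % 2
        gamete[name] = haps[strand, np.arange(len(rel))]
        strands[name] = strand
    return (gamete, strands) if return_strands else gamete


@dataclass
class Family:
    """One mapping family; ``sire``/``dam`` may be untyped but are never unknown
    to the simulator's truth."""

    name: str
    sire: str
    dam: str
    offspring: list[str]
    half_sib: bool = False


@dataclass
class PedigreeGenotypes:
    """Unphased genotype matrix plus pedigree structure.

    Genotypes count copies of the ``1`` allele: values in {0, 1, 2} with
    ``-1`` for missing.  ``sex`` covers parents ('M'/'F').  ``truth`` (when
    produced by the simulator) retains phased parental haplotypes and
    per-offspring transmitted strands for parameter-recovery tests.
    """

    individuals: list[str]
    markers: list[str]
    genotypes: np.ndarray  # (n_individuals, n_markers) int8
    families: list[Family]
    sex: dict[str, str]
    truth: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.individuals), len(self.markers)):
            raise ValueError("genotype matrix shape does not match individuals x markers")
        self._index = {ind: i for i, ind in enumerate(self.individuals)}

    def row(self, individual: str) -> np.ndarray:
        return self.genotypes[self._index[individual]]

    def marker_index(self, marker: str) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise KeyError(f"unknown marker {marker!r}") from None

    def is_typed(self, individual: str) -> bool:
        return individual in self._index and bool((self.row(individual) >= 0).any())

    def allele_frequencies(self) -> np.ndarray:
        """Frequency of allele 1 per marker, estimated from typed parents."""
        parents = sorted({f.sire for f in self.families} | {f.dam for f in self.families})
        rows = [self.row(p) for p in parents if self.is_typed(p)]
        if not rows:
            rows = [self.genotypes[i] for i in range(len(self.individuals))]
        g = np.asarray(rows, dtype=float)
        g[g < 0] = np.nan
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(g, axis=0) / 2.0
        return np.nan_to_num(freq, nan=0.5)


def simulate_pedigree_genotypes(
    truth_map: TruthMap,
    n_families: int = 40,
    offspring_per_family: int = 30,
    half_sib_fraction: float = 0.0,
    missing_rate: float = 0.0,
    maf_range: tuple[float, float] = (0.1, 0.5),
    seed: int = 0,
) -> PedigreeGenotypes:
    """Simulate genotypes for independent full-sib families.

    Founder haplotypes are drawn at linkage equilibrium with per-marker minor
    allele frequencies uniform on ``maf_range``.  In half-sib families one
    parent (chosen at random) has its genotypes withheld — masked as missing
    while its haplotypes still drive the meioses.  ``missing_rate`` masks
    genotypes at random on top of that.
    """
    if n_families < 1 or offspring_per_family < 1:
        raise ValueError("family counts must be >= 1")
    for name, rate in (("half_sib_fraction", half_sib_fraction), ("missing_rate", missing_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)

    chrom_names = list(truth_map.chromosomes)
    chrom_sizes = [len(truth_map.chromosomes[c].markers) for c in chrom_names]
    markers = truth_map.marker_ids()
    n_markers = len(markers)
    maf = rng.uniform(maf_range[0], maf_range[1], n_markers)

    def split(arr: np.ndarray) -> dict[str, np.ndarray]:
        out, start = {}, 0
        for c, k in zip(chrom_names, chrom_sizes):
            out[c] = arr[..., start : start + k]
            start += k
        return out

    individuals: list[str] = []
    rows: list[np.ndarray] = []
    families: list[Family] = []
    sex: dict[str, str] = {}
    truth: dict = {"haplotypes": {}, "strands": {}, "maf": maf}

    for f in range(n_families):
        fam_name = f"fam{f + 1:03d}"
        sire, dam = f"{fam_name}_sire", f"{fam_name}_dam"
        half_sib = bool(rng.random() < half_sib_fraction)
        withheld = (sire if rng.random() < 0.5 else dam) if half_sib else None
        parent_haps = {}
        for parent, s in ((sire, "M"), (dam, "F")):
            haps = (rng.random((2, n_markers)) < maf).astype(np.int8)
            parent_haps[parent] = haps
            truth["haplotypes"][parent] = haps
            sex[parent] = s
            individuals.append(parent)
            geno = haps.sum(axis=0)
            rows.append(np.full(n_markers, MISSING, np.int8) if parent == withheld else geno)
        offspring = []
        for j in range(offspring_per_family):
            child = f"{fam_name}_o{j + 1:03d}"
            offspring.append(child)
            child_geno = np.zeros(n_markers, np.int8)
            child_strands = {}
            for parent, psex in ((sire, "male"), (dam, "female")):
                gam, strands = simulate_meiosis(
                    split(parent_haps[parent]), truth_map, psex, rng, return_strands=True
                )
                child_geno += np.concatenate([gam[c] for c in chrom_names]).astype(np.int8)
                child_strands[psex] = np.concatenate([strands[c] for c in chrom_names])
            truth["strands"][child] = child_strands
            individuals.append(child)
            rows.append(child_geno)
        families.append(Family(fam_name, sire, dam, offspring, half_sib))

    genotypes = np.vstack(rows)
    if missing_rate > 0:
        typed = genotypes >= 0
        mask = (rng.random(genotypes.shape) < missing_rate) & typed
        genotypes = genotypes.copy()
        genotypes[mask] = MISSING
    return PedigreeGenotypes(individuals, markers, genotypes, families, sex, truth)


# ---------------------------------------------------------------------------
# FISH-style probe co-location counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FishCounts:
    """Chromosome counts for a two-probe co-location experiment on one event."""

    co_located: int  # chromosomes carrying both probes
    separate_a: int  # chromosomes carrying only the first probe
    separate_b: int  # chromosomes carrying only the second probe


_FISH_STATES = {
    "hom_fused": FishCounts(2, 0, 0),
    "het": FishCounts(1, 1, 1),
    "hom_unfused": FishCounts(0, 2, 2),
}


def simulate_fish_counts(state: str) -> FishCounts:
    """Probe co-location summary for an individual's fusion state.

    A homozygous-fused individual shows both probes together on both
    homologs; a heterozygote shows one fused chromosome plus one of each
    unfused homolog; a homozygous-unfused individual never co-locates.
    """
    try:
        return _FISH_STATES[state]
    except KeyError:
        raise ValueError(
            f"state must be one of {sorted(_FISH_STATES)}, got {state!r}"
        ) from None


# ---------------------------------------------------------------------------
# bundled demonstration panel
# ---------------------------------------------------------------------------

def demo_rearrangement_panel() -> tuple[Karyotype, tuple[RearrangementEvent, ...]]:
    """An 8-pair reference karyotype plus the three standard events.

    The panel is the subset of the European-type reference involved in the
    translocation (ssa01, ssa23), the Robertsonian fusion (ssa26, ssa28) and
    the tandem fusion (ssa08, ssa29), with ssa09 and ssa10 as conserved
    controls.
    """
    base = build_european_reference()
    panel = base.subset(
        ["ssa01", "ssa08", "ssa09", "ssa10", "ssa23", "ssa26", "ssa28", "ssa29"],
        label="demo panel",
    )
    return panel, north_american_events()
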