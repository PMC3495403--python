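"""Karyotypes as collections of chromosome pairs with explicit arm structure.

A karyotype is modelled per haploid set: each :class:`ChromosomePair` carries
one arm (acrocentric) or two arms (metacentric).  Summary statistics follow
cytogenetic convention:

* ``2n``  — diploid chromosome number, twice the number of pairs;
* ``NF``  — fundamental number, the diploid arm count, where a metacentric
  pair contributes four arms and an acrocentric pair two.

Rearrangement operators are pure functions: they return a new
:class:`Karyotype` and never mutate their input.  Arm "mass" (the sum of arm
lengths) is conserved by every operator; arm lengths default to 1 so that a
metacentric chromosome has mass 2 and an acrocentric mass 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

__all__ = [
    "ChromosomeArm",
    "ChromosomePair",
    "Karyotype",
    "RearrangementEvent",
    "KaryotypeError",
    "UnknownParticipantError",
    "InvalidEventError",
    "METACENTRIC",
    "ACROCENTRIC",
    "ROBERTSONIAN_FUSION",
    "TANDEM_FUSION",
    "FISSION",
    "WHOLE_ARM_TRANSLOCATION",
    "HEAD_TO_HEAD",
    "TAIL_TO_HEAD",
    "NOT_APPLICABLE",
    "EVENT_TYPES",
    "build_european_reference",
    "north_american_events",
    "apply_event",
    "apply_event_set",
    "summarize",
    "robertsonian_fusion",
    "tandem_fusion",
    "fission",
    "whole_arm_translocation",
]

METACENTRIC = "metacentric"
ACROCENTRIC = "acrocentric"

ROBERTSONIAN_FUSION = "robertsonian_fusion"
TANDEM_FUSION = "tandem_fusion"
FISSION = "fission"
WHOLE_ARM_TRANSLOCATION = "whole_arm_translocation"
EVENT_TYPES = (
    ROBERTSONIAN_FUSION,
    TANDEM_FUSION,
    FISSION,
    WHOLE_ARM_TRANSLOCATION,
)

HEAD_TO_HEAD = "head_to_head"
TAIL_TO_HEAD = "tail_to_head"
NOT_APPLICABLE = "not_applicable"


class KaryotypeError(ValueError):
    """Base error for invalid karyotypes or events."""


class UnknownParticipantError(KaryotypeError):
    """An event references a chromosome or arm absent from the karyotype."""


class InvalidEventError(KaryotypeError):
    """An event type is incompatible with its participants."""


@dataclass(frozen=True)
class ChromosomeArm:
    """A single chromosome arm with a relative length (arbitrary units)."""

    name: str
    length: float = 1.0

    def __post_init__(self) -> None:
        if not self.name:
            raise KaryotypeError("arm name must be non-empty")
        if not self.length > 0:
            raise KaryotypeError(f"arm {self.name!r}: length must be > 0, got {self.length}")


@dataclass(frozen=True)
class ChromosomePair:
    """A homologous chromosome pair: one arm (acrocentric) or two (metacentric)."""

    name: str
    arms: tuple[ChromosomeArm, ...]

    def __post_init__(self) -> None:
        if len(self.arms) not in (1, 2):
            raise KaryotypeError(
                f"chromosome {self.name!r}: arm count must be 1 or 2, got {len(self.arms)}"
            )
        object.__setattr__(self, "arms", tuple(self.arms))

    @property
    def centromere_class(self) -> str:
        return METACENTRIC if len(self.arms) == 2 else ACROCENTRIC

    @property
    def mass(self) -> float:
        """Total arm length of the pair (haploid)."""
        return sum(arm.length for arm in self.arms)


@dataclass(frozen=True)
class Karyotype:
    """An ordered collection of chromosome pairs with distinct names."""

    pairs: tuple[ChromosomePair, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(self.pairs))
        names = [p.name for p in self.pairs]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise KaryotypeError(f"duplicate chromosome names: {dup}")
        arm_names = [a.name for p in self.pairs for a in p.arms]
        if len(set(arm_names)) != len(arm_names):
            dup = sorted({n for n in arm_names if arm_names.count(n) > 1})
            raise KaryotypeError(f"duplicate arm names: {dup}")

    def __iter__(self) -> Iterator[ChromosomePair]:
        return iter(self.pairs)

    def __contains__(self, name: str) -> bool:
        return any(p.name == name for p in self.pairs)

    def pair(self, name: str) -> ChromosomePair:
        for p in self.pairs:
            if p.name == name:
                return p
        raise UnknownParticipantError(f"unknown chromosome {name!r} in karyotype {self.label!r}")

    def pair_with_arm(self, arm_name: str) -> ChromosomePair:
        for p in self.pairs:
            if any(a.name == arm_name for a in p.arms):
                return p
        raise UnknownParticipantError(f"unknown arm {arm_name!r} in karyotype {self.label!r}")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def two_n(self) -> int:
        return 2 * self.n_pairs

    @property
    def nf(self) -> int:
        """Diploid arm count: 2 arms per metacentric pair, 1 per acrocentric, times two."""
        return 2 * sum(len(p.arms) for p in self.pairs)

    @property
    def metacentric_count(self) -> int:
        return sum(1 for p in self.pairs if p.centromere_class == METACENTRIC)

    @property
    def acrocentric_count(self) -> int:
        return sum(1 for p in self.pairs if p.centromere_class == ACROCENTRIC)

    @property
    def total_mass(self) -> float:
        return sum(p.mass for p in self.pairs)

    def subset(self, names: Sequence[str], label: str = "") -> "Karyotype":
        """A karyotype restricted to the named pairs, preserving order of `names`."""
        return Karyotype(tuple(self.pair(n) for n in names), label=label or self.label)


@dataclass(frozen=True)
class RearrangementEvent:
    """A typed structural rearrangement applied to a karyotype.

    ``participants`` are chromosome names, except for
    ``whole_arm_translocation`` where the first participant is the arm being
    moved and the second the (acrocentric) destination chromosome.  For a
    tandem fusion the first participant donates the centromere.
    """

    event_type: str
    participants: tuple[str, ...]
    orientation: str = NOT_APPLICABLE
    polymorphic: bool = False

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise InvalidEventError(f"unknown event type {self.event_type!r}")
        object.__setattr__(self, "participants", tuple(self.participants))
        need = 1 if self.event_type == FISSION else 2
        if len(self.participants) != need:
            raise InvalidEventError(
                f"{self.event_type} takes {need} participant(s), got {len(self.participants)}"
            )


# -- convenience constructors -------------------------------------------------

def robertsonian_fusion(a: str, b: str, polymorphic: bool = False) -> RearrangementEvent:
    return RearrangementEvent(ROBERTSONIAN_FUSION, (a, b), HEAD_TO_HEAD, polymorphic)


def tandem_fusion(donor: str, other: str, polymorphic: bool = False) -> RearrangementEvent:
    return RearrangementEvent(TANDEM_FUSION, (donor, other), TAIL_TO_HEAD, polymorphic)


def fission(name: str) -> RearrangementEvent:
    return RearrangementEvent(FISSION, (name,))


def whole_arm_translocation(arm: str, destination: str) -> RearrangementEvent:
    return RearrangementEvent(WHOLE_ARM_TRANSLOCATION, (arm, destination))


def _composite_name(first: str, second: str) -> str:
    """Join two names, stripping the shared leading alphabetic prefix from the second.

    ``ssa26 + ssa28 -> ssa26/28``; ``ssa01p + ssa23 -> ssa01p/23``.
    """
    i = 0
    while i < min(len(first), len(second)) and first[i] == second[i] and first[i].isalpha():
        i += 1
    return f"{first}/{second[i:]}"


def build_european_reference() -> Karyotype:
    """The 29-pair European-type reference: 8 metacentric + 21 acrocentric pairs.

    Metacentric pairs are ssa01..ssa08 with unit-length p and q arms;
    ssa09..ssa29 are acrocentric with a single unit-length q arm.  NF = 74.
    """
    pairs: list[ChromosomePair] = []
    for i in range(1, 30):
        name = f"ssa{i:02d}"
        if i <= 8:
            arms = (ChromosomeArm(f"{name}p"), ChromosomeArm(f"{name}q"))
        else:
            arms = (ChromosomeArm(f"{name}q"),)
        pairs.append(ChromosomePair(name, arms))
    return Karyotype(tuple(pairs), label="European reference")


def north_american_events() -> tuple[RearrangementEvent, ...]:
    """The three rearrangements carrying the European reference to the
    North American standard karyotype: a whole-arm translocation of ssa01p
    onto ssa23 (leaving the ssa01q residue), a Robertsonian fusion of
    ssa26 + ssa28 and a tandem fusion of ssa29 onto the q arm of ssa08."""
    return (
        whole_arm_translocation("ssa01p", "ssa23"),
        robertsonian_fusion("ssa26", "ssa28", polymorphic=True),
        tandem_fusion("ssa08", "ssa29", polymorphic=True),
    )


def _replace_pairs(
    karyotype: Karyotype,
    remove: Iterable[str],
    insert_at: str,
    new_pairs: Sequence[ChromosomePair],
) -> Karyotype:
    """Rebuild the pair tuple with `new_pairs` at the position of `insert_at`
    and all of `remove` dropped."""
    removed = set(remove)
    out: list[ChromosomePair] = []
    for p in karyotype.pairs:
        if p.name == insert_at:
            out.extend(new_pairs)
        elif p.name not in removed:
            out.append(p)
    return Karyotype(tuple(out), label=karyotype.label)


def apply_event(karyotype: Karyotype, event: RearrangementEvent) -> Karyotype:
    """Apply one rearrangement, returning a new karyotype.

    * Robertsonian fusion of two acrocentrics: pairs −1, NF unchanged,
      product metacentric.
    * Tandem fusion: pairs −1, NF −2 (diploid); the first participant donates
      the centromere, the second is absorbed into its last arm.
    * Fission of a metacentric: pairs +1, NF unchanged, products acrocentric
      and named after the arms.
    * Whole-arm translocation: moves a named arm onto an acrocentric
      chromosome; pairs and NF unchanged.
    """
    if event.event_type == ROBERTSONIAN_FUSION:
        a = karyotype.pair(event.participants[0])
        b = karyotype.pair(event.participants[1])
        for p in (a, b):
            if p.centromere_class != ACROCENTRIC:
                raise InvalidEventError(
                    f"robertsonian_fusion requires acrocentric participants; "
                    f"{p.name!r} is {p.centromere_class}"
                )
        product = ChromosomePair(_composite_name(a.name, b.name), a.arms + b.arms)
        return _replace_pairs(karyotype, {b.name}, a.name, [product])

    if event.event_type == TANDEM_FUSION:
        donor = karyotype.pair(event.participants[0])
        other = karyotype.pair(event.participants[1])
        if donor.name == other.name:
            raise InvalidEventError("tandem_fusion participants must differ")
        merged = ChromosomeArm(
            _composite_name(donor.arms[-1].name, other.name),
            donor.arms[-1].length + other.mass,
        )
        product = ChromosomePair(
            _composite_name(donor.name, other.name), donor.arms[:-1] + (merged,)
        )
        return _replace_pairs(karyotype, {other.name}, donor.name, [product])

    if event.event_type == FISSION:
        target = karyotype.pair(event.participants[0])
        if target.centromere_class != METACENTRIC:
            raise InvalidEventError(f"fission requires a metacentric chromosome, not {target.name!r}")
        products = [ChromosomePair(arm.name, (arm,)) for arm in target.arms]
        return _replace_pairs(karyotype, set(), target.name, products)

    if event.event_type == WHOLE_ARM_TRANSLOCATION:
        arm_name, dest_name = event.participants
        source = karyotype.pair_with_arm(arm_name)
        dest = karyotype.pair(dest_name)
        if source.name == dest.name:
            raise InvalidEventError("cannot translocate an arm onto its own chromosome")
        if len(source.arms) < 2:
            raise InvalidEventError(
                f"moving {arm_name!r} would leave {source.name!r} without arms"
            )
        if dest.centromere_class != ACROCENTRIC:
            raise InvalidEventError(
                f"whole_arm_translocation destination {dest.name!r} must be acrocentric"
            )
        moved = next(a for a in source.arms if a.name == arm_name)
        residue_arms = tuple(a for a in source.arms if a.name != arm_name)
        residue = ChromosomePair(residue_arms[0].name, residue_arms)
        product = ChromosomePair(_composite_name(arm_name, dest.name), (moved,) + dest.arms)
        k = _replace_pairs(karyotype, set(), source.name, [residue])
        return _replace_pairs(k, set(), dest.name, [product])

    raise InvalidEventError(f"unknown event type {event.event_type!r}")  # pragma: no cover


def apply_event_set(
    karyotype: Karyotype, events: Sequence[RearrangementEvent]
) -> Karyotype:
    """Apply events sequentially, propagating errors from :func:`apply_event`."""
    for event in events:
        karyotype = apply_event(karyotype, event)
    return karyotype


def summarize(karyotype: Karyotype) -> dict:
    """Deterministic karyotype summary: pair, 2n, NF and centromere-class counts."""
    return {
        "n_pairs": karyotype.n_pairs,
        "2n": karyotype.two_n,
        "NF": karyotype.nf,
        "metacentric": karyotype.metacentric_count,
        "acrocentric": karyotype.acrocentric_count,
    }
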