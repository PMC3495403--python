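"""Comparative alignment of two linkage maps and rearrangement-event calling.

Maps are aligned on shared marker ids; linkage groups of the two maps become
the two sides of a bipartite correspondence graph weighted by shared-marker
counts.  Each connected component is classified relative to the reference
map (side A):

* one A group <-> one B group                      -> ``conserved``
* two A groups merged into one B group             -> ``fusion``
* one A group split over several B groups          -> ``fission``
* one A group split with one fragment joining an
  intact second A group                            -> ``translocation_plus_fission``
* anything else                                    -> ``complex`` (never an exception)

For fusion-like calls the junction is the open interval, in female-map cM of
the query group, between the two reference-derived marker blocks.  Block
orientation comes from the sign of the Spearman correlation between A and B
positions; the ends meeting at the junction are labelled ``head`` (the
position-0, proximal end in A) or ``tail`` (the distal end), which yields the
head-to-head / tail-to-head orientation of the event.

Fusion architecture is inferred from the male recombination profile of the
query group: a junction inside the male-recombination-cold interior with
recombinationally active distal ends indicates a centromere-to-centromere
fusion when two acrocentric reference groups meet head to head, and a tandem
fusion when a metacentric reference group's tail meets an acrocentric's head.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .karyotype import (
    ACROCENTRIC,
    METACENTRIC,
    Karyotype,
    RearrangementEvent,
    apply_event_set,
    fission as fission_event,
    robertsonian_fusion,
    tandem_fusion,
    whole_arm_translocation,
)
from .maptable import LinkageMapTable

__all__ = [
    "SharedPairing",
    "CorrespondenceEdge",
    "CorrespondenceGraph",
    "DetectedEvent",
    "ComplexEventError",
    "match_shared_markers",
    "build_correspondence",
    "classify_events",
    "male_telomere_statistic",
    "infer_architecture",
    "detect_events",
    "events_to_karyotype",
    "plot_event",
]

CONSERVED = "conserved"
FUSION = "fusion"
FISSION_EVENT = "fission"
TRANSLOCATION_PLUS_FISSION = "translocation_plus_fission"
COMPLEX = "complex"

CENTROMERE_TO_CENTROMERE = "centromere_to_centromere"
TANDEM = "tandem"
UNDETERMINED = "undetermined"


class ComplexEventError(ValueError):
    """A complex event cannot be mapped onto karyotype operators."""


@dataclass(frozen=True)
class SharedPairing:
    shared: tuple[str, ...]
    only_a: tuple[str, ...]
    only_b: tuple[str, ...]


def match_shared_markers(map_a: LinkageMapTable, map_b: LinkageMapTable) -> SharedPairing:
    """Bijective id pairing on the marker intersection of two maps."""
    a, b = map_a.markers, map_b.markers
    for name, ids in (("A", a), ("B", b)):
        seen = set()
        for m in ids:
            if m in seen:
                raise ValueError(f"duplicate marker id {m!r} in map {name}")
            seen.add(m)
    sa, sb = set(a), set(b)
    shared = [m for m in a if m in sb]
    return SharedPairing(
        shared=tuple(shared),
        only_a=tuple(m for m in a if m not in sb),
        only_b=tuple(m for m in b if m not in sa),
    )


@dataclass(frozen=True)
class CorrespondenceEdge:
    group_a: str
    group_b: str
    n_shared: int
    correlation_sign: int  # sign of the Spearman correlation of shared positions


@dataclass
class CorrespondenceGraph:
    """Bipartite relation between the linkage groups of two maps."""

    edges: list[CorrespondenceEdge]
    groups_a: list[str]
    groups_b: list[str]
    marker_assignment: dict[str, tuple[str, str]]  # shared marker -> (group_a, group_b)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for name in self.groups_a:
            g.add_node(("A", name))
        for name in self.groups_b:
            g.add_node(("B", name))
        for e in self.edges:
            g.add_edge(("A", e.group_a), ("B", e.group_b), edge=e)
        return g


def build_correspondence(
    pairing: SharedPairing,
    map_a: LinkageMapTable,
    map_b: LinkageMapTable,
    min_shared: int = 3,
) -> CorrespondenceGraph:
    """Correspondence graph with edges supported by >= min_shared markers."""
    groups_a = map_a.marker_groups()
    groups_b = map_b.marker_groups()
    pos_a = map_a.marker_positions("female")
    pos_b = map_b.marker_positions("female")
    by_pair: dict[tuple[str, str], list[str]] = {}
    for m in pairing.shared:
        by_pair.setdefault((groups_a[m], groups_b[m]), []).append(m)
    edges = []
    assignment = {}
    for (ga, gb), markers in sorted(by_pair.items()):
        if len(markers) < min_shared:
            continue
        xs = [pos_a[m] for m in markers]
        ys = [pos_b[m] for m in markers]
        sign = 0
        if len(markers) >= 2 and len(set(xs)) > 1 and len(set(ys)) > 1:
            rho = spearmanr(xs, ys).correlation
            if rho is not None and not np.isnan(rho):
                sign = int(np.sign(rho))
        edges.append(CorrespondenceEdge(ga, gb, len(markers), sign))
        for m in markers:
            assignment[m] = (ga, gb)
    return CorrespondenceGraph(edges, map_a.groups, map_b.groups, assignment)


@dataclass
class DetectedEvent:
    """A classified structural difference between the two maps."""

    event_type: str
    groups_a: tuple[str, ...]
    groups_b: tuple[str, ...]
    junction: tuple[float, float] | None = None  # open interval, query female cM
    orientations: dict[str, str] = field(default_factory=dict)  # A group -> forward/reverse
    junction_ends: tuple[str, str] | None = None  # (end of first block, end of second)
    architecture: str = UNDETERMINED
    residue_group: str | None = None  # B group holding the fission residue
    fragment_proximal: bool | None = None  # translocated fragment from proximal part of A?
    note: str = ""

    @property
    def orientation_label(self) -> str | None:
        if self.junction_ends is None:
            return None
        ends = self.junction_ends
        if ends == ("head", "head"):
            return "head_to_head"
        if ends == ("tail", "head"):
            return "tail_to_head"
        if ends == ("tail", "tail"):
            return "tail_to_tail"
        return None


def _two_block_split(labels: list[str]) -> tuple[list[int], list[int], int] | None:
    """Split a label sequence into two homogeneous blocks with minimal removals.

    Returns (first-block indices, second-block indices, n_removed) for the
    best (label order, split point), or None for fewer than two labels.
    Removed indices are the interlopers and belong to neither block.
    """
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        return None
    best = None
    n = len(labels)
    for first, second in ((uniq[0], uniq[1]), (uniq[1], uniq[0])):
        wrong_prefix = np.cumsum([lab != first for lab in labels])  # removals if cut after i
        wrong_suffix = np.cumsum([lab != second for lab in labels[::-1]])[::-1]
        for cut in range(1, n):  # cut between cut-1 and cut
            cost = int(wrong_prefix[cut - 1]) + int(wrong_suffix[cut])
            if best is None or cost < best[0]:
                blk1 = [i for i in range(cut) if labels[i] == first]
                blk2 = [i for i in range(cut, n) if labels[i] == second]
                best = (cost, blk1, blk2)
    assert best is not None
    return best[1], best[2], best[0]


def _block_orientation(markers: list[str], pos_a, pos_b) -> str | None:
    if len(markers) < 2:
        return None
    rho = spearmanr([pos_a[m] for m in markers], [pos_b[m] for m in markers]).correlation
    if rho is None or np.isnan(rho) or rho == 0:
        return None
    return "forward" if rho > 0 else "reverse"


def _meeting_end(orientation: str | None, is_first_block: bool) -> str | None:
    """Which A-end of a block meets the junction.

    The first block (lower query positions) meets the junction at its high
    end, the second at its low end.  ``head`` is the proximal (position 0)
    end in the reference group.
    """
    if orientation is None:
        return None
    if is_first_block:
        return "tail" if orientation == "forward" else "head"
    return "head" if orientation == "forward" else "tail"


def _is_contiguous(sorted_labels: list[str], label: str, max_interlopers: int) -> bool:
    idx = [i for i, lab in enumerate(sorted_labels) if lab == label]
    if not idx:
        return False
    span = idx[-1] - idx[0] + 1
    return span - len(idx) <= max_interlopers


def classify_events(
    graph: CorrespondenceGraph,
    map_a: LinkageMapTable,
    map_b: LinkageMapTable,
    max_interlopers: int = 2,
) -> list[DetectedEvent]:
    """Classify every connected component of the correspondence graph.

    ``complex`` is the fallback classification; this function never raises on
    unexpected topology.
    """
    pos_a = map_a.marker_positions("female")
    pos_b = map_b.marker_positions("female")
    g = graph.graph()
    events = []
    for comp in nx.connected_components(g):
        a_nodes = sorted(n[1] for n in comp if n[0] == "A")
        b_nodes = sorted(n[1] for n in comp if n[0] == "B")
        if not a_nodes or not b_nodes:
            continue  # groups without correspondence carry no signal
        ev = _classify_component(
            tuple(a_nodes), tuple(b_nodes), graph, pos_a, pos_b, max_interlopers
        )
        events.append(ev)
    events.sort(key=lambda e: (e.groups_a, e.groups_b))
    return events


def _shared_in_b_group(graph: CorrespondenceGraph, gb: str) -> list[str]:
    return [m for m, (_, b) in graph.marker_assignment.items() if b == gb]


def _classify_component(
    a_nodes: tuple[str, ...],
    b_nodes: tuple[str, ...],
    graph: CorrespondenceGraph,
    pos_a,
    pos_b,
    max_interlopers: int,
) -> DetectedEvent:
    ga_of = {m: pair[0] for m, pair in graph.marker_assignment.items()}

    if len(a_nodes) == 1 and len(b_nodes) == 1:
        return DetectedEvent(CONSERVED, a_nodes, b_nodes)

    if len(a_nodes) == 2 and len(b_nodes) == 1:
        gb = b_nodes[0]
        markers = sorted(_shared_in_b_group(graph, gb), key=pos_b.__getitem__)
        labels = [ga_of[m] for m in markers]
        split = _two_block_split(labels)
        if split is None:
            return DetectedEvent(COMPLEX, a_nodes, b_nodes, note="degenerate labels")
        blk1, blk2, removed = split
        if removed > max_interlopers:
            return DetectedEvent(
                COMPLEX, a_nodes, b_nodes,
                note=f"blocks not contiguous ({removed} interlopers)",
            )
        m1 = [markers[i] for i in blk1]
        m2 = [markers[i] for i in blk2]
        o1 = _block_orientation(m1, pos_a, pos_b)
        o2 = _block_orientation(m2, pos_a, pos_b)
        g1, g2 = ga_of[m1[0]], ga_of[m2[0]]
        e1, e2 = _meeting_end(o1, True), _meeting_end(o2, False)
        junction = (pos_b[m1[-1]], pos_b[m2[0]])
        ends = None
        groups = (g1, g2)
        orient = {g1: o1, g2: o2}
        if e1 is not None and e2 is not None:
            if (e1, e2) == ("head", "tail"):
                # canonicalize so the tail-side participant is listed first
                groups = (g2, g1)
                ends = ("tail", "head")
            else:
                ends = (e1, e2)
        return DetectedEvent(
            FUSION, groups, b_nodes, junction=junction,
            orientations=orient, junction_ends=ends,
        )

    if len(a_nodes) == 1 and len(b_nodes) >= 2:
        ga = a_nodes[0]
        for gb in b_nodes:
            markers = sorted(
                (m for m, (a, b) in graph.marker_assignment.items() if b == gb and a == ga),
                key=pos_a.__getitem__,
            )
            all_in_a = sorted(
                (m for m, (a, _) in graph.marker_assignment.items() if a == ga),
                key=pos_a.__getitem__,
            )
            labels = [graph.marker_assignment[m][1] for m in all_in_a]
            if not _is_contiguous(labels, gb, max_interlopers):
                return DetectedEvent(COMPLEX, a_nodes, b_nodes, note="fragments interleaved")
        return DetectedEvent(FISSION_EVENT, a_nodes, b_nodes)

    if len(a_nodes) == 2 and len(b_nodes) == 2:
        ev = _classify_translocation(a_nodes, b_nodes, graph, pos_a, pos_b, max_interlopers)
        if ev is not None:
            return ev

    return DetectedEvent(COMPLEX, a_nodes, b_nodes, note="unrecognized topology")


def _classify_translocation(
    a_nodes, b_nodes, graph, pos_a, pos_b, max_interlopers
) -> DetectedEvent | None:
    """Detect: one A group split over two B groups, one fragment fused with an
    intact second A group, the other standing alone (the fission residue)."""
    g = graph.graph()
    deg_a = {a: g.degree(("A", a)) for a in a_nodes}
    deg_b = {b: g.degree(("B", b)) for b in b_nodes}
    split = [a for a in a_nodes if deg_a[a] == 2]
    intact = [a for a in a_nodes if deg_a[a] == 1]
    fused_b = [b for b in b_nodes if deg_b[b] == 2]
    residue_b = [b for b in b_nodes if deg_b[b] == 1]
    if len(split) != 1 or len(intact) != 1 or len(fused_b) != 1 or len(residue_b) != 1:
        return None
    a_split, a_intact = split[0], intact[0]
    b_fused, b_res = fused_b[0], residue_b[0]
    # the residue group must hold only markers of the split A group
    if any(
        pair == (a_intact, b_res) for pair in graph.marker_assignment.values()
    ):
        return None
    # the split group's markers must partition contiguously in A coordinates
    split_markers = sorted(
        (m for m, (a, _) in graph.marker_assignment.items() if a == a_split),
        key=pos_a.__getitem__,
    )
    labels = [graph.marker_assignment[m][1] for m in split_markers]
    two = _two_block_split(labels)
    if two is None or two[2] > max_interlopers:
        return None
    # blocks inside the fused B group must be contiguous as well
    fused_markers = sorted(_shared_in_b_group(graph, b_fused), key=pos_b.__getitem__)
    fused_labels = [graph.marker_assignment[m][0] for m in fused_markers]
    fused_split = _two_block_split(fused_labels)
    if fused_split is None or fused_split[2] > max_interlopers:
        return None
    fragment = [m for m in split_markers if graph.marker_assignment[m][1] == b_fused]
    residue = [m for m in split_markers if graph.marker_assignment[m][1] == b_res]
    frag_mean = float(np.mean([pos_a[m] for m in fragment]))
    res_mean = float(np.mean([pos_a[m] for m in residue]))
    blk1, blk2, _ = fused_split
    m1 = [fused_markers[i] for i in blk1]
    m2 = [fused_markers[i] for i in blk2]
    junction = (pos_b[m1[-1]], pos_b[m2[0]])
    orient = {
        graph.marker_assignment[m1[0]][0]: _block_orientation(m1, pos_a, pos_b),
        graph.marker_assignment[m2[0]][0]: _block_orientation(m2, pos_a, pos_b),
    }
    return DetectedEvent(
        TRANSLOCATION_PLUS_FISSION,
        (a_split, a_intact),
        (b_fused, b_res),
        junction=junction,
        orientations=orient,
        residue_group=b_res,
        fragment_proximal=frag_mean < res_mean,
    )


# ---------------------------------------------------------------------------
# male recombination profile
# ---------------------------------------------------------------------------

def male_telomere_statistic(
    group_rows: pd.DataFrame, terminal_fraction: float = 0.1
) -> float | None:
    """Share of a group's male map length accumulated in its terminal windows.

    Terminal windows span ``terminal_fraction`` of the female extent at each
    end; an adjacent-marker male increment counts as terminal when either of
    its endpoints falls inside a window.  Returns None when the group has no
    male map length.
    """
    if not 0 < terminal_fraction < 0.5:
        raise ValueError("terminal_fraction must be in (0, 0.5)")
    rows = group_rows.sort_values("order")
    if len(rows) < 3:
        raise ValueError("male_telomere_statistic requires >= 3 markers")
    f = rows["female_cM"].to_numpy()
    m = rows["male_cM"].to_numpy()
    total = m[-1] - m[0]
    if total <= 0:
        return None
    span = f[-1] - f[0]
    lo = f[0] + terminal_fraction * span
    hi = f[-1] - terminal_fraction * span
    in_window = (f <= lo) | (f >= hi)
    seg_terminal = in_window[:-1] | in_window[1:]
    return float(np.diff(m)[seg_terminal].sum() / total)


def _male_at(rows: pd.DataFrame, female_pos: float) -> float:
    f = rows["female_cM"].to_numpy()
    m = rows["male_cM"].to_numpy()
    return float(np.interp(female_pos, f, m))


def infer_architecture(
    event: DetectedEvent,
    query_rows: pd.DataFrame,
    reference_karyotype: Karyotype | None = None,
    terminal_fraction: float = 0.1,
    junction_window: float = 0.1,
    junction_male_share: float = 0.05,
    junction_cold_factor: float = 0.5,
) -> str:
    """Fusion architecture from marker order and the male recombination profile.

    The junction must sit in the male-cold interior with both distal ends
    recombinationally active in males.  "Cold" is judged against the group's
    own telomeric signal: the male cM inside a window of ``junction_window``
    x female span around the junction must stay below ``junction_male_share``
    of the group male length, or below ``junction_cold_factor`` times the
    weaker terminal window's share.  Then head-to-head joining of two
    acrocentric reference groups is a centromere-to-centromere fusion and
    tail-to-head joining led by a metacentric reference group is a tandem
    fusion; everything else stays undetermined.
    """
    if event.event_type not in (FUSION,):
        return UNDETERMINED
    if event.junction is None or reference_karyotype is None:
        return UNDETERMINED
    rows = query_rows.sort_values("order")
    f = rows["female_cM"].to_numpy()
    m = rows["male_cM"].to_numpy()
    male_total = m[-1] - m[0]
    if male_total <= 0:
        return UNDETERMINED
    span = f[-1] - f[0]
    center = 0.5 * (event.junction[0] + event.junction[1])
    lo = max(f[0], center - junction_window * span)
    hi = min(f[-1], center + junction_window * span)
    junction_share = (_male_at(rows, hi) - _male_at(rows, lo)) / male_total
    eps = 1e-9
    left = (_male_at(rows, f[0] + terminal_fraction * span) - m[0]) / male_total
    right = (m[-1] - _male_at(rows, f[-1] - terminal_fraction * span)) / male_total
    # the junction competes with the telomeric signal on its own side: a
    # window as male-hot as the nearer terminal window is no interior junction
    nearer = left if (center - f[0]) <= (f[-1] - center) else right
    cold = junction_share < max(
        junction_male_share, junction_cold_factor * nearer
    )
    if not (cold and left > eps and right > eps):
        return UNDETERMINED
    try:
        classes = [reference_karyotype.pair(g).centromere_class for g in event.groups_a]
    except Exception:
        return UNDETERMINED
    label = event.orientation_label
    if label == "head_to_head" and all(c == ACROCENTRIC for c in classes):
        return CENTROMERE_TO_CENTROMERE
    if label == "tail_to_head" and classes[0] == METACENTRIC and classes[1] == ACROCENTRIC:
        return TANDEM
    return UNDETERMINED


def detect_events(
    map_a: LinkageMapTable,
    map_b: LinkageMapTable,
    reference_karyotype: Karyotype | None = None,
    min_shared: int = 3,
    max_interlopers: int = 2,
    terminal_fraction: float = 0.1,
    junction_window: float = 0.1,
    junction_male_share: float = 0.05,
    junction_cold_factor: float = 0.5,
) -> list[DetectedEvent]:
    """End-to-end comparison: pairing -> correspondence -> classification ->
    architecture inference for fusion events."""
    pairing = match_shared_markers(map_a, map_b)
    graph = build_correspondence(pairing, map_a, map_b, min_shared=min_shared)
    events = classify_events(graph, map_a, map_b, max_interlopers=max_interlopers)
    out = []
    for ev in events:
        if ev.event_type == FUSION:
            arch = infer_architecture(
                ev,
                map_b.group_rows(ev.groups_b[0]),
                reference_karyotype,
                terminal_fraction=terminal_fraction,
                junction_window=junction_window,
                junction_male_share=junction_male_share,
                junction_cold_factor=junction_cold_factor,
            )
            ev.architecture = arch
        out.append(ev)
    return out


# ---------------------------------------------------------------------------
# karyotype prediction
# ---------------------------------------------------------------------------

def events_to_karyotype(
    events: Sequence[DetectedEvent], reference: Karyotype
) -> tuple[Karyotype, list[RearrangementEvent]]:
    """Translate detected events into karyotype operators and apply them.

    Complex events cannot be mapped deterministically and are refused.  A
    fusion with undetermined architecture falls back on the participants'
    centromere classes (two acrocentrics -> Robertsonian; exactly one
    metacentric -> tandem with the metacentric donating the centromere).
    """
    complex_events = [e for e in events if e.event_type == COMPLEX]
    if complex_events:
        raise ComplexEventError(
            "cannot map complex events onto karyotype operators: "
            + "; ".join(f"{e.groups_a} -> {e.groups_b} ({e.note})" for e in complex_events)
        )
    ops: list[RearrangementEvent] = []
    for ev in events:
        if ev.event_type in (CONSERVED, FISSION_EVENT):
            # a bare fission of a metacentric reference group
            if ev.event_type == FISSION_EVENT:
                ops.append(fission_event(ev.groups_a[0]))
            continue
        if ev.event_type == FUSION:
            g1, g2 = ev.groups_a
            arch = ev.architecture
            if arch == UNDETERMINED:
                classes = {g: reference.pair(g).centromere_class for g in ev.groups_a}
                metas = [g for g, c in classes.items() if c == METACENTRIC]
                if not metas:
                    arch = CENTROMERE_TO_CENTROMERE
                elif len(metas) == 1:
                    arch = TANDEM
                    g1 = metas[0]
                    g2 = next(g for g in ev.groups_a if g != g1)
                else:
                    raise ComplexEventError(
                        f"fusion of two metacentric groups {ev.groups_a} is not representable"
                    )
            if arch == CENTROMERE_TO_CENTROMERE:
                ops.append(robertsonian_fusion(g1, g2))
            else:
                ops.append(tandem_fusion(g1, g2))
        elif ev.event_type == TRANSLOCATION_PLUS_FISSION:
            a_split, a_intact = ev.groups_a
            pair = reference.pair(a_split)
            if pair.centromere_class != METACENTRIC:
                raise ComplexEventError(
                    f"translocation source {a_split!r} is not metacentric in the reference"
                )
            arm = pair.arms[0] if ev.fragment_proximal else pair.arms[-1]
            ops.append(whole_arm_translocation(arm.name, a_intact))
        else:  # pragma: no cover
            raise ComplexEventError(f"unhandled event type {ev.event_type!r}")
    return apply_event_set(reference, ops), ops


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

def plot_event(
    event: DetectedEvent,
    map_a: LinkageMapTable,
    map_b: LinkageMapTable,
    path: str,
) -> None:
    """Dual-map plot of one event: query group on the left, reference groups
    on the right, shared markers connected and colored by reference group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 8))
    colors = itertools.cycle(["tab:red", "tab:green", "tab:blue", "tab:orange"])
    pos_b = map_b.marker_positions("female")
    gb = event.groups_b[0]
    rows_b = map_b.group_rows(gb)
    ax.plot([0, 0], [rows_b["female_cM"].min(), rows_b["female_cM"].max()], lw=6, color="0.8")
    offset = 1.0
    for ga, color in zip(event.groups_a, colors):
        rows_a = map_a.group_rows(ga)
        ax.plot(
            [offset, offset],
            [rows_a["female_cM"].min(), rows_a["female_cM"].max()],
            lw=6,
            color=color,
            alpha=0.4,
        )
        shared = [m for m in rows_a["marker"] if m in pos_b]
        pos_a = dict(zip(rows_a["marker"], rows_a["female_cM"]))
        for m in shared:
            ax.plot([0, offset], [pos_b[m], pos_a[m]], color=color, lw=0.5)
        ax.text(offset, -3, ga, ha="center", fontsize=8)
        offset += 1.0
    ax.text(0, -3, gb, ha="center", fontsize=8)
    if event.junction is not None:
        ax.axhline(0.5 * sum(event.junction), color="k", ls=":", lw=1)
    ax.set_ylabel("female cM")
    ax.set_xticks([])
    ax.set_title(f"{event.event_type} ({event.architecture})", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
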