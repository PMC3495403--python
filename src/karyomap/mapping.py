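"""Two-point linkage mapping from pedigree genotypes.

The recombination fraction between a marker pair is estimated by EM over the
unknown linkage phase of each doubly-heterozygous parent:

* E-step — the posterior over a parent's two phases is computed from that
  parent's offspring, together with the posterior probability that each
  transmitted gamete is recombinant;
* M-step — theta is set to the expected recombinant fraction.

Two implementations share this model.  :func:`estimate_theta` is the exact
per-pair estimator: offspring whose transmitted alleles cannot be resolved
(the other parent heterozygous or untyped) enter the likelihood through a
marginal over the unobserved transmissions, using population allele
frequencies for untyped parents.  :func:`estimate_all_thetas` is the fast
all-pairs scan used by the pipeline: it restricts each parent's meioses to
those with deterministically resolvable transmissions, which reduces the
sufficient statistics per parent and pair to two counts (phase-consistent /
phase-inconsistent transmissions) and lets the EM run vectorized over every
marker pair at once.

LOD scores are base-10 log-likelihood ratios against theta = 0.5.  Sex
-specific estimates use only the meioses of parents of that sex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit

from .maptable import COLUMNS, LinkageMapTable, map_summary  # noqa: F401  (re-export)
from .simulate import PedigreeGenotypes

__all__ = [
    "TwoPointEstimate",
    "TwoPointTable",
    "MapInconsistencyError",
    "estimate_theta",
    "estimate_all_thetas",
    "group_markers",
    "order_markers",
    "build_map",
    "build_map_from_genotypes",
    "map_summary",
    "haldane",
    "kosambi",
    "MAP_FUNCTIONS",
]

logger = logging.getLogger(__name__)

_THETA_FLOOR = 1e-12


class MapInconsistencyError(ValueError):
    """Adjacent markers are unlinked (theta = 0.5): grouping/ordering is broken."""


# ---------------------------------------------------------------------------
# mapping functions
# ---------------------------------------------------------------------------

def haldane(theta):
    """Haldane map distance in cM: d = -50 ln(1 - 2 theta)."""
    theta = np.asarray(theta, dtype=float)
    return -50.0 * np.log1p(-2.0 * theta)


def kosambi(theta):
    """Kosambi map distance in cM: d = 25 ln((1 + 2 theta) / (1 - 2 theta))."""
    theta = np.asarray(theta, dtype=float)
    return 25.0 * np.log((1.0 + 2.0 * theta) / (1.0 - 2.0 * theta))


MAP_FUNCTIONS: dict[str, Callable] = {"haldane": haldane, "kosambi": kosambi}


# ---------------------------------------------------------------------------
# exact single-pair estimator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoPointEstimate:
    marker_a: str
    marker_b: str
    theta: float
    theta_female: float
    theta_male: float
    lod: float
    n_female: int
    n_male: int

    @property
    def n_informative(self) -> int:
        return self.n_female + self.n_male


def _transmission_weights(
    obs: np.ndarray, other_geno: np.ndarray | None, freq: float
) -> np.ndarray:
    """P(offspring observation | focal parent transmitted g), g in {0, 1}.

    ``obs`` holds offspring genotypes at one marker (-1 missing).  The other
    parent's transmission is marginalized: resolved exactly when its genotype
    is homozygous, through Mendelian transmission probabilities when
    heterozygous, and through the population allele frequency when untyped.
    """
    n = len(obs)
    # probability the OTHER parent transmits allele 1
    if other_geno is None:
        p1 = np.full(n, freq)
    else:
        p1 = np.where(other_geno < 0, freq, other_geno / 2.0)
    u = np.zeros((n, 2))
    for g in (0, 1):
        need = obs - g  # allele the other parent must have transmitted
        u[:, g] = np.where(need == 0, 1.0 - p1, np.where(need == 1, p1, 0.0))
    u[obs < 0] = 1.0  # missing observation carries no information
    return u


def _collect_pair_families(
    data: PedigreeGenotypes, ia: int, ib: int
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Per doubly-heterozygous typed parent: (sex, S_same, S_diff) arrays.

    ``S_same[o]``/``S_diff[o]`` are the offspring-o likelihood factors for the
    focal parent transmitting equal / different alleles at the two markers.
    """
    freq = data.allele_frequencies()
    out = []
    for fam in data.families:
        for parent, other in ((fam.sire, fam.dam), (fam.dam, fam.sire)):
            if not data.is_typed(parent):
                continue
            gp = data.row(parent)
            if gp[ia] != 1 or gp[ib] != 1:
                continue
            other_row = data.row(other) if data.is_typed(other) else None
            if other_row is not None and other_row[ia] == 1 and other_row[ib] == 1:
                # co-parent doubly heterozygous: the resolvable meioses are an
                # ascertained subset correlated with its phase; excluded
                continue
            obs = np.array([data.row(o) for o in fam.offspring])
            ua = _transmission_weights(
                obs[:, ia], None if other_row is None else other_row[ia], freq[ia]
            )
            ub = _transmission_weights(
                obs[:, ib], None if other_row is None else other_row[ib], freq[ib]
            )
            keep = (obs[:, ia] >= 0) | (obs[:, ib] >= 0)
            ua, ub = ua[keep], ub[keep]
            s_same = ua[:, 0] * ub[:, 0] + ua[:, 1] * ub[:, 1]
            s_diff = ua[:, 0] * ub[:, 1] + ua[:, 1] * ub[:, 0]
            ok = (s_same + s_diff) > 0  # drop Mendelian-impossible observations
            if ok.sum() == 0:
                continue
            out.append((data.sex.get(parent, "?"), s_same[ok], s_diff[ok]))
    return out


def _em_exact(
    parents: list[tuple[str, np.ndarray, np.ndarray]],
    init: float,
    tol: float,
    max_iter: int,
) -> tuple[float, float, list[float]]:
    """EM on the phase-mixture likelihood; returns (theta, loglik, trace)."""

    def loglik(theta: float) -> float:
        total = 0.0
        with np.errstate(divide="ignore"):
            for _, ss, sd in parents:
                l0 = np.log(0.5 * ((1 - theta) * ss + theta * sd)).sum()
                l1 = np.log(0.5 * (theta * ss + (1 - theta) * sd)).sum()
                total += np.logaddexp(l0, l1) + np.log(0.5)
        return total

    theta = init
    trace = [loglik(theta)]
    for _ in range(max_iter):
        num = 0.0
        den = 0.0
        t = min(max(theta, _THETA_FLOOR), 0.5)
        for _, ss, sd in parents:
            a0 = (1 - t) * ss + t * sd  # per-offspring likelihood, phase 0
            a1 = t * ss + (1 - t) * sd
            l0 = np.log(a0).sum()
            l1 = np.log(a1).sum()
            p0 = expit(l0 - l1)
            r0 = t * sd / a0  # posterior recombination probability, phase 0
            r1 = t * ss / a1
            num += p0 * r0.sum() + (1 - p0) * r1.sum()
            den += len(ss)
        new = num / den if den else 0.5
        trace.append(loglik(new))
        if abs(new - theta) < tol:
            theta = new
            break
        theta = new
    return float(np.clip(theta, 0.0, 0.5)), trace[-1], trace


def estimate_theta(
    marker_a: str,
    marker_b: str,
    data: PedigreeGenotypes,
    tol: float = 1e-8,
    max_iter: int = 2000,
    inits: Sequence[float] = (0.05, 0.25, 0.45),
    return_trace: bool = False,
):
    """Maximum-likelihood two-point recombination fraction for one marker pair.

    Returns a :class:`TwoPointEstimate`; with ``return_trace`` the per
    -iteration observed-data log-likelihoods of the best EM run are returned
    as a second value (non-decreasing by construction of the EM).
    """
    ia, ib = data.marker_index(marker_a), data.marker_index(marker_b)
    parents = _collect_pair_families(data, ia, ib)

    def run(sub: list) -> tuple[float, float, list[float], int]:
        n = sum(len(ss) for _, ss, _ in sub)
        if n == 0:
            return 0.5, 0.0, [], 0
        best = None
        for init in inits:
            theta, ll, trace = _em_exact(sub, init, tol, max_iter)
            if best is None or ll > best[1] + 1e-12:
                best = (theta, ll, trace)
        return best[0], best[1], best[2], n

    theta, ll, trace, n_all = run(parents)
    theta_m, _, _, n_m = run([p for p in parents if p[0] == "M"])
    theta_f, _, _, n_f = run([p for p in parents if p[0] == "F"])
    if n_all:
        null = sum(len(ss) * np.log(0.5) + np.log(ss * 0.5 + sd * 0.5).sum()
                   for _, ss, sd in parents)
        lod = max(0.0, (ll - null) / np.log(10.0))
    else:
        lod = 0.0
    est = TwoPointEstimate(
        marker_a, marker_b, theta, theta_f, theta_m, float(lod), n_f, n_m
    )
    return (est, trace) if return_trace else est


# ---------------------------------------------------------------------------
# fast all-pairs estimator
# ---------------------------------------------------------------------------

def _deterministic_transmissions(data: PedigreeGenotypes):
    """Per typed parent: (sex, T, other_het) with T[o, m] the transmitted
    allele (nan if the parent is not heterozygous at m or the transmission is
    ambiguous) and other_het the co-parent's heterozygosity mask."""
    out = []
    G = data.genotypes
    for fam in data.families:
        off_idx = [data._index[o] for o in fam.offspring]
        O = G[off_idx]
        for parent, other in ((fam.sire, fam.dam), (fam.dam, fam.sire)):
            if not data.is_typed(parent):
                continue
            gp = data.row(parent)
            het = gp == 1
            if not het.any():
                continue
            T = np.full(O.shape, np.nan)
            T[O == 0] = 0.0
            T[O == 2] = 1.0
            other_het = None
            if data.is_typed(other):
                go = data.row(other)
                T[(O == 1) & (go == 0)[None, :]] = 1.0
                T[(O == 1) & (go == 2)[None, :]] = 0.0
                other_het = go == 1
            T[:, ~het] = np.nan
            out.append((data.sex.get(parent, "?"), T, other_het))
    return out


def _em_counts(
    ns: np.ndarray, nd: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized phase-mixture EM on per-parent (same, different) transmission
    counts.  ``ns``/``nd`` have shape (n_parents, n_pairs); returns
    (theta, lod) per pair."""
    ns = ns.astype(np.float64)
    nd = nd.astype(np.float64)
    n_per_pair = ns.sum(axis=0) + nd.sum(axis=0)
    k = ns.shape[1]
    theta = np.full(k, 0.25)
    informative = n_per_pair > 0
    active = np.flatnonzero(informative)
    for _ in range(max_iter):
        if len(active) == 0:
            break
        th = theta[active]
        ns_a = ns[:, active]
        nd_a = nd[:, active]
        lt = np.log(np.clip(th, _THETA_FLOOR, None))
        lu = np.log(np.clip(1.0 - th, _THETA_FLOOR, None))
        p0 = expit(ns_a * (lu - lt) + nd_a * (lt - lu))
        r = (p0 * nd_a + (1.0 - p0) * ns_a).sum(axis=0)
        new = np.clip(r / np.maximum(n_per_pair[active], 1.0), 0.0, 0.5)
        moved = np.abs(new - th) >= tol
        theta[active] = new
        active = active[moved]
    theta = np.where(informative, theta, 0.5)
    lt = np.log(np.clip(theta, _THETA_FLOOR, None))
    lu = np.log(np.clip(1.0 - theta, _THETA_FLOOR, None))
    loglik = (np.logaddexp(ns * lu + nd * lt, ns * lt + nd * lu) + np.log(0.5)).sum(axis=0)
    lod = np.where(informative, (loglik - n_per_pair * np.log(0.5)) / np.log(10.0), 0.0)
    return theta, np.maximum(lod, 0.0)


@dataclass
class TwoPointTable:
    """All-pairs two-point estimates plus retained per-parent statistics.

    ``theta``/``lod`` are condensed upper-triangle vectors over ``markers``.
    The per-parent transmission-count stacks are kept so that sex-specific
    thetas can be computed lazily for any pair subset.
    """

    markers: list[str]
    theta: np.ndarray
    lod: np.ndarray
    n_informative: np.ndarray
    marker_meioses: np.ndarray
    _ns: np.ndarray = field(repr=False)
    _nd: np.ndarray = field(repr=False)
    _parent_sex: np.ndarray = field(repr=False)
    em_tol: float = 1e-6
    em_max_iter: int = 200

    def __post_init__(self) -> None:
        self._index = {m: i for i, m in enumerate(self.markers)}
        self._sex_overrides: dict[int, tuple[float, float, int, int]] = {}
        m = len(self.markers)
        self._iu = np.triu_indices(m, 1)
        flat = np.full((m, m), -1, dtype=np.int64)
        flat[self._iu] = np.arange(len(self.theta))
        flat[(self._iu[1], self._iu[0])] = np.arange(len(self.theta))
        self._flat = flat

    def pair_index(self, a: str, b: str) -> int:
        i, j = self._index[a], self._index[b]
        if i == j:
            raise KeyError("marker pair must be distinct")
        return int(self._flat[i, j])

    def theta_matrix(self) -> np.ndarray:
        m = len(self.markers)
        out = np.zeros((m, m))
        out[self._iu] = self.theta
        return out + out.T

    def shrunk_theta_matrix(self, prior_meioses: float = 8.0) -> np.ndarray:
        """Theta shrunk toward 0.5 in proportion to informativeness.

        With unknown phase, sparsely informative pairs are biased toward
        theta 0 (min(same, different) counts are small), which makes raw
        thetas unusable as a seriation cost.  The shrunk estimate
        ``(theta * n + 0.5 * n0) / (n + n0)`` behaves like a posterior mean
        with ``n0`` pseudo-meioses at theta 0.5.
        """
        m = len(self.markers)
        n = self.n_informative.astype(float)
        shrunk = (self.theta * n + 0.5 * prior_meioses) / (n + prior_meioses)
        out = np.zeros((m, m))
        out[self._iu] = shrunk
        return out + out.T

    def lod_matrix(self) -> np.ndarray:
        m = len(self.markers)
        out = np.zeros((m, m))
        out[self._iu] = self.lod
        return out + out.T

    def sex_thetas(self, pair_indices: np.ndarray):
        """(theta_female, theta_male, n_female, n_male) for selected pairs.

        Pairs refined with :func:`refine_thetas` return their exact-EM
        overrides; the rest fall back on the deterministic-transmission scan.
        """
        pair_indices = np.asarray(pair_indices, dtype=np.int64)
        results = {}
        for sex in ("F", "M"):
            rows = self._parent_sex == sex
            ns = self._ns[rows][:, pair_indices]
            nd = self._nd[rows][:, pair_indices]
            theta, _ = _em_counts(ns, nd, self.em_tol, self.em_max_iter)
            results[sex] = (theta, (ns + nd).sum(axis=0).astype(int))
        tf, nf = results["F"]
        tm, nm = results["M"]
        for pos, p in enumerate(pair_indices):
            if int(p) in self._sex_overrides:
                tf[pos], tm[pos], nf[pos], nm[pos] = self._sex_overrides[int(p)]
        return tf, tm, nf, nm

    def estimate(self, a: str, b: str) -> TwoPointEstimate:
        k = self.pair_index(a, b)
        tf, tm, nf, nm = self.sex_thetas(np.array([k]))
        return TwoPointEstimate(
            a, b, float(self.theta[k]), float(tf[0]), float(tm[0]),
            float(self.lod[k]), int(nf[0]), int(nm[0]),
        )


def estimate_all_thetas(
    data: PedigreeGenotypes, em_tol: float = 1e-6, em_max_iter: int = 200
) -> TwoPointTable:
    """Vectorized two-point scan over every marker pair.

    Only deterministically resolvable transmissions contribute (ambiguous
    meioses — other parent heterozygous or untyped with a heterozygous
    offspring — are dropped), which is what allows the per-parent sufficient
    statistics to reduce to two counts per pair.
    """
    m = len(data.markers)
    iu = np.triu_indices(m, 1)
    transmissions = _deterministic_transmissions(data)
    n_parents = len(transmissions)
    k = len(iu[0])
    ns = np.zeros((n_parents, k), dtype=np.int16)
    nd = np.zeros((n_parents, k), dtype=np.int16)
    sexes = np.empty(n_parents, dtype="U1")
    meioses = np.zeros(m, dtype=np.int64)
    for p, (sex, T, other_het) in enumerate(transmissions):
        sexes[p] = sex
        a = (T == 1.0).astype(np.float32)
        b = (T == 0.0).astype(np.float32)
        same = a.T @ a + b.T @ b
        diff = a.T @ b + b.T @ a
        if other_het is not None and other_het.any():
            # pairs where the co-parent is heterozygous at both markers are
            # dropped for this parent: the resolvable-meioses subset there is
            # ascertained through the co-parent's correlated transmissions
            # (its linkage phase), which biases theta in either direction
            hh = np.flatnonzero(other_het)
            same[np.ix_(hh, hh)] = 0.0
            diff[np.ix_(hh, hh)] = 0.0
        ns[p] = same[iu].astype(np.int16)
        nd[p] = diff[iu].astype(np.int16)
        meioses += (a + b).sum(axis=0).astype(np.int64)
    theta, lod = _em_counts(ns, nd, em_tol, em_max_iter)
    return TwoPointTable(
        markers=list(data.markers),
        theta=theta,
        lod=lod,
        n_informative=(ns.astype(np.int64) + nd).sum(axis=0),
        marker_meioses=meioses,
        _ns=ns,
        _nd=nd,
        _parent_sex=sexes,
        em_tol=em_tol,
        em_max_iter=em_max_iter,
    )


# ---------------------------------------------------------------------------
# exact EM refinement for selected pairs
# ---------------------------------------------------------------------------

def _exact_em_selected(
    data: PedigreeGenotypes,
    pair_markers: list[tuple[int, int]],
    sexes: set[str] | None = None,
    init: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
):
    """Ambiguity-aware EM, vectorized across a list of marker-index pairs.

    Unlike the deterministic-transmission scan, every meiosis of a doubly
    -heterozygous parent contributes: unresolvable transmissions enter
    through their marginal probabilities (population allele frequencies for
    untyped co-parents).  Returns (theta, n_meioses) arrays.
    """
    ia = np.array([p[0] for p in pair_markers])
    ib = np.array([p[1] for p in pair_markers])
    k = len(pair_markers)
    freq = data.allele_frequencies()
    cache = []  # per parent: (Ss, Sd, mask, n_off)
    for fam in data.families:
        off_rows = np.array([data.row(o) for o in fam.offspring])
        for parent, other in ((fam.sire, fam.dam), (fam.dam, fam.sire)):
            if not data.is_typed(parent):
                continue
            if sexes is not None and data.sex.get(parent) not in sexes:
                continue
            gp = data.row(parent)
            other_row = data.row(other) if data.is_typed(other) else None
            u = np.ones((len(fam.offspring), len(data.markers), 2))
            obs = off_rows
            if other_row is None:
                p1 = np.broadcast_to(freq, obs.shape)
            else:
                p1 = np.where(other_row < 0, freq, other_row / 2.0)[None, :]
                p1 = np.broadcast_to(p1, obs.shape)
            for g in (0, 1):
                need = obs - g
                u[:, :, g] = np.where(need == 0, 1.0 - p1, np.where(need == 1, p1, 0.0))
            u[obs < 0] = 1.0
            mask = ((gp[ia] == 1) & (gp[ib] == 1)).astype(float)
            if other_row is not None:
                oh = other_row == 1
                mask *= ~(oh[ia] & oh[ib])  # co-parent doubly het: ascertainment bias
            if not mask.any():
                continue
            u0a, u1a = u[:, ia, 0], u[:, ia, 1]
            u0b, u1b = u[:, ib, 0], u[:, ib, 1]
            ss = u0a * u0b + u1a * u1b
            sd = u0a * u1b + u1a * u0b
            bad = (ss + sd) <= 0  # Mendelian-impossible observation: drop
            ss[bad] = 1.0
            sd[bad] = 1.0
            cache.append((ss.astype(np.float32), sd.astype(np.float32), mask,
                          float(len(fam.offspring))))
    n = np.zeros(k)
    for _, _, mask, n_off in cache:
        n += mask * n_off
    if not cache or not n.any():
        return np.full(k, 0.5), n

    theta = np.clip(init if init is not None else np.full(k, 0.25), 0.01, 0.49)
    theta = np.asarray(theta, dtype=np.float64).copy()
    active = np.flatnonzero(n > 0)
    for _ in range(max_iter):
        if len(active) == 0:
            break
        th = theta[active]
        num = np.zeros(len(active))
        for ss, sd, mask, _ in cache:
            m_a = mask[active]
            if not m_a.any():
                continue
            ss_a = ss[:, active].astype(np.float64)
            sd_a = sd[:, active].astype(np.float64)
            a0 = (1.0 - th) * ss_a + th * sd_a
            a1 = th * ss_a + (1.0 - th) * sd_a
            p0 = expit(np.log(a0 / a1).sum(axis=0))
            r0 = (th * sd_a / a0).sum(axis=0)
            r1 = (th * ss_a / a1).sum(axis=0)
            num += m_a * (p0 * r0 + (1.0 - p0) * r1)
        new = np.clip(num / np.maximum(n[active], 1.0), _THETA_FLOOR, 0.5)
        moved = np.abs(new - th) >= tol
        theta[active] = new
        active = active[moved]
    theta = np.where(n > 0, theta, 0.5)
    return theta, n


def refine_thetas(
    table: TwoPointTable,
    data: PedigreeGenotypes,
    pair_indices: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 100,
    include_sex: bool = False,
) -> None:
    """Replace fast-scan estimates for selected pairs with exact EM estimates.

    Updates the combined theta and meiosis count in place (LOD keeps the
    conservative fast-scan value used for grouping).  With ``include_sex``
    sex-specific overrides are stored, consulted by
    :meth:`TwoPointTable.sex_thetas`; these are only needed for adjacent
    pairs, so the default defers them.
    """
    pair_indices = np.asarray(pair_indices, dtype=np.int64)
    if len(pair_indices) == 0:
        return
    i_idx, j_idx = table._iu
    pair_markers = [(int(i_idx[p]), int(j_idx[p])) for p in pair_indices]
    theta, n = _exact_em_selected(
        data, pair_markers, None, table.theta[pair_indices], tol, max_iter
    )
    table.theta[pair_indices] = theta
    table.n_informative[pair_indices] = n.astype(table.n_informative.dtype)
    if include_sex:
        tf, nf = _exact_em_selected(data, pair_markers, {"F"}, theta, tol, max_iter)
        tm, nm = _exact_em_selected(data, pair_markers, {"M"}, theta, tol, max_iter)
        for p, a, b, c, d_ in zip(pair_indices, tf, tm, nf, nm):
            table._sex_overrides[int(p)] = (float(a), float(b), int(c), int(d_))


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def group_markers(
    table: TwoPointTable, lod_threshold: float = 5.0
) -> tuple[list[list[str]], list[str]]:
    """Single-linkage partition of markers: transitive closure over pairs with
    LOD >= threshold.  Returns (groups, singletons); groups are sorted by
    descending size, then by smallest marker id, and listed in input marker
    order internally."""
    g = nx.Graph()
    g.add_nodes_from(table.markers)
    keep = table.lod >= lod_threshold
    i_idx, j_idx = table._iu
    for i, j in zip(i_idx[keep], j_idx[keep]):
        g.add_edge(table.markers[i], table.markers[j])
    order = {m: i for i, m in enumerate(table.markers)}
    groups, singletons = [], []
    for comp in nx.connected_components(g):
        members = sorted(comp, key=order.__getitem__)
        if len(members) == 1:
            singletons.append(members[0])
        else:
            groups.append(members)
    groups.sort(key=lambda ms: (-len(ms), min(ms)))
    singletons.sort()
    return groups, singletons


# ---------------------------------------------------------------------------
# ordering
# ---------------------------------------------------------------------------

def _greedy_chain(d: np.ndarray, names: list[str]) -> list[int]:
    """Greedy nearest-neighbour chaining: grow paths by repeatedly joining the
    two fragment ends with the smallest pairwise theta.  Ties are broken by
    lexicographic marker id for determinism."""
    n = len(d)
    frags: list[list[int]] = [[i] for i in range(n)]
    while len(frags) > 1:
        best = None
        for a in range(len(frags)):
            for b in range(a + 1, len(frags)):
                for ea in (frags[a][0], frags[a][-1]):
                    for eb in (frags[b][0], frags[b][-1]):
                        key = (d[ea, eb], names[ea], names[eb])
                        if best is None or key < best[0]:
                            best = (key, a, b, ea, eb)
        _, a, b, ea, eb = best
        fa = frags[a] if frags[a][-1] == ea else frags[a][::-1]
        fb = frags[b] if frags[b][0] == eb else frags[b][::-1]
        frags[a] = fa + fb
        del frags[b]
    return frags[0]


_BAND_LAGS = 3


def _banded_cost(order, d: np.ndarray, lags: int = _BAND_LAGS) -> float:
    """Seriation objective: lag-weighted sum of thetas over a small band.

    Restricted to lag 1 this is the plain adjacent-theta sum.  The extra
    lags pool nearly independent two-point estimates, which suppresses the
    estimate noise that otherwise makes spurious adjacent swaps optimal.
    The true order minimizes every lag term in expectation (theta increases
    with map distance), so the banded sum keeps the same optimum while
    shrinking its variance.
    """
    arr = np.asarray(order)
    total = 0.0
    for lag in range(1, min(lags, len(arr) - 1) + 1):
        total += d[arr[:-lag], arr[lag:]].sum() / lag
    return float(total)


def _two_opt(order: list[int], d: np.ndarray, max_passes: int = 60) -> list[int]:
    """Local search: reverse any sub-segment while it lowers the banded cost."""
    n = len(order)
    cost = _banded_cost(order, d)
    for _ in range(max_passes):
        improved = False
        for a in range(n - 1):
            for b in range(a + 1, n):
                cand = order[:a] + order[a : b + 1][::-1] + order[b + 1 :]
                c = _banded_cost(cand, d)
                if c < cost - 1e-12:
                    order, cost = cand, c
                    improved = True
        if not improved:
            break
    return order


def _window_polish(order: list[int], d: np.ndarray, window: int = 5, max_passes: int = 50) -> list[int]:
    """Exhaustive permutation of every sliding window until no gain (flips-style)."""
    from itertools import permutations

    n = len(order)
    if n <= 2:
        return order
    window = min(window, n)
    perms = [list(p) for p in permutations(range(window))]
    cost = _banded_cost(order, d)
    for _ in range(max_passes):
        improved = False
        for start in range(n - window + 1):
            seg = order[start : start + window]
            best, best_cost = None, cost
            for p in perms:
                cand = order[:start] + [seg[i] for i in p] + order[start + window :]
                c = _banded_cost(cand, d)
                if c < best_cost - 1e-12:
                    best, best_cost = cand, c
            if best is not None:
                order, cost = best, best_cost
                improved = True
        if not improved:
            break
    return order


def _pair_variances(table: TwoPointTable) -> np.ndarray:
    """Approximate sampling variance of each theta estimate, as a full matrix."""
    n = np.maximum(table.n_informative.astype(float), 1.0)
    t = np.clip(table.theta, 0.05, 0.45)  # floor keeps variance of theta-hat = 0 sane
    v = t * (1.0 - t) / n
    m = len(table.markers)
    out = np.zeros((m, m))
    out[table._iu] = v
    return out + out.T


def _reference_polish(
    order: list[int],
    group: list[str],
    d: np.ndarray,
    var: np.ndarray,
    ref_key: dict,
    window: int = 4,
    z: float = 2.0,
    max_passes: int = 10,
) -> list[int]:
    """Resolve locally unsupported order choices with the reference map.

    For every sliding window, permutations whose banded cost is within
    ``z`` standard errors of the optimum (standard error from the summed
    sampling variances of the differing theta terms) are considered
    unresolved by the recombination data; among those, the permutation most
    concordant with the reference order is chosen.

    Concordance is evaluated per reference linkage group and up to block
    reversal: each reference group's direction along the current order is
    estimated first, so a genuinely reverse-oriented block (one side of a
    head-to-head fusion) is polished toward the reversed reference order
    rather than being flipped back.
    """
    from itertools import permutations

    n = len(order)
    if n < 2:
        return order
    window = min(window, n)
    perms = [list(p) for p in permutations(range(window))]

    def banded_terms(o: list[int]) -> set:
        terms = set()
        for lag in range(1, min(_BAND_LAGS, len(o) - 1) + 1):
            for i in range(len(o) - lag):
                a, b = o[i], o[i + lag]
                terms.add((min(a, b), max(a, b), lag))
        return terms

    def oriented_keys(o: list[int]) -> dict[int, tuple]:
        directions = _group_directions(o, group, ref_key)
        keys = {}
        for i in range(n):
            m = group[i]
            if m in ref_key:
                g, pos = ref_key[m]
                keys[i] = (g, directions.get(g, 1) * pos)
        return keys

    def ref_discord(o: list[int], keys: dict[int, tuple]) -> int:
        seq = [keys[i] for i in o if i in keys]
        return sum(
            1
            for x in range(len(seq))
            for y in range(x + 1, len(seq))
            if seq[x][0] == seq[y][0] and seq[x][1] > seq[y][1]
        )

    for _ in range(max_passes):
        changed = False
        keys = oriented_keys(order)
        for start in range(n - window + 1):
            seg = order[start : start + window]
            candidates = []
            for p in perms:
                cand = order[:start] + [seg[i] for i in p] + order[start + window :]
                candidates.append(cand)
            # single-marker relocations reach beyond the window: they rescue
            # weakly informative markers parked at a chromosome end
            if start == 0:
                for i in range(n):
                    for j in range(n):
                        if i == j:
                            continue
                        cand = order[:i] + order[i + 1 :]
                        cand = cand[:j] + [order[i]] + cand[j:]
                        candidates.append(cand)
            costs = [_banded_cost(c, d) for c in candidates]
            best_cost = min(costs)
            best_terms = banded_terms(candidates[int(np.argmin(costs))])
            keep = []
            for cand, cost in zip(candidates, costs):
                if cost <= best_cost + 1e-12:
                    keep.append(cand)
                    continue
                diff = banded_terms(cand) ^ best_terms
                se = np.sqrt(sum(var[a, b] / (lag * lag) for a, b, lag in diff))
                if cost - best_cost <= z * se:
                    keep.append(cand)
            best = min(
                keep, key=lambda c: (ref_discord(c, keys), _banded_cost(c, d))
            )
            if best != order:
                order = best
                changed = True
        if not changed:
            break
    return order


def _group_directions(order: list[int], group: list[str], ref_key: dict) -> dict:
    """Direction (+1/-1) of each reference group's positions along an order."""
    by_group: dict[str, list[float]] = {}
    for i in order:
        m = group[i]
        if m in ref_key:
            g, pos = ref_key[m]
            by_group.setdefault(g, []).append(pos)
    directions = {}
    for g, seq in by_group.items():
        inv = sum(
            1
            for x in range(len(seq))
            for y in range(x + 1, len(seq))
            if seq[x] > seq[y]
        )
        total = len(seq) * (len(seq) - 1) // 2
        directions[g] = 1 if inv * 2 <= total else -1
    return directions


def order_markers(
    group: Sequence[str],
    table: TwoPointTable,
    reference_order=None,
    bin_theta: float = 1e-4,
) -> list[str]:
    """Order a linkage group by seriation on pairwise thetas.

    A greedy nearest-neighbour chain (grown by joining fragment ends at the
    smallest theta) is improved by 2-opt segment reversals and exhaustive
    sliding-window permutation until no banded-cost reduction remains.  With
    a reference supplied, local arrangements the recombination data cannot
    distinguish (within two standard errors of the optimum) are resolved
    toward the reference order, and runs of markers at effectively zero
    theta — co-segregating bins — take their internal order from the
    reference when it covers every member, otherwise the input order.  The
    final orientation is chosen so that shared-marker positions correlate
    positively with the reference; without one it is canonicalized
    lexicographically.
    """
    group = list(group)
    if len(group) <= 1:
        return group
    ref_key = _as_reference_keys(reference_order)
    idx = [table._index[m] for m in group]
    d_raw = table.theta_matrix()[np.ix_(idx, idx)]
    # seriation cost uses information-shrunk thetas; raw thetas define bins
    d = table.shrunk_theta_matrix()[np.ix_(idx, idx)]
    n = len(group)

    if n == 2:
        order = [0, 1]
    else:
        order = _greedy_chain(d, [group[i] for i in range(n)])
        order = _two_opt(order, d)
        order = _window_polish(order, d)
    if ref_key is not None and n > 2:
        var = _pair_variances(table)[np.ix_(idx, idx)]
        order = _reference_polish(order, group, d, var, ref_key)

    # orientation first, so bin-internal reference order survives as written
    if ref_key is not None:
        shared = [i for i in order if group[i] in ref_key]
        if len(shared) >= 2:
            from scipy.stats import spearmanr

            pos = [order.index(i) for i in shared]
            rank = {
                i: r
                for r, i in enumerate(sorted(shared, key=lambda i: ref_key[group[i]]))
            }
            rho = spearmanr(pos, [rank[i] for i in shared]).correlation
            if rho is not None and not np.isnan(rho) and rho < 0:
                order = order[::-1]
    elif group[order[0]] > group[order[-1]]:
        order = order[::-1]

    # co-segregating bins: adjacent theta below bin_theta
    bins: list[list[int]] = [[order[0]]]
    for prev, cur in zip(order, order[1:]):
        if d_raw[prev, cur] < bin_theta:
            bins[-1].append(cur)
        else:
            bins.append([cur])
    input_rank = {m: i for i, m in enumerate(group)}
    directions = _group_directions(order, group, ref_key) if ref_key is not None else {}
    for b in bins:
        if len(b) == 1:
            continue
        members = [group[i] for i in b]
        if ref_key is not None and all(m in ref_key for m in members):
            ref_groups = {ref_key[m][0] for m in members}
            if len(ref_groups) == 1:
                # follow the block's direction so reversed fusion blocks keep
                # their (reversed) reference order inside bins
                sign = directions.get(next(iter(ref_groups)), 1)
                members.sort(key=lambda m: sign * ref_key[m][1])
            else:
                members.sort(key=ref_key.__getitem__)
        else:
            members.sort(key=input_rank.__getitem__)
        b[:] = [input_rank[m] for m in members]

    return [group[i] for b in bins for i in b]


def _as_reference_keys(reference_order):
    """Normalize a reference order to a mapping id -> (group, position).

    Accepts an ordered list of ids, a mapping to scalar positions, or a
    mapping to (group, position) tuples.
    """
    if reference_order is None:
        return None
    if isinstance(reference_order, dict):
        out = {}
        for m, v in reference_order.items():
            out[m] = v if isinstance(v, tuple) else ("", float(v))
        return out
    return {m: ("", float(i)) for i, m in enumerate(reference_order)}


# ---------------------------------------------------------------------------
# map building
# ---------------------------------------------------------------------------

def _skip_theta(ordered: Sequence[str], k: int, table: TwoPointTable) -> float:
    """Estimate the theta of the adjacent pair (k, k+1) from a flanking skip
    pair, for adjacent pairs without any informative meioses of their own."""
    candidates = []
    if k > 0:
        skip = table.pair_index(ordered[k - 1], ordered[k + 1])
        near = table.pair_index(ordered[k - 1], ordered[k])
        if table.n_informative[skip] > 0 and table.n_informative[near] > 0:
            candidates.append(table.theta[skip] - table.theta[near])
    if k + 2 < len(ordered):
        skip = table.pair_index(ordered[k], ordered[k + 2])
        near = table.pair_index(ordered[k + 1], ordered[k + 2])
        if table.n_informative[skip] > 0 and table.n_informative[near] > 0:
            candidates.append(table.theta[skip] - table.theta[near])
    if not candidates:
        return 0.0
    return float(np.clip(np.mean(candidates), 0.0, 0.49))


def build_map(
    ordered: Sequence[str],
    table: TwoPointTable,
    mapping_function: str = "kosambi",
    max_theta: float = 0.499999,
) -> pd.DataFrame:
    """Cumulative sex-specific cM positions for an ordered marker list.

    Adjacent-pair thetas are converted to distances with the chosen mapping
    function.  Where one sex has no informative meioses for an adjacent pair
    the combined theta is substituted.  An adjacent combined theta of 0.5
    (unlinked neighbours) raises :class:`MapInconsistencyError`.
    """
    if mapping_function not in MAP_FUNCTIONS:
        raise ValueError(f"unknown mapping function {mapping_function!r}")
    fn = MAP_FUNCTIONS[mapping_function]
    ordered = list(ordered)
    if len(ordered) == 1:
        female = male = np.zeros(1)
    else:
        pairs = np.array(
            [table.pair_index(a, b) for a, b in zip(ordered, ordered[1:])]
        )
        theta_c = table.theta[pairs].copy()
        n_inf = table.n_informative[pairs]
        for k in np.flatnonzero(n_inf == 0):
            # no informative meioses at all for this adjacent pair: bridge the
            # gap with a skip-pair difference instead of calling it unlinked
            theta_c[k] = _skip_theta(ordered, int(k), table)
            logger.warning(
                "no informative meioses for adjacent pair %s/%s; bridged "
                "with skip-pair estimate %.4f", ordered[k], ordered[k + 1], theta_c[k]
            )
        if np.any((theta_c >= max_theta) & (n_inf > 0)):
            bad = int(np.argmax((theta_c >= max_theta) & (n_inf > 0)))
            raise MapInconsistencyError(
                f"adjacent markers {ordered[bad]!r}/{ordered[bad + 1]!r} are unlinked "
                "(theta = 0.5); grouping or ordering is inconsistent"
            )
        tf, tm, nf, nm = table.sex_thetas(pairs)
        tf = np.where(nf > 0, tf, theta_c)
        tm = np.where(nm > 0, tm, theta_c)
        if np.any(nf == 0) or np.any(nm == 0):
            logger.warning(
                "substituted combined theta for %d/%d adjacent pairs lacking "
                "sex-specific meioses", int((nf == 0).sum() + (nm == 0).sum()), len(pairs)
            )
        tf = np.minimum(tf, max_theta)
        tm = np.minimum(tm, max_theta)
        female = np.concatenate([[0.0], np.cumsum(fn(tf))])
        male = np.concatenate([[0.0], np.cumsum(fn(tm))])
    meioses = [int(table.marker_meioses[table._index[m]]) for m in ordered]
    return pd.DataFrame(
        {
            "marker": ordered,
            "order": np.arange(1, len(ordered) + 1),
            "female_cM": female,
            "male_cM": male,
            "n_meioses": meioses,
        }
    )


def build_map_from_genotypes(
    data: PedigreeGenotypes,
    lod_threshold: float = 5.0,
    mapping_function: str = "kosambi",
    reference: LinkageMapTable | None = None,
    bin_theta: float = 1e-4,
    em_tol: float = 1e-6,
    em_max_iter: int = 200,
) -> tuple[LinkageMapTable, TwoPointTable]:
    """Full pipeline: thetas -> groups -> per-group order -> cM positions.

    Groups are named LG01, LG02, ... by descending size.  When a reference
    table is given it supplies co-segregation tie-breaking and orientation,
    and markers absent from it are flagged population specific.
    """
    table = estimate_all_thetas(data, em_tol=em_tol, em_max_iter=em_max_iter)
    groups, singletons = group_markers(table, lod_threshold)
    if singletons:
        logger.info("dropping %d unlinked singleton markers", len(singletons))
    # within-group pairs get the exact (ambiguity-aware) EM: ordering and
    # distances then use every meiosis, not just resolvable transmissions
    within = np.concatenate(
        [
            np.array(
                [table.pair_index(a, b) for i, a in enumerate(g) for b in g[i + 1 :]],
                dtype=np.int64,
            )
            for g in groups
        ]
    ) if groups else np.empty(0, dtype=np.int64)
    refine_thetas(table, data, within, tol=em_tol)
    ref_key = None
    ref_ids: set[str] = set()
    if reference is not None:
        ref_ids = set(reference.markers)
        ref_groups = reference.marker_groups()
        ref_pos = reference.marker_positions("female")
        ref_key = {m: (ref_groups[m], ref_pos[m]) for m in reference.markers}
    orders = [
        order_markers(members, table, reference_order=ref_key, bin_theta=bin_theta)
        for members in groups
    ]
    adjacent = [
        table.pair_index(a, b)
        for ordered in orders
        for a, b in zip(ordered, ordered[1:])
    ]
    refine_thetas(
        table, data, np.array(adjacent, dtype=np.int64), tol=em_tol, include_sex=True
    )
    frames = []
    for g, ordered in enumerate(orders):
        rows = build_map(ordered, table, mapping_function=mapping_function)
        rows.insert(1, "group", f"LG{g + 1:02d}")
        rows["accession"] = ""
        rows["population_specific"] = [
            (m not in ref_ids) if reference is not None else False for m in rows["marker"]
        ]
        frames.append(rows)
    if frames:
        df = pd.concat(frames, ignore_index=True)[COLUMNS]
    else:
        df = pd.DataFrame(columns=COLUMNS)
    return LinkageMapTable(df), table
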