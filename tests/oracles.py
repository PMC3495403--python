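"""Independent brute-force oracles used by unit and acceptance tests.

The grid-search oracle evaluates the exact two-point phase-mixture
likelihood with explicit loops over phases and transmitted-allele
configurations — deliberately sharing no code with the package's EM.
"""

import numpy as np

from karyomap.simulate import Family, PedigreeGenotypes

GRID = np.arange(0.0, 0.5 + 1e-12, 1e-4)


def _u_weights(obs, other_geno, freq):
    """P(offspring obs | focal parent transmitted g) for g in {0, 1}."""
    if obs < 0:
        return np.array([1.0, 1.0])
    if other_geno is None or other_geno < 0:
        p1 = freq
    else:
        p1 = other_geno / 2.0
    out = np.zeros(2)
    for g in (0, 1):
        need = obs - g
        if need == 0:
            out[g] = 1.0 - p1
        elif need == 1:
            out[g] = p1
    return out


def loglik_on_grid(data: PedigreeGenotypes, marker_a: str, marker_b: str, grid=GRID):
    """Log-likelihood of theta over a grid, summing over parental phases and
    unobserved transmissions."""
    ia = data.marker_index(marker_a)
    ib = data.marker_index(marker_b)
    freq = data.allele_frequencies()
    total = np.zeros(len(grid))
    for fam in data.families:
        for parent, other in ((fam.sire, fam.dam), (fam.dam, fam.sire)):
            if not data.is_typed(parent):
                continue
            gp = data.row(parent)
            if gp[ia] != 1 or gp[ib] != 1:
                continue
            other_row = data.row(other) if data.is_typed(other) else None
            if other_row is not None and other_row[ia] == 1 and other_row[ib] == 1:
                continue  # mirror the estimator's ascertainment exclusion
            lphase = [np.zeros(len(grid)), np.zeros(len(grid))]
            for off in fam.offspring:
                o = data.row(off)
                ua = _u_weights(o[ia], None if other_row is None else other_row[ia], freq[ia])
                ub = _u_weights(o[ib], None if other_row is None else other_row[ib], freq[ib])
                if o[ia] < 0 and o[ib] < 0:
                    continue
                consistent = False
                probs = [np.zeros(len(grid)), np.zeros(len(grid))]
                for phase in (0, 1):
                    for g1 in (0, 1):
                        for g2 in (0, 1):
                            w = ua[g1] * ub[g2]
                            if w == 0:
                                continue
                            consistent = True
                            recombinant = (g1 ^ g2) ^ phase
                            pt = grid if recombinant else 1.0 - grid
                            probs[phase] = probs[phase] + 0.5 * w * pt
                if not consistent:
                    continue
                for phase in (0, 1):
                    with np.errstate(divide="ignore"):
                        lphase[phase] = lphase[phase] + np.log(probs[phase])
            total = total + np.logaddexp(lphase[0], lphase[1]) + np.log(0.5)
    return total


def grid_argmax_theta(data, marker_a, marker_b, grid=GRID):
    ll = loglik_on_grid(data, marker_a, marker_b, grid)
    return float(grid[int(np.argmax(ll))]), ll


def random_two_marker_instance(rng) -> tuple[PedigreeGenotypes, float]:
    """A small random two-marker pedigree with known theta.

    Dams are doubly heterozygous (informative); sires are drawn hom/het/
    untyped but never doubly heterozygous, so the estimator's likelihood and
    the oracle's coincide on every meiosis.
    """
    theta = float(rng.uniform(0.02, 0.40))
    n_fam = int(rng.integers(2, 5))
    individuals, rows, families, sex = [], [], [], {}
    for f in range(n_fam):
        sire, dam = f"f{f}s", f"f{f}d"
        phase = int(rng.integers(2))
        dam_haps = np.array([[0, phase], [1, 1 - phase]])
        untyped = rng.random() < 0.25
        while True:
            sire_geno = rng.integers(0, 3, size=2)
            if not (sire_geno[0] == 1 and sire_geno[1] == 1):
                break
        # sire haplotypes per marker: hom -> equal alleles, het -> 0/1
        h0 = np.array([0 if g == 0 else (1 if g == 2 else 0) for g in sire_geno])
        h1 = np.array([0 if g == 0 else 1 for g in sire_geno])
        offspring = []
        n_off = int(rng.integers(8, 25))
        geno_rows = []
        for j in range(n_off):
            s0 = int(rng.integers(2))
            s1 = s0 if rng.random() > theta else 1 - s0
            dam_gamete = np.array([dam_haps[s0, 0], dam_haps[s1, 1]])
            sire_gamete = np.array(
                [h0[m] if rng.random() < 0.5 else h1[m] for m in range(2)]
            )
            geno = (dam_gamete + sire_gamete).astype(np.int8)
            for m in range(2):  # sprinkle missing observations
                if rng.random() < 0.08:
                    geno[m] = -1
            offspring.append(f"f{f}o{j}")
            geno_rows.append(geno)
        individuals += [sire, dam] + offspring
        rows += [
            np.full(2, -1, np.int8) if untyped else sire_geno.astype(np.int8),
            dam_haps.sum(axis=0).astype(np.int8),
        ] + geno_rows
        sex[sire], sex[dam] = "M", "F"
        families.append(Family(f"f{f}", sire, dam, offspring))
    data = PedigreeGenotypes(
        individuals, ["mA", "mB"], np.array(rows, dtype=np.int8), families, sex
    )
    return data, theta
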