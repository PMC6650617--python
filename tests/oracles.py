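"""Independent brute-force oracles used to validate the package.

Everything here is written as plain loops over the defining formulas,
deliberately independent of the vectorized implementation paths.
"""

from __future__ import annotations

import math

import numpy as np


def min_image(vec, box):
    if box is None:
        return vec
    return vec - box * np.round(vec / box)


def dist(frame, i, j):
    return float(
        np.linalg.norm(min_image(frame.coordinates[i] - frame.coordinates[j], frame.box))
    )


def brute_contact_residues(frame, system, cutoff):
    """Set of (chain, residue index) of protein residues with any heavy atom
    within cutoff of any ligand heavy atom."""
    out = set()
    for i in range(system.n_atoms):
        if system.groups[i] != "protein" or system.elements[i] == "H":
            continue
        for j in range(system.n_atoms):
            if system.groups[j] not in ("head", "alpha", "tail"):
                continue
            if system.elements[j] == "H":
                continue
            if dist(frame, i, j) <= cutoff:
                out.add((system.chains[i], int(system.residue_indices[i])))
    return out


def brute_hbonds(frame, system, da_cutoff, angle_cutoff):
    """Set of (donor, hydrogen, acceptor) triples meeting the criteria."""
    out = set()
    for d, h in system.donors:
        for a in system.acceptors:
            if a == d or a == h:
                continue
            r = dist(frame, d, a)
            if r > da_cutoff:
                continue
            if angle_cutoff is not None and h is not None:
                v1 = min_image(frame.coordinates[h] - frame.coordinates[d], frame.box)
                v2 = min_image(frame.coordinates[a] - frame.coordinates[d], frame.box)
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                if angle > angle_cutoff:
                    continue
            out.add((d, h, a))
    return out


def brute_bridges(frame, system, da_cutoff, angle_cutoff):
    """Set of (protein atom, water residue, ligand atom) bridge triples."""
    bonds = brute_hbonds(frame, system, da_cutoff, angle_cutoff)
    groups = system.groups
    resid = system.residue_indices
    prot_by_w: dict[int, set[int]] = {}
    lig_by_w: dict[int, set[int]] = {}
    for d, h, a in bonds:
        for x, y in ((d, a), (a, d)):
            if groups[x] == "water" and groups[y] == "protein":
                prot_by_w.setdefault(int(resid[x]), set()).add(y)
            if groups[x] == "water" and groups[y] in ("head", "alpha", "tail"):
                lig_by_w.setdefault(int(resid[x]), set()).add(y)
    out = set()
    for w in set(prot_by_w) & set(lig_by_w):
        for p in prot_by_w[w]:
            for l in lig_by_w[w]:
                out.add((p, w, l))
    return out


def coulomb_formula(qi, qj, r_nm, scheme, r_c):
    """Hand-evaluated pair Coulomb energy, kJ/mol."""
    f = 138.935458
    if r_nm > r_c:
        return 0.0
    if scheme == "plain_cutoff":
        return f * qi * qj / r_nm
    return f * qi * qj * (
        1.0 / r_nm + r_nm**2 / (2.0 * r_c**3) - 3.0 / (2.0 * r_c)
    )


def lj_formula(c6i, c6j, c12i, c12j, r_nm, r_c):
    if r_c is not None and r_nm > r_c:
        return 0.0
    c6 = math.sqrt(c6i * c6j)
    c12 = math.sqrt(c12i * c12j)
    return c12 / r_nm**12 - c6 / r_nm**6


def brute_group_energy(frame, system, idx_a, idx_b, scheme, r_c):
    """(coulomb, lj) sums over all cross pairs, double loop."""
    e_c = 0.0
    e_l = 0.0
    for i in idx_a:
        for j in idx_b:
            r_nm = dist(frame, int(i), int(j)) / 10.0
            e_c += coulomb_formula(
                system.charges[i], system.charges[j], r_nm, scheme, r_c
            )
            e_l += lj_formula(
                system.c6[i], system.c6[j], system.c12[i], system.c12[j],
                r_nm, r_c,
            )
    return e_c, e_l


def quaternion_superpose_rmsd(x, y):
    """Horn's quaternion method for optimal rigid superposition RMSD.

    Independent of the SVD/Kabsch route: builds the 4x4 key matrix from
    the correlation matrix and takes its largest eigenvalue.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    s = yc.T @ xc  # correlation matrix
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    n = x.shape[0]
    msd = (np.sum(xc**2) + np.sum(yc**2) - 2.0 * lam) / n
    return math.sqrt(max(msd, 0.0))
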