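"""Independent brute-force oracles used by the test suite.

These deliberately avoid the production code paths: the formula oracle
enumerates the entire bounded element grid (chunked over oxygen) instead
of solving for (C, H); the alignment oracle is transitive-closure
single-linkage; the series oracle is a pairwise union-find; the Welch
oracle computes the t statistic and Satterthwaite dof from first
principles.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

ELEMENT_MASS = {
    "C": 12.000000,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "P": 30.97376163,
    "S": 31.97207117,
}

DEFAULT_BOUNDS = {
    "C": (1, 100), "H": (1, 200), "O": (0, 60),
    "N": (0, 5), "S": (0, 2), "P": (0, 2),
}


class GridFormulaOracle:
    """Exhaustive enumeration of every CHONSP formula in the bounded grid.

    Builds a flat table of ALL grid points (c, h, o, n, s, p) passing the
    validity rules with mass below ``max_mass``, sorted by mass; queries
    return the exact candidate set within a strict ppm tolerance.
    """

    def __init__(self, bounds=None, hc_range=(0.2, 3.0), oc_range=(0.0, 1.5),
                 parity=True, max_mass=950.0):
        b = bounds or DEFAULT_BOUNDS
        m = ELEMENT_MASS
        c = np.arange(b["C"][0], b["C"][1] + 1)
        h = np.arange(b["H"][0], b["H"][1] + 1)
        n = np.arange(b["N"][0], b["N"][1] + 1)
        s = np.arange(b["S"][0], b["S"][1] + 1)
        p = np.arange(b["P"][0], b["P"][1] + 1)
        C, H, N, S, P = np.meshgrid(c, h, n, s, p, indexing="ij")
        C, H, N, S, P = (a.ravel() for a in (C, H, N, S, P))
        base = (C * m["C"] + H * m["H"] + N * m["N"] + S * m["S"] + P * m["P"])
        hc = H / C
        static_ok = (hc >= hc_range[0]) & (hc <= hc_range[1])
        rdbe = C - H / 2 + N / 2 + P / 2 + 1
        static_ok &= rdbe >= 0
        if parity:
            static_ok &= (H - N - P) % 2 == 0
        masses_chunks, elems_chunks = [], []
        for o in range(b["O"][0], b["O"][1] + 1):
            mass = base + o * m["O"]
            oc = o / C
            ok = static_ok & (mass <= max_mass)
            ok &= (oc >= oc_range[0]) & (oc <= oc_range[1])
            masses_chunks.append(mass[ok])
            elems_chunks.append(
                np.stack([C[ok], H[ok], np.full(int(ok.sum()), o), N[ok], S[ok], P[ok]],
                         axis=1)
            )
        self.masses = np.concatenate(masses_chunks)
        self.elems = np.concatenate(elems_chunks)
        order = np.argsort(self.masses, kind="stable")
        self.masses = self.masses[order]
        self.elems = self.elems[order]

    def candidates(self, mass: float, tol_ppm: float = 0.5):
        """Set of (c, h, o, n, s, p) tuples with |error| strictly < tol_ppm."""
        tol = tol_ppm * 1e-6 * mass
        lo = np.searchsorted(self.masses, mass - tol, side="left")
        hi = np.searchsorted(self.masses, mass + tol, side="right")
        out = set()
        for i in range(lo, hi):
            if abs(self.masses[i] - mass) < tol:
                out.add(tuple(int(x) for x in self.elems[i]))
        return out


def single_linkage_clusters(mzs: np.ndarray, tol_ppm: float) -> list[set[int]]:
    """All-pairs transitive-closure clustering at a ppm tolerance."""
    n = len(mzs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(mzs[i] - mzs[j]) / min(mzs[i], mzs[j]) * 1e6 <= tol_ppm:
                parent[find(i)] = find(j)
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return list(groups.values())


def closure_series(kmds: np.ndarray, nkms: np.ndarray, tol: float, step: int = 50):
    """Union-find series grouping: edge iff same NKM residue class AND KMD
    within tolerance; keep components of size >= 2 as frozensets of indices."""
    n = len(kmds)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if (nkms[i] - nkms[j]) % step == 0 and abs(kmds[i] - kmds[j]) <= tol:
                parent[find(i)] = find(j)
    comps: dict[int, set[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return {frozenset(c) for c in comps.values() if len(c) >= 2}


def welch_one_sided_greater(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Welch t and one-sided p for H1: mean(x) > mean(y), from first principles."""
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    dof = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return float(t), float(stats.t.sf(t, dof))
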