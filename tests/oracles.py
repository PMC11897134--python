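"""Independent brute-force oracles used to cross-check the implementation.

Every function here recomputes a quantity by the most literal possible
method (full distance matrices, exhaustive triple loops, grid scans) and
shares no code with the library paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def naive_clusters(config, cutoff: float) -> list[set[int]]:
    """Connected components of the peptide contact graph via the full
    O(n^2) heavy-atom distance matrix and breadth-first search."""
    heavy = config.elements != "H"
    pos = config.positions[heavy]
    pid = config.peptide_ids[heavy]
    n_pep = config.n_peptides
    d = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2))
    adj = [set() for _ in range(n_pep)]
    n = len(pos)
    for i in range(n):
        for j in range(i + 1, n):
            if pid[i] != pid[j] and d[i, j] < cutoff:
                adj[pid[i]].add(pid[j])
                adj[pid[j]].add(pid[i])
    seen = [False] * n_pep
    comps = []
    for start in range(n_pep):
        if seen[start]:
            continue
        comp, queue = set(), [start]
        seen[start] = True
        while queue:
            u = queue.pop()
            comp.add(u)
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    queue.append(v)
        comps.append(comp)
    return comps


def partition_signature(comps) -> set[frozenset]:
    return {frozenset(c) for c in comps}


def labels_to_signature(labels: np.ndarray) -> set[frozenset]:
    out: dict[int, set[int]] = {}
    for pep, lab in enumerate(labels):
        out.setdefault(int(lab), set()).add(pep)
    return {frozenset(c) for c in out.values()}


def exhaustive_hbonds(config, d_max: float, angle_max: float, intermolecular_only: bool = True):
    """Triple-loop hydrogen-bond detection with scalar math only."""
    found = []
    n = config.n_atoms
    for d_idx in range(n):
        h_idx = int(config.donor_h_index[d_idx])
        if h_idx < 0:
            continue
        dpos = config.positions[d_idx]
        hpos = config.positions[h_idx]
        dh = hpos - dpos
        for a_idx in range(n):
            if not config.is_acceptor[a_idx] or a_idx in (d_idx, h_idx):
                continue
            da = config.positions[a_idx] - dpos
            dist = math.sqrt(float(da @ da))
            if not dist < d_max or dist == 0:
                continue
            if intermolecular_only and config.peptide_ids[d_idx] == config.peptide_ids[a_idx]:
                continue
            cosang = float(dh @ da) / (math.sqrt(float(dh @ dh)) * dist)
            angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if angle < angle_max:
                found.append((d_idx, h_idx, a_idx))
    return set(found)


def two_sphere_sasa(r: float, probe: float, d: float) -> float:
    """Analytic SASA of two equal spheres at center distance d."""
    radius = r + probe
    if d >= 2 * radius:
        return 2 * 4 * math.pi * radius**2
    h = radius - d / 2.0  # height of the buried cap on each sphere
    return 2 * (4 * math.pi * radius**2 - 2 * math.pi * radius * h)


def grid_search_frap(times, intensity, bleach_index):
    """Coarse-to-fine grid search over (i0, plateau, tau) minimizing RSS."""
    t = times[bleach_index:]
    y = intensity[bleach_index:]
    tb = t[0]

    def rss(i0, plateau, tau):
        model = plateau - (plateau - i0) * np.exp(-(t - tb) / tau)
        return float(((model - y) ** 2).sum())

    best = None
    i0_grid = np.linspace(y.min(), y.max(), 21)
    p_grid = np.linspace(y.min(), y.max() * 1.2, 21)
    tau_grid = np.linspace(0.05 * (t[-1] - tb), t[-1] - tb, 40)
    for i0 in i0_grid:
        for p in p_grid:
            for tau in tau_grid:
                r = rss(i0, p, tau)
                if best is None or r < best[0]:
                    best = (r, i0, p, tau)
    # refine around the coarse optimum
    _, i0c, pc, tc = best
    for _ in range(3):
        i0_grid = np.linspace(i0c - 0.05, i0c + 0.05, 11)
        p_grid = np.linspace(pc - 0.05, pc + 0.05, 11)
        tau_grid = np.linspace(max(tc * 0.7, 1e-3), tc * 1.3, 11)
        for i0 in i0_grid:
            for p in p_grid:
                for tau in tau_grid:
                    r = rss(i0, p, tau)
                    if r < best[0]:
                        best = (r, i0, p, tau)
        _, i0c, pc, tc = best
    return {"i0": best[1], "plateau": best[2], "tau": best[3], "rss": best[0]}


def slope_scan(l, tau, lo, hi, steps=6001) -> float:
    """Brute-force 1D scan for the through-origin slope minimizing SSE."""
    grid = np.linspace(lo, hi, steps)
    sse = [((tau - s * l) ** 2).sum() for s in grid]
    return float(grid[int(np.argmin(sse))])


def ols_slope(x, y) -> tuple[float, float]:
    """Closed-form OLS slope and its standard error."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    slope = ((x - xm) * (y - ym)).sum() / sxx
    resid = y - (ym + slope * (x - xm))
    n = len(x)
    se = math.sqrt((resid**2).sum() / (n - 2) / sxx)
    return slope, se


def random_contactable_config(n_peptides: int, rng: np.random.Generator, box: float = 5.0):
    """Random peptide placement with no separation constraint — produces a
    mix of touching and isolated peptides for oracle comparisons."""
    from phasekit.synthetic import (
        _assign_species,
        _build_configuration,
        _random_rotation,
    )

    centroids = rng.uniform(1.0, box - 1.0, size=(n_peptides, 3))
    rots = [_random_rotation(rng) for _ in range(n_peptides)]
    species = _assign_species(n_peptides, {"FFM": 0.5, "MFF": 0.5}, rng)
    return _build_configuration(centroids, rots, species, box)
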