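"""Model-quality metrics: Kabsch superposition, Cα-RMSD, GDT-TS/HA, lDDT.

GDT follows the standard definition — for each distance cutoff, the largest
fraction of Cα atoms that can be brought within the cutoff of the reference
by one rigid superposition — estimated with a deterministic seed-fragment
search (contiguous fragments of several lengths, iterative re-superposition
on the within-cutoff subset until a fixed point).  GDT-TS averages cutoffs
{1, 2, 4, 8} Å and GDT-HA {0.5, 1, 2, 4} Å, reported as percentages.

lDDT is superposition-free: the fraction of reference interatomic distances
(different residues, within a 15 Å inclusion radius in the native) preserved
in the model within {0.5, 1, 2, 4} Å tolerances, averaged per residue and
then over residues.  All-atom pairs are used; no stereochemistry penalty is
applied.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import SuperpositionError, ValidationError
from .structure import ProteinStructure, pair_model_native

GDT_TS_CUTOFFS = (1.0, 2.0, 4.0, 8.0)
GDT_HA_CUTOFFS = (0.5, 1.0, 2.0, 4.0)
LDDT_CUTOFFS = (0.5, 1.0, 2.0, 4.0)
LDDT_INCLUSION_RADIUS = 15.0


@dataclass(frozen=True)
class MetricsReport:
    gdt_ts: float            # percent, 0–100
    gdt_ha: float            # percent, 0–100
    rmsd_ca: float           # Å
    lddt_global: float       # fraction, 0–1
    lddt_per_residue: tuple  # fractions, NaN for residues without pairs


def kabsch_superpose(
    mobile: np.ndarray, fixed: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``fixed``.

    Returns ``(R, t, rmsd)`` with the proper rotation (det = +1) and
    translation minimizing ``|R·mobile + t − fixed|``.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    fixed = np.asarray(fixed, dtype=np.float64)
    if mobile.shape != fixed.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise SuperpositionError("point sets must both have shape (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise SuperpositionError(f"need at least 3 points, got {n}")
    if not (np.isfinite(mobile).all() and np.isfinite(fixed).all()):
        raise SuperpositionError("non-finite coordinates")
    mc, fc = mobile.mean(axis=0), fixed.mean(axis=0)
    a, b = mobile - mc, fixed - fc
    if np.allclose(a, 0) or np.allclose(b, 0):
        raise SuperpositionError("degenerate (coincident) point set")
    u, _, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(u @ vt))
    rot = (u @ np.diag([1.0, 1.0, d]) @ vt).T
    t = fc - rot @ mc
    rmsd = float(np.sqrt(np.mean(np.sum((a @ rot.T - b) ** 2, axis=1))))
    return rot, t, rmsd


def _gdt_fraction(model: np.ndarray, native: np.ndarray, cutoff: float) -> float:
    """Max fraction of points superposable within ``cutoff``.

    Exact for n ≤ 10 by exhaustive subset enumeration; above that, a
    deterministic search: contiguous seed fragments of several lengths are
    iteratively re-superposed on their within-cutoff subset until a fixed
    point, and from each fixed point the m best-fitting residues (every m)
    are tried as refined superposition subsets.
    """
    n = model.shape[0]
    if n <= 10:
        best = 0
        for k in range(3, n + 1):
            for subset in itertools.combinations(range(n), k):
                idx = np.asarray(subset)
                rot, t, _ = kabsch_superpose(model[idx], native[idx])
                dev = np.linalg.norm(model @ rot.T + t - native, axis=1)
                best = max(best, int((dev <= cutoff).sum()))
        return best / n
    lengths = range(3, n + 1) if n <= 30 else list(range(3, n + 1, 2)) + [n]
    seeds = [np.arange(n)]
    for length in lengths:
        step = 1 if n <= 60 else max(1, length // 2)
        for start in range(0, n - length + 1, step):
            seeds.append(np.arange(start, start + length))

    best = 0

    def iterate(subset: np.ndarray) -> np.ndarray:
        """Fixed-point iteration; returns deviations of the final transform."""
        nonlocal best
        dev = None
        for _ in range(10):
            rot, t, _ = kabsch_superpose(model[subset], native[subset])
            dev = np.linalg.norm(model @ rot.T + t - native, axis=1)
            within = np.flatnonzero(dev <= cutoff)
            best = max(best, within.size)
            if within.size < 3 or np.array_equal(within, subset):
                break
            subset = within
        return dev

    for seed in seeds:
        dev = iterate(seed)
        # closest-m expansion from this fixed point
        order = np.argsort(dev, kind="stable")
        for m in range(3, n + 1):
            subset = np.sort(order[:m])
            rot, t, _ = kabsch_superpose(model[subset], native[subset])
            d2 = np.linalg.norm(model @ rot.T + t - native, axis=1)
            count = int((d2 <= cutoff).sum())
            if count > best:
                best = count
                if count >= 3:
                    iterate(np.flatnonzero(d2 <= cutoff))
    return best / n


def gdt(model_ca: np.ndarray, native_ca: np.ndarray, cutoffs) -> float:
    """GDT score in percent for the given cutoff set."""
    model_ca = np.asarray(model_ca, dtype=np.float64)
    native_ca = np.asarray(native_ca, dtype=np.float64)
    if model_ca.shape != native_ca.shape:
        raise ValidationError("Cα arrays must have equal shapes")
    if model_ca.shape[0] < 3:
        raise ValidationError("GDT needs at least 3 residues")
    fracs = [_gdt_fraction(model_ca, native_ca, c) for c in cutoffs]
    return 100.0 * float(np.mean(fracs))


def lddt(
    model: ProteinStructure,
    native: ProteinStructure,
    inclusion_radius: float = LDDT_INCLUSION_RADIUS,
    cutoffs=LDDT_CUTOFFS,
) -> tuple[float, np.ndarray]:
    """Global and per-residue lDDT (all-atom, superposition-free)."""
    m, n = pair_model_native(model, native)
    mx, nx = m.flat_coords(), n.flat_coords()
    res_of_atom = np.repeat(np.arange(n.n_residues), n.atom_mask.sum(axis=1))

    dn = squareform(pdist(nx))
    dm = squareform(pdist(mx))
    ii, jj = np.triu_indices(len(nx), k=1)
    keep = (dn[ii, jj] < inclusion_radius) & (res_of_atom[ii] != res_of_atom[jj])
    if not keep.any():
        raise ValidationError("no qualifying atom pairs within the inclusion radius")
    ii, jj = ii[keep], jj[keep]
    diff = np.abs(dm[ii, jj] - dn[ii, jj])
    pair_score = np.mean(diff[:, None] < np.asarray(cutoffs)[None, :], axis=1)

    per_res = np.full(n.n_residues, np.nan)
    for r in range(n.n_residues):
        involved = (res_of_atom[ii] == r) | (res_of_atom[jj] == r)
        if involved.any():
            per_res[r] = pair_score[involved].mean()
    glob = float(np.nanmean(per_res))
    return glob, per_res


def evaluate(model: ProteinStructure, native: ProteinStructure) -> MetricsReport:
    """All metrics for a model/native pair (paired on shared atoms first)."""
    m, n = pair_model_native(model, native)
    ca_m, ca_n = m.ca_coords(), n.ca_coords()
    _, _, rmsd_ca = kabsch_superpose(ca_m, ca_n)
    gdt_ts = gdt(ca_m, ca_n, GDT_TS_CUTOFFS)
    gdt_ha = gdt(ca_m, ca_n, GDT_HA_CUTOFFS)
    lddt_global, lddt_res = lddt(m, n)
    return MetricsReport(
        gdt_ts=gdt_ts,
        gdt_ha=gdt_ha,
        rmsd_ca=rmsd_ca,
        lddt_global=lddt_global,
        lddt_per_residue=tuple(lddt_res),
    )


def best_of_five(
    refined: list[ProteinStructure], native: ProteinStructure
) -> tuple[ProteinStructure, MetricsReport]:
    """Select the candidate with the highest GDT-HA (ties: lower index)."""
    if not refined:
        raise ValidationError("empty candidate list")
    reports = [evaluate(r, native) for r in refined]
    best = int(np.argmax([r.gdt_ha for r in reports]))
    return refined[best], reports[best]
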