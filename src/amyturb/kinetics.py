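"""Consensus kinetic models of amyloid/aggregate growth.

Six limiting-case mechanisms are integrated under a single-moment closure in
which each aggregate type is represented by its weight-average polymer
degree <i> = sum(C_i i^2)/sum(C_i i):

1. irreversible nucleated growth (Oosawa-type, nucleus size n),
2. nucleated growth with uniform fibre breakage (rate b_A per bond),
3. slow fibre end-to-end joining (rate f_JEE),
4. slow lateral protofibril dimerization (rate f_JLA, capped at dimers),
5. seeded amyloid-vs-amorphous competition for a shared monomer pool,
6. seeded amyloid-vs-amyloid (strain) competition.

A full-distribution Smoluchowski master-equation integrator is provided as a
small-system oracle against which the reduced models are checked.

All concentrations are molar (mol/L); bimolecular rate constants are
M^-1 s^-1 and unimolecular ones s^-1.  Free monomer is reconstructed from
mass conservation at every time point, so conservation holds to integrator
tolerance by construction and is asserted, not imposed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "OosawaParams",
    "RedistributionParams",
    "SeededTypeParams",
    "SeededCompetitionParams",
    "SpeciesTrajectory",
    "KineticTrajectory",
    "SmoluchowskiSystem",
    "SmoluchowskiTrajectory",
    "KineticSignature",
    "StiffnessError",
    "TruncationError",
    "SignatureUndefinedError",
    "simulate_nucleated_growth",
    "simulate_redistribution",
    "simulate_seeded_competition",
    "simulate_smoluchowski",
    "kinetic_signature",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-14  # M
SEED_GATE_WIDTH = 0.1  # monomer units of <i>; smooth seed-floor switch


class StiffnessError(RuntimeError):
    """The implicit integrator failed; retry with looser rtol/atol."""


class TruncationError(RuntimeError):
    """Mass piled up at the maximum-degree boundary of the master equations."""


class SignatureUndefinedError(ValueError):
    """Trajectory is non-monotone or unconverged; signatures are undefined."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OosawaParams:
    """Nucleated-growth rate constants and initial condition.

    ``f_N`` (M^-1 s^-1) governs nucleus formation from n monomers, ``f_A``
    monomer addition to nuclei and fibres, ``b_A`` (s^-1) uniform breakage
    per internal bond (0 for the irreversible model), ``c_tot_M`` the total
    monomer concentration.  The scheme presumes f_A >> f_N.
    """

    f_N: float
    f_A: float
    n: int = 2
    b_A: float = 0.0
    c_tot_M: float = 1e-3

    def __post_init__(self) -> None:
        if self.f_N < 0 or self.f_A < 0 or self.b_A < 0:
            raise ValueError("rate constants must be non-negative")
        if self.f_A < self.f_N:
            warnings.warn("model premise f_A >> f_N violated (f_A < f_N)",
                          stacklevel=2)
        if self.n < 2:
            raise ValueError("nucleus size must be >= 2")
        if self.c_tot_M <= 0:
            raise ValueError("total monomer must be positive")


@dataclass(frozen=True)
class RedistributionParams:
    """Slow post-growth redistribution: end-to-end joining (f_JEE) and
    lateral dimerization (f_JLA), both assumed << f_A (time-scale
    separation between the mass reaction and the distribution)."""

    f_JEE: float = 0.0
    f_JLA: float = 0.0

    def __post_init__(self) -> None:
        if self.f_JEE < 0 or self.f_JLA < 0:
            raise ValueError("joining constants must be non-negative")


@dataclass(frozen=True)
class SeededTypeParams:
    """One competing aggregate type growing from fixed, non-dissociable
    seeds: growth constant f (M^-1 s^-1), monomer-loss constant b (s^-1),
    seed number concentration and seed degree."""

    label: str
    f: float
    b: float
    seed_conc_M: float
    seed_degree: float

    def __post_init__(self) -> None:
        if self.f < 0 or self.b < 0:
            raise ValueError("rate constants must be non-negative")
        if self.seed_conc_M <= 0 or self.seed_degree < 1:
            raise ValueError("seeds require positive concentration and degree >= 1")


@dataclass(frozen=True)
class SeededCompetitionParams:
    """Two fixed-seeded types competing for one monomer pool of c_tot_M
    free monomer at t = 0 (seed mass is carried in addition)."""

    types: tuple[SeededTypeParams, SeededTypeParams]
    c_tot_M: float = 1e-3

    def __post_init__(self) -> None:
        if self.c_tot_M <= 0:
            raise ValueError("total monomer must be positive")
        if len({t.label for t in self.types}) != 2:
            raise ValueError("the two competing types need distinct labels")


# ---------------------------------------------------------------------------
# trajectory containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesTrajectory:
    """Number and monomer-mass concentration time series for one aggregate
    type; the closure average degree is their ratio."""

    label: str
    number_conc_M: np.ndarray
    mass_conc_M: np.ndarray

    @property
    def mean_degree(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            deg = np.where(self.number_conc_M > 0,
                           self.mass_conc_M / np.where(self.number_conc_M > 0,
                                                       self.number_conc_M, 1.0),
                           0.0)
        return deg


@dataclass(frozen=True)
class KineticTrajectory:
    """Time course of a reduced-model integration.

    ``conserved_total_M`` is the invariant monomer budget:
    C_M + n C_N + sum of aggregate mass concentrations at every time point.
    """

    t_s: np.ndarray
    monomer_M: np.ndarray
    nucleus_M: np.ndarray
    species: dict[str, SpeciesTrajectory]
    nucleus_size: int
    conserved_total_M: float

    def mass_balance_residual(self) -> np.ndarray:
        """Relative deviation of the monomer budget from its invariant."""
        total = self.monomer_M + self.nucleus_size * self.nucleus_M
        for sp in self.species.values():
            total = total + sp.mass_conc_M
        return (total - self.conserved_total_M) / self.conserved_total_M

    @property
    def primary(self) -> SpeciesTrajectory:
        """The first (or only) aggregate species."""
        return next(iter(self.species.values()))


def _integrate(rhs, y0, t_grid, rtol, atol, method="Radau"):
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be ascending with >= 2 points")
    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), y0, t_eval=t_grid,
                    method=method, rtol=rtol, atol=atol)
    if not sol.success:
        raise StiffnessError(
            f"integrator failed: {sol.message}; try rtol~{rtol*100:g}, "
            f"atol~{atol*100:g} or method='BDF'"
        )
    return sol.y


# ---------------------------------------------------------------------------
# mechanisms 1-4: nucleated growth, breakage, joining
# ---------------------------------------------------------------------------

def simulate_nucleated_growth(p: OosawaParams, t_grid: Sequence[float],
                              rtol: float = DEFAULT_RTOL,
                              atol: float = DEFAULT_ATOL) -> KineticTrajectory:
    """Integrate the reduced Oosawa-type nucleated-growth model.

    State (C_N nucleus, C_A fibre number, C_MA monomer-in-amyloid):

        dC_N/dt  = f_N C_M^n - f_A C_M C_N
        dC_A/dt  = f_A C_M C_N + b_A (C_MA - C_A)
        dC_MA/dt = (n+1) f_A C_M C_N + f_A C_M C_A - 2 b_A C_A

    with C_M from conservation.  Breakage treats every internal bond
    (C_MA - C_A of them per volume) as scissile at rate b_A; the two
    terminal bonds per fibre release monomer on breaking.  b_A = 0 recovers
    the irreversible model exactly.
    """
    return simulate_redistribution(p, RedistributionParams(), t_grid,
                                   rtol=rtol, atol=atol)


def simulate_redistribution(p: OosawaParams, r: RedistributionParams,
                            t_grid: Sequence[float],
                            rtol: float = DEFAULT_RTOL,
                            atol: float = DEFAULT_ATOL) -> KineticTrajectory:
    """Nucleated growth plus slow fibre redistribution.

    Joining redistributes already-formed polymer without feeding back on
    the monomer/polymer-mass reaction (time-scale separation: fibre ends
    keep their reactivity when fibres join, so monomer incorporation is
    blind to both joining modes).  The bookkeeping carries the growing
    protofibril-unit count C_U alongside the countable-particle numbers:
    end-to-end joining removes particles (dC_A/dt -= f_JEE C_A^2) but not
    units; lateral association pairs protofibrils into centre-aligned
    dimers (number C_A2, doubled cross-sectional area, same length) whose
    two constituent units keep growing: dC_A2/dt = f_JLA C_A^2 / 2.
    """
    f_n, f_a, n, b_a, c_tot = p.f_N, p.f_A, p.n, p.b_A, p.c_tot_M
    f_jee, f_jla = r.f_JEE, r.f_JLA

    def rhs(_t, y):
        c_n, c_u, c_a, c_a2, c_ma = y
        c_m = c_tot - n * c_n - c_ma
        c_m = max(c_m, 0.0)
        nucleation = f_n * c_m**n
        conversion = f_a * c_m * c_n
        production = conversion + b_a * (c_ma - c_a)
        d_cn = nucleation - conversion
        d_cu = production
        d_ca = production - f_jee * c_a * c_a - f_jla * c_a * c_a
        d_ca2 = 0.5 * f_jla * c_a * c_a
        d_cma = (n + 1.0) * conversion + f_a * c_m * c_u - 2.0 * b_a * c_a
        return (d_cn, d_cu, d_ca, d_ca2, d_cma)

    y = _integrate(rhs, (0.0, 0.0, 0.0, 0.0, 0.0), t_grid, rtol, atol)
    c_n, c_u, c_a, c_a2, c_ma = y
    t = np.asarray(t_grid, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        unit_deg = np.where(c_u > 0, c_ma / np.where(c_u > 0, c_u, 1.0), 0.0)
    mass_dimer = 2.0 * unit_deg * c_a2
    mass_proto = c_ma - mass_dimer
    species = {
        "fibril": SpeciesTrajectory("fibril", number_conc_M=c_a,
                                    mass_conc_M=mass_proto),
    }
    if f_jla > 0 or np.any(c_a2 > 0):
        species["lateral_dimer"] = SpeciesTrajectory(
            "lateral_dimer", number_conc_M=c_a2, mass_conc_M=mass_dimer)
    monomer = np.clip(c_tot - p.n * c_n - c_ma, 0.0, None)
    return KineticTrajectory(t_s=t, monomer_M=monomer, nucleus_M=c_n,
                             species=species, nucleus_size=p.n,
                             conserved_total_M=c_tot)


# ---------------------------------------------------------------------------
# mechanisms 5-6: fixed-seeded competition
# ---------------------------------------------------------------------------

def _seed_gate(delta: float) -> float:
    """Smooth switch turning monomer loss off at the seed floor: 0 at
    delta = 0, -> 1 over ~SEED_GATE_WIDTH monomer units of <i>."""
    if delta <= 0.0:
        return 0.0
    return delta * delta / (delta * delta + SEED_GATE_WIDTH * SEED_GATE_WIDTH)


def simulate_seeded_competition(p: SeededCompetitionParams,
                                t_grid: Sequence[float],
                                rtol: float = DEFAULT_RTOL,
                                atol: float = DEFAULT_ATOL) -> KineticTrajectory:
    """Two fixed-seeded aggregate types growing/shrinking by monomer
    exchange only, competing for a shared monomer pool.

    For each type X (fixed seed number concentration C_X):

        dC_MX/dt = f_X C_M C_X - b_X C_X s(<i_X> - <i_X>_0)

    where s is a smooth gate suppressing monomer loss at the seed floor
    (seeds are non-dissociable, so <i_X> never falls below its t = 0
    value).  No nucleation, no fragmentation; C_M by conservation.
    """
    t1, t2 = p.types
    c_seed = np.array([t1.seed_conc_M, t2.seed_conc_M])
    i0 = np.array([t1.seed_degree, t2.seed_degree])
    f = np.array([t1.f, t2.f])
    b = np.array([t1.b, t2.b])
    mass0 = i0 * c_seed
    c_tot = p.c_tot_M

    def rhs(_t, y):
        mass = np.asarray(y)
        c_m = c_tot - float(np.sum(mass - mass0))
        c_m = max(c_m, 0.0)
        deg = mass / c_seed
        gates = np.array([_seed_gate(deg[0] - i0[0]), _seed_gate(deg[1] - i0[1])])
        return f * c_m * c_seed - b * c_seed * gates

    y = _integrate(rhs, mass0, t_grid, rtol, atol)
    t = np.asarray(t_grid, dtype=float)
    monomer = np.clip(c_tot - (y[0] - mass0[0]) - (y[1] - mass0[1]), 0.0, None)
    species = {
        tp.label: SpeciesTrajectory(tp.label,
                                    number_conc_M=np.full_like(t, tp.seed_conc_M),
                                    mass_conc_M=y[k])
        for k, tp in enumerate(p.types)
    }
    # conserved budget includes the seed mass carried in addition to c_tot
    return KineticTrajectory(t_s=t, monomer_M=monomer, nucleus_M=np.zeros_like(t),
                             species=species, nucleus_size=0,
                             conserved_total_M=c_tot + float(np.sum(mass0)))


# ---------------------------------------------------------------------------
# full-distribution Smoluchowski oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SmoluchowskiSystem:
    """Truncated coagulation-fragmentation master equations up to degree z.

    ``f_mat[i-1, j-1]`` is the chemical rate constant for the association
    i + j -> i+j (event rate f C_i C_j, including i = j, where two i-mers
    are consumed per event).  ``b_mat[i-1, j-1]`` (symmetric) gives the
    rate at which a parent of degree i+j breaks into the ordered fragment
    pair (i, j); the total breakage rate of a p-mer is the antidiagonal sum
    over i+j = p.  The boundary at z is closed (no association flux past
    z), so total monomer mass is conserved; runs are rejected when mass
    accumulates at the boundary.
    """

    z: int
    f_mat: np.ndarray
    b_mat: np.ndarray
    c0: np.ndarray

    def __post_init__(self) -> None:
        z = self.z
        if not 2 <= z <= 2000:
            raise ValueError("z must be in [2, 2000] for dense integration")
        f = np.asarray(self.f_mat, dtype=float)
        b = np.asarray(self.b_mat, dtype=float)
        c0 = np.asarray(self.c0, dtype=float)
        if f.shape != (z, z) or b.shape != (z, z) or c0.shape != (z,):
            raise ValueError("f_mat/b_mat must be (z, z) and c0 (z,)")
        if not np.allclose(f, f.T) or not np.allclose(b, b.T):
            raise ValueError("rate matrices must be symmetric")
        if np.any(f < 0) or np.any(b < 0) or np.any(c0 < 0):
            raise ValueError("rates and concentrations must be non-negative")
        object.__setattr__(self, "f_mat", f)
        object.__setattr__(self, "b_mat", b)
        object.__setattr__(self, "c0", c0)

    @classmethod
    def oosawa(cls, p: OosawaParams, z: int) -> "SmoluchowskiSystem":
        """Monomer-addition mapping of the Oosawa scheme: monomer + monomer
        at f_N (nucleus size n = 2), monomer + k-mer (k >= n) at f_A, and
        uniform bond scission at b_A for fibril-sized species."""
        if p.n != 2:
            raise ValueError("the monomer-addition mapping is built for n = 2")
        f = np.zeros((z, z))
        f[0, p.n - 1:] = p.f_A  # monomer + (>= n)-mer, nucleus included
        f[p.n - 1:, 0] = p.f_A
        f[0, 0] = p.f_N
        b = np.zeros((z, z))
        if p.b_A > 0:
            # every internal bond of a (> n)-mer breaks at b_A
            for parent in range(p.n + 1, z + 1):
                for i in range(1, parent):
                    b[i - 1, parent - i - 1] = p.b_A
        c0 = np.zeros(z)
        c0[0] = p.c_tot_M
        return cls(z=z, f_mat=f, b_mat=b, c0=c0)


@dataclass(frozen=True)
class SmoluchowskiTrajectory:
    """Per-species concentrations C_k(t); reductions follow the same
    definitions as the closure models (aggregates are species of degree
    > nucleus size unless stated otherwise)."""

    t_s: np.ndarray
    conc_M: np.ndarray  # shape (z, nt); row k-1 is C_k

    @property
    def z(self) -> int:
        return self.conc_M.shape[0]

    def total_monomer_M(self) -> np.ndarray:
        k = np.arange(1, self.z + 1)
        return k @ self.conc_M

    def aggregate_mass_M(self, min_degree: int = 2) -> np.ndarray:
        k = np.arange(1, self.z + 1)
        sel = k >= min_degree
        return k[sel] @ self.conc_M[sel]

    def aggregate_number_M(self, min_degree: int = 2) -> np.ndarray:
        k = np.arange(1, self.z + 1)
        return self.conc_M[k >= min_degree].sum(axis=0)

    def weight_mean_degree(self, min_degree: int = 2) -> np.ndarray:
        """Weight-average degree <i> = sum C_i i^2 / sum C_i i over the
        aggregate distribution (the closure moment)."""
        k = np.arange(1, self.z + 1)
        sel = k >= min_degree
        num = (k[sel] ** 2) @ self.conc_M[sel]
        den = k[sel] @ self.conc_M[sel]
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)


def simulate_smoluchowski(sys: SmoluchowskiSystem, t_grid: Sequence[float],
                          rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
                          method: str = "BDF",
                          boundary_tol: float = 1e-3) -> SmoluchowskiTrajectory:
    """Integrate the full master equations (dense, O(z^2) per evaluation).

    Raises :class:`TruncationError` if more than ``boundary_tol`` of the
    monomer mass ends up in the top species, which signals that the
    distribution does not fit below degree z.
    """
    z = sys.z
    kernel = sys.f_mat.copy()
    np.fill_diagonal(kernel, 2.0 * np.diag(kernel))  # chemical -> kernel convention
    sizes = np.arange(1, z + 1)
    pair_sum = sizes[:, None] + sizes[None, :]  # degree of each (i, j) product
    kernel[pair_sum > z] = 0.0  # closed boundary: no flux past degree z
    flat_idx = pair_sum.ravel() - 1
    # breakage: loss vector per parent and fragment-gain matrix
    b_loss = np.zeros(z)
    for parent in range(2, z + 1):
        i = np.arange(1, parent)
        b_loss[parent - 1] = float(np.sum(sys.b_mat[i - 1, parent - i - 1]))
    gain_b = np.zeros((z, z))  # gain_b[j-1, p-1] = 2 b(j, p-j)
    for j in range(1, z):
        pp = np.arange(j + 1, z + 1)
        gain_b[j - 1, pp - 1] = 2.0 * sys.b_mat[j - 1, pp - j - 1]
    any_assoc = np.any(kernel > 0)
    any_break = np.any(sys.b_mat > 0)

    def rhs(_t, c):
        d = np.zeros(z + 1)
        if any_assoc:
            rate = kernel * np.outer(c, c)
            # loss: C_k sum_j K_kj C_j; gain: half the antidiagonal sums
            d[:z] = -(kernel @ c) * c
            gains = np.bincount(flat_idx, weights=rate.ravel(),
                                minlength=2 * z)
            d[:z] += 0.5 * gains[:z]
        if any_break:
            d[:z] += gain_b @ c - b_loss * c
        return d[:z]

    y = _integrate(rhs, sys.c0, t_grid, rtol, atol, method=method)
    traj = SmoluchowskiTrajectory(t_s=np.asarray(t_grid, dtype=float), conc_M=y)
    total = traj.total_monomer_M()
    top_mass = z * y[z - 1]
    if np.any(top_mass > boundary_tol * np.maximum(total, 1e-300)):
        raise TruncationError(
            f"{float(np.max(top_mass / total)):.2%} of monomer mass reached the "
            f"degree-{z} boundary; increase z"
        )
    return traj


# ---------------------------------------------------------------------------
# kinetic signatures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticSignature:
    """Reduction of a growth curve: lag (t10), growth phase (t50 - t10) and
    asymptotic extent of the aggregated mass."""

    t10_s: float
    t50_s: float
    asymptote_M: float

    @property
    def growth_span_s(self) -> float:
        return self.t50_s - self.t10_s


def _crossing_time(t: np.ndarray, y: np.ndarray, level: float) -> float:
    idx = int(np.argmax(y >= level))
    if y[idx] < level:
        raise SignatureUndefinedError(f"trajectory never reaches {level:.0%}")
    if idx == 0:
        return float(t[0])
    t0, t1 = t[idx - 1], t[idx]
    y0, y1 = y[idx - 1], y[idx]
    return float(t0 + (level - y0) / (y1 - y0) * (t1 - t0))


def kinetic_signature(t_s: np.ndarray, mass_M: np.ndarray,
                      asymptote_window: float = 0.05,
                      drift_tol: float = 0.01) -> KineticSignature:
    """Reduce an aggregated-mass time course to (t10, t50, asymptote).

    The asymptote is the mean over the trailing ``asymptote_window``
    fraction of the time grid; the run is rejected as unconverged if the
    curve drifts by more than ``drift_tol`` (relative) across that window,
    or as ill-formed if it is substantially non-monotone.
    """
    t = np.asarray(t_s, dtype=float)
    y = np.asarray(mass_M, dtype=float)
    if t.shape != y.shape or t.ndim != 1 or t.size < 4:
        raise ValueError("need matching 1-D time and mass arrays")
    n_tail = max(2, int(math.ceil(asymptote_window * t.size)))
    tail = y[-n_tail:]
    asym = float(np.mean(tail))
    if asym <= 0:
        raise SignatureUndefinedError("no aggregate mass formed")
    drift = (float(np.max(tail)) - float(np.min(tail))) / asym
    if drift > drift_tol:
        raise SignatureUndefinedError(
            f"asymptote window drifts by {drift:.2%} (> {drift_tol:.0%}): "
            "unconverged; extend the time grid"
        )
    dips = np.min(np.diff(y) / asym)
    if dips < -0.01:
        raise SignatureUndefinedError(
            f"trajectory non-monotone (largest dip {dips:.2%} of asymptote)")
    frac = y / asym
    t10 = _crossing_time(t, frac, 0.10)
    t50 = _crossing_time(t, frac, 0.50)
    return KineticSignature(t10_s=t10, t50_s=t50, asymptote_M=asym)
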