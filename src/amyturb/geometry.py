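"""Mesoscopic fibre geometry: sphero-cylinder deconvolution, persistence
statistics, and the geometry <-> mass <-> polymer-degree <-> concentration
conversions.

Microscopy-scale inputs (perimeter, area, backbone traces) are expressed in
nanometres; everything downstream of the unit boundary is SI (m, kg, mol, s).
A protein aggregate of ``i`` monomers is modelled as an arbitrarily diffuse
rod (trace length ``L_i``, trace radius ``R_i``) or sphere (radius ``R_i``)
whose envelope ("trace") volume is ``V_trace = i*M1*v/(alpha*N_A)``, with
``alpha`` the fraction of the envelope occupied by protein and ``v`` the
partial specific volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

AVOGADRO = 6.02214076e23  # 1/mol

__all__ = [
    "AVOGADRO",
    "FibreMeasurement",
    "SpheroCylinder",
    "ParticleModel",
    "CountHistogram",
    "InvalidMeasurementError",
    "InsufficientTraceError",
    "EmptyDistributionError",
    "deconvolve_sphero_cylinder",
    "sphero_cylinder_perimeter_area",
    "average_deviation_angle",
    "trace_volume",
    "mass_from_volume",
    "degree_from_mass",
    "counts_to_distribution",
    "read_measurement_table",
    "read_trace_table",
]


class InvalidMeasurementError(ValueError):
    """Perimeter/area pair is inconsistent with a sphero-cylinder."""


class InsufficientTraceError(ValueError):
    """Backbone trace too short for the requested chord length."""


class EmptyDistributionError(ValueError):
    """Count histogram holds no particles."""


@dataclass(frozen=True)
class FibreMeasurement:
    """Per-particle measurement from a segmented micrograph.

    Parameters
    ----------
    perimeter_nm : float
        Projected outline perimeter P (nm).
    area_nm2 : float
        Projected area A (nm^2).
    trace_nm : ndarray, optional
        Ordered (n, 2) backbone coordinates in nm.
    """

    perimeter_nm: float
    area_nm2: float
    trace_nm: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.perimeter_nm <= 0 or self.area_nm2 <= 0:
            raise ValueError("perimeter and area must be positive")
        if self.trace_nm is not None:
            t = np.asarray(self.trace_nm, dtype=float)
            if t.ndim != 2 or t.shape[1] != 2 or t.shape[0] < 2:
                raise ValueError("trace must be an (n>=2, 2) point array")
            object.__setattr__(self, "trace_nm", t)


@dataclass(frozen=True)
class SpheroCylinder:
    """Equivalent sphero-cylinder: internal length L and width W (nm)."""

    length_nm: float
    width_nm: float

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ValueError("width must be positive")
        if self.length_nm < -1e-12:
            raise ValueError("length must be non-negative")


@dataclass(frozen=True)
class ParticleModel:
    """Shape model for one aggregate species.

    ``shape`` is ``"rod"`` (trace length + cross-sectional radius) or
    ``"sphere"`` (radius only).  ``alpha`` in (0, 1] is the packing
    fraction, ``monomer_mass_kg_mol`` the monomer molar mass M1 and
    ``specific_volume_m3_kg`` the partial specific volume.
    """

    shape: Literal["rod", "sphere"]
    radius_m: float
    length_m: float = 0.0
    alpha: float = 1.0
    monomer_mass_kg_mol: float = 27.65
    specific_volume_m3_kg: float = 0.73e-3

    def __post_init__(self) -> None:
        if self.shape not in ("rod", "sphere"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.radius_m <= 0:
            raise ValueError("radius must be positive")
        if self.shape == "rod" and self.length_m < 0:
            raise ValueError("rod length must be non-negative")
        if not 0 < self.alpha <= 1:
            raise ValueError("packing fraction must lie in (0, 1]")
        if self.specific_volume_m3_kg <= 0 or self.monomer_mass_kg_mol <= 0:
            raise ValueError("M1 and v must be positive")


@dataclass(frozen=True)
class CountHistogram:
    """Particle counts binned by polymer degree, plus the independently
    measured total aggregate mass concentration (mol monomer / L)."""

    bin_edges: np.ndarray  # ascending degree edges, length nbins+1
    counts: np.ndarray  # length nbins, >= 0
    c_aggregate_M: float  # total monomer-in-aggregate concentration

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if edges.ndim != 1 or counts.ndim != 1 or edges.size != counts.size + 1:
            raise ValueError("need nbins+1 edges for nbins counts")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly ascending")
        if edges[0] < 2:
            raise ValueError("aggregate degree starts at 2")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if self.c_aggregate_M <= 0:
            raise ValueError("c_aggregate must be positive")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)


# ---------------------------------------------------------------------------
# sphero-cylinder deconvolution
# ---------------------------------------------------------------------------

def sphero_cylinder_perimeter_area(length_nm: float, width_nm: float) -> tuple[float, float]:
    """Forward model: (P, A) of a sphero-cylinder of internal length L, width W."""
    p = 2.0 * (length_nm + math.pi * width_nm / 2.0)
    a = length_nm * width_nm + math.pi * width_nm**2 / 4.0
    return p, a


def deconvolve_sphero_cylinder(m: FibreMeasurement) -> SpheroCylinder:
    """Invert a (perimeter, area) pair to the equivalent sphero-cylinder.

    Width solves the quadratic (-pi/4) W^2 + (P/2) W - A = 0; the smaller
    positive root is taken (the larger implies negative internal length).
    For a true sphero-cylinder the discriminant P^2 - 4 pi A equals (2L)^2,
    so a negative discriminant (beyond a 1e-9 * P^2 rounding tolerance)
    means the outline cannot be a sphero-cylinder.
    """
    p, a = m.perimeter_nm, m.area_nm2
    disc = p * p - 4.0 * math.pi * a
    tol = 1e-9 * p * p
    if disc < -tol:
        raise InvalidMeasurementError(
            f"P^2 - 4*pi*A = {disc:.6g} < 0: shape cannot be a sphero-cylinder"
        )
    disc = max(disc, 0.0)
    width = (p - math.sqrt(disc)) / math.pi
    length = p / 2.0 - math.pi * width / 2.0
    return SpheroCylinder(length_nm=max(length, 0.0), width_nm=width)


# ---------------------------------------------------------------------------
# persistence statistic
# ---------------------------------------------------------------------------

def _chord_points(trace: np.ndarray, chord: float) -> np.ndarray:
    """March along a polyline picking successive points a fixed Euclidean
    chord length apart (linear interpolation between vertices); the tail
    shorter than one chord is discarded."""
    pts = [trace[0]]
    cur = trace[0]
    seg = 0  # index of segment being examined
    pos = trace[0].copy()
    while True:
        # find first crossing of the circle |x - cur| = chord along the path
        found = False
        p0 = pos
        j = seg
        while j < len(trace) - 1:
            p1 = trace[j + 1]
            d = p1 - p0
            # solve |p0 + t d - cur|^2 = chord^2 for t in (0, 1]
            f = p0 - cur
            aa = float(d @ d)
            if aa > 0:
                bb = 2.0 * float(f @ d)
                cc = float(f @ f) - chord * chord
                disc = bb * bb - 4 * aa * cc
                if disc >= 0:
                    t = (-bb + math.sqrt(disc)) / (2 * aa)
                    if 0.0 < t <= 1.0:
                        cur = p0 + t * d
                        pts.append(cur)
                        pos = cur
                        seg = j
                        found = True
                        break
            p0 = p1
            j += 1
        if not found:
            break
    return np.asarray(pts)


def average_deviation_angle(trace_nm: Sequence[Sequence[float]] | np.ndarray,
                            segment_length_nm: float) -> float:
    """Mean absolute turning angle (radians) between successive fixed-length
    chords marched along the backbone trace.

    The chord (projection-vector) length is conventionally chosen equal to
    the fibre width.  Successive chord vectors I_j are extracted from the
    linearly interpolated backbone; the statistic is the mean of
    ``|acos(I_j . I_{j-1} / (l_j l_{j-1}))|``.
    """
    trace = np.asarray(trace_nm, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 2 or trace.shape[0] < 2:
        raise ValueError("trace must be an (n>=2, 2) point array")
    if segment_length_nm <= 0:
        raise ValueError("segment length must be positive")
    arc = float(np.sum(np.linalg.norm(np.diff(trace, axis=0), axis=1)))
    if arc < 2.0 * segment_length_nm:
        raise InsufficientTraceError(
            f"trace arc length {arc:.3g} nm < two chords of {segment_length_nm:.3g} nm"
        )
    pts = _chord_points(trace, segment_length_nm)
    if len(pts) < 3:
        raise InsufficientTraceError("fewer than two chords could be extracted")
    vec = np.diff(pts, axis=0)
    norm = np.linalg.norm(vec, axis=1)
    cosang = np.einsum("ij,ij->i", vec[:-1], vec[1:]) / (norm[:-1] * norm[1:])
    ang = np.abs(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return float(np.mean(ang))


# ---------------------------------------------------------------------------
# geometry <-> mass <-> degree
# ---------------------------------------------------------------------------

def trace_volume(p: ParticleModel) -> float:
    """Envelope (trace) volume in m^3: (4/3) pi R^3 for spheres, L pi R^2 for rods."""
    if p.shape == "sphere":
        return 4.0 / 3.0 * math.pi * p.radius_m**3
    return p.length_m * math.pi * p.radius_m**2


def mass_from_volume(volume_m3: float, alpha: float, specific_volume_m3_kg: float) -> float:
    """Molar mass (kg/mol) of an aggregate of trace volume V: M = V alpha N_A / v."""
    if volume_m3 < 0:
        raise ValueError("volume must be non-negative")
    if not 0 < alpha <= 1:
        raise ValueError("packing fraction must lie in (0, 1]")
    if specific_volume_m3_kg <= 0:
        raise ValueError("partial specific volume must be positive")
    return volume_m3 * alpha * AVOGADRO / specific_volume_m3_kg


def degree_from_mass(mass_kg_mol: float, monomer_mass_kg_mol: float) -> float:
    """Polymer degree i = M_i / M_1."""
    if monomer_mass_kg_mol <= 0:
        raise ValueError("monomer mass must be positive")
    return mass_kg_mol / monomer_mass_kg_mol


# ---------------------------------------------------------------------------
# counts -> solution distribution
# ---------------------------------------------------------------------------

def counts_to_distribution(h: CountHistogram) -> pd.DataFrame:
    """Convert adsorbed-particle counts to solution number concentrations.

    The independently measured aggregate mass concentration anchors the
    normalization: with mid-bin degrees i_mid, the per-bin molar number
    concentration is ``C_bin = N_bin / sum_j(N_j * i_mid_j) * c_aggregate``,
    so the monomer-weighted sum over bins recovers c_aggregate exactly.
    Returns a frame with bin_low, bin_high, count, number_conc_M,
    number_density_M (per unit degree) and mass_conc_M columns.
    """
    counts = h.counts
    if not np.any(counts > 0):
        raise EmptyDistributionError("all histogram counts are zero")
    lo = h.bin_edges[:-1]
    hi = h.bin_edges[1:]
    mid = 0.5 * (lo + hi)
    width = hi - lo
    denom = float(np.sum(counts * mid))
    number_conc = counts / denom * h.c_aggregate_M
    return pd.DataFrame(
        {
            "bin_low": lo,
            "bin_high": hi,
            "count": counts,
            "number_conc_M": number_conc,
            "number_density_M": number_conc / width,
            "mass_conc_M": number_conc * mid,
        }
    )


# ---------------------------------------------------------------------------
# table I/O (CSV dialects shared with the fixture generator)
# ---------------------------------------------------------------------------

def read_measurement_table(path) -> pd.DataFrame:
    """Read a fibre measurement CSV (particle_id, perimeter_nm, area_nm2)."""
    df = pd.read_csv(path)
    required = {"particle_id", "perimeter_nm", "area_nm2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    return df


def read_trace_table(path) -> dict[object, np.ndarray]:
    """Read backbone traces (particle_id, x_nm, y_nm ordered rows) into arrays."""
    df = pd.read_csv(path)
    required = {"particle_id", "x_nm", "y_nm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace table missing columns: {sorted(missing)}")
    return {
        pid: g[["x_nm", "y_nm"]].to_numpy(dtype=float)
        for pid, g in df.groupby("particle_id", sort=False)
    }
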