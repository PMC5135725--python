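"""Synthetic inputs with known ground truth.

Everything here is generated, seeded and reproducible: fibre measurement
tables built by forward-applying the sphero-cylinder relations to sampled
(L, W) pairs, backbone traces of analytically known mean turning angle, and
jittered kinetic-parameter ensembles.  Observation noise is multiplicative
lognormal (segmentation error in micrographs scales with the feature), and
truth tables are always emitted alongside the observations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .geometry import sphero_cylinder_perimeter_area
from .kinetics import OosawaParams

__all__ = [
    "FibreTableSpec",
    "BackboneSpec",
    "EnsembleSpec",
    "make_fibre_table",
    "make_backbone",
    "make_ensemble",
]


@dataclass(frozen=True)
class FibreTableSpec:
    """Lognormal fibre lengths at fixed width, with optional multiplicative
    observation noise on perimeter and area."""

    n: int = 100
    length_mean_nm: float = 300.0
    length_sigma: float = 0.5  # lognormal shape (sd of log)
    width_nm: float = 10.0
    noise_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("need at least one particle")
        if self.length_mean_nm <= 0 or self.width_nm <= 0:
            raise ValueError("scale parameters must be positive")
        if self.noise_frac < 0 or self.length_sigma < 0:
            raise ValueError("noise and sigma must be non-negative")


@dataclass(frozen=True)
class BackboneSpec:
    """Constant-curvature arc (or straight line at curvature 0) sampled
    densely enough for chord extraction."""

    arc_length_nm: float = 500.0
    curvature_per_nm: float = 0.0  # signed 1/radius; 0 -> straight
    n_points: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arc_length_nm <= 0:
            raise ValueError("arc length must be positive")
        if self.n_points < 2:
            raise ValueError("need at least two points")


@dataclass(frozen=True)
class EnsembleSpec:
    """Median-preserving lognormal jitter around a base kinetic parameter
    set; ``jitter`` is one fraction for all rate constants or a mapping
    from field name (f_N, f_A, b_A, c_tot_M) to fraction."""

    base: OosawaParams
    n: int = 50
    jitter: float | Mapping[str, float] = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("need at least one replicate")


def make_fibre_table(spec: FibreTableSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample (L, W) ground truth, forward-compute (P, A) and apply noise.

    Returns ``(observed, truth)`` frames sharing ``particle_id``; observed
    has perimeter_nm/area_nm2 columns in the measurement-table dialect.
    """
    rng = np.random.default_rng(spec.seed)
    mu = math.log(spec.length_mean_nm)
    lengths = rng.lognormal(mean=mu, sigma=spec.length_sigma, size=spec.n)
    widths = np.full(spec.n, spec.width_nm)
    p = np.empty(spec.n)
    a = np.empty(spec.n)
    for k in range(spec.n):
        p[k], a[k] = sphero_cylinder_perimeter_area(lengths[k], widths[k])
    if spec.noise_frac > 0:
        sigma = math.sqrt(math.log1p(spec.noise_frac**2))
        p = p * rng.lognormal(0.0, sigma, spec.n)
        a = a * rng.lognormal(0.0, sigma, spec.n)
    ids = np.arange(spec.n)
    observed = pd.DataFrame(
        {"particle_id": ids, "perimeter_nm": p, "area_nm2": a})
    truth = pd.DataFrame(
        {"particle_id": ids, "length_nm": lengths, "width_nm": widths})
    return observed, truth


def make_backbone(spec: BackboneSpec) -> tuple[np.ndarray, float]:
    """Generate a backbone trace with analytically known mean turning angle.

    Returns ``(trace, curvature)``.  For a circular arc of radius rho and
    chord length l the expected mean turning angle is 2 asin(l / (2 rho));
    a straight path (curvature 0) turns by 0.
    """
    s = np.linspace(0.0, spec.arc_length_nm, spec.n_points)
    kappa = spec.curvature_per_nm
    if kappa == 0.0:
        trace = np.column_stack([s, np.zeros_like(s)])
    else:
        rho = 1.0 / abs(kappa)
        ang = s / rho * np.sign(kappa)
        trace = np.column_stack([rho * np.sin(np.abs(ang)),
                                 np.sign(kappa) * rho * (1.0 - np.cos(ang))])
    return trace, kappa


def expected_arc_turning_angle(chord_nm: float, radius_nm: float) -> float:
    """Closed-form mean turning angle of equal chords on a circle."""
    return 2.0 * math.asin(chord_nm / (2.0 * radius_nm))


_RATE_FIELDS = ("f_N", "f_A", "b_A", "c_tot_M")


def make_ensemble(spec: EnsembleSpec) -> list[OosawaParams]:
    """Deterministic-given-seed jittered parameter draws.

    Lognormal multiplicative jitter preserves positivity and the median of
    each rate constant; fields with jitter 0 (including any not named in a
    mapping) are passed through unchanged.
    """
    rng = np.random.default_rng(spec.seed)
    if isinstance(spec.jitter, Mapping):
        fracs = {f: float(spec.jitter.get(f, 0.0)) for f in _RATE_FIELDS}
    else:
        fr = float(spec.jitter)
        fracs = {f: fr for f in ("f_N", "f_A", "b_A")}
        fracs["c_tot_M"] = 0.0
    draws = []
    for _ in range(spec.n):
        kwargs = {}
        for name in _RATE_FIELDS:
            val = getattr(spec.base, name)
            frac = fracs[name]
            if frac > 0 and val > 0:
                sigma = math.sqrt(math.log1p(frac**2))
                val = val * rng.lognormal(0.0, sigma)
            kwargs[name] = val
        draws.append(replace(spec.base, **kwargs))
    return draws
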