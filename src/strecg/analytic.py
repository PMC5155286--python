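"""Closed-form forward solution for a central dipole between concentric spheres.

A time-varying current dipole p(t) at the center of a homogeneous conducting
sphere of radius ``r_B`` (conductivity sigma, insulated at the outer
boundary) produces the potential

    Phi(r, t) = p(t) . r_hat / (4 pi sigma) * (1 / r**2 + 2 r / r_B**3),

the l = 1 interior harmonic satisfying Laplace's equation with
dPhi/dr = 0 at r = r_B.  Sampling Phi on the inner ("heart", r_H) and
outer ("body", r_B) spheres yields the ground-truth pair x(s, t), y(s, t)
of the simulation study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TriangleMesh

#: default duration of the simulated record, ms
T_MAX_MS = 300.0


@dataclass
class TwoSphereGeometry:
    """Concentric-sphere geometry: inner radius ``r_h``, outer radius ``r_b``,
    conductivity ``sigma`` (dimensionless, 1 in the study)."""

    r_h: float = 1.0
    r_b: float = 1.5
    sigma: float = 1.0

    def __post_init__(self):
        if not 0 < self.r_h < self.r_b:
            raise ValueError("require 0 < r_h < r_b")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def radial_profile(self, r: float) -> float:
        """The (1/r**2 + 2 r / r_b**3) / (4 pi sigma) factor at radius r."""
        if not 0 < r <= self.r_b:
            raise ValueError("radius must lie in (0, r_b]")
        return (1.0 / r**2 + 2.0 * r / self.r_b**3) / (4.0 * np.pi * self.sigma)

    def radial_profile_derivative(self, r: float) -> float:
        """d/dr of :meth:`radial_profile` — the radial (outward-normal)
        derivative factor of the interior potential."""
        return (-2.0 / r**3 + 2.0 / self.r_b**3) / (4.0 * np.pi * self.sigma)


@dataclass
class DipoleSource:
    """Central dipole moment sampled on a time grid.

    ``moment`` is (T, 3); ``times`` is (T,) in ms.
    """

    times: np.ndarray
    moment: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.moment = np.asarray(self.moment, dtype=float)
        if self.moment.shape != (len(self.times), 3):
            raise ValueError("moment must be (len(times), 3)")
        if not np.all(np.isfinite(self.moment)):
            raise ValueError("dipole moment must be finite")


@dataclass
class PotentialField:
    """Nodes x time matrix of surface potentials (mV) with its time axis (ms)."""

    values: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.times):
            raise ValueError("values must be (nodes, len(times))")

    @property
    def node_count(self) -> int:
        return self.values.shape[0]

    def save(self, path) -> None:
        """Delimited text, one row per node, header line of sample times."""
        header = " ".join(f"{t:.17g}" for t in self.times)
        np.savetxt(path, self.values, header=header, fmt="%.17g")

    @classmethod
    def load(cls, path) -> "PotentialField":
        with open(path) as fh:
            first = fh.readline()
        if not first.startswith("#"):
            raise ValueError("missing time-axis header line")
        times = np.array(first.lstrip("#").split(), dtype=float)
        return cls(np.loadtxt(path), times)


def dipole_amplitude(geometry: TwoSphereGeometry, peak_mv: float = 2.5) -> float:
    """Dipole amplitude such that the inner-sphere potential peaks at
    ``peak_mv`` (the reference maps span -2.5 to 2.5 mV).

    The waveform below has max |p(t)| = A * sqrt(2), and the peak surface
    potential is max |p| * radial_profile(r_h), so
    A = peak_mv / (sqrt(2) * radial_profile(r_h)).
    """
    return peak_mv / (np.sqrt(2.0) * geometry.radial_profile(geometry.r_h))


def dipole_waveform(t_grid=None, geometry: TwoSphereGeometry | None = None,
                    amplitude: float | None = None) -> DipoleSource:
    """The study's central dipole trajectory over t = 0..300 ms.

    A smooth rotating dipole

        p(t) = A * (sin(w t), sin(2 w t), cos(w t)),   w = 2 pi / 300 ms^-1,

    tracing a closed loop over the record, with amplitude A calibrated so
    the inner-sphere potential spans -2.5..2.5 mV (see
    :func:`dipole_amplitude`).  Default sampling is 1 ms (301 samples).

    Parameters
    ----------
    t_grid : array_like, optional
        Sample times in ms, each within [0, 300].
    """
    if t_grid is None:
        t_grid = np.arange(0.0, T_MAX_MS + 0.5, 1.0)
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0.0) or np.any(t > T_MAX_MS):
        raise ValueError(f"sample times must lie in [0, {T_MAX_MS}] ms")
    if amplitude is None:
        amplitude = dipole_amplitude(geometry or TwoSphereGeometry())
    w = 2.0 * np.pi / T_MAX_MS
    moment = amplitude * np.column_stack(
        [np.sin(w * t), np.sin(2.0 * w * t), np.cos(w * t)])
    return DipoleSource(times=t, moment=moment)


def analytic_potentials(geometry: TwoSphereGeometry, source: DipoleSource,
                        surface: str | TriangleMesh, mesh: TriangleMesh | None = None,
                        ) -> PotentialField:
    """Evaluate the analytic dipole potential on a sphere-surface mesh.

    Parameters
    ----------
    surface : {"inner", "outer"} or TriangleMesh
        Which sphere to sample.  Passing the mesh directly (or via
        ``mesh``) uses its vertices; with a string, ``mesh`` must supply
        the node locations (its vertices are radially projected onto the
        requested sphere radius, so either sphere's mesh may be reused).

    Returns
    -------
    PotentialField
        Node x time potentials in mV; exactly linear in p(t) and
        axisymmetric about the instantaneous dipole direction.
    """
    if isinstance(surface, TriangleMesh):
        mesh, surface = surface, None
        radius = float(np.linalg.norm(mesh.vertices, axis=1).mean())
    else:
        if mesh is None:
            raise ValueError("a mesh providing node directions is required")
        radius = {"inner": geometry.r_h, "outer": geometry.r_b}[surface]
    rhat = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
    values = geometry.radial_profile(radius) * (rhat @ source.moment.T)
    return PotentialField(values=values, times=source.times)
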