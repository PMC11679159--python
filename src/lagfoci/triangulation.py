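"""Transit-time geometry and focus localization.

A putative focus emits activity that reaches each electrode after a transit
time t_k = |x - e_k| / v (+ synaptic delays), with conduction velocity v in
the physiological 30-70 m/s range.  Working backwards, the focus is the
point whose predicted transit times (or time differences against a reference
electrode) best match the measured ones: spheres of radius v * t_k around
the electrodes intersect at the source.  With a planar electrode array the
three-sphere intersection has a mirror ambiguity, resolved by the convention
that sources lie beneath the array (negative depth).

The module also provides the analytic design relations that set the method's
requirements: achievable spatial resolution v * dt, the temporal resolution
and Nyquist sampling rate needed for a target dt, loop propagation times of
re-entrant excitation paths, and the minimum oscillation frequency a
self-excited focus would need given the neuronal refractory period.

Units: positions mm, times ms, velocity m/s (1 mm/ms == 1 m/s, so transit
times in ms are distances in mm divided by velocity).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import least_squares

from .exceptions import DegenerateGeometryError

__all__ = [
    "PropagationModel",
    "SourceEstimate",
    "transit_time",
    "transit_time_difference",
    "triangulate_absolute",
    "triangulate_tdoa",
    "spatial_resolution",
    "required_sampling",
    "min_loop_frequency",
    "loop_time",
]


@dataclasses.dataclass(frozen=True)
class PropagationModel:
    """Neural propagation parameters.

    velocity : conduction velocity in m/s (physiological range 30-70).
    synaptic_delay_ms : delay per synapse on the path.
    n_synapses : number of synapses on the path.
    """

    velocity: float = 70.0
    synaptic_delay_ms: float = 0.0
    n_synapses: int = 0

    def __post_init__(self):
        if not self.velocity > 0:
            raise ValueError("conduction velocity must be positive")
        if self.synaptic_delay_ms < 0:
            raise ValueError("synaptic delay cannot be negative")
        if self.n_synapses < 0:
            raise ValueError("synapse count cannot be negative")

    @property
    def synaptic_offset_ms(self) -> float:
        return self.n_synapses * self.synaptic_delay_ms


@dataclasses.dataclass
class SourceEstimate:
    """Estimated focus position with solver diagnostics."""

    position: np.ndarray  # (3,) mm
    residual_ms: float  # RMS timing misfit
    converged: bool
    n_iter: int

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.residual_ms < 0:
            raise ValueError("residual cannot be negative")
        if self.converged and not np.all(np.isfinite(self.position)):
            raise ValueError("a converged estimate must be finite")


def transit_time(source, electrode, model: PropagationModel | None = None) -> float:
    """Propagation time from ``source`` to ``electrode`` in ms."""
    model = model or PropagationModel()
    source = np.asarray(source, dtype=float)
    electrode = np.asarray(electrode, dtype=float)
    dist_mm = float(np.linalg.norm(source - electrode))
    return dist_mm / model.velocity + model.synaptic_offset_ms


def transit_time_difference(
    source, ref_electrode, electrode, model: PropagationModel | None = None
) -> float:
    """Transit-time difference t(electrode) - t(ref_electrode) in ms."""
    return transit_time(source, electrode, model) - transit_time(
        source, ref_electrode, model
    )


def _array_frame(electrodes: np.ndarray):
    """Centroid, unit normal (oriented toward +z) and planarity of an array."""
    centroid = electrodes.mean(axis=0)
    centered = electrodes - centroid
    _, svals, vt = np.linalg.svd(centered, full_matrices=True)
    if len(svals) < 2 or svals[1] <= 1e-9 * max(svals[0], 1.0):
        raise DegenerateGeometryError(
            "electrodes are collinear (or coincident); the source is not determined"
        )
    normal = vt[2]
    if normal[2] < 0 or (normal[2] == 0 and normal[np.argmax(np.abs(normal))] < 0):
        normal = -normal
    return centroid, normal


def _check_distinct(electrodes: np.ndarray) -> None:
    d = electrodes[:, None, :] - electrodes[None, :, :]
    dist = np.linalg.norm(d, axis=-1)
    np.fill_diagonal(dist, np.inf)
    if dist.min() <= 1e-12:
        raise DegenerateGeometryError("duplicated electrode position in input")


def triangulate_absolute(
    electrodes,
    times_ms,
    model: PropagationModel | None = None,
    depth_sign: str = "below",
) -> SourceEstimate:
    """Locate a source from absolute transit times at >= 3 electrodes.

    Solves the least-squares sphere intersection |x - e_k| = v * t_k.  With
    three electrodes (or any planar array) the two mirror solutions are
    disambiguated by ``depth_sign``: ``"below"`` selects the solution on the
    negative-normal side of the array plane (sources beneath the scalp),
    ``"above"`` the other one.
    """
    model = model or PropagationModel()
    if depth_sign not in ("below", "above"):
        raise ValueError("depth_sign must be 'below' or 'above'")
    electrodes = np.atleast_2d(np.asarray(electrodes, dtype=float))
    times_ms = np.asarray(times_ms, dtype=float)
    if len(electrodes) < 3:
        raise ValueError("need at least 3 electrodes for absolute triangulation")
    if len(times_ms) != len(electrodes):
        raise ValueError("one transit time per electrode required")
    path_times = times_ms - model.synaptic_offset_ms
    if np.any(path_times < 0):
        raise ValueError("transit times fall below the synaptic delay offset")
    _check_distinct(electrodes)
    centroid, normal = _array_frame(electrodes)
    radii = model.velocity * path_times  # mm

    # Linearised seed: subtracting sphere k from sphere 0 is linear in x.
    e0, r0 = electrodes[0], radii[0]
    a_mat = 2.0 * (electrodes[1:] - e0)
    b_vec = (
        np.sum(electrodes[1:] ** 2, axis=1)
        - np.sum(e0**2)
        - (radii[1:] ** 2 - r0**2)
    )
    x_lin, *_ = np.linalg.lstsq(a_mat, b_vec, rcond=None)
    # restore the out-of-plane component from sphere 0
    in_plane = x_lin - normal * np.dot(x_lin - centroid, normal)
    h2 = r0**2 - float(np.sum((in_plane - e0) ** 2))
    h = np.sqrt(max(h2, 0.0))
    seeds = [in_plane - h * normal, in_plane + h * normal, x_lin]

    def misfit(x):
        return np.linalg.norm(x - electrodes, axis=1) - radii

    candidates = []
    n_iter = 0
    for seed in seeds:
        sol = least_squares(misfit, seed, method="lm")
        n_iter += sol.nfev
        rms = float(np.sqrt(np.mean(sol.fun**2))) / model.velocity  # mm -> ms
        depth = float(np.dot(sol.x - centroid, normal))
        candidates.append((sol.x, rms, sol.status > 0, depth))

    best_rms = min(c[1] for c in candidates)
    want_negative = depth_sign == "below"
    matching = [
        c
        for c in candidates
        if c[1] <= best_rms + 1e-9 and ((c[3] < 0) == want_negative or abs(c[3]) < 1e-9)
    ]
    pos, rms, ok, _ = matching[0] if matching else min(candidates, key=lambda c: c[1])
    return SourceEstimate(pos, rms, bool(ok and np.all(np.isfinite(pos))), n_iter)


#: Deterministic multistart depths (mm) under the array for the TDOA solver.
TDOA_START_DEPTHS_MM = (10.0, 30.0, 50.0, 70.0, 90.0)


def triangulate_tdoa(
    electrodes, tdoas_ms, model: PropagationModel | None = None
) -> SourceEstimate:
    """Locate a source from transit-time *differences* against electrode 0.

    Needs >= 4 electrodes (three independent differences for three unknown
    coordinates).  A nonlinear least-squares fit is started from five
    deterministic seeds beneath the array centroid; the best-residual
    solution is returned, so results are reproducible without a random seed.
    """
    model = model or PropagationModel()
    electrodes = np.atleast_2d(np.asarray(electrodes, dtype=float))
    tdoas_ms = np.asarray(tdoas_ms, dtype=float)
    if len(electrodes) < 4:
        raise ValueError(
            "TDOA triangulation needs >= 4 electrodes; with absolute transit "
            "times and 3 electrodes use triangulate_absolute instead"
        )
    if len(tdoas_ms) != len(electrodes) - 1:
        raise ValueError("need one time difference per non-reference electrode")
    _check_distinct(electrodes)
    centroid, normal = _array_frame(electrodes)

    e0 = electrodes[0]
    others = electrodes[1:]

    def misfit(x):
        t = (np.linalg.norm(x - others, axis=1) - np.linalg.norm(x - e0)) / model.velocity
        return t - tdoas_ms

    best = None
    n_iter = 0
    for depth in TDOA_START_DEPTHS_MM:
        seed = centroid - depth * normal
        sol = least_squares(misfit, seed, method="lm")
        n_iter += sol.nfev
        rms = float(np.sqrt(np.mean(sol.fun**2)))
        if best is None or rms < best[1]:
            best = (sol.x, rms, sol.status > 0)
    pos, rms, ok = best
    return SourceEstimate(pos, rms, bool(ok and np.all(np.isfinite(pos))), n_iter)


def spatial_resolution(model: PropagationModel, dt_ms: float) -> float:
    """Localization resolution v * dt in mm for temporal resolution ``dt_ms``."""
    if not dt_ms > 0:
        raise ValueError("temporal resolution must be positive")
    return model.velocity * dt_ms


def required_sampling(dt_ms: float) -> tuple[float, float]:
    """(resolution frequency, Nyquist sampling rate) in Hz for a target dt."""
    if not dt_ms > 0:
        raise ValueError("temporal resolution must be positive")
    return 1000.0 / dt_ms, 2000.0 / dt_ms


def min_loop_frequency(refractory_ms: float) -> float:
    """Minimum oscillation frequency (Hz) of a self-excited focus.

    A focus re-firing as soon as its refractory period allows oscillates at
    1 / refractory; lower observed frequencies imply a longer re-entrant
    loop instead of local self-excitation.
    """
    if not refractory_ms > 0:
        raise ValueError("refractory period must be positive")
    return 1000.0 / refractory_ms


def loop_time(path_length_m: float, model: PropagationModel | None = None) -> float:
    """Propagation time (ms) around a loop of ``path_length_m`` metres."""
    model = model or PropagationModel()
    if not path_length_m > 0:
        raise ValueError("path length must be positive")
    return 1000.0 * path_length_m / model.velocity + model.synaptic_offset_ms
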