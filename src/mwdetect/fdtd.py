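"""Desk-scale dispersive FDTD forward solver.

A uniform 3D Yee grid with single-pole Debye media handled by an
auxiliary-differential-equation (ADE) polarization current, convolutional
PML (CPML) absorbing boundaries, and center-fed dipole antennas driven
through a lumped source resistance.  Transmission coefficients between
antenna ports are obtained by recording port voltages, evaluating their
spectra by direct DFT on the requested frequency grid, and normalizing the
received spectra by a reference spectrum from a calibration run with the
array in the homogeneous immersion medium.

The solver is sized for toy scenes and reduced phantoms (2--4 mm cells, a
few antennas); the full 16-antenna, 1 mm configuration is expressible but
is a cluster-scale computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .dielectric import EPS0, DebyeModel, TissueLibrary
from .phantom import LABELS, VoxelPhantom
from .records import TransmissionRecord, antenna_pairs, default_frequency_grid

MU0 = 4e-7 * np.pi
C0 = 1.0 / np.sqrt(EPS0 * MU0)
ETA0 = np.sqrt(MU0 / EPS0)

VACUUM = DebyeModel(eps_static=1.0, eps_inf=1.0, sigma=0.0, tau=1e-12)

__all__ = [
    "Antenna",
    "AntennaArrayLayout",
    "build_layout",
    "FDTDSolver",
    "gaussian_derivative_pulse",
    "windowed_sine_pulse",
    "extract_spectrum",
    "first_arrival",
    "run_forward",
    "plane_wave_alpha",
]

_AXIS = {"x": 0, "y": 1, "z": 2}


# ---------------------------------------------------------------------------
# Excitations
# ---------------------------------------------------------------------------

def gaussian_derivative_pulse(f_center: float = 0.8e9):
    """Differentiated Gaussian with spectral peak near ``f_center``.

    Broad support covering 0.4--1.2 GHz at the default center.
    """
    tw = 1.0 / (2.0 * np.pi * f_center)
    t0 = 5.0 * tw

    def v(t: np.ndarray) -> np.ndarray:
        u = (t - t0) / tw
        return -u * np.exp(-0.5 * u ** 2)

    v.duration = t0 + 5.0 * tw
    return v


def windowed_sine_pulse(f0: float = 0.8e9, n_cycles: float = 3.0):
    """Hann-windowed sinusoid with *compact support* (exactly zero outside
    its window) — useful for causal arrival-time measurements."""
    T = n_cycles / f0

    def v(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        inside = (t >= 0) & (t <= T)
        out = np.zeros_like(t)
        out[inside] = (np.sin(2 * np.pi * f0 * t[inside])
                       * 0.5 * (1 - np.cos(2 * np.pi * t[inside] / T)))
        return out

    v.duration = T
    return v


def extract_spectrum(series: np.ndarray, dt: float,
                     freqs: np.ndarray) -> np.ndarray:
    """Direct DFT of a time series evaluated exactly on ``freqs``.

    ``V(f) = dt * sum_n v[n] exp(-2 pi i f n dt)`` — no FFT-bin
    interpolation.  The series should have decayed (or be windowed).
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty time series")
    n = np.arange(series.size)
    kernel = np.exp(-2j * np.pi * np.asarray(freqs)[:, None] * n[None, :] * dt)
    return dt * (kernel @ series)


def first_arrival(trace: np.ndarray, dt: float, threshold: float) -> float:
    """Causal first-arrival time of a transient by threshold crossing.

    Returns the time at which ``|trace|`` first exceeds the absolute
    ``threshold``, refined to sub-step accuracy by linear interpolation.
    Arrival *differences* between two traces of the same waveform are
    unbiased because the rise to a common threshold cancels.
    """
    a = np.abs(np.asarray(trace, dtype=float))
    above = a > threshold
    if not above.any():
        raise ValueError("trace never exceeds the threshold")
    i = int(np.argmax(above))
    if i == 0:
        return 0.0
    return (i - 1 + (threshold - a[i - 1]) / (a[i] - a[i - 1])) * dt


def plane_wave_alpha(model: DebyeModel, freq) -> np.ndarray:
    """Closed-form plane-wave attenuation constant alpha(omega), Np/m.

    ``k = omega sqrt(eps)/c`` with the e^{+j omega t} convention; the field
    decays as ``exp(-alpha r)`` with ``alpha = -Im k``.
    """
    eps = np.asarray(model(freq))
    k = 2.0 * np.pi * np.asarray(freq) / C0 * np.sqrt(eps)
    return -k.imag


# ---------------------------------------------------------------------------
# Antenna array layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Antenna:
    """Center-fed dipole: center position (m), orientation axis, length (m)."""

    center: tuple[float, float, float]
    axis: str
    length: float = 0.021

    def __post_init__(self) -> None:
        if self.axis not in _AXIS:
            raise ValueError(f"axis must be x, y or z, got {self.axis!r}")


@dataclass(frozen=True)
class BolusSpec:
    """Elliptic-cylinder deionized-water container around one antenna.

    Cross-section semi-axes (m) perpendicular to the antenna axis; the
    cylinder extends ``overhang`` beyond each antenna endpoint.
    """

    semi_axes: tuple[float, float] = (0.015, 0.010)
    overhang: float = 0.005


@dataclass
class AntennaArrayLayout:
    antennas: list[Antenna]
    boluses: list[BolusSpec]

    @property
    def n_antennas(self) -> int:
        return len(self.antennas)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return antenna_pairs(self.n_antennas)


def build_layout(head_semi_axes_xy: tuple[float, float] = (0.090, 0.105),
                 head_top_z: float = 0.075,
                 n_ring: int = 12, n_top: int = 4,
                 standoff: float = 0.012, ring_z: float = 0.0,
                 antenna_length: float = 0.021,
                 bolus: BolusSpec = BolusSpec()) -> AntennaArrayLayout:
    """Antenna array around a head: a ring of vertical dipoles plus
    horizontal dipoles above.

    ``n_ring`` z-oriented dipoles are spaced equally in angle with their
    centers coplanar at ``ring_z``, offset ``standoff`` outside the head
    ellipse; ``n_top`` x/y-oriented dipoles sit on a cross pattern above the
    head.  Defaults give 16 antennas and 120 pairs.
    """
    a, b = head_semi_axes_xy
    antennas = []
    for k in range(n_ring):
        th = 2.0 * np.pi * k / n_ring
        pos = ((a + standoff) * np.cos(th), (b + standoff) * np.sin(th), ring_z)
        antennas.append(Antenna(center=pos, axis="z", length=antenna_length))
    # cross pattern above the head, alternating x/y orientation
    top_z = head_top_z + standoff
    offsets = [(0.03, 0.0), (-0.03, 0.0), (0.0, 0.03), (0.0, -0.03)]
    for k in range(n_top):
        ox, oy = offsets[k % 4]
        axis = "y" if abs(ox) > 0 else "x"
        antennas.append(Antenna(center=(ox, oy, top_z), axis=axis,
                                length=antenna_length))
    return AntennaArrayLayout(antennas=antennas,
                              boluses=[bolus] * len(antennas))


# ---------------------------------------------------------------------------
# CPML profiles
# ---------------------------------------------------------------------------

def _cpml_1d(n: int, npml: int, dx: float, dt: float, eps_bg: float,
             half: bool, m: int = 3, kappa_max: float = 3.0,
             alpha_max: float = 0.05):
    """(b, a, 1/kappa) along one axis; zero/one outside the PML slabs."""
    sigma_max = 0.8 * (m + 1) / (ETA0 * dx * np.sqrt(eps_bg))
    pos = np.arange(n, dtype=float) + (0.5 if half else 0.0)
    depth = np.maximum.reduce([
        (npml - pos) / npml,          # low side
        (pos - (n - 1 - npml)) / npml,  # high side
        np.zeros(n),
    ])
    depth = np.clip(depth, 0.0, 1.0)
    sigma = sigma_max * depth ** m
    kappa = 1.0 + (kappa_max - 1.0) * depth ** m
    alpha = alpha_max * (1.0 - depth)
    alpha[depth == 0.0] = 0.0
    b = np.exp(-(sigma / kappa + alpha) * dt / EPS0)
    denom = sigma * kappa + kappa ** 2 * alpha
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(denom > 0, sigma * (b - 1.0) / denom, 0.0)
    b = np.where(depth > 0, b, 0.0)  # outside PML: psi forced to stay zero
    return b, a, 1.0 / kappa


@njit(cache=True)
def _h_step(Ex, Ey, Ez, Hx, Hy, Hz,
            p_xy, p_xz, p_yz, p_yx, p_zx, p_zy,
            bhx, ahx, ikhx, bhy, ahy, ikhy, bhz, ahz, ikhz,
            dtm, inv_dx):  # pragma: no cover - exercised via FDTDSolver.run
    nx, ny, nz = Ex.shape
    for i in range(nx):
        for j in range(ny - 1):
            for k in range(nz - 1):
                d_zy = (Ez[i, j + 1, k] - Ez[i, j, k]) * inv_dx
                d_yz = (Ey[i, j, k + 1] - Ey[i, j, k]) * inv_dx
                p = 0.0
                if ahy[j] != 0.0:
                    p = bhy[j] * p_xy[i, j, k] + ahy[j] * d_zy
                    p_xy[i, j, k] = p
                q = 0.0
                if ahz[k] != 0.0:
                    q = bhz[k] * p_xz[i, j, k] + ahz[k] * d_yz
                    p_xz[i, j, k] = q
                Hx[i, j, k] -= dtm * (ikhy[j] * d_zy + p
                                      - ikhz[k] * d_yz - q)
    for i in range(nx - 1):
        for j in range(ny):
            for k in range(nz - 1):
                d_xz = (Ex[i, j, k + 1] - Ex[i, j, k]) * inv_dx
                d_zx = (Ez[i + 1, j, k] - Ez[i, j, k]) * inv_dx
                p = 0.0
                if ahz[k] != 0.0:
                    p = bhz[k] * p_yz[i, j, k] + ahz[k] * d_xz
                    p_yz[i, j, k] = p
                q = 0.0
                if ahx[i] != 0.0:
                    q = bhx[i] * p_yx[i, j, k] + ahx[i] * d_zx
                    p_yx[i, j, k] = q
                Hy[i, j, k] -= dtm * (ikhz[k] * d_xz + p
                                      - ikhx[i] * d_zx - q)
    for i in range(nx - 1):
        for j in range(ny - 1):
            for k in range(nz):
                d_yx = (Ey[i + 1, j, k] - Ey[i, j, k]) * inv_dx
                d_xy = (Ex[i, j + 1, k] - Ex[i, j, k]) * inv_dx
                p = 0.0
                if ahx[i] != 0.0:
                    p = bhx[i] * p_zx[i, j, k] + ahx[i] * d_yx
                    p_zx[i, j, k] = p
                q = 0.0
                if ahy[j] != 0.0:
                    q = bhy[j] * p_zy[i, j, k] + ahy[j] * d_xy
                    p_zy[i, j, k] = q
                Hz[i, j, k] -= dtm * (ikhx[i] * d_yx + p
                                      - ikhy[j] * d_xy - q)


@njit(cache=True)
def _e_step(Ex, Ey, Ez, Hx, Hy, Hz, Jx, Jy, Jz,
            p_xy, p_xz, p_yz, p_yx, p_zx, p_zy,
            num, denom, kj, bj,
            bex, aex, ikex, bey, aey, ikey, bez, aez, ikez,
            inv_dx):  # pragma: no cover - exercised via FDTDSolver.run
    nx, ny, nz = Ex.shape
    for i in range(nx):
        for j in range(1, ny):
            for k in range(1, nz):
                d_zy = (Hz[i, j, k] - Hz[i, j - 1, k]) * inv_dx
                d_yz = (Hy[i, j, k] - Hy[i, j, k - 1]) * inv_dx
                p = 0.0
                if aey[j] != 0.0:
                    p = bey[j] * p_xy[i, j, k] + aey[j] * d_zy
                    p_xy[i, j, k] = p
                q = 0.0
                if aez[k] != 0.0:
                    q = bez[k] * p_xz[i, j, k] + aez[k] * d_yz
                    p_xz[i, j, k] = q
                curl = (ikey[j] * d_zy + p - ikez[k] * d_yz - q)
                e_old = Ex[i, j, k]
                e_new = (num[i, j, k] * e_old + curl
                         - kj[i, j, k] * Jx[i, j, k]) / denom[i, j, k]
                Ex[i, j, k] = e_new
                Jx[i, j, k] = kj[i, j, k] * Jx[i, j, k] \
                    + bj[i, j, k] * (e_new - e_old)
    for i in range(1, nx):
        for j in range(ny):
            for k in range(1, nz):
                d_xz = (Hx[i, j, k] - Hx[i, j, k - 1]) * inv_dx
                d_zx = (Hz[i, j, k] - Hz[i - 1, j, k]) * inv_dx
                p = 0.0
                if aez[k] != 0.0:
                    p = bez[k] * p_yz[i, j, k] + aez[k] * d_xz
                    p_yz[i, j, k] = p
                q = 0.0
                if aex[i] != 0.0:
                    q = bex[i] * p_yx[i, j, k] + aex[i] * d_zx
                    p_yx[i, j, k] = q
                curl = (ikez[k] * d_xz + p - ikex[i] * d_zx - q)
                e_old = Ey[i, j, k]
                e_new = (num[i, j, k] * e_old + curl
                         - kj[i, j, k] * Jy[i, j, k]) / denom[i, j, k]
                Ey[i, j, k] = e_new
                Jy[i, j, k] = kj[i, j, k] * Jy[i, j, k] \
                    + bj[i, j, k] * (e_new - e_old)
    for i in range(1, nx):
        for j in range(1, ny):
            for k in range(nz):
                d_yx = (Hy[i, j, k] - Hy[i - 1, j, k]) * inv_dx
                d_xy = (Hx[i, j, k] - Hx[i, j - 1, k]) * inv_dx
                p = 0.0
                if aex[i] != 0.0:
                    p = bex[i] * p_zx[i, j, k] + aex[i] * d_yx
                    p_zx[i, j, k] = p
                q = 0.0
                if aey[j] != 0.0:
                    q = bey[j] * p_zy[i, j, k] + aey[j] * d_xy
                    p_zy[i, j, k] = q
                curl = (ikex[i] * d_yx + p - ikey[j] * d_xy - q)
                e_old = Ez[i, j, k]
                e_new = (num[i, j, k] * e_old + curl
                         - kj[i, j, k] * Jz[i, j, k]) / denom[i, j, k]
                Ez[i, j, k] = e_new
                Jz[i, j, k] = kj[i, j, k] * Jz[i, j, k] \
                    + bj[i, j, k] * (e_new - e_old)


class FieldBlowUpError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------

class FDTDSolver:
    """Yee-grid FDTD with ADE Debye media and CPML boundaries.

    Parameters
    ----------
    material_index : (nx, ny, nz) int array
        Per-cell material id, indexing into ``materials``.
    materials : list of DebyeModel
        Dispersive material table; entry 0 is typically the immersion
        medium or vacuum.
    dx : float
        Uniform cell size in meters.
    pml_cells : int
        CPML thickness on every face (>= 8 recommended).
    courant : float
        Fraction of the 3D CFL limit used for the time step.
    """

    def __init__(self, material_index: np.ndarray,
                 materials: list[DebyeModel], dx: float,
                 pml_cells: int = 10, courant: float = 0.98):
        self.mat = np.ascontiguousarray(material_index, dtype=np.int16)
        if self.mat.ndim != 3:
            raise ValueError("material index must be 3D")
        if self.mat.max() >= len(materials) or self.mat.min() < 0:
            raise ValueError("material index references an unresolved material")
        self.materials = list(materials)
        self.dx = float(dx)
        self.dt = courant * self.dx / (C0 * np.sqrt(3.0))
        self.npml = int(pml_cells)
        self.shape = self.mat.shape

        # per-material ADE coefficients -> per-cell arrays
        eps_inf = np.array([m.eps_inf for m in materials])
        d_eps = np.array([m.delta_eps for m in materials])
        sigma = np.array([m.sigma for m in materials])
        tau = np.array([m.tau for m in materials])
        kj = (2.0 * tau - self.dt) / (2.0 * tau + self.dt)
        bj = 2.0 * EPS0 * d_eps / (2.0 * tau + self.dt)
        self._denom = (EPS0 * eps_inf / self.dt + sigma / 2.0 + bj)[self.mat]
        self._num = (EPS0 * eps_inf / self.dt - sigma / 2.0 + bj)[self.mat]
        self._kj = kj[self.mat]
        self._bj = bj[self.mat]
        self._dispersive = bool(np.any(d_eps[np.unique(self.mat)] != 0.0))

        # grade the PML for the dominant (immersion/background) material
        eps_bg = float(eps_inf[int(np.bincount(self.mat.ravel()).argmax())])
        prof = {}
        for ax, n in zip("xyz", self.shape):
            prof[ax + "e"] = _cpml_1d(n, self.npml, self.dx, self.dt,
                                      eps_bg, half=False)
            prof[ax + "h"] = _cpml_1d(n, self.npml, self.dx, self.dt,
                                      eps_bg, half=True)
        self._prof = prof

        self._ports: list[dict] = []
        self._pec_cells: list[tuple[int, np.ndarray]] = []

    # -- scene construction -------------------------------------------------

    def cell_of(self, position: tuple[float, float, float],
                origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
                ) -> tuple[int, int, int]:
        """Grid cell containing a physical position; grid centered on origin."""
        idx = []
        for p, o, n in zip(position, origin, self.shape):
            idx.append(int(round(p / self.dx + n / 2.0 + o)))
        return tuple(idx)

    def add_dipole(self, center_cell: tuple[int, int, int], axis: str,
                   length_cells: int, resistance: float = 50.0) -> int:
        """Add a center-fed thin-wire dipole; returns its port index.

        The dipole occupies ``length_cells`` collinear edges of the E
        component along ``axis`` with a one-cell feed gap at the center; the
        feed is loaded with ``resistance`` ohms (a resistive voltage source
        when driven, a matched load otherwise).
        """
        ax = _AXIS[axis]
        if length_cells < 3 or length_cells % 2 == 0:
            raise ValueError("length_cells must be odd and >= 3")
        half = length_cells // 2
        cells = []
        for s in range(-half, half + 1):
            c = list(center_cell)
            c[ax] += s
            if not all(0 <= c[d] < self.shape[d] for d in range(3)):
                raise ValueError(f"dipole cell {c} outside the grid")
            cells.append(tuple(c))
        feed = cells[half]
        arms = np.array([c for c in cells if c != feed])
        if any(self.mat[tuple(a)] < 0 for a in arms):  # pragma: no cover
            raise ValueError("antenna intersects an invalid region")
        self._pec_cells.append((ax, arms))
        # arm cells are perfect conductors: no polarization current there
        self._bj[arms[:, 0], arms[:, 1], arms[:, 2]] = 0.0
        g = 1.0 / (resistance * self.dx)  # dz/(R dx dy) with cubic cells
        self._ports.append({"feed": feed, "axis": ax, "g": g,
                            "resistance": resistance})
        # load conductance enters the E-update denominators at the feed cell
        self._denom[feed] += g / 2.0
        self._num[feed] -= g / 2.0
        return len(self._ports) - 1

    @property
    def n_ports(self) -> int:
        return len(self._ports)

    # -- time stepping ------------------------------------------------------

    def run(self, tx_port: int, waveform, n_steps: int | None = None,
            max_steps: int = 20000, decay_db: float = 50.0,
            check_every: int = 500, on_step=None) -> np.ndarray:
        """Time-step the scene with one driven port; record all port voltages.

        Stops after ``n_steps`` if given, otherwise when the trailing port
        voltages have decayed ``decay_db`` below their peak (residual port
        energy criterion), capped at ``max_steps``.  Returns an array
        (n_ports, n_recorded_steps).
        """
        if not self._ports:
            raise ValueError("no ports defined")
        f = {c: np.zeros(self.shape) for c in
             ("Ex", "Ey", "Ez", "Hx", "Hy", "Hz", "Jx", "Jy", "Jz")}
        psi_e = [np.zeros(self.shape) for _ in range(6)]
        psi_h = [np.zeros(self.shape) for _ in range(6)]
        dt, dx = self.dt, self.dx
        dtm = dt / MU0
        inv_dx = 1.0 / dx
        (bex, aex, ikex) = self._prof["xe"]
        (bhx, ahx, ikhx) = self._prof["xh"]
        (bey, aey, ikey) = self._prof["ye"]
        (bhy, ahy, ikhy) = self._prof["yh"]
        (bez, aez, ikez) = self._prof["ze"]
        (bhz, ahz, ikhz) = self._prof["zh"]

        port = self._ports[tx_port]
        src_axis = port["axis"]
        feed = port["feed"]
        total = n_steps if n_steps is not None else max_steps
        volts = np.zeros((self.n_ports, total))
        e_names = ("Ex", "Ey", "Ez")
        j_names = ("Jx", "Jy", "Jz")

        for n in range(total):
            _h_step(f["Ex"], f["Ey"], f["Ez"], f["Hx"], f["Hy"], f["Hz"],
                    psi_h[0], psi_h[1], psi_h[2], psi_h[3], psi_h[4], psi_h[5],
                    bhx, ahx, ikhx, bhy, ahy, ikhy, bhz, ahz, ikhz,
                    dtm, inv_dx)
            _e_step(f["Ex"], f["Ey"], f["Ez"], f["Hx"], f["Hy"], f["Hz"],
                    f["Jx"], f["Jy"], f["Jz"],
                    psi_e[0], psi_e[1], psi_e[2], psi_e[3], psi_e[4], psi_e[5],
                    self._num, self._denom, self._kj, self._bj,
                    bex, aex, ikex, bey, aey, ikey, bez, aez, ikez, inv_dx)

            # resistive voltage source: curl-consistent increment at the feed
            vs = float(waveform(np.array([(n + 0.5) * dt]))[0])
            d_e = vs / (port["resistance"] * dx * dx) / self._denom[feed]
            f[e_names[src_axis]][feed] += d_e
            f[j_names[src_axis]][feed] += self._bj[feed] * d_e

            # PEC antenna arms
            for ax, arms in self._pec_cells:
                f[e_names[ax]][arms[:, 0], arms[:, 1], arms[:, 2]] = 0.0

            # record port voltages
            for k, pt in enumerate(self._ports):
                volts[k, n] = -f[e_names[pt["axis"]]][pt["feed"]] * dx

            if on_step is not None:
                on_step(n, f)

            if (n + 1) % check_every == 0:
                peak = np.max(np.abs(volts[:, :n + 1]))
                if not np.isfinite(peak) or peak > 1e12:
                    raise FieldBlowUpError(
                        f"field blow-up at step {n + 1} (dt={dt:.3e} s)")
                if n_steps is None and (n + 1) * dt > waveform.duration:
                    recent = np.max(np.abs(volts[:, n + 1 - check_every:n + 1]))
                    if recent < peak * 10.0 ** (-decay_db / 20.0):
                        return volts[:, :n + 1]
        return volts

    # -- energy diagnostic --------------------------------------------------

    @staticmethod
    def field_energy(f: dict, eps_cells: np.ndarray, dx: float) -> float:
        """Instantaneous EM energy sum( eps|E|^2 + mu|H|^2 )/2 * dV."""
        e2 = f["Ex"] ** 2 + f["Ey"] ** 2 + f["Ez"] ** 2
        h2 = f["Hx"] ** 2 + f["Hy"] ** 2 + f["Hz"] ** 2
        return float(0.5 * np.sum(EPS0 * eps_cells * e2 + MU0 * h2) * dx ** 3)


# ---------------------------------------------------------------------------
# Scene assembly and forward runs
# ---------------------------------------------------------------------------

def _paint_boluses(mat: np.ndarray, layout: AntennaArrayLayout, dx: float,
                   water_id: int, background_id: int = 0) -> None:
    """Fill elliptic-cylinder water containers around each antenna."""
    nx, ny, nz = mat.shape
    centers = (np.arange(nx) - nx / 2.0) * dx, \
              (np.arange(ny) - ny / 2.0) * dx, \
              (np.arange(nz) - nz / 2.0) * dx
    for ant, bolus in zip(layout.antennas, layout.boluses):
        ax = _AXIS[ant.axis]
        t_axes = [d for d in range(3) if d != ax]
        half_len = ant.length / 2.0 + bolus.overhang
        ga = centers[ax][_reshape_for(ax)] - ant.center[ax]
        g1 = centers[t_axes[0]][_reshape_for(t_axes[0])] - ant.center[t_axes[0]]
        g2 = centers[t_axes[1]][_reshape_for(t_axes[1])] - ant.center[t_axes[1]]
        inside = ((np.abs(ga) <= half_len)
                  & ((g1 / bolus.semi_axes[0]) ** 2
                     + (g2 / bolus.semi_axes[1]) ** 2 <= 1.0))
        mat[inside & (mat == background_id)] = water_id


def _reshape_for(axis: int):
    sl = [None, None, None]
    sl[axis] = slice(None)
    return tuple(sl)


def scene_from_phantom(phantom: VoxelPhantom, layout: AntennaArrayLayout,
                       dx: float, library: TissueLibrary | None = None,
                       padding_cells: int = 16
                       ) -> tuple[np.ndarray, list[DebyeModel], dict[str, int]]:
    """Voxelize a phantom + water boluses onto an FDTD material grid.

    The phantom's label grid is resampled (nearest neighbor) to the FDTD
    cell size and centered; returns the material index grid, the material
    table, and the label->material-id map.  Material 0 is vacuum.
    """
    library = library or TissueLibrary.default()
    labels_present = sorted(int(v) for v in np.unique(phantom.labels))
    models = [VACUUM]
    mat_of_label = {LABELS["background"]: 0}
    for lab in labels_present:
        name = phantom.label_map[lab]
        if name == "background":
            continue
        mat_of_label[lab] = len(models)
        models.append(library.get_debye(name))
    water_id = len(models)
    models.append(library.get_debye("water"))

    # resample labels to the FDTD resolution
    factors = [v / (dx * 1000.0) for v in phantom.voxel_size]
    n_ph = [int(round(n * f)) for n, f in zip(phantom.labels.shape, factors)]
    res = phantom.labels
    for axisn, (n_out, f) in enumerate(zip(n_ph, factors)):
        centers = (np.arange(n_out) + 0.5) / f
        idx = np.clip(np.floor(centers).astype(int), 0,
                      res.shape[axisn] - 1)
        res = np.take(res, idx, axis=axisn)

    shape = tuple(n + 2 * padding_cells for n in res.shape)
    mat = np.zeros(shape, dtype=np.int16)
    sl = tuple(slice(padding_cells, padding_cells + n) for n in res.shape)
    lut = np.zeros(max(mat_of_label) + 1, dtype=np.int16)
    for lab, mid in mat_of_label.items():
        lut[lab] = mid
    mat[sl] = lut[res]
    _paint_boluses(mat, layout, dx, water_id)
    return mat, models, mat_of_label


def run_forward(phantom: VoxelPhantom, layout: AntennaArrayLayout,
                dx: float = 0.003, frequencies: np.ndarray | None = None,
                library: TissueLibrary | None = None,
                pml_cells: int = 10, waveform=None,
                label: str = "healthy", metadata: dict | None = None,
                resistance: float = 50.0) -> TransmissionRecord:
    """Compute noise-free transmission coefficients for one subject.

    For every transmit antenna a full FDTD run records all port voltages;
    ``S_ij`` is the received spectrum at ``j`` divided by the reference
    spectrum of the driven port from a calibration run with the antennas in
    the homogeneous immersion medium (water-filled scene, no phantom).
    """
    frequencies = default_frequency_grid() if frequencies is None else \
        np.asarray(frequencies)
    waveform = waveform or gaussian_derivative_pulse()
    mat, models, _ = scene_from_phantom(phantom, layout, dx, library)
    library = library or TissueLibrary.default()

    def make_solver(material_grid) -> FDTDSolver:
        solver = FDTDSolver(material_grid, models, dx, pml_cells=pml_cells)
        length_cells = max(3, int(round(layout.antennas[0].length / dx)) | 1)
        for ant in layout.antennas:
            cell = solver.cell_of(ant.center)
            solver.add_dipole(cell, ant.axis, length_cells,
                              resistance=resistance)
        return solver

    # calibration: same array in homogeneous immersion (water everywhere)
    water_id = len(models) - 1
    cal_mat = np.full_like(mat, water_id)
    cal = make_solver(cal_mat)
    v_cal = cal.run(0, waveform)
    ref = extract_spectrum(v_cal[0], cal.dt, frequencies)

    solver = make_solver(mat)
    pairs = layout.pairs
    S = np.empty((frequencies.size, len(pairs)), dtype=complex)
    spectra: dict[tuple[int, int], np.ndarray] = {}
    for tx in range(layout.n_antennas):
        if not any(p[0] == tx for p in pairs):
            continue
        volts = solver.run(tx, waveform)
        for rx in range(layout.n_antennas):
            if (tx, rx) in pairs:
                spectra[(tx, rx)] = extract_spectrum(volts[rx], solver.dt,
                                                     frequencies)
    for col, p in enumerate(pairs):
        S[:, col] = spectra[p] / ref
    return TransmissionRecord(frequencies=frequencies, pairs=pairs, s=S,
                              label=label, metadata=metadata or
                              {"source": "fdtd", "dx_m": dx})
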