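"""Dispersive dielectric models for biological tissues.

Tissue permittivity in the microwave band is described by multi-pole
Cole--Cole fits to measured data.  A time-domain solver with an
auxiliary-differential-equation update can only handle single-pole Debye
media, so each tissue's Cole--Cole curve is approximated by a four-parameter
Debye model fitted by least squares over the operating band (0.5--1.5 GHz
by default).

Conventions
-----------
All permittivities are *relative*.  The harmonic time convention is
``e^{+j omega t}``, so lossy media have a negative imaginary part.  The
static-conductivity term is ``sigma / (j omega eps0)`` which keeps the
result dimensionless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m

__all__ = [
    "DebyeModel",
    "ColeColeModel",
    "TissueLibrary",
    "eval_debye",
    "eval_cole_cole",
    "fit_debye",
    "DEFAULT_FIT_BAND",
    "WATER",
]

DEFAULT_FIT_BAND = (0.5e9, 1.5e9)


@dataclass(frozen=True)
class DebyeModel:
    """Single-pole Debye medium with a static-conductivity term.

    Parameters
    ----------
    eps_static : float
        Relative permittivity at the low-frequency end of the pole.
    eps_inf : float
        Relative permittivity at the high-frequency limit.
    sigma : float
        Static conductivity in S/m.
    tau : float
        Relaxation time in seconds.
    """

    eps_static: float
    eps_inf: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.eps_static >= self.eps_inf >= 1.0):
            raise ValueError(
                f"require eps_static >= eps_inf >= 1, got "
                f"eps_static={self.eps_static}, eps_inf={self.eps_inf}"
            )
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")

    @property
    def delta_eps(self) -> float:
        return self.eps_static - self.eps_inf

    def __call__(self, freq):
        return eval_debye(self, freq)


@dataclass(frozen=True)
class ColeColePole:
    delta_eps: float
    tau: float
    alpha: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError(f"alpha must lie in [0, 1), got {self.alpha}")
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")


@dataclass(frozen=True)
class ColeColeModel:
    """Multi-pole Cole--Cole medium: broadened relaxations plus conductivity."""

    eps_inf: float
    poles: tuple[ColeColePole, ...]
    sigma: float

    def __post_init__(self) -> None:
        if len(self.poles) == 0:
            raise ValueError("Cole-Cole model needs at least one pole")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")

    @classmethod
    def from_lists(cls, eps_inf, delta_eps, tau, alpha, sigma) -> "ColeColeModel":
        poles = tuple(
            ColeColePole(d, t, a) for d, t, a in zip(delta_eps, tau, alpha)
        )
        return cls(eps_inf=eps_inf, poles=poles, sigma=sigma)

    def __call__(self, freq):
        return eval_cole_cole(self, freq)


# Deionized immersion water used in the antenna boluses.
WATER = DebyeModel(eps_static=77.5, eps_inf=4.65, sigma=0.0, tau=8.8e-12)


def _check_freq(freq) -> np.ndarray:
    f = np.asarray(freq, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    return f


def eval_debye(model: DebyeModel, freq):
    """Complex relative permittivity of a Debye medium at ``freq`` (Hz).

    ``eps(w) = eps_inf + (eps_static - eps_inf)/(1 + j w tau) + sigma/(j w eps0)``
    with ``w = 2 pi freq``.  Scalar in, scalar out.
    """
    f = _check_freq(freq)
    w = 2.0 * np.pi * f
    eps = (
        model.eps_inf
        + model.delta_eps / (1.0 + 1j * w * model.tau)
        + model.sigma / (1j * w * EPS0)
    )
    if np.isscalar(freq):
        return complex(eps)
    return eps


def eval_cole_cole(model: ColeColeModel, freq):
    """Complex relative permittivity of a multi-pole Cole--Cole medium.

    Each pole contributes ``delta_eps / (1 + (j w tau)^(1-alpha))``; with
    ``alpha = 0`` the pole degenerates to Debye.
    """
    f = _check_freq(freq)
    w = 2.0 * np.pi * f
    eps = np.full_like(w, model.eps_inf, dtype=complex)
    for pole in model.poles:
        eps = eps + pole.delta_eps / (1.0 + (1j * w * pole.tau) ** (1.0 - pole.alpha))
    eps = eps + model.sigma / (1j * w * EPS0)
    if np.isscalar(freq):
        return complex(eps)
    return eps


class DebyeFitError(RuntimeError):
    """Raised when the bounded least-squares Debye fit fails to converge."""


def fit_debye(samples, band: tuple[float, float] = DEFAULT_FIT_BAND,
              n_starts: int = 3) -> tuple[DebyeModel, float]:
    """Fit a Debye model to sampled complex permittivity by least squares.

    Parameters
    ----------
    samples : sequence of (freq_hz, complex_eps) pairs
        Sampled complex relative permittivity.
    band : (f_lo, f_hi)
        Only samples inside this band enter the cost.  Default 0.5--1.5 GHz.
    n_starts : int
        Multi-start count; initial relaxation times are spread over
        {1, 10, 100} ps to avoid the shallow local minima of the tau axis.

    Returns
    -------
    (DebyeModel, residual)
        The best model and its root-mean-square complex-modulus residual.
    """
    samples = list(samples)
    freqs = np.array([f for f, _ in samples], dtype=float)
    vals = np.array([v for _, v in samples], dtype=complex)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    freqs, vals = freqs[in_band], vals[in_band]
    if freqs.size < 4:
        raise ValueError(
            f"need at least 4 samples inside band {band}, got {freqs.size}"
        )

    w = 2.0 * np.pi * freqs

    def residual(p):
        eps_inf, d_eps, sigma, log_tau = p
        tau = 10.0 ** log_tau
        model_eps = (
            eps_inf + d_eps / (1.0 + 1j * w * tau) + sigma / (1j * w * EPS0)
        )
        r = model_eps - vals
        return np.concatenate([r.real, r.imag])

    # parameters: eps_inf, delta_eps (>=0 enforces eps_static >= eps_inf),
    # sigma, log10(tau)
    lo = [1.0, 0.0, 0.0, -13.5]
    hi = [1e3, 1e4, 1e2, -9.0]
    tau_starts = [1e-12, 1e-11, 1e-10][:n_starts]
    eps_hi = float(np.real(vals[np.argmax(freqs)]))
    eps_lo = float(np.real(vals[np.argmin(freqs)]))
    best = None
    for tau0 in tau_starts:
        x0 = [
            max(1.0, min(eps_hi, 1e3)),
            max(0.0, eps_lo - eps_hi) + 1.0,
            0.1,
            np.log10(tau0),
        ]
        try:
            sol = least_squares(residual, x0, bounds=(lo, hi),
                                ftol=1e-12, xtol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise DebyeFitError("Debye fit did not converge from any start")
    eps_inf, d_eps, sigma, log_tau = best.x
    model = DebyeModel(
        eps_static=eps_inf + d_eps,
        eps_inf=max(eps_inf, 1.0),
        sigma=max(sigma, 0.0),
        tau=10.0 ** log_tau,
    )
    rms = float(np.sqrt(2.0 * best.cost / freqs.size))
    return model, rms


# ---------------------------------------------------------------------------
# Tissue library
# ---------------------------------------------------------------------------

# §tissue substitutions: tissues without published dielectric data are
# aliased to a structurally similar tissue.
TISSUE_ALIASES = {
    "glial": "fat",
    "connective": "grey_matter",
    "hair": "nail",
}


@dataclass
class TissueLibrary:
    """Maps tissue labels to dielectric models.

    Debye models are either read directly from the table or fitted on demand
    from the tissue's Cole--Cole description over the operating band.
    """

    cole_cole: dict[str, ColeColeModel] = field(default_factory=dict)
    debye: dict[str, DebyeModel] = field(default_factory=dict)
    fit_band: tuple[float, float] = DEFAULT_FIT_BAND

    def resolve(self, tissue: str) -> str:
        return TISSUE_ALIASES.get(tissue, tissue)

    def __contains__(self, tissue: str) -> bool:
        t = self.resolve(tissue)
        return t in self.debye or t in self.cole_cole

    def tissues(self) -> list[str]:
        return sorted(set(self.debye) | set(self.cole_cole))

    def get_debye(self, tissue: str) -> DebyeModel:
        t = self.resolve(tissue)
        if t in self.debye:
            return self.debye[t]
        if t in self.cole_cole:
            cc = self.cole_cole[t]
            freqs = np.linspace(self.fit_band[0], self.fit_band[1], 41)
            samples = [(f, eval_cole_cole(cc, f)) for f in freqs]
            model, _ = fit_debye(samples, band=self.fit_band)
            self.debye[t] = model  # cache
            return model
        raise KeyError(f"tissue {tissue!r} not in library")

    def get_cole_cole(self, tissue: str) -> ColeColeModel:
        t = self.resolve(tissue)
        if t not in self.cole_cole:
            raise KeyError(f"no Cole-Cole model for tissue {tissue!r}")
        return self.cole_cole[t]

    @classmethod
    def from_csv(cls, path) -> "TissueLibrary":
        """Load a library from a columnar text table.

        Columns: ``tissue,eps_inf,eps_static,sigma,tau[,cole_cole]`` where
        ``cole_cole`` is a JSON blob
        ``{"eps_inf": ..., "delta_eps": [...], "tau": [...], "alpha": [...],
        "sigma": ...}``.  Debye columns may be empty for tissues that are
        fitted from their Cole--Cole description.
        """
        df = pd.read_csv(path)
        lib = cls()
        for _, row in df.iterrows():
            name = str(row["tissue"]).strip()
            if not pd.isna(row.get("eps_static")):
                lib.debye[name] = DebyeModel(
                    eps_static=float(row["eps_static"]),
                    eps_inf=float(row["eps_inf"]),
                    sigma=float(row["sigma"]),
                    tau=float(row["tau"]),
                )
            blob = row.get("cole_cole")
            if isinstance(blob, str) and blob.strip():
                d = json.loads(blob)
                lib.cole_cole[name] = ColeColeModel.from_lists(
                    d["eps_inf"], d["delta_eps"], d["tau"], d["alpha"], d["sigma"]
                )
        return lib

    @classmethod
    def default(cls) -> "TissueLibrary":
        """Library shipped with the package (editable CSV fixture)."""
        with resources.as_file(
            resources.files("mwdetect").joinpath("data/tissues.csv")
        ) as p:
            return cls.from_csv(Path(p))
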