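"""Vector-network-analyzer style measurement noise.

Noise enters the transmission coefficients as independent amplitude and
phase perturbations per frequency and antenna pair:

    S_noisy = (A + sigma N1) exp[i (phi + arctan(sigma N2 / A))]

with N1, N2 standard normal and sigma = 10^(nf/20), where nf is the noise
floor in dB.  The phase perturbation shrinks as the signal amplitude grows,
which mirrors how trace noise behaves on a real VNA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .records import TransmissionRecord

__all__ = ["NoiseSpec", "sigma_from_noise_floor", "add_vna_noise"]


def sigma_from_noise_floor(nf_db: float) -> float:
    """Noise standard deviation from the noise floor in dB: 10^(nf/20)."""
    return 10.0 ** (nf_db / 20.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Noise floor nf (dB) and the derived standard deviation sigma.

    ``shared_draw=True`` reuses one normal draw for amplitude and phase
    instead of the default independent draws.
    """

    nf_db: float
    shared_draw: bool = False

    @property
    def sigma(self) -> float:
        return sigma_from_noise_floor(self.nf_db)


def add_vna_noise(record: TransmissionRecord, spec: NoiseSpec,
                  rng: np.random.Generator) -> TransmissionRecord:
    """Return a copy of ``record`` with VNA amplitude/phase noise applied.

    Noisy amplitudes are clamped at zero.  Where the clean amplitude is
    exactly zero the arctan ratio is unbounded, so the phase perturbation is
    drawn uniformly on (-pi/2, pi/2) instead (logged via a warning).
    """
    amp = np.abs(record.s)
    phase = np.angle(record.s)
    sigma = spec.sigma
    n1 = rng.standard_normal(record.s.shape)
    n2 = n1 if spec.shared_draw else rng.standard_normal(record.s.shape)

    amp_noisy = np.maximum(amp + sigma * n1, 0.0)
    zero = amp == 0.0
    if sigma > 0 and zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-amplitude entries: phase noise drawn "
            "uniformly on (-pi/2, pi/2)", stacklevel=2)
        phase_noise = np.arctan(np.divide(sigma * n2, amp,
                                          out=np.full_like(amp, np.inf),
                                          where=~zero))
        phase_noise[zero] = rng.uniform(-np.pi / 2, np.pi / 2,
                                        size=int(zero.sum()))
    else:
        phase_noise = np.arctan(sigma * n2 / amp) if sigma > 0 else 0.0

    s_noisy = amp_noisy * np.exp(1j * (phase + phase_noise))
    metadata = dict(record.metadata)
    metadata["noise_floor_db"] = spec.nf_db
    return TransmissionRecord(
        frequencies=record.frequencies.copy(),
        pairs=list(record.pairs),
        s=s_noisy,
        label=record.label,
        metadata=metadata,
    )
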