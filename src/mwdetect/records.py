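"""Complex transmission-coefficient records.

One record holds a single subject's S(omega) = A(omega) e^{i phi(omega)}
between all unordered antenna pairs, on a common frequency grid, plus the
class label and generation metadata.  Records are produced either by the
FDTD forward solver or by the surrogate cohort generator; downstream stages
cannot tell the two apart.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "HEALTHY",
    "BLEEDING",
    "TransmissionRecord",
    "default_frequency_grid",
    "antenna_pairs",
    "save_records",
    "load_records",
]

HEALTHY = "healthy"
BLEEDING = "bleeding"

# Measurement band: 0.4-1.2 GHz on 267 points (step ~3.008 MHz).
N_FREQ_DEFAULT = 267
BAND_DEFAULT = (0.4e9, 1.2e9)


def default_frequency_grid(n_freq: int = N_FREQ_DEFAULT,
                           band: tuple[float, float] = BAND_DEFAULT
                           ) -> np.ndarray:
    return np.linspace(band[0], band[1], n_freq)


def antenna_pairs(n_antennas: int) -> list[tuple[int, int]]:
    """All unordered antenna index pairs (i < j); 16 antennas give 120."""
    return [(i, j) for i in range(n_antennas) for j in range(i + 1, n_antennas)]


@dataclass
class TransmissionRecord:
    """One subject's transmission data.

    ``s`` has shape (n_freq, n_pairs), complex; ``pairs`` lists the
    unordered antenna index pairs column by column.
    """

    frequencies: np.ndarray
    pairs: list[tuple[int, int]]
    s: np.ndarray
    label: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.s = np.asarray(self.s, dtype=complex)
        if self.frequencies.ndim != 1 or np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if self.s.shape != (self.frequencies.size, len(self.pairs)):
            raise ValueError(
                f"S shape {self.s.shape} does not match "
                f"({self.frequencies.size}, {len(self.pairs)})")
        if self.label not in (HEALTHY, BLEEDING):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def n_freq(self) -> int:
        return self.frequencies.size

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def amplitude(self) -> np.ndarray:
        return np.abs(self.s)

    def phase(self) -> np.ndarray:
        return np.angle(self.s)

    def write_touchstone(self, path, pair_index: int) -> None:
        """Export one pair's transmission as a 2-port Touchstone (.s2p) file.

        Only S21/S12 are populated (equal, reciprocal path); S11/S22 are
        written as zero since reflection is not modeled by this record.
        """
        i, j = self.pairs[pair_index]
        s21 = self.s[:, pair_index]
        with open(path, "w") as f:
            f.write(f"! transmission antenna {i} -> antenna {j}\n")
            f.write("# Hz S RI R 50\n")
            for freq, val in zip(self.frequencies, s21):
                f.write(f"{freq:.6e} 0 0 {val.real:.9e} {val.imag:.9e} "
                        f"{val.real:.9e} {val.imag:.9e} 0 0\n")


def save_records(path, records: list[TransmissionRecord]) -> None:
    """Write a cohort of records to one HDF5 file."""
    with h5py.File(path, "w") as f:
        for k, rec in enumerate(records):
            g = f.create_group(f"subject_{k:05d}")
            g.create_dataset("frequencies", data=rec.frequencies)
            g.create_dataset("pairs", data=np.asarray(rec.pairs, dtype=int))
            g.create_dataset("s", data=rec.s)
            g.attrs["label"] = rec.label
            g.attrs["metadata"] = json.dumps(rec.metadata, default=str)


def load_records(path) -> list[TransmissionRecord]:
    records = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            g = f[name]
            records.append(TransmissionRecord(
                frequencies=g["frequencies"][...],
                pairs=[tuple(int(v) for v in p) for p in g["pairs"][...]],
                s=g["s"][...],
                label=str(g.attrs["label"]),
                metadata=json.loads(g.attrs["metadata"]),
            ))
    return records
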