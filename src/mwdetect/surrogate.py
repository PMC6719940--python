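"""Surrogate cohorts of complex transmission vectors.

Running thousands of 1 mm 3D forward simulations is a cluster-scale
campaign.  This generator emulates the *statistical* structure of such a
campaign so the classifier, cross-validation, and learning-curve machinery
can be exercised at a thousand subjects on one CPU: each subject's spectrum
is a smooth common mean plus a low-rank "anatomy" background with
complex-normal coefficients, patients additionally carry a lesion signature
whose amplitude scales with a lesion volume drawn from the phantom module's
bleeding law, and VNA noise is applied exactly as to simulated data.

The class geometry — a common low-rank span perturbed, for patients, along
a nearly fixed extra direction — is precisely what the subspace classifier
assumes, which is the point: the surrogate supports property-based and
scaled-down studies, not quantitative claims about full-wave cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .evaluation import nested_cv, stack_records
from .noise import NoiseSpec, add_vna_noise
from .phantom import MAX_BLEEDING_ML, draw_bleeding_volume_ml
from .records import (BLEEDING, HEALTHY, TransmissionRecord, antenna_pairs,
                      default_frequency_grid)

__all__ = ["CohortSpec", "TOY_PROFILE", "generate_cohort", "calibrate_effect"]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one surrogate cohort.

    ``n_subjects`` is split half/half into bleeding patients and healthy
    subjects.  ``background_rank``/``background_scale`` set the rank and
    coefficient scale of the shared anatomical-variability subspace
    (relative to the mean transmission amplitude); ``effect_amplitude`` is
    the class-separation amplitude Delta applied to the lesion signature,
    scaled per subject by ``(volume / volume_max) ** volume_exponent``.
    """

    n_subjects: int = 1000
    n_freq: int = 267
    n_pairs: int = 120
    background_rank: int = 8
    background_scale: float = 0.3
    effect_amplitude: float = 0.0
    volume_exponent: float = 1.0
    volume_range_ml: tuple[float, float] = (0.0, MAX_BLEEDING_ML)
    lesion_rotation: float = 0.2
    mean_amplitude: float = 1e-3
    noise_floor_db: float = -100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects % 2 != 0 or self.n_subjects < 2:
            raise ValueError("n_subjects must be even and >= 2")
        if self.effect_amplitude < 0:
            raise ValueError("effect amplitude must be >= 0")
        if self.background_rank < 1:
            raise ValueError("background rank must be >= 1")


# 20 frequencies x 6 pairs: fast profile for tests and desk-scale studies
TOY_PROFILE = dict(n_freq=20, n_pairs=6)


def _pairs_for(n_pairs: int) -> list[tuple[int, int]]:
    # recover an antenna count when n_pairs is triangular, else synthesize
    n = int((1 + np.sqrt(1 + 8 * n_pairs)) / 2)
    if n * (n - 1) // 2 == n_pairs:
        return antenna_pairs(n)
    return [(0, j + 1) for j in range(n_pairs)]


def _smooth_complex(rng: np.random.Generator, n_freq: int, n_pairs: int,
                    n_harmonics: int = 4) -> np.ndarray:
    """Random complex surface, smooth along the frequency axis."""
    t = np.linspace(0.0, 1.0, n_freq)[:, None]
    out = np.zeros((n_freq, n_pairs), dtype=complex)
    for h in range(n_harmonics + 1):
        c = rng.standard_normal(n_pairs) + 1j * rng.standard_normal(n_pairs)
        out += c[None, :] * np.exp(2j * np.pi * h * t)
    return out / np.sqrt(2.0 * (n_harmonics + 1))


def generate_cohort(spec: CohortSpec) -> list[TransmissionRecord]:
    """Generate one surrogate cohort as a list of transmission records.

    Healthy and patient subjects use independently seeded random streams,
    so the healthy half of a cohort is bit-identical between two specs that
    differ only in ``effect_amplitude``.
    """
    ss = np.random.SeedSequence(spec.seed)
    s_struct, s_healthy, s_patient, s_noise_h, s_noise_p = ss.spawn(5)
    rng_struct = np.random.default_rng(s_struct)

    freqs = default_frequency_grid(spec.n_freq)
    pairs = _pairs_for(spec.n_pairs)
    shape = (spec.n_freq, spec.n_pairs)
    n_half = spec.n_subjects // 2

    # cohort-level structure, fixed across subjects
    # mean spectrum: amplitude decaying with frequency, linear phase
    f_norm = (freqs - freqs[0]) / (freqs[-1] - freqs[0])
    delay = rng_struct.uniform(0.5e-9, 1.5e-9, size=spec.n_pairs)
    atten_db = rng_struct.uniform(0.0, 20.0, size=spec.n_pairs)
    mean = (spec.mean_amplitude
            * 10.0 ** (-atten_db[None, :] * f_norm[:, None] / 20.0)
            * np.exp(-2j * np.pi * freqs[:, None] * delay[None, :]))
    background = [
        _smooth_complex(rng_struct, *shape) * spec.mean_amplitude
        for _ in range(spec.background_rank)
    ]
    lesion = _smooth_complex(rng_struct, *shape)
    lesion = lesion / np.linalg.norm(lesion) * spec.mean_amplitude

    noise = NoiseSpec(nf_db=spec.noise_floor_db)

    def make_subjects(label: str, rng: np.random.Generator,
                      rng_noise: np.random.Generator
                      ) -> list[TransmissionRecord]:
        out = []
        for i in range(n_half):
            s = mean.copy()
            for b in background:
                z = (rng.standard_normal() + 1j * rng.standard_normal()) \
                    / np.sqrt(2.0)
                s = s + spec.background_scale * z * b
            meta = {"source": "surrogate", "subject": f"{label}_{i}"}
            if label == BLEEDING:
                vol = draw_bleeding_volume_ml(rng, spec.volume_range_ml)
                v_max = spec.volume_range_ml[1]
                gain = spec.effect_amplitude * (vol / v_max) ** spec.volume_exponent
                rot = _smooth_complex(rng, *shape)
                sig = lesion + spec.lesion_rotation * rot \
                    * spec.mean_amplitude / np.linalg.norm(rot)
                s = s + gain * sig
                meta["volume_ml"] = vol
            rec = TransmissionRecord(frequencies=freqs, pairs=pairs, s=s,
                                     label=label, metadata=meta)
            out.append(add_vna_noise(rec, noise, rng_noise))
        return out

    healthy = make_subjects(HEALTHY, np.random.default_rng(s_healthy),
                            np.random.default_rng(s_noise_h))
    patients = make_subjects(BLEEDING, np.random.default_rng(s_patient),
                             np.random.default_rng(s_noise_p))
    # interleave so stratified slicing is trivial downstream
    cohort = []
    for h, p in zip(healthy, patients):
        cohort.extend([h, p])
    return cohort


def calibrate_effect(target_auc: float, n_subjects: int,
                     spec_template: CohortSpec,
                     rng: np.random.Generator,
                     repeats: int = 5, tol: float = 0.03,
                     max_iter: int = 12) -> tuple[float, float]:
    """Bisect the effect amplitude Delta to hit a target nested-CV AUC.

    Evaluates the mean nested-CV AUC over ``repeats`` independently seeded
    cohorts of ``n_subjects`` at each candidate Delta and bisects until the
    mean is within ``tol`` of ``target_auc``.  Returns ``(delta,
    achieved_auc)``.
    """
    if not (0.5 < target_auc < 1.0):
        raise ValueError("target AUC must lie in (0.5, 1)")

    eval_seeds = rng.integers(0, 2 ** 31 - 1, size=repeats)

    def mean_auc(delta: float) -> float:
        aucs = []
        for s in eval_seeds:
            spec = replace(spec_template, n_subjects=n_subjects,
                           effect_amplitude=float(delta), seed=int(s))
            X, y = stack_records(generate_cohort(spec))
            res = nested_cv(X, y, rng=np.random.default_rng(int(s) + 1))
            aucs.append(res.auc)
        return float(np.mean(aucs))

    lo, hi = 0.0, 1.0
    auc_hi = mean_auc(hi)
    doublings = 0
    while auc_hi < target_auc:
        hi *= 2.0
        doublings += 1
        if doublings > 8:
            raise RuntimeError(
                f"could not bracket target AUC {target_auc}: "
                f"AUC at delta={hi} is {auc_hi}")
        auc_hi = mean_auc(hi)
    if abs(auc_hi - target_auc) <= tol:
        return hi, auc_hi
    best = (hi, auc_hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        auc_mid = mean_auc(mid)
        if abs(auc_mid - target_auc) < abs(best[1] - target_auc):
            best = (mid, auc_mid)
        if abs(auc_mid - target_auc) <= tol:
            return mid, auc_mid
        if auc_mid < target_auc:
            lo = mid
        else:
            hi = mid
    return best
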