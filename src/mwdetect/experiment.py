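"""End-to-end study orchestration.

An :class:`ExperimentConfig` captures every knob of one learning-curve study
(cohort construction, noise floors, subset sizes, repetitions, master seed,
output paths) and round-trips losslessly through YAML.  :func:`run_study`
executes the study — one learning curve per noise floor — and writes CSV
tables, a JSON summary, figures, and a provenance manifest (config hash,
derived seeds, package versions, per-stage timings) so every artifact is
traceable.

One master seed is split with ``numpy.random.SeedSequence`` into per-stage
streams (cohort generation per noise floor, CV fold shuffling per noise
floor), so the stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .evaluation import LearningCurveResult, learning_curve, stack_records
from .records import TransmissionRecord, save_records
from .surrogate import CohortSpec, generate_cohort

__all__ = [
    "ExperimentConfig",
    "StudyResult",
    "run_study",
    "generate_fdtd_cohort",
    "plot_learning_curves",
    "plot_decision_scatter",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentConfig:
    """All parameters of one learning-curve study.

    ``source`` selects the data generator: ``"surrogate"`` (statistical
    cohort, desk scale) or ``"fdtd"`` (full-wave forward runs; hours per
    subject — intended for cluster-scale campaigns or tiny smoke runs).
    ``cohort`` holds :class:`~mwdetect.surrogate.CohortSpec` field overrides
    (``seed`` and ``noise_floor_db`` are managed by the runner and may not
    appear there); ``fdtd`` holds forward-model overrides (``dx``,
    ``n_subjects``).
    """

    name: str = "study"
    source: str = "surrogate"
    cohort: dict = field(default_factory=dict)
    fdtd: dict = field(default_factory=dict)
    noise_floors_db: tuple[float, ...] = (-100.0, -70.0)
    subset_sizes: tuple[int, ...] = (30, 40, 50, 60, 100, 200, 300, 500,
                                     750, 1000)
    repeats: int = 10
    seed: int = 0
    output_dir: str = "study_out"
    overwrite: bool = False

    def __post_init__(self) -> None:
        if self.source not in ("surrogate", "fdtd"):
            raise ValueError(f"unknown source {self.source!r}")
        reserved = {"seed", "noise_floor_db"} & set(self.cohort)
        if reserved:
            raise ValueError(f"cohort overrides may not set {sorted(reserved)}"
                             " (managed by the runner)")

    # -- lossless YAML round-trip -------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["noise_floors_db"] = list(self.noise_floors_db)
        d["subset_sizes"] = list(self.subset_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        d = dict(d)
        for key in ("noise_floors_db", "subset_sizes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class StudyResult:
    """Learning curves keyed by noise floor, plus the written manifest."""

    config: ExperimentConfig
    curves: dict[float, LearningCurveResult]
    manifest: dict
    output_dir: Path


def _derived_seed(ss: np.random.SeedSequence) -> int:
    """A loggable 31-bit integer seed derived from a SeedSequence."""
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def generate_fdtd_cohort(config: ExperimentConfig, nf_db: float,
                         seed: int) -> list[TransmissionRecord]:
    """Full-wave cohort: randomized subjects through the FDTD forward model.

    Every subject is a randomized head (rescale + optional lesion + hair)
    simulated with :func:`~mwdetect.fdtd.run_forward` and degraded with VNA
    noise.  At 1 mm resolution and 16 antennas this is a cluster-scale
    campaign; use small ``n_subjects`` and coarse ``dx`` for smoke runs.
    """
    from .fdtd import build_layout, run_forward
    from .noise import NoiseSpec, add_vna_noise
    from .phantom import make_reference_phantom, randomize_subject
    from .records import BLEEDING, HEALTHY

    opts = dict(config.fdtd)
    n_subjects = int(opts.pop("n_subjects", 2))
    dx = float(opts.pop("dx", 0.005))
    if n_subjects % 2 != 0:
        raise ValueError("n_subjects must be even")
    rng = np.random.default_rng(seed)
    reference = make_reference_phantom()
    layout = build_layout()
    noise = NoiseSpec(nf_db=nf_db)
    records = []
    for i in range(n_subjects):
        bleeding = i % 2 == 1
        subject, spec = randomize_subject(reference, rng, bleeding=bleeding)
        t0 = time.perf_counter()
        rec = run_forward(subject, layout, dx=dx,
                          label=BLEEDING if bleeding else HEALTHY, **opts)
        logger.info("fdtd subject %d/%d (%s) in %.1f s", i + 1, n_subjects,
                    rec.label, time.perf_counter() - t0)
        rec.metadata["subject"] = i
        if spec is not None:
            rec.metadata["volume_ml"] = spec.volume_ml
        records.append(add_vna_noise(rec, noise, rng))
    return records


def run_study(config: ExperimentConfig) -> StudyResult:
    """Run the full learning-curve study described by ``config``.

    For each noise floor: generate (or simulate) the cohort, run
    :func:`~mwdetect.evaluation.learning_curve` over the configured subset
    sizes and repetitions, and write per-repeat CSV, summary CSV/JSON,
    figures, and a provenance manifest into ``config.output_dir``.
    Reruns with the same config and seed are byte-identical; a non-empty
    output directory is refused unless ``config.overwrite`` is set.
    """
    out = Path(config.output_dir)
    if out.exists() and any(out.iterdir()) and not config.overwrite:
        raise FileExistsError(
            f"output directory {out} is not empty; set overwrite=true "
            "to replace prior results")
    out.mkdir(parents=True, exist_ok=True)

    master = np.random.SeedSequence(config.seed)
    stage_seeds = {}
    curves: dict[float, LearningCurveResult] = {}
    timings: dict[str, float] = {}
    rows_written = []

    for nf, (ss_cohort, ss_folds) in zip(
            config.noise_floors_db,
            zip(master.spawn(len(config.noise_floors_db)),
                master.spawn(len(config.noise_floors_db)))):
        cohort_seed = _derived_seed(ss_cohort)
        folds_seed = _derived_seed(ss_folds)
        stage_seeds[f"cohort_nf{nf:g}"] = cohort_seed
        stage_seeds[f"folds_nf{nf:g}"] = folds_seed

        t0 = time.perf_counter()
        if config.source == "surrogate":
            spec = CohortSpec(noise_floor_db=nf, seed=cohort_seed,
                              **config.cohort)
            records = generate_cohort(spec)
        else:
            records = generate_fdtd_cohort(config, nf, cohort_seed)
        timings[f"cohort_nf{nf:g}_s"] = time.perf_counter() - t0
        logger.info("cohort at nf=%g dB: %d subjects in %.1f s", nf,
                    len(records), timings[f"cohort_nf{nf:g}_s"])
        save_records(out / f"cohort_nf{nf:g}.h5", records)

        X, y = stack_records(records)
        t0 = time.perf_counter()
        curve = learning_curve(X, y, sizes=config.subset_sizes,
                               repeats=config.repeats,
                               rng=np.random.default_rng(folds_seed))
        timings[f"learning_curve_nf{nf:g}_s"] = time.perf_counter() - t0
        logger.info("learning curve at nf=%g dB in %.1f s", nf,
                    timings[f"learning_curve_nf{nf:g}_s"])
        curves[nf] = curve

        df = curve.to_dataframe()
        df.insert(0, "noise_floor_db", nf)
        csv_path = out / f"learning_curve_nf{nf:g}.csv"
        df.to_csv(csv_path, index=False)
        rows_written.append(csv_path.name)
        summary_path = out / f"summary_nf{nf:g}.csv"
        curve.summary().to_csv(summary_path, index=False)
        rows_written.append(summary_path.name)

    summary_json = {
        f"{nf:g}": {str(n): {"mean_auc": c.mean[n], "sd_auc": c.sd[n]}
                    for n in c.sizes}
        for nf, c in curves.items()
    }
    (out / "summary.json").write_text(json.dumps(summary_json, indent=2))
    config.to_yaml(out / "config.yaml")

    fig_names = _write_figures(out, config, curves)

    import matplotlib
    import pandas
    import scipy
    manifest = {
        "name": config.name,
        "config_hash": config.content_hash(),
        "master_seed": config.seed,
        "stage_seeds": stage_seeds,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "matplotlib": matplotlib.__version__,
        },
        "outputs": sorted(rows_written + fig_names
                          + ["config.yaml", "summary.json"]
                          + [f"cohort_nf{nf:g}.h5"
                             for nf in config.noise_floors_db]),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return StudyResult(config=config, curves=curves, manifest=manifest,
                       output_dir=out)


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

def plot_learning_curves(curves: dict[float, LearningCurveResult], ax=None):
    """Mean AUC vs subset size with error bars, one line per noise floor."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for nf, curve in sorted(curves.items()):
        sizes = curve.sizes
        ax.errorbar(sizes, [curve.mean[n] for n in sizes],
                    yerr=[curve.sd[n] for n in sizes],
                    marker="o", capsize=3, label=f"noise floor {nf:g} dB")
    ax.axhline(0.5, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("subset size (subjects)")
    ax.set_ylabel("AUC (mean ± sd over repetitions)")
    ax.set_xscale("log")
    ax.legend()
    return ax


def plot_decision_scatter(decisions: np.ndarray, labels: np.ndarray,
                          ax=None, clip: float | None = None):
    """Per-subject decision values by class (negative favors bleeding)."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    decisions = np.asarray(decisions, dtype=float)
    labels = np.asarray(labels).astype(int)
    if clip is not None:
        decisions = np.clip(decisions, -clip, clip)
    for cls, name, color in ((0, "healthy", "tab:blue"),
                             (1, "bleeding", "tab:red")):
        idx = np.flatnonzero(labels == cls)
        ax.scatter(idx, decisions[idx], s=10, label=name, color=color)
    ax.axhline(0.0, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("subject index")
    ax.set_ylabel("decision value")
    ax.legend()
    return ax


def _write_figures(out: Path, config: ExperimentConfig,
                   curves: dict[float, LearningCurveResult]) -> list[str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = []
    ax = plot_learning_curves(curves)
    ax.set_title(config.name)
    ax.figure.savefig(out / "auc_vs_size.png", dpi=150,
                      bbox_inches="tight")
    plt.close(ax.figure)
    names.append("auc_vs_size.png")
    return names
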