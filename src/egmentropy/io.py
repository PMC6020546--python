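"""Plain-text I/O: signal files, study configuration, report dumps.

The signal format is deliberately minimal — a handful of ``# key: value``
header lines followed by one sample per line at full precision — because
the intended users carry their own recordings in ad-hoc text exports.
Round-trips preserve samples bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .entropy import EntropyParams
from .perturb import LOSS_GRID, SPIKE_GRID
from .robustness import RobustnessReport
from .signal import Signal
from .synthesis import (
    C_BASELINE_TARGET,
    C_PARAMS,
    NC_BASELINE_TARGET,
    NC_PARAMS,
    ClassParams,
    CohortSpec,
)

__all__ = [
    "SignalFormatError",
    "read_signal",
    "write_signal",
    "StudyConfig",
    "write_report",
    "read_report_frame",
]


class SignalFormatError(ValueError):
    """Malformed signal file; message carries the offending line number."""


def write_signal(path: str | Path, x: Signal) -> None:
    """Write a signal as ``# id / # fs_hz / # label`` headers plus samples."""
    path = Path(path)
    lines = [f"# id: {x.id}", f"# fs_hz: {x.fs:.17g}"]
    if x.label is not None:
        lines.append(f"# label: {x.label}")
    lines.extend(f"{v:.17g}" for v in x.samples)
    path.write_text("\n".join(lines) + "\n")


def read_signal(path: str | Path) -> Signal:
    """Parse a signal file written by :func:`write_signal`.

    A missing label header yields ``label=None``; a missing sampling rate,
    an unknown header, or a non-numeric sample line is a
    :class:`SignalFormatError` naming the line.
    """
    path = Path(path)
    headers: dict[str, str] = {}
    samples: list[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if samples:
                raise SignalFormatError(
                    f"{path}:{lineno}: header line after sample data"
                )
            body = line.lstrip("#").strip()
            if ":" not in body:
                raise SignalFormatError(f"{path}:{lineno}: malformed header {raw!r}")
            key, _, value = body.partition(":")
            key = key.strip()
            if key not in ("id", "fs_hz", "label"):
                raise SignalFormatError(f"{path}:{lineno}: unknown header {key!r}")
            headers[key] = value.strip()
        else:
            try:
                samples.append(float(line))
            except ValueError:
                raise SignalFormatError(
                    f"{path}:{lineno}: non-numeric sample {raw!r}"
                ) from None
    if "fs_hz" not in headers:
        raise SignalFormatError(f"{path}: missing required 'fs_hz' header")
    try:
        fs = float(headers["fs_hz"])
    except ValueError:
        raise SignalFormatError(f"{path}: non-numeric fs_hz header") from None
    if not samples:
        raise SignalFormatError(f"{path}: no samples")
    return Signal(
        np.array(samples),
        fs=fs,
        label=headers.get("label"),
        id=headers.get("id", path.stem),
    )


@dataclass(frozen=True)
class StudyConfig:
    """Every knob of the study, defaulting to the reference settings:
    SampEn(m=2, r=0.2 x SD), the 64/49 cohort of 1500-sample signals at
    1 kHz, the standard perturbation grids, 50 realisations per signal,
    and significance level 0.01."""

    cohort: CohortSpec = CohortSpec()
    entropy: EntropyParams = EntropyParams()
    spike_grid: tuple[float, ...] = SPIKE_GRID
    loss_grid: tuple[float, ...] = LOSS_GRID
    n_realisations: int = 50
    alpha: float = 0.01
    calibration_targets: dict = field(
        default_factory=lambda: {"NC": NC_BASELINE_TARGET, "C": C_BASELINE_TARGET}
    )
    calibration_tolerances: dict = field(
        default_factory=lambda: {"NC": 0.01, "C": 0.02}
    )
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_realisations < 1:
            raise ValueError("n_realisations must be >= 1")
        for grid in (self.spike_grid, self.loss_grid):
            if any(not 0 < g <= 1 for g in grid):
                raise ValueError("grid levels must lie in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "cohort": {
                **{
                    k: v
                    for k, v in dataclasses.asdict(self.cohort).items()
                    if k not in ("nc_params", "c_params")
                },
                "nc_params": dataclasses.asdict(self.cohort.nc_params),
                "c_params": dataclasses.asdict(self.cohort.c_params),
            },
            "entropy": dataclasses.asdict(self.entropy),
            "spike_grid": list(self.spike_grid),
            "loss_grid": list(self.loss_grid),
            "n_realisations": self.n_realisations,
            "alpha": self.alpha,
            "calibration_targets": dict(self.calibration_targets),
            "calibration_tolerances": dict(self.calibration_tolerances),
            "master_seed": self.master_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        if cohort:
            nc = cohort.pop("nc_params", None)
            c = cohort.pop("c_params", None)
            cohort = CohortSpec(
                **cohort,
                nc_params=ClassParams(**nc) if nc else NC_PARAMS,
                c_params=ClassParams(**c) if c else C_PARAMS,
            )
        else:
            cohort = CohortSpec()
        entropy = d.pop("entropy", {})
        entropy = EntropyParams(**entropy) if entropy else EntropyParams()
        for key in ("spike_grid", "loss_grid"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(cohort=cohort, entropy=entropy, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def digest(self) -> str:
        """Stable hash of the configuration, embedded in output provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _provenance(config: StudyConfig) -> dict:
    return {
        "version": __version__,
        "config_hash": config.digest(),
        "master_seed": config.master_seed,
    }


def write_report(report: RobustnessReport, out_dir: str | Path, config: StudyConfig) -> None:
    """Serialise a sweep report: long CSV, wide study-style table, JSON dump,
    and per-level ROC curve tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = report.to_frame()
    for key, value in _provenance(config).items():
        frame[key] = value
    frame.to_csv(out / f"{report.kind}_summary.csv", index=False)
    report.to_wide_table().to_csv(out / f"{report.kind}_table.csv")
    dump = {
        "kind": report.kind,
        "provenance": {**report.provenance, **_provenance(config)},
        "signal_ids": report.signal_ids,
        "labels": report.labels,
        "levels": [
            {
                "level": ls.level,
                "p_value": ls.p_value,
                "rho_xy": ls.rho_xy,
                "robust": ls.robust,
                "n_undefined": ls.n_undefined,
                "per_signal": [
                    None if np.isnan(v) else v for v in report.per_signal[ls.level]
                ],
                "stats": {
                    lab: {
                        "n": cs.n,
                        "mean": cs.mean,
                        "sd": cs.sd,
                        "interval": list(cs.interval),
                    }
                    for lab, cs in ls.stats.items()
                },
            }
            for ls in report.levels
        ],
        "linear_fit": (
            {
                lab: dataclasses.asdict(fit)
                for lab, fit in report.linear_fit.items()
            }
            if report.linear_fit
            else None
        ),
        "roc_auc": (
            {f"{lvl:g}": r.auc for lvl, r in report.roc.items()}
            if report.roc
            else None
        ),
    }
    (out / f"{report.kind}_report.json").write_text(json.dumps(dump, indent=1))
    if report.roc:
        import pandas as pd

        for lvl, r in report.roc.items():
            pd.DataFrame(
                {"threshold": r.thresholds, "fpr": r.fpr, "tpr": r.tpr}
            ).to_csv(out / f"{report.kind}_roc_{lvl:g}.csv", index=False)


def read_report_frame(path: str | Path):
    """Load a saved ``*_report.json`` back into a long-format DataFrame."""
    import pandas as pd

    dump = json.loads(Path(path).read_text())
    rows = []
    for ls in dump["levels"]:
        for lab, cs in ls["stats"].items():
            rows.append(
                {
                    "level": ls["level"],
                    "class": lab,
                    "n": cs["n"],
                    "mean": cs["mean"],
                    "sd": cs["sd"],
                    "ci_lo": cs["interval"][0],
                    "ci_hi": cs["interval"][1],
                    "p_value": ls["p_value"],
                    "rho_xy": ls["rho_xy"],
                    "robust": ls["robust"],
                    "n_undefined": ls["n_undefined"],
                }
            )
    return pd.DataFrame(rows)
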