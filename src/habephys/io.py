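"""Formats, run configuration and end-to-end pipeline orchestration.

Traces are stored as a CSV (``time_s,v_mV,i_pA``) plus a JSON sidecar
carrying the sampling rate and metadata.  Floats are written with 17
significant digits, which round-trips IEEE doubles bit-exactly.  The
pipeline composes simulate -> features -> classify -> stats into a
deterministic report bundle with a provenance log.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (CohortConfig, StepProtocol, VoltageTrace, make_cohort,
                    simulate_cell)
from .features import (detect_spikes, frequency_adaptation_index,
                       measure_rdp_duration, FeatureUndefined)
from .classify import Thresholds, assign_subtype
from .stats import chi_squared_with_residuals

log = logging.getLogger("habephys")

_FLOAT_FMT = "%.17g"  # exact decimal round trip for IEEE doubles


class TraceFormatError(ValueError):
    """Malformed trace file (bad header, non-uniform time base, ...)."""


# ---------------------------------------------------------------------------
# trace round trip
# ---------------------------------------------------------------------------

def write_trace(trace: VoltageTrace, path) -> Path:
    """Write ``<path>.csv`` + ``<path>.json`` (sidecar); returns the CSV
    path.  ``path`` may or may not carry the ``.csv`` suffix."""
    csv_path = Path(path)
    if csv_path.suffix != ".csv":
        csv_path = csv_path.with_suffix(".csv")
    sidecar = csv_path.with_suffix(".json")
    t = np.arange(trace.v_mV.size) / trace.fs
    df = pd.DataFrame({"time_s": t, "v_mV": trace.v_mV, "i_pA": trace.i_pA})
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    meta = {"fs": trace.fs, "n_samples": int(trace.v_mV.size),
            "meta": _jsonable(trace.meta)}
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return csv_path


def read_trace(path) -> VoltageTrace:
    """Read a trace written by :func:`write_trace`.

    Raises :class:`TraceFormatError` when the sidecar is missing, the
    header is wrong, or the time column deviates from a uniform grid by
    more than 1e-9 s (the offending CSV line number is reported).
    """
    csv_path = Path(path)
    if csv_path.suffix != ".csv":
        csv_path = csv_path.with_suffix(".csv")
    sidecar = csv_path.with_suffix(".json")
    if not csv_path.exists():
        raise FileNotFoundError(csv_path)
    if not sidecar.exists():
        raise TraceFormatError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(csv_path, float_precision="round_trip")
    if list(df.columns) != ["time_s", "v_mV", "i_pA"]:
        raise TraceFormatError(
            f"{csv_path}: header must be time_s,v_mV,i_pA "
            f"(got {list(df.columns)})")
    fs = float(meta["fs"])
    t = df["time_s"].to_numpy()
    expected = np.arange(t.size) / fs
    bad = np.flatnonzero(np.abs(t - expected) > 1e-9)
    if bad.size:
        # +2: one for the header line, one for 1-based numbering
        line = int(bad[0]) + 2
        raise TraceFormatError(
            f"{csv_path}: non-uniform time column at line {line} "
            f"(expected {expected[bad[0]]!r}, got {t[bad[0]]!r})")
    if int(meta.get("n_samples", t.size)) != t.size:
        raise TraceFormatError(
            f"{csv_path}: sidecar declares {meta['n_samples']} samples, "
            f"file has {t.size}")
    return VoltageTrace(fs=fs, v_mV=df["v_mV"].to_numpy(),
                        i_pA=df["i_pA"].to_numpy(),
                        meta=dict(meta.get("meta", {})))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class GroupSpec:
    """One synthetic cohort in a pipeline run."""

    group: str
    n_cells: int
    p_long: float
    p_hf: float = 0.6
    jitter_sd: float = 0.08


@dataclass
class RunConfig:
    """Everything a pipeline run needs; round-trips losslessly to JSON."""

    groups: list = field(default_factory=list)   # list[GroupSpec]
    seed: int = 0
    out_dir: str = "pipeline_out"
    log_level: str = "INFO"
    # threshold overrides; None -> derive nothing, use published defaults
    theta_rdp_ms: float = 400.0
    theta_fai: float = 0.8
    # protocols
    hyper_amp_pA: float = -100.0
    hyper_t_total_s: float = 10.0
    depol_amp_pA: float = 100.0

    def __post_init__(self) -> None:
        self.groups = [g if isinstance(g, GroupSpec) else GroupSpec(**g)
                       for g in self.groups]

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cell."""


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def _hyper_protocol(cfg: RunConfig) -> StepProtocol:
    return StepProtocol(amp_pA=cfg.hyper_amp_pA,
                        t_total=cfg.hyper_t_total_s)


def _depol_protocol(cfg: RunConfig) -> StepProtocol:
    return StepProtocol(amp_pA=cfg.depol_amp_pA, t_total=2.5)


def extract_cohort_features(cells, cfg: RunConfig) -> pd.DataFrame:
    """Simulate the standard protocol pair per cell and measure
    (rdp_ms, fai).  ``cells`` is the output of :func:`make_cohort`."""
    pr_h = _hyper_protocol(cfg)
    pr_d = _depol_protocol(cfg)
    rows = []
    for cell in cells:
        try:
            tr_h = simulate_cell(cell.params, pr_h, cell_id=cell.cell_id,
                                 seed=cell.params.seed)
            tr_d = simulate_cell(cell.params, pr_d, cell_id=cell.cell_id,
                                 seed=cell.params.seed)
            m = measure_rdp_duration(tr_h, pr_h)
            try:
                fai, _, _ = frequency_adaptation_index(
                    detect_spikes(tr_d), pr_d)
            except FeatureUndefined:
                fai = float("nan")
        except Exception as e:  # noqa: BLE001 - report stage + cell id
            raise PipelineError(
                f"stage 'features' failed for cell {cell.cell_id}: {e}"
            ) from e
        rows.append({
            "cell_id": cell.cell_id, "group": cell.group,
            "rdp_ms": m.duration_ms, "rdp_censored": m.censored,
            "fai": fai,
            "true_long": cell.is_long, "true_hf": cell.is_hf,
        })
    return pd.DataFrame(rows)


def label_features(features: pd.DataFrame,
                   thresholds: Thresholds) -> pd.DataFrame:
    rows = []
    for _, r in features.iterrows():
        try:
            fai = r["fai"] if np.isfinite(r["fai"]) else None
            lab = assign_subtype(r["rdp_ms"], fai, thresholds)
        except Exception as e:  # noqa: BLE001
            raise PipelineError(
                f"stage 'classify' failed for cell {r['cell_id']}: {e}"
            ) from e
        rows.append({"cell_id": r["cell_id"], "group": r["group"],
                     "rdp_class": lab.rdp_class,
                     "firing_class": lab.firing_class or "",
                     "combined": lab.combined or ""})
    return pd.DataFrame(rows)


def group_rdp_stats(labels: pd.DataFrame) -> dict:
    """Chi-squared group x (short/long) comparison with residual marks."""
    groups = sorted(labels["group"].unique())
    if len(groups) < 2:
        raise PipelineError(
            "stage 'stats' failed: need >= 2 groups for comparison")
    table = [[int(((labels["group"] == g)
                   & (labels["rdp_class"] == c)).sum())
              for c in ("short", "long")] for g in groups]
    if any(sum(col) == 0 for col in zip(*table)):
        # degenerate table (a class absent from every group, e.g. tiny
        # cohorts): report the counts without a test
        return {"groups": groups, "classes": ["short", "long"],
                "table": table, "chi2": None, "dof": None, "p": None,
                "residuals": None, "cell_p": None, "marks": None,
                "note": "chi-squared undefined: a class has zero total"}
    chi2, dof, p, rep = chi_squared_with_residuals(table)
    marks = {g: {"short": rep.marks[i][0], "long": rep.marks[i][1]}
             for i, g in enumerate(groups)}
    return {
        "groups": groups, "classes": ["short", "long"], "table": table,
        "chi2": chi2, "dof": dof, "p": p,
        "residuals": rep.residuals.tolist(),
        "cell_p": rep.p_values.tolist(), "marks": marks,
    }


def run_pipeline(config: RunConfig) -> dict:
    """simulate -> features -> classify -> stats; writes the report
    bundle into ``config.out_dir`` and returns a summary dict.

    Deterministic for a fixed config: rerunning produces byte-identical
    feature and label tables.
    """
    if not config.groups:
        raise ValueError("pipeline config has an empty cohort list")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level.upper())

    rng = np.random.default_rng(config.seed)
    frames = []
    for spec in config.groups:
        if spec.n_cells <= 0:
            raise ValueError(f"group {spec.group!r} has no cells")
        cohort_seed = int(rng.integers(0, 2 ** 31 - 1))
        log.info("simulating group %s (n=%d, seed=%d)",
                 spec.group, spec.n_cells, cohort_seed)
        cells = make_cohort(CohortConfig(
            group=spec.group, n_cells=spec.n_cells, p_long=spec.p_long,
            p_hf=spec.p_hf, jitter_sd=spec.jitter_sd, seed=cohort_seed))
        frames.append(extract_cohort_features(cells, config))
    features = pd.concat(frames, ignore_index=True)

    thresholds = Thresholds(theta_rdp_ms=config.theta_rdp_ms,
                            theta_fai=config.theta_fai)
    labels = label_features(features, thresholds)
    stats_report = group_rdp_stats(labels) if len(config.groups) >= 2 else {}

    features.to_csv(out / "features.csv", index=False,
                    float_format=_FLOAT_FMT)
    labels.to_csv(out / "labels.csv", index=False)
    (out / "thresholds.json").write_text(thresholds.to_json() + "\n")
    (out / "stats_report.json").write_text(
        json.dumps(stats_report, indent=2, sort_keys=True) + "\n")
    provenance = {
        "config": json.loads(config.to_json()),
        "config_hash": config.config_hash(),
        "python": sys.version.split()[0],
        "platform": platform.platform(),
        "versions": _package_versions(),
        "outputs": ["features.csv", "labels.csv", "thresholds.json",
                    "stats_report.json"],
    }
    (out / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    return {"features": features, "labels": labels,
            "thresholds": thresholds, "stats": stats_report,
            "provenance": provenance, "out_dir": str(out)}


def _package_versions() -> dict:
    import numpy
    import pandas
    import scipy
    import sklearn

    from . import __version__
    return {"habephys": __version__, "numpy": numpy.__version__,
            "scipy": scipy.__version__, "pandas": pandas.__version__,
            "scikit-learn": sklearn.__version__}


# ---------------------------------------------------------------------------
# tabular helpers
# ---------------------------------------------------------------------------

def write_features(features: pd.DataFrame, path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    features.to_csv(p, index=False, float_format=_FLOAT_FMT)
    return p


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"rdp_ms", "fai"} - set(df.columns)
    if missing:
        raise TraceFormatError(
            f"{path}: feature table missing columns {sorted(missing)}")
    return df
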