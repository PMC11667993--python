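"""End-to-end orchestration: simulate -> quantify -> features -> compare ->
classify -> report, as one reproducible run.

A run is driven by a :class:`RunConfig` (fully serialisable to YAML); every
output lands in the run directory together with ``manifest.json`` recording
the config, its digest, per-stage seeds and software versions, so a
persisted config re-executes to identical outputs.

Stage seeds are derived from the master seed with a stable hash, so changing
e.g. the CV layout never silently reshuffles the simulated cohort.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    FAMILIES,
    CVConfig,
    evaluate_features,
    rank_features,
    rank_models,
    summarize,
)
from .datatypes import (
    FEATURE_COLUMNS,
    ROISpec,
    SubtractionConfig,
    WindowConfig,
)
from .errors import ConfigurationError, FidgetQuantError
from .features import extract_features
from .group_stats import comparison_table, format_report
from .motion import quantify_session
from .synthetic import (
    HIGH_FIDGET,
    LOW_FIDGET,
    CohortClassParams,
    generate_cohort,
)
from .video_io import load_session

log = logging.getLogger("fidgetquant")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class RunConfig:
    """Everything needed to reproduce a synthetic end-to-end run."""

    n_pos: int = 43
    n_neg: int = 42
    rates: list[int] = field(default_factory=lambda: [6, 15, 30])
    clip_seconds: float = 240.0
    theta: int = 100
    window_seconds: float = 5.0
    overlap_seconds: float = 2.5
    families: list[str] = field(default_factory=lambda: list(FAMILIES))
    outer_folds: int = 10
    inner_folds: int = 5
    repeats: int = 10
    seed: int = 0
    pos_params: CohortClassParams = HIGH_FIDGET
    neg_params: CohortClassParams = LOW_FIDGET

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("pos_params", "neg_params"):
            if key in d and isinstance(d[key], dict):
                d[key] = CohortClassParams(**d[key])
        return cls(**d)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _simulate_series(cfg: RunConfig) -> pd.DataFrame:
    """Simulate per-subject movement series for every requested rate.

    Each subject keeps the same underlying fidget process across rates; only
    the effective sampling (series length and rate d - 1) changes, mirroring
    how one real video is quantified at several downsampling rates.
    """
    sim_seed = stage_seed(cfg.seed, "simulate")
    rows = []
    for rate_d in cfg.rates:
        eff = rate_d - 1
        n = int(round(cfg.clip_seconds * eff))
        from dataclasses import replace

        pos = replace(cfg.pos_params, n_samples=n, effective_rate=float(eff))
        neg = replace(cfg.neg_params, n_samples=n, effective_rate=float(eff))
        # the same master seed per rate keeps subject identities aligned
        members = generate_cohort(cfg.n_pos, cfg.n_neg, pos, neg, seed=sim_seed)
        for mem in members:
            for k, mk in enumerate(mem.data.m):
                rows.append(
                    {
                        "subject_id": mem.subject_id,
                        "label": mem.label,
                        "rate_d": rate_d,
                        "k": k,
                        "m_k": int(mk),
                    }
                )
    return pd.DataFrame(rows)


def _series_to_features(series_df: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    from .datatypes import MovementSeries

    wcfg = WindowConfig(cfg.window_seconds, cfg.overlap_seconds)
    records = []
    for (sid, label, rate_d), grp in series_df.groupby(
        ["subject_id", "label", "rate_d"], sort=True
    ):
        m = grp.sort_values("k")["m_k"].to_numpy()
        series = MovementSeries(
            m=m, effective_rate=float(rate_d - 1), roi_area=int(max(m.max(), 1))
        )
        records.append(extract_features(series, wcfg, sid, label, rate_d=int(rate_d)))
    return pd.DataFrame([r.as_dict() for r in records])


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full synthetic pipeline and write all artifacts.

    Writes: ``series.csv``, ``features.csv``, ``comparison.csv`` (+ .txt),
    ``metrics.csv`` (per-iteration), ``summary.csv`` (mean +- SEM),
    ``rank_features.csv``, ``rank_models.csv`` and ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "simulate"
    try:
        series_df = _simulate_series(cfg)
        log.info("simulate: %d subjects x %d rates", cfg.n_pos + cfg.n_neg, len(cfg.rates))
        series_df.to_csv(out / "series.csv", index=False)

        stage = "features"
        feats = _series_to_features(series_df, cfg)
        feats.to_csv(out / "features.csv", index=False)

        stage = "compare"
        comp = comparison_table(feats)
        comp.to_csv(out / "comparison.csv", index=False)
        (out / "comparison.txt").write_text(format_report(comp) + "\n")

        stage = "classify"
        cv = CVConfig(
            outer_folds=cfg.outer_folds,
            inner_folds=cfg.inner_folds,
            repeats=cfg.repeats,
            seed=stage_seed(cfg.seed, "classify"),
            positive_class="pos",
        )
        perf = evaluate_features(feats, list(FEATURE_COLUMNS), cfg.families, cv)
        perf.to_csv(out / "metrics.csv", index=False)
        summarize(perf).to_csv(out / "summary.csv", index=False)

        stage = "rank"
        rf_frames, rm_frames = [], []
        for rate_d in cfg.rates:
            sub = perf[perf["rate_d"] == rate_d]
            rf = rank_features(sub).reset_index(names="feature")
            rf.insert(0, "rate_d", rate_d)
            rf_frames.append(rf)
            rm = rank_models(sub, "se_bar").reset_index(names="model")
            rm.insert(0, "rate_d", rate_d)
            rm_frames.append(rm)
        pd.concat(rf_frames).to_csv(out / "rank_features.csv", index=False)
        pd.concat(rm_frames).to_csv(out / "rank_models.csv", index=False)

        stage = "manifest"
        manifest = {
            "config": cfg.to_dict(),
            "config_digest": cfg.digest(),
            "stage_seeds": {
                s: stage_seed(cfg.seed, s) for s in ("simulate", "classify")
            },
            "versions": _versions(),
            "elapsed_seconds": round(time.time() - t0, 2),
            "artifacts": sorted(p.name for p in out.glob("*.csv")),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except FidgetQuantError as exc:
        raise FidgetQuantError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def _versions() -> dict[str, str]:
    import sklearn
    import scipy
    import xgboost

    return {
        "fidgetquant": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "xgboost": xgboost.__version__,
    }


REQUIRED_ARTIFACTS = (
    "features.csv",
    "comparison.csv",
    "metrics.csv",
    "summary.csv",
    "manifest.json",
)


def report(run_dir: str | Path, fig_name: str = "report.png") -> Path:
    """Render the stored run results as metric bar charts with SEM whiskers.

    Reads only the stored CSVs — the report introduces no new numbers.
    Raises listing the missing artifacts if the run is incomplete.
    """
    run_dir = Path(run_dir)
    missing = [a for a in REQUIRED_ARTIFACTS if not (run_dir / a).exists()]
    if missing:
        raise ConfigurationError(
            f"incomplete run directory {run_dir}: missing {missing}"
        )
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = pd.read_csv(run_dir / "summary.csv")
    rates = sorted(summary["rate_d"].unique()) if "rate_d" in summary else [None]
    metrics = ("accuracy", "sensitivity", "specificity", "auc")
    fig, axes = plt.subplots(
        len(rates), len(metrics), figsize=(4 * len(metrics), 3 * len(rates)),
        squeeze=False,
    )
    for i, rate in enumerate(rates):
        sub = summary if rate is None else summary[summary["rate_d"] == rate]
        pivot_order = sorted(sub["feature"].unique())
        for j, metric in enumerate(metrics):
            ax = axes[i][j]
            means = sub.pivot(index="model", columns="feature", values=f"{metric}_mean")
            sems = sub.pivot(index="model", columns="feature", values=f"{metric}_sem")
            means[pivot_order].plot.bar(
                ax=ax, yerr=sems[pivot_order], legend=(i == 0 and j == 0), rot=45
            )
            ax.set_ylim(0, 1.05)
            ax.set_title(f"{metric}" + (f" (d={rate})" if rate is not None else ""))
    fig.tight_layout()
    fig_path = run_dir / fig_name
    fig.savefig(fig_path, dpi=110)
    plt.close(fig)
    return fig_path


def quantify_video(
    path: str | Path,
    roi: ROISpec,
    cfg: SubtractionConfig,
    rate: float | None = None,
) -> pd.DataFrame:
    """Load one video (file or PNG directory), quantify it, return a tidy
    series table ready for ``series.csv``."""
    seq = load_session(path, clip_seconds=cfg.clip_seconds, rate=rate)
    series = quantify_session(seq, roi, cfg)
    return pd.DataFrame(
        {
            "subject_id": Path(path).stem or str(path),
            "rate_d": cfg.downsample_rate,
            "k": np.arange(series.n),
            "m_k": series.m,
        }
    )
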