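"""Pipeline orchestration: simulate -> qc -> fit -> summarize -> compare -> report.

One structured YAML config drives the whole analysis; every stage writes CSV
products into the output directory, and a JSON run manifest records the
resolved config, seeds, per-stage timing, convergence flags, and a content
hash of every emitted file. No figure is produced whose backing numbers are
not also written as machine-readable CSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from rnfltrend import __version__
from rnfltrend.cohort import CIRRUS, SPECTRALIS, PairedCohort, read_cohort, write_cohort
from rnfltrend.qc import screen_cohort
from rnfltrend.sampler import PosteriorDraws, PriorSpec, SamplerConfig, fit_sector
from rnfltrend.summaries import (
    McNemarResult,
    SectorSummary,
    SlopeClassification,
    bayesian_mcnemar,
    classify_slopes,
    proportions,
    summaries_to_frame,
    summarize_sector,
)
from rnfltrend.synthetic import CohortDesign, generate_cohort

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Pipeline configuration violates the documented schema."""


@dataclass
class RunManifest:
    """Machine-readable record of one pipeline run."""

    version: str
    config: dict
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)   # path -> sha256
    timings: dict[str, float] = field(default_factory=dict)  # stage -> seconds
    diagnostics: dict[str, bool] = field(default_factory=dict)  # sector -> passed
    dropped: dict[str, list] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "config": self.config,
                "seed": self.seed,
                "outputs": self.outputs,
                "timings": {k: round(v, 3) for k, v in self.timings.items()},
                "diagnostics": self.diagnostics,
                "dropped": self.dropped,
            },
            indent=2,
            sort_keys=True,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


_DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "rnfltrend_out",
    "data": {
        "source": "simulate",
        "path": None,
        "n_eyes": 94,
        "sectors": ["G"],
        "round_cirrus": True,
        "round_spectralis": False,
        "outlier_rate": 0.0,
        "outlier_magnitude_um": 25.0,
    },
    "qc": {"enabled": True, "k": 4.0},
    "sampler": {"chains": 4, "warmup": 1000, "draws": 1000},
    "summaries": {"level": 0.95},
    "report": {"enabled": True},
}

_KNOWN_KEYS = {
    None: {"seed", "out_dir", "data", "qc", "sampler", "summaries", "report"},
    "data": {
        "source", "path", "n_eyes", "sectors", "round_cirrus",
        "round_spectralis", "outlier_rate", "outlier_magnitude_um",
    },
    "qc": {"enabled", "k"},
    "sampler": {"chains", "warmup", "draws", "thin", "min_visits"},
    "summaries": {"level"},
    "report": {"enabled"},
}


def load_config(source) -> dict:
    """Load and validate a pipeline config (path, YAML string, or dict)."""
    if isinstance(source, dict):
        user = source
    else:
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        user = yaml.safe_load(text) or {}
    if not isinstance(user, dict):
        raise ConfigError("config must be a mapping")
    cfg = json.loads(json.dumps(_DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if key not in _KNOWN_KEYS[None]:
            raise ConfigError(f"unknown config key: {key!r}")
        if isinstance(val, dict):
            for sub in val:
                if sub not in _KNOWN_KEYS.get(key, set()):
                    raise ConfigError(f"unknown config key: {key}.{sub}")
            cfg[key].update(val)
        else:
            cfg[key] = val
    if cfg["data"]["source"] not in ("simulate", "file"):
        raise ConfigError("data.source must be 'simulate' or 'file'")
    if cfg["data"]["source"] == "file" and not cfg["data"]["path"]:
        raise ConfigError("data.path is required when data.source is 'file'")
    return cfg


def render_report(
    summaries: list[SectorSummary],
    mcnemar_results: list[McNemarResult],
    proportions_frame: pd.DataFrame,
    out_dir: Path,
) -> list[Path]:
    """Emit bar charts plus the CSVs that back every plotted number.

    Charts: population rates of change and average residual SDs per sector per
    device (asterisks mark sectors whose device difference/ratio CrI excludes
    the null), and percentages of eyes with significant negative slopes with
    counts annotated.
    """
    if not summaries:
        raise ValueError("no summaries to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    summary_frame = summaries_to_frame(summaries)
    chart_csv = out_dir / "chart_sector_summaries.csv"
    summary_frame.to_csv(chart_csv, index=False)
    written.append(chart_csv)

    sectors = [s.sector for s in summaries]
    x = np.arange(len(sectors))
    w = 0.38

    def _bars(title, ylabel, means, errs, flags, fname):
        fig, ax = plt.subplots(figsize=(max(6, 0.8 * len(sectors) + 2), 4))
        for j, (dev, color) in enumerate(
            ((SPECTRALIS, "#1f77b4"), (CIRRUS, "#d62728"))
        ):
            ax.bar(
                x + (j - 0.5) * w, means[dev], width=w, label=dev,
                color=color, yerr=errs[dev], capsize=2,
            )
        for i, flag in enumerate(flags):
            if flag:
                top = max(
                    means[SPECTRALIS][i] + errs[SPECTRALIS][1][i],
                    means[CIRRUS][i] + errs[CIRRUS][1][i],
                    0,
                )
                ax.annotate("*", (x[i], top), ha="center", fontsize=14)
        ax.set_xticks(x)
        ax.set_xticklabels(sectors)
        ax.set_xlabel("sector")
        ax.set_ylabel(ylabel)
        ax.set_title(title)
        ax.axhline(0, color="k", lw=0.5)
        ax.legend()
        fig.tight_layout()
        path = out_dir / fname
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    roc_means = {
        dev: [s.slope[dev]["mean"] for s in summaries] for dev in (SPECTRALIS, CIRRUS)
    }
    roc_errs = {
        dev: (
            [s.slope[dev]["mean"] - s.slope[dev]["lower"] for s in summaries],
            [s.slope[dev]["upper"] - s.slope[dev]["mean"] for s in summaries],
        )
        for dev in (SPECTRALIS, CIRRUS)
    }
    _bars(
        "Population RNFL rates of change",
        "rate of change (um/year)",
        roc_means,
        roc_errs,
        [s.verdicts["diff_slope"] != "null" for s in summaries],
        "chart_rates_of_change.png",
    )

    sd_means = {
        dev: [s.resid_sd[dev]["mean"] for s in summaries] for dev in (SPECTRALIS, CIRRUS)
    }
    sd_errs = {
        dev: (
            [s.resid_sd[dev]["mean"] - s.resid_sd[dev]["lower"] for s in summaries],
            [s.resid_sd[dev]["upper"] - s.resid_sd[dev]["mean"] for s in summaries],
        )
        for dev in (SPECTRALIS, CIRRUS)
    }
    _bars(
        "Average residual SD of RNFL measurements",
        "residual SD (um)",
        sd_means,
        sd_errs,
        [s.verdicts["ratio_resid_sd"] != "null" for s in summaries],
        "chart_residual_sd.png",
    )

    if not proportions_frame.empty:
        prop_csv = out_dir / "chart_proportions.csv"
        proportions_frame.to_csv(prop_csv, index=False)
        written.append(prop_csv)
        neg = proportions_frame[proportions_frame["direction"] == "negative"]
        fig, ax = plt.subplots(figsize=(max(6, 0.8 * len(sectors) + 2), 4))
        for j, (dev, color) in enumerate(
            ((SPECTRALIS, "#1f77b4"), (CIRRUS, "#d62728"))
        ):
            sub = neg[neg["device"] == dev].set_index("sector")
            vals = [100.0 * sub.loc[s, "proportion"] if s in sub.index else 0.0
                    for s in sectors]
            counts = [int(sub.loc[s, "count"]) if s in sub.index else 0
                      for s in sectors]
            bars = ax.bar(x + (j - 0.5) * w, vals, width=w, label=dev, color=color)
            for rect, cnt in zip(bars, counts):
                ax.annotate(
                    str(cnt), (rect.get_x() + rect.get_width() / 2, rect.get_height()),
                    ha="center", va="bottom", fontsize=8,
                )
        ax.set_xticks(x)
        ax.set_xticklabels(sectors)
        ax.set_xlabel("sector")
        ax.set_ylabel("% eyes with significant negative slope")
        ax.set_title("Detection of significant negative rates of change")
        ax.legend()
        fig.tight_layout()
        path = out_dir / "chart_negative_proportions.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    if mcnemar_results:
        mc_csv = out_dir / "chart_mcnemar.csv"
        pd.DataFrame([m.to_row() for m in mcnemar_results]).to_csv(mc_csv, index=False)
        written.append(mc_csv)
    return written


def run_pipeline(config, out_dir: str | Path | None = None) -> RunManifest:
    """Execute the full analysis per the config; fail fast, hash all outputs."""
    cfg = load_config(config)
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = RunManifest(version=__version__, config=cfg, seed=seed)

    def _stage(name):
        logger.info("stage: %s", name)
        return time.perf_counter()

    def _done(name, t0):
        manifest.timings[name] = time.perf_counter() - t0

    # --- data ---------------------------------------------------------------
    t0 = _stage("data")
    d = cfg["data"]
    if d["source"] == "simulate":
        design = CohortDesign(
            n_eyes=int(d["n_eyes"]),
            sectors=tuple(str(s) for s in d["sectors"]),
            round_cirrus=bool(d["round_cirrus"]),
            round_spectralis=bool(d["round_spectralis"]),
            outlier_rate=float(d["outlier_rate"]),
            outlier_magnitude_um=float(d["outlier_magnitude_um"]),
        )
        cohort, truth = generate_cohort(design, seed=seed)
        truth.effects.to_csv(out / "truth_effects.csv", index=False)
        truth.outliers.to_csv(out / "truth_outliers.csv", index=False)
    else:
        cohort = read_cohort(d["path"])
    write_cohort(cohort, out / "cohort.csv")
    _done("data", t0)

    # --- qc -----------------------------------------------------------------
    t0 = _stage("qc")
    if cfg["qc"]["enabled"]:
        cohort, qc_report = screen_cohort(cohort, k=float(cfg["qc"]["k"]))
        qc_report.to_frame().to_csv(out / "qc_flags.csv", index=False)
        manifest.dropped["qc_removed_pairs"] = sorted(qc_report.removed_pairs)
        logger.info(
            "qc: removed %d pairs (%d S-only, %d C-only, %d both)",
            qc_report.n_removed, qc_report.n_spectralis_only,
            qc_report.n_cirrus_only, qc_report.n_both,
        )
    write_cohort(cohort, out / "cohort_clean.csv")
    _done("qc", t0)

    # --- fit ----------------------------------------------------------------
    t0 = _stage("fit")
    sectors = [str(s) for s in cfg["data"]["sectors"]]
    scfg = SamplerConfig(
        seed=seed,
        chains=int(cfg["sampler"]["chains"]),
        warmup=int(cfg["sampler"]["warmup"]),
        draws=int(cfg["sampler"]["draws"]),
        thin=int(cfg["sampler"].get("thin", 1)),
        min_visits=int(cfg["sampler"].get("min_visits", 2)),
    )
    fits: dict[str, PosteriorDraws] = {}
    for sector in sectors:
        fits[sector] = fit_sector(cohort, sector, priors=PriorSpec(), cfg=scfg)
        fits[sector].to_long_frame().to_csv(out / f"draws_{sector}.csv", index=False)
        manifest.diagnostics[sector] = bool(fits[sector].diagnostics.passed)
    _done("fit", t0)

    # --- summarize ----------------------------------------------------------
    t0 = _stage("summarize")
    level = float(cfg["summaries"]["level"])
    summaries = [
        summarize_sector(fits[s], level=level, allow_failed_diagnostics=True)
        for s in sectors
    ]
    summaries_to_frame(summaries).to_csv(out / "summary_table.csv", index=False)
    _done("summarize", t0)

    # --- compare ------------------------------------------------------------
    t0 = _stage("compare")
    classifications: list[SlopeClassification] = []
    prop_frames = []
    mcnemar_results: list[McNemarResult] = []
    for s in sectors:
        cl = classify_slopes(fits[s], level=level)
        classifications.append(cl)
        prop_frames.append(proportions(cl))
        for direction in ("negative", "positive"):
            mcnemar_results.append(bayesian_mcnemar(cl, direction=direction))
    pd.concat([c.to_frame() for c in classifications]).to_csv(
        out / "classification.csv", index=False
    )
    prop_frame = pd.concat(prop_frames, ignore_index=True)
    prop_frame.to_csv(out / "proportions.csv", index=False)
    pd.DataFrame([m.to_row() for m in mcnemar_results]).to_csv(
        out / "mcnemar.csv", index=False
    )
    _done("compare", t0)

    # --- report -------------------------------------------------------------
    if cfg["report"]["enabled"]:
        t0 = _stage("report")
        render_report(summaries, mcnemar_results, prop_frame, out)
        _done("report", t0)

    for path in sorted(out.glob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest.outputs[path.name] = _sha256(path)
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
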