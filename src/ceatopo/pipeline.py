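"""Configuration and the end-to-end pipeline runner.

The pipeline stages mirror the analysis workflow: ``simulate`` builds a
synthetic trace cohort and tracing cohort, ``preprocess`` normalizes
traces, ``classify`` calls stimulus responses, ``fit`` runs the
linear/sigmoid model comparison with bootstrap, ``topo`` runs the
tracing-topography statistics, and ``report`` writes a machine-readable
JSON summary.  Every stochastic stage is seeded from the config, so a
fixed config reproduces the summary bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import classify as _classify
from . import fits as _fits
from . import synthetic as _synth
from . import topography as _topo
from . import traces as _traces
from .io import write_table, write_trace_bundle

log = logging.getLogger("ceatopo")

STAGES = ("simulate", "preprocess", "classify", "fit", "topo", "report")

#: peristimulus window defaults in seconds: 10 s before/after CS and US,
#: 5 s before/after freezing bouts
DEFAULT_WINDOWS = {"cs": 10.0, "us": 10.0, "freezing": 5.0}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (YAML-loadable)."""

    stages: list[str] = field(default_factory=lambda: list(STAGES))
    out_dir: str = "ceatopo_out"
    seed: int = 0
    alpha: float = 0.05
    auc_factor: float = 2.0
    n_boot: int = 10_000
    n_shuffle: int = 1000
    windows: dict = field(default_factory=lambda: dict(DEFAULT_WINDOWS))
    # synthetic cohort sizes
    n_neurons: int = 200
    duration: float = 240.0
    noise_sd: float = 0.1
    n_subjects: int = 12

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s) {unknown}; expected subset of {STAGES}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.auc_factor <= 0:
            raise ValueError("auc_factor must be positive")
        if self.n_boot < 1 or self.n_shuffle < 1:
            raise ValueError("n_boot and n_shuffle must be >= 1")
        for k, v in self.windows.items():
            if v <= 0:
                raise ValueError(f"window {k!r} must be positive, got {v}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {f_.name for f_ in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config key(s): {sorted(bad)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the selected stages; returns (and writes) the summary dict."""
    config.validate()
    if not config.stages:
        warnings.warn("no stages selected; nothing to do", stacklevel=2)
        return {}
    os.makedirs(config.out_dir, exist_ok=True)
    summary: dict = {"config": asdict(config)}

    event_onset, event_offset = config.duration / 2.0, config.duration / 2.0 + 60.0
    spec = _synth.TraceCohortSpec(
        n_neurons=config.n_neurons,
        duration=config.duration,
        noise_sd=config.noise_sd,
        event_plan=(("stim", event_onset, event_offset),),
        seed=config.seed,
    )
    traces, schedule, truth = _synth.generate_trace_dataset(spec)

    if "simulate" in config.stages:
        write_trace_bundle(os.path.join(config.out_dir, "bundle"), traces, schedule, seed=config.seed)
        write_table(truth, os.path.join(config.out_dir, "ground_truth.csv"))
        summary["simulate"] = {"n_neurons": traces.n_neurons, "n_frames": traces.n_frames}
        log.info("simulated %d neurons x %d frames", traces.n_neurons, traces.n_frames)

    dff = _traces.deltaf_over_f(traces)
    if "preprocess" in config.stages:
        summary["preprocess"] = {"mode": "dff", "mean_abs": float(np.abs(dff.values).mean())}

    if "classify" in config.stages:
        pre = post = 10.0
        peri = _traces.slice_peri_event(dff, schedule, pre=pre, post=post)
        labels = _classify.classify_response(
            peri,
            baseline_window=(-pre, 0.0),
            response_window=(0.0, post),
            alpha=config.alpha,
            auc_factor=config.auc_factor,
        )
        write_table(labels, os.path.join(config.out_dir, "labels.csv"))
        prop = _classify.population_proportions(labels, n_boot=config.n_boot, seed=config.seed)
        summary["classify"] = {
            "n_excited": int((labels["call"] == "excited").sum()),
            "n_inhibited": int((labels["call"] == "inhibited").sum()),
            "p_hat": prop.p_hat,
            "boot_mean": prop.boot_mean,
            "boot_sd": prop.boot_sd,
        }

    if "fit" in config.stages:
        t_rel = dff.times - event_onset
        sel = (t_rel >= 0) & (t_rel <= 60.0)
        rows = []
        for i in range(dff.n_neurons):
            lin = _fits.fit_linear(t_rel[sel], dff.values[i, sel])
            sig = _fits.fit_sigmoid(t_rel[sel], dff.values[i, sel])
            cmp_ = _fits.compare_models(lin, sig)
            rows.append(
                {
                    "neuron_id": i,
                    "slope": lin.slope,
                    "r2_lin": lin.r2,
                    "k": sig.k,
                    "r2_sig": sig.r2,
                    "delta_se": cmp_.delta_se,
                    "converged": sig.converged,
                }
            )
        import pandas as pd

        fit_table = pd.DataFrame(rows)
        write_table(fit_table, os.path.join(config.out_dir, "fits.csv"))
        boot = _fits.bootstrap_population_stat(
            fit_table["delta_se"].to_numpy(), "delta_se", n_boot=config.n_boot, seed=config.seed
        )
        summary["fit"] = {"delta_se_boot_mean": boot.mean, "delta_se_boot_sd": boot.sd}

    if "topo" in config.stages:
        tspec = _synth.TopographyCohortSpec(
            n_subjects=config.n_subjects,
            n_regions=12,
            cluster_plan=((("SPFp", "BLAa", "SSs"), "rostral", 0.9), (("VISC", "PB", "BLAp"), "caudal", 0.9)),
            inplane_r=0.6,
            seed=config.seed,
        )
        counts, starters, sections, _ = _synth.generate_tracing_cohort(tspec)
        retained = _topo.filter_regions(counts)
        corr = _topo.connectivity_correlation_matrix(counts, retained)
        clusters = _topo.hierarchical_cluster(corr, n_clusters=min(8, len(corr)))
        rel = _topo.cluster_starter_relationship(clusters, counts, starters)
        table, p_inplane = _topo.inplane_correlation_test(
            sections, n_shuffle=config.n_shuffle, seed=config.seed
        )
        write_table(rel, os.path.join(config.out_dir, "cluster_starter.csv"))
        write_table(table, os.path.join(config.out_dir, "inplane.csv"))
        summary["topo"] = {
            "n_retained_regions": len(retained),
            "n_clusters": clusters.n_clusters,
            "inplane_p": p_inplane,
        }

    if "report" in config.stages:
        payload = json.dumps(summary, sort_keys=True, indent=2, default=float)
        with open(os.path.join(config.out_dir, "summary.json"), "w") as f:
            f.write(payload)
        summary["report"] = {
            "summary_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        }
    return summary
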