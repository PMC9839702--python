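"""End-to-end calibration and recovery experiments on synthetic cohorts.

Each function builds a cohort with the study's planted conditions, runs
the corresponding analysis path, and returns the measured quantities:
classifier false-positive calibration on null neurons, sigmoid
parameter recovery, linear-vs-sigmoid model discrimination, the
in-plane permutation test's size and power, and recovery of planted
connectivity topography.  These double as the package's reproducibility
experiments; all are pure functions of their seeds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import classify as _classify
from . import fits as _fits
from . import synthetic as _synth
from . import topography as _topo
from . import traces as _traces
from .datatypes import PeriEventTensor


def null_classifier_calibration(
    n_neurons: int = 1000, seed: int = 0, alpha: float = 0.05
) -> dict:
    """False-positive rates of the response classifier on pure-noise neurons.

    Traces are baseline + Gaussian noise; classification compares the
    10 s pre-onset window to the 10 s post-onset window.  Reports the
    signed-rank-only excited/inhibited rates (each expected near
    alpha/2), the OR-criterion rate, and whether negating every trace
    swaps excited and inhibited calls exactly.
    """
    spec = _synth.TraceCohortSpec(
        n_neurons=n_neurons,
        duration=240.0,
        noise_sd=1.0,
        baseline_level=5.0,
        responder_mix={"null": 1.0},
        event_plan=(("stim", 120.0, 180.0),),
        seed=seed,
    )
    traces, schedule, _ = _synth.generate_trace_dataset(spec)
    dff = _traces.deltaf_over_f(traces)
    peri = _traces.slice_peri_event(dff, schedule, pre=10.0, post=10.0)
    sr = _classify.classify_response(
        peri, (-10.0, 0.0), (0.0, 10.0), alpha=alpha, criterion="signed_rank"
    )
    both = _classify.classify_response(peri, (-10.0, 0.0), (0.0, 10.0), alpha=alpha)
    neg = PeriEventTensor(
        values=-peri.values, frame_rate=peri.frame_rate, window=peri.window
    )
    both_neg = _classify.classify_response(neg, (-10.0, 0.0), (0.0, 10.0), alpha=alpha)
    swap = {"excited": "inhibited", "inhibited": "excited", "none": "none"}
    return {
        "excited_rate_signed_rank": float((sr["call"] == "excited").mean()),
        "inhibited_rate_signed_rank": float((sr["call"] == "inhibited").mean()),
        "responsive_rate_or": float((both["call"] != "none").mean()),
        "negation_symmetric": bool(
            (both["call"].map(swap).to_numpy() == both_neg["call"].to_numpy()).all()
        ),
    }


def _fit_window(dff, onset: float, length: float = 60.0):
    t_rel = dff.times - onset
    sel = (t_rel >= -1e-9) & (t_rel <= length + 1e-9)
    return t_rel[sel], sel


def sigmoid_recovery(
    n_neurons: int = 200,
    k: float = 0.1,
    x0: float = 30.0,
    noise_frac: float = 0.1,
    seed: int = 0,
) -> dict:
    """Median relative error of recovered sigmoid k and x0.

    Cohort of pure sigmoid responders (c = 1, y0 = 0) with Gaussian
    noise at ``noise_frac`` of the amplitude; traces are dF/F-normalized
    before fitting t = 0-60 s from event onset (k and x0 are invariant
    to that affine rescaling).
    """
    spec = _synth.TraceCohortSpec(
        n_neurons=n_neurons,
        duration=240.0,
        noise_sd=noise_frac * 1.0,
        baseline_level=5.0,
        responder_mix={"sigmoid": 1.0},
        sigmoid_params=(1.0, k, x0, 0.0),
        event_plan=(("stim", 120.0, 180.0),),
        seed=seed,
    )
    traces, _, _ = _synth.generate_trace_dataset(spec)
    dff = _traces.deltaf_over_f(traces)
    t, sel = _fit_window(dff, 120.0)
    k_err, x0_err = [], []
    for i in range(dff.n_neurons):
        fit = _fits.fit_sigmoid(t, dff.values[i, sel])
        if not fit.converged:
            continue
        k_err.append(abs(fit.k - k) / k)
        x0_err.append(abs(fit.x0 - x0) / x0)
    return {
        "k_median_rel_err": float(np.median(k_err)),
        "x0_median_rel_err": float(np.median(x0_err)),
        "n_converged": len(k_err),
    }


def model_discrimination(
    n_per_class: int = 200,
    noise_frac: float = 0.1,
    seed: int = 0,
    n_boot: int = 10_000,
) -> dict:
    """Separate planted linear-ramp from sigmoid-saturating populations.

    Both classes rise to the same amplitude over the 60 s stimulus; a
    neuron is predicted sigmoid when delta_se = se_lin - se_sig > 0.
    Also compares the two populations' bootstrapped mean delta_se with
    the unpaired t route.
    """
    deltas = {}
    for cls, mix in (("linear_ramp", {"linear_ramp": 1.0}), ("sigmoid", {"sigmoid": 1.0})):
        spec = _synth.TraceCohortSpec(
            n_neurons=n_per_class,
            duration=240.0,
            noise_sd=noise_frac * 1.0,
            baseline_level=5.0,
            responder_mix=mix,
            ramp_slope=1.0 / 60.0,
            sigmoid_params=(1.0, 0.2, 30.0, 0.0),
            event_plan=(("stim", 120.0, 180.0),),
            seed=seed if cls == "linear_ramp" else seed + 1,
        )
        traces, _, _ = _synth.generate_trace_dataset(spec)
        dff = _traces.deltaf_over_f(traces)
        t, sel = _fit_window(dff, 120.0)
        ds = []
        for i in range(dff.n_neurons):
            lin = _fits.fit_linear(t, dff.values[i, sel])
            sig = _fits.fit_sigmoid(t, dff.values[i, sel])
            if sig.converged:
                ds.append(_fits.compare_models(lin, sig).delta_se)
        deltas[cls] = np.asarray(ds)
    correct = (deltas["linear_ramp"] <= 0).sum() + (deltas["sigmoid"] > 0).sum()
    accuracy = correct / (deltas["linear_ramp"].size + deltas["sigmoid"].size)
    boot_a = _fits.bootstrap_population_stat(deltas["linear_ramp"], "delta_se", n_boot, seed)
    boot_b = _fits.bootstrap_population_stat(deltas["sigmoid"], "delta_se", n_boot, seed + 1)
    _, p = _fits.compare_population_fits(boot_a, boot_b)
    return {"accuracy": float(accuracy), "bootstrap_comparison_p": float(p)}


def _inplane_cohort_p(inplane_r: float, seed: int, n_subjects: int, n_sections: int, n_shuffle: int) -> float:
    spec = _synth.TopographyCohortSpec(
        n_subjects=n_subjects,
        n_regions=4,
        n_sections=n_sections,
        inplane_r=inplane_r,
        seed=seed,
    )
    _, _, sections, _ = _synth.generate_tracing_cohort(spec)
    _, p = _topo.inplane_correlation_test(sections, n_shuffle=n_shuffle, seed=seed)
    return p


def inplane_test_calibration(
    n_cohorts: int = 200,
    inplane_r: float = 0.0,
    n_subjects: int = 12,
    n_sections: int = 10,
    n_shuffle: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Rejection rate of the AP-shuffle paired test over simulated cohorts.

    With ``inplane_r=0`` this measures size (expected near alpha); with
    a planted correlation it measures power.
    """
    ss = np.random.SeedSequence([seed, int(abs(inplane_r) * 1000)])
    seeds = ss.generate_state(n_cohorts) % (2**31 - 1)
    ps = [
        _inplane_cohort_p(inplane_r, int(s), n_subjects, n_sections, n_shuffle)
        for s in seeds
    ]
    return {"rejection_rate": float(np.mean(np.asarray(ps) < alpha)), "n_cohorts": n_cohorts}


TWO_BLOCK_PLAN = (
    (("SPFp", "BLAa", "SSs"), "rostral", 0.9),
    (("VISC", "PB", "BLAp"), "caudal", 0.9),
)


def two_block_recovery(seed: int = 0) -> dict:
    """Exact cluster recovery on a noiseless planted two-block cohort.

    The cohort contains exactly the two planted blocks (no background
    regions: their fractions would covary with the blocks through the
    shared denominator); average-linkage clustering of the fraction
    correlation matrix cut at two must return the blocks exactly.
    """
    spec = _synth.TopographyCohortSpec(
        n_subjects=12, n_regions=6, cluster_plan=TWO_BLOCK_PLAN, count_noise="none", seed=seed
    )
    counts, _, _, truth = _synth.generate_tracing_cohort(spec)
    corr = _topo.connectivity_correlation_matrix(counts)
    clusters = _topo.hierarchical_cluster(corr, n_clusters=2)
    planted = {
        frozenset(truth.regions.query("cluster == @c")["region"]) for c in ("C0", "C1")
    }
    return {"exact_recovery": bool(set(clusters.as_sets()) == planted)}


def direction_recovery_rate(
    n_seeds: int = 100, coupling: float = 0.9, n_subjects: int = 12, seed: int = 0
) -> dict:
    """How often the starter-AP relationship recovers planted directions.

    Poisson-noise cohorts with one rostral and one caudal cluster at
    the given coupling; per seed, the planted clusters' mean penetrance
    is correlated with the starter AP centroid and the recovered
    rostral/caudal sign compared with the plan.
    """
    plan = tuple((regions, d, coupling) for regions, d, _ in TWO_BLOCK_PLAN)
    hits = 0
    for i in range(n_seeds):
        spec = _synth.TopographyCohortSpec(
            n_subjects=n_subjects, n_regions=8, cluster_plan=plan, seed=seed + i
        )
        counts, starters, _, truth = _synth.generate_tracing_cohort(spec)
        labels = {
            r: 1 if c == "C0" else 2
            for r, c in zip(truth.regions["region"], truth.regions["cluster"])
            if c != "background"
        }
        clusters = _topo.ClusterAssignment.from_labels(labels)
        rel = _topo.cluster_starter_relationship(clusters, counts, starters)
        got = dict(zip(rel["cluster"], rel["direction"]))
        hits += got[1] == "rostral" and got[2] == "caudal"
    return {"recovery_rate": hits / n_seeds, "n_seeds": n_seeds}


def region_filter_exactness() -> dict:
    """The designed straddle-the-cutoff toy table filters exactly.

    Four regions at mean fractions 2%, 0.6%, 0.5% (boundary) and 0.4%
    of each subject's total labeled cells; only the first two survive
    the strict > 0.5% rule.
    """
    fractions = {"KEEP_A": 0.02, "KEEP_B": 0.006, "EDGE": 0.005, "DROP": 0.004}
    rows = []
    total = 10_000
    for j in range(4):
        named = sum(fractions.values())
        rows.append((f"S{j}", "REST", "ipsi", int(round(total * (1 - named)))))
        for region, f in fractions.items():
            rows.append((f"S{j}", region, "ipsi", int(round(total * f))))
    counts = pd.DataFrame(rows, columns=["subject_id", "region", "hemisphere", "count"])
    kept = set(_topo.filter_regions(counts)) - {"REST"}
    return {
        "retained": sorted(kept),
        "matches_design": kept == {"KEEP_A", "KEEP_B"},
    }
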