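"""Synthetic cohorts with planted ground truth.

Three generators emulate the three data families the pipeline consumes:

1. **Trace cohorts** — neurons x frames fluorescence matrices at a fixed
   frame rate with event-locked responses of four planted classes:
   nulls (baseline + noise), transients (instantaneous rise, exponential
   decay), linear ramps, and saturating sigmoids
   ``y(x) = c / (1 + exp(-k*(x - x0))) + y0`` evaluated on time since
   event onset.  Noise is additive i.i.d. Gaussian on fluorescence.
2. **Tracing cohorts** — per-subject brain-region retrograde cell-count
   tables in which planted region clusters co-vary with each subject's
   starter-cell anterior-posterior (AP) centroid in a planted rostral or
   caudal direction, plus section-wise paired input/starter counts with
   a controllable in-plane Pearson correlation.
3. **Projection tables** — per-subject injection-normalized fluorescence
   across AP levels with a planted linear AP bias.

All generators are pure functions of (spec, seed): identical inputs give
bit-identical outputs.  Counts are non-negative integers (Poisson around
a log-linear mean in the starter-AP centroid, or deterministic rounding
of the mean when noise is disabled).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import EventSchedule, TraceMatrix

RESPONSE_CLASSES = ("null", "transient", "linear_ramp", "sigmoid")

#: subnuclei of the central amygdala used for starter-cell mixes
SUBNUCLEI = ("CeC", "CeL", "CeM")


class InvalidSpecError(ValueError):
    """A generator spec violates its invariants."""


def largest_remainder_counts(fractions: dict[str, float], total: int) -> dict[str, int]:
    """Apportion ``total`` items to classes by the largest-remainder method.

    Deterministic and sums exactly to ``total``; ties in remainder are
    broken by class order in ``fractions``.
    """
    keys = list(fractions)
    raw = np.array([fractions[k] * total for k in keys], dtype=float)
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    # stable sort: descending remainder, original order among ties
    order = sorted(range(len(keys)), key=lambda i: (-(raw[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return dict(zip(keys, base.tolist()))


def sigmoid(x: np.ndarray | float, c: float, k: float, x0: float, y0: float) -> np.ndarray:
    """Four-parameter logistic: ``c / (1 + exp(-k*(x - x0))) + y0``."""
    z = np.clip(-k * (np.asarray(x, dtype=float) - x0), -500.0, 500.0)
    return c / (1.0 + np.exp(z)) + y0


# ---------------------------------------------------------------------------
# trace cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraceCohortSpec:
    """Recipe for a synthetic calcium-trace cohort.

    Parameters
    ----------
    n_neurons, duration, frame_rate
        Cohort size and recording geometry; 6 frames/s is the miniscope
        acquisition convention used throughout.
    baseline_level, noise_sd
        Constant fluorescence baseline and i.i.d. Gaussian noise SD, in
        the same arbitrary fluorescence units.
    responder_mix
        Fractions by class over ``("null", "transient", "linear_ramp",
        "sigmoid")``; must sum to 1.  Counts are apportioned by the
        largest-remainder method, so they sum to ``n_neurons`` exactly.
    ramp_slope
        Ramp gain in fluorescence units per second during each event.
    sigmoid_params
        (c, k, x0, y0): amplitude, rate (1/s), inflection time (s since
        event onset), and offset of the planted sigmoid response.
    transient_amp, transient_tau
        Peak amplitude and exponential decay constant (s) of the
        transient class.
    event_plan
        (label, onset_s, offset_s) triples; responses lock to onsets.
    """

    n_neurons: int
    duration: float
    frame_rate: float = 6.0
    baseline_level: float = 5.0
    noise_sd: float = 0.5
    responder_mix: dict = field(
        default_factory=lambda: {"null": 0.55, "transient": 0.15, "linear_ramp": 0.15, "sigmoid": 0.15}
    )
    ramp_slope: float = 1.0 / 60.0
    sigmoid_params: tuple[float, float, float, float] = (1.0, 0.2, 30.0, 0.0)
    transient_amp: float = 2.0
    transient_tau: float = 1.0
    event_plan: tuple = (("stim", 120.0, 180.0),)
    seed: int = 0

    def validate(self) -> None:
        if self.n_neurons < 1:
            raise InvalidSpecError("n_neurons must be >= 1")
        if self.duration <= 0 or self.frame_rate <= 0:
            raise InvalidSpecError("duration and frame_rate must be positive")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be non-negative")
        unknown = set(self.responder_mix) - set(RESPONSE_CLASSES)
        if unknown:
            raise InvalidSpecError(f"unknown responder classes: {sorted(unknown)}")
        total = sum(self.responder_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidSpecError(f"responder_mix fractions sum to {total}, expected 1")
        for label, onset, offset in self.event_plan:
            if not (0.0 <= onset <= offset <= self.duration):
                raise InvalidSpecError(
                    f"event {label!r} [{onset}, {offset}] outside recording [0, {self.duration}]"
                )


def _class_template(cls: str, spec: TraceCohortSpec, t: np.ndarray) -> np.ndarray:
    """Noise-free event-locked response summed over the event plan."""
    out = np.zeros_like(t)
    for _, onset, offset in spec.event_plan:
        x = t - onset
        if cls == "transient":
            m = x >= -1e-12
            out[m] += spec.transient_amp * np.exp(-x[m] / spec.transient_tau)
        elif cls == "linear_ramp":
            m = (x >= -1e-12) & (t <= offset + 1e-12)
            out[m] += spec.ramp_slope * x[m]
        elif cls == "sigmoid":
            m = (x >= -1e-12) & (t <= offset + 1e-12)
            out[m] += sigmoid(x[m], *spec.sigmoid_params)
    return out


def generate_trace_dataset(
    spec: TraceCohortSpec,
) -> tuple[TraceMatrix, EventSchedule, pd.DataFrame]:
    """Simulate a trace cohort; returns (traces, events, ground_truth).

    Ground truth is a DataFrame with columns ``neuron_id`` and
    ``true_class``; class counts match the largest-remainder rounding of
    ``responder_mix`` exactly.  With ``noise_sd=0`` each responder trace
    equals baseline plus its analytic template to machine precision.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_frames = int(round(spec.duration * spec.frame_rate))
    t = np.arange(n_frames) / spec.frame_rate

    mix = {c: spec.responder_mix.get(c, 0.0) for c in RESPONSE_CLASSES}
    counts = largest_remainder_counts(mix, spec.n_neurons)
    classes: list[str] = []
    for c in RESPONSE_CLASSES:
        classes.extend([c] * counts[c])

    templates = {c: _class_template(c, spec, t) for c in RESPONSE_CLASSES}
    values = np.empty((spec.n_neurons, n_frames))
    for i, cls in enumerate(classes):
        values[i] = spec.baseline_level + templates[cls]
    if spec.noise_sd > 0:
        values += rng.normal(0.0, spec.noise_sd, size=values.shape)

    traces = TraceMatrix(values=values, frame_rate=spec.frame_rate)
    schedule = EventSchedule([tuple(e) for e in spec.event_plan])
    truth = pd.DataFrame({"neuron_id": np.arange(spec.n_neurons), "true_class": classes})
    return traces, schedule, truth


# ---------------------------------------------------------------------------
# tracing cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TopographyCohortSpec:
    """Recipe for a synthetic retrograde-tracing cohort.

    ``cluster_plan`` lists (region_names, direction, coupling) triples:
    the named regions' labeled-cell counts follow a log-linear mean in
    the subject's starter-cell AP centroid, rising toward the rostral
    (less negative AP) or caudal pole with strength ``coupling`` in
    [0, 1].  Regions outside every cluster have AP-independent means.
    ``inplane_r`` sets the target per-subject Pearson correlation of
    section-wise (input, starter) counts.  ``count_noise`` is "poisson"
    or "none" (deterministic rounded means).
    """

    n_subjects: int = 12
    n_regions: int = 12
    cluster_plan: tuple = ()
    ap_range: tuple[float, float] = (-2.0, -0.75)
    n_sections: int = 10
    inplane_r: float = 0.0
    count_scale: float = 100.0
    count_noise: str = "poisson"
    coupling_gain: float = 1.5
    seed: int = 0

    def region_names(self) -> list[str]:
        named = [r for regions, _, _ in self.cluster_plan for r in regions]
        extra = self.n_regions - len(named)
        return named + [f"BG{i:02d}" for i in range(max(extra, 0))]

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise InvalidSpecError("n_subjects must be >= 1")
        if abs(self.inplane_r) > 1:
            raise InvalidSpecError("|inplane_r| must be <= 1")
        if self.count_noise not in ("poisson", "none"):
            raise InvalidSpecError("count_noise must be 'poisson' or 'none'")
        if self.ap_range[0] >= self.ap_range[1]:
            raise InvalidSpecError("ap_range must be (low, high) in mm")
        seen: set[str] = set()
        for regions, direction, coupling in self.cluster_plan:
            if direction not in ("rostral", "caudal"):
                raise InvalidSpecError(f"unknown direction {direction!r}")
            if not (0.0 <= coupling <= 1.0):
                raise InvalidSpecError(f"coupling {coupling} outside [0, 1]")
            overlap = seen & set(regions)
            if overlap:
                raise InvalidSpecError(f"cluster sets not disjoint: {sorted(overlap)}")
            seen |= set(regions)
        named = [r for regions, _, _ in self.cluster_plan for r in regions]
        if len(named) > self.n_regions:
            raise InvalidSpecError("cluster_plan names more regions than n_regions")


@dataclass
class TracingGroundTruth:
    """Planted structure of a tracing cohort."""

    regions: pd.DataFrame  # region, cluster, direction, coupling
    subjects: pd.DataFrame  # subject_id, ap_centroid, group


def _counts(rng: np.random.Generator, lam: np.ndarray, noise: str) -> np.ndarray:
    if noise == "poisson":
        return rng.poisson(lam)
    return np.rint(lam).astype(int)


def generate_tracing_cohort(
    spec: TopographyCohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TracingGroundTruth]:
    """Simulate a tracing cohort.

    Returns tidy DataFrames: region counts (subject_id, region,
    hemisphere, count), starter cells (subject_id, ap_level, subnucleus,
    count), section series (subject_id, section_ap, input_count,
    starter_count), plus the planted ground truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.ap_range
    mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0

    # rostral / caudal injection targets, mirroring a split cohort design
    n_rostral = spec.n_subjects // 2
    groups = ["rostral"] * n_rostral + ["caudal"] * (spec.n_subjects - n_rostral)
    target = {"rostral": mid + 0.5 * half, "caudal": mid - 0.5 * half}
    centroids = np.clip(
        [target[g] + rng.normal(0.0, 0.12) for g in groups], lo + 0.05, hi - 0.05
    )
    a = (centroids - mid) / half  # standardized AP centroid, ~[-1, 1]

    regions = spec.region_names()
    beta = np.zeros(len(regions))
    cluster_of = {r: "background" for r in regions}
    direction_of = {r: "" for r in regions}
    coupling_of = {r: 0.0 for r in regions}
    for ci, (rset, direction, coupling) in enumerate(spec.cluster_plan):
        sgn = 1.0 if direction == "rostral" else -1.0
        for r in rset:
            beta[regions.index(r)] = sgn * coupling * spec.coupling_gain
            cluster_of[r] = f"C{ci}"
            direction_of[r] = direction
            coupling_of[r] = coupling
    scale = spec.count_scale * np.exp(rng.normal(0.0, 0.3, size=len(regions)))

    rows = []
    for j in range(spec.n_subjects):
        lam = scale * np.exp(beta * a[j])
        total = _counts(rng, lam, spec.count_noise)
        ipsi = np.rint(total * 0.85).astype(int)
        for r, tot, ip in zip(regions, total, ipsi):
            rows.append((f"S{j:02d}", r, "ipsi", int(ip)))
            rows.append((f"S{j:02d}", r, "contra", int(tot - ip)))
    region_counts = pd.DataFrame(rows, columns=["subject_id", "region", "hemisphere", "count"])

    # starter cells: Gaussian AP spread around the centroid, split by subnucleus
    ap_levels = np.linspace(lo, hi, 6)
    srows = []
    for j in range(spec.n_subjects):
        w = np.exp(-0.5 * ((ap_levels - centroids[j]) / 0.25) ** 2)
        lam = 40.0 * w / w.sum()
        mix = rng.dirichlet([4.0, 6.0, 3.0])  # CeC, CeL, CeM
        for ap, l in zip(ap_levels, lam):
            per = _counts(rng, l * mix, spec.count_noise)
            for sub, c in zip(SUBNUCLEI, per):
                if c > 0:
                    srows.append((f"S{j:02d}", float(ap), sub, int(c)))
    starters = pd.DataFrame(srows, columns=["subject_id", "ap_level", "subnucleus", "count"])

    # section-wise paired counts with target in-plane correlation
    sec_ap = np.linspace(lo, hi, spec.n_sections)
    xrows = []
    r_target = float(spec.inplane_r)
    for j in range(spec.n_subjects):
        prof = np.exp(-0.5 * ((sec_ap - centroids[j]) / 0.3) ** 2)
        starter_sec = _counts(rng, 30.0 * prof + 2.0, spec.count_noise)
        if spec.count_noise == "none" and abs(r_target) == 1.0:
            # exact integer-affine coupling; rounding would spoil r = +/-1
            if r_target > 0:
                input_sec = 2 * starter_sec
            else:
                input_sec = 2 * (int(starter_sec.max()) + 1 - starter_sec)
        else:
            zs = starter_sec - starter_sec.mean()
            sd = zs.std()
            zs = zs / sd if sd > 0 else np.zeros_like(zs, dtype=float)
            ze = rng.standard_normal(spec.n_sections)
            mixed = r_target * zs + math.sqrt(max(0.0, 1.0 - r_target**2)) * ze
            input_sec = np.maximum(
                0, np.rint(spec.count_scale + (spec.count_scale / 4.0) * mixed)
            ).astype(int)
        for ap, inp, st in zip(sec_ap, input_sec, starter_sec):
            xrows.append((f"S{j:02d}", float(ap), int(inp), int(st)))
    sections = pd.DataFrame(
        xrows, columns=["subject_id", "section_ap", "input_count", "starter_count"]
    )

    truth = TracingGroundTruth(
        regions=pd.DataFrame(
            {
                "region": regions,
                "cluster": [cluster_of[r] for r in regions],
                "direction": [direction_of[r] for r in regions],
                "coupling": [coupling_of[r] for r in regions],
            }
        ),
        subjects=pd.DataFrame(
            {
                "subject_id": [f"S{j:02d}" for j in range(spec.n_subjects)],
                "ap_centroid": centroids,
                "group": groups,
            }
        ),
    )
    return region_counts, starters, sections, truth


# ---------------------------------------------------------------------------
# projection tables
# ---------------------------------------------------------------------------


def generate_projection_dataset(
    n_subjects: int,
    ap_levels: list[float] | np.ndarray,
    bias_slope: float,
    seed: int = 0,
    noise_sd: float = 0.05,
    regions: tuple[str, ...] = ("injection_site",),
) -> pd.DataFrame:
    """Per-subject normalized fluorescence across AP levels with a planted
    linear AP trend of slope ``bias_slope`` (1/mm).

    Negative bias denotes rostrally weighted expression, matching the
    convention that a bias of -1 reflects a strongly rostral injection.
    Raises on fewer than two AP levels (a slope is then undefined).
    """
    ap = np.asarray(ap_levels, dtype=float)
    if ap.size < 2:
        raise InvalidSpecError("need >= 2 AP levels to define an AP bias")
    rng = np.random.default_rng(seed)
    mid = ap.mean()
    # intercept large enough that the planted line stays positive
    b0 = 1.0 + abs(bias_slope) * (ap.max() - ap.min())
    group = "rostral" if bias_slope <= 0 else "caudal"
    rows = []
    for j in range(n_subjects):
        for region in regions:
            vals = b0 + bias_slope * (ap - mid)
            if noise_sd > 0:
                vals = vals + rng.normal(0.0, noise_sd, size=ap.size)
            for a_, v in zip(ap, vals):
                rows.append((f"S{j:02d}", region, float(a_), float(max(v, 0.0)), group))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "region", "ap_level", "normalized_fluorescence", "group"],
    )
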