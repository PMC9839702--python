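"""Per-neuron response classification and population summaries.

A neuron is called *excited* by a stimulus if either sub-criterion
fires: a two-sided Wilcoxon signed-rank test of response-window versus
baseline-window frames rejects at ``alpha`` with a positive median
shift, or the length-normalized response area-under-curve exceeds
``auc_factor`` times the absolute length-normalized baseline AUC
(the "> |2x| baseline" rule).  *Inhibited* is the mirror image; both
sub-criterion outcomes are recorded for auditing.  No multiple-testing
correction is applied across neurons — downstream summaries report raw
proportions.

Also here: blockwise classification against a pre-injection baseline
block, monotonic-increase detection over a fixed post-contact window,
trial-by-trial learning modulation, zero-lag trial cross-correlation,
threshold-crossing response latency, and bootstrapped population
proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import InsufficientDataError, NormalizedTrace, PeriEventTensor, SchemaError


def _auc_rate(y: np.ndarray, frame_rate: float) -> np.ndarray:
    """Trapezoidal AUC per unit time along the last axis."""
    n = y.shape[-1]
    if n < 2:
        return y[..., 0]
    duration = (n - 1) / frame_rate
    return np.trapezoid(y, dx=1.0 / frame_rate, axis=-1) / duration


def _signed_rank(diff: np.ndarray) -> tuple[float, float, bool]:
    """Two-sided Wilcoxon signed-rank on paired differences.

    Returns (p, median_shift, degenerate).  All-zero differences are the
    degenerate no-evidence case: p = 1.
    """
    diff = np.asarray(diff, dtype=float)
    nz = diff[diff != 0]
    if nz.size == 0:
        return 1.0, 0.0, True
    res = stats.wilcoxon(diff, zero_method="wilcox", alternative="two-sided", method="auto")
    return float(res.pvalue), float(np.median(diff)), False


def classify_response(
    peri: PeriEventTensor,
    baseline_window: tuple[float, float],
    response_window: tuple[float, float],
    alpha: float = 0.05,
    auc_factor: float = 2.0,
    criterion: str = "either",
) -> pd.DataFrame:
    """Call each neuron excited / inhibited / none for one stimulus.

    Windows are in seconds relative to event onset (negative = before).
    Frames are event-averaged per neuron before testing; with equal
    window lengths the signed-rank test pairs frames positionally,
    otherwise response frames are paired against the baseline mean.

    Returns a DataFrame with per-neuron call, sub-criterion outcomes
    (``sr_call``, ``auc_call``), p-value, median shift, AUC ratio, and a
    ``degenerate`` flag for all-tied windows (always called none).
    """
    if criterion not in ("signed_rank", "auc_ratio", "either"):
        raise ValueError(f"unknown criterion {criterion!r}")
    mean_trace = peri.mean_over_events()
    b_mask = peri.frames_in(*baseline_window)
    r_mask = peri.frames_in(*response_window)
    if b_mask.sum() < 2 or r_mask.sum() < 2:
        raise ValueError("baseline and response windows need >= 2 frames each")
    base = mean_trace[:, b_mask]
    resp = mean_trace[:, r_mask]

    base_rate = _auc_rate(base, peri.frame_rate)
    resp_rate = _auc_rate(resp, peri.frame_rate)

    rows = []
    for i in range(peri.n_neurons):
        if resp.shape[1] == base.shape[1]:
            diff = resp[i] - base[i]
        else:
            diff = resp[i] - base[i].mean()
        p, shift, degenerate = _signed_rank(diff)
        sr_call = "none"
        if not degenerate and p < alpha:
            sr_call = "excited" if shift > 0 else ("inhibited" if shift < 0 else "none")
        thr = auc_factor * abs(base_rate[i])
        if resp_rate[i] > thr:
            auc_call = "excited"
        elif resp_rate[i] < -thr:
            auc_call = "inhibited"
        else:
            auc_call = "none"
        auc_ratio = resp_rate[i] / abs(base_rate[i]) if base_rate[i] != 0 else np.inf * np.sign(
            resp_rate[i]
        ) if resp_rate[i] != 0 else 0.0

        if criterion == "signed_rank":
            call = sr_call
        elif criterion == "auc_ratio":
            call = auc_call
        else:  # either sub-criterion fires; conflicting directions -> none
            fired = {c for c in (sr_call, auc_call) if c != "none"}
            call = fired.pop() if len(fired) == 1 else "none"
        rows.append(
            (
                peri.neuron_ids[i],
                peri.alignment,
                call,
                criterion,
                p,
                shift,
                auc_ratio,
                sr_call,
                auc_call,
                degenerate,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "neuron_id",
            "stimulus",
            "call",
            "criterion",
            "p_value",
            "median_shift",
            "auc_ratio",
            "sr_call",
            "auc_call",
            "degenerate",
        ],
    )


def classify_blockwise(
    blocks: list[PeriEventTensor],
    baseline_block: PeriEventTensor,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify each recording block against a baseline block.

    Designed for repeated short recordings after a challenge (e.g. 2-min
    windows at 0.5-2.5 h post-injection): each block's event-averaged
    frames are compared to the baseline block by signed-rank, and a
    neuron is flagged ``any_block_excited`` if any block is excited.

    Returns (per_block, summary) DataFrames.
    """
    ids = np.asarray(baseline_block.neuron_ids)
    for b in blocks:
        if b.n_neurons != baseline_block.n_neurons or not np.array_equal(
            np.asarray(b.neuron_ids), ids
        ):
            raise SchemaError("all blocks must contain the same neurons in the same order")
    base = baseline_block.mean_over_events()
    rows = []
    for bi, block in enumerate(blocks):
        cur = block.mean_over_events()
        for i in range(block.n_neurons):
            if cur.shape[1] == base.shape[1]:
                diff = cur[i] - base[i]
            else:
                diff = cur[i] - base[i].mean()
            p, shift, degenerate = _signed_rank(diff)
            call = "none"
            if not degenerate and p < alpha:
                call = "excited" if shift > 0 else ("inhibited" if shift < 0 else "none")
            rows.append((ids[i], bi, call, p, shift))
    per_block = pd.DataFrame(rows, columns=["neuron_id", "block", "call", "p_value", "median_shift"])
    summary = (
        per_block.assign(excited=lambda d: d["call"] == "excited")
        .groupby("neuron_id", sort=False)["excited"]
        .any()
        .rename("any_block_excited")
        .reset_index()
    )
    return per_block, summary


def detect_monotonic_increase(
    norm: NormalizedTrace,
    window: tuple[float, float] = (0.0, 60.0),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-neuron test for monotonically increasing activity in a window.

    Ordinary least-squares regression of activity on time over
    ``window`` (session-clock seconds, e.g. 0-60 s from first paw
    contact when t0 is referenced to contact); the flag is set when the
    one-sided p for slope > 0 rejects at ``alpha``.  Constant traces
    yield slope 0, p 1, flag False.
    """
    i0 = max(norm.frame_at(window[0]), 0)
    i1 = min(norm.frame_at(window[1]), norm.n_frames)
    if i1 - i0 < 3:
        raise ValueError("need >= 3 frames in the regression window")
    t = norm.times[i0:i1]
    rows = []
    for i in range(norm.n_neurons):
        y = norm.values[i, i0:i1]
        if np.ptp(y) == 0:
            rows.append((norm.neuron_ids[i], 0.0, 1.0, False))
            continue
        fit = stats.linregress(t, y)
        p_one = fit.pvalue / 2.0 if fit.slope > 0 else 1.0 - fit.pvalue / 2.0
        rows.append((norm.neuron_ids[i], float(fit.slope), float(p_one), bool(fit.slope > 0 and p_one < alpha)))
    return pd.DataFrame(rows, columns=["neuron_id", "slope", "p_one_sided", "increasing"])


def detect_learning_modulation(
    per_trial_responses: np.ndarray,
    first_trial_frames: np.ndarray | None = None,
    last_trial_frames: np.ndarray | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify trial-by-trial response trajectories per neuron.

    ``per_trial_responses`` is neurons x trials of response magnitudes
    (mean z in the response window).  A neuron is *increasing* if the
    regression of magnitude on trial number has a significantly positive
    slope, or if frame-level first-versus-last-trial samples (when
    provided, neurons x frames each) differ by signed-rank with a
    positive shift; *decreasing* is symmetric; otherwise *stable*.
    The ``method`` column records which criterion produced the call.
    """
    resp = np.asarray(per_trial_responses, dtype=float)
    if resp.ndim != 2 or resp.shape[1] < 2:
        raise InsufficientDataError("need >= 2 trials per neuron")
    trials = np.arange(resp.shape[1], dtype=float)
    rows = []
    for i in range(resp.shape[0]):
        call, method = "stable", "none"
        y = resp[i]
        slope, p_slope = 0.0, 1.0
        # slope significance needs residual df: >= 3 trials
        if y.size >= 3 and np.ptp(y) > 0:
            fit = stats.linregress(trials, y)
            slope, p_slope = float(fit.slope), float(fit.pvalue)
        if p_slope < alpha and slope != 0:
            call = "increasing" if slope > 0 else "decreasing"
            method = "slope"
        elif first_trial_frames is not None and last_trial_frames is not None:
            p_fl, shift, degenerate = _signed_rank(
                np.asarray(last_trial_frames[i], float) - np.asarray(first_trial_frames[i], float)
            )
            if not degenerate and p_fl < alpha and shift != 0:
                call = "increasing" if shift > 0 else "decreasing"
                method = "first_vs_last"
        rows.append((i, call, method, slope, p_slope))
    return pd.DataFrame(rows, columns=["neuron_id", "call", "method", "slope", "p_slope"])


def trial_cross_correlation(
    peri: PeriEventTensor, trial_a: int, trial_b: int
) -> pd.DataFrame:
    """Zero-lag Pearson correlation of two peri-event snippets per neuron.

    Zero-variance snippets yield NaN with ``defined=False`` and should
    be excluded from population summaries.
    """
    if max(trial_a, trial_b) >= peri.n_events:
        raise IndexError("trial index outside tensor")
    a = peri.values[:, trial_a, :]
    b = peri.values[:, trial_b, :]
    if a.shape[1] < 3:
        raise ValueError("need >= 3 frames for a correlation")
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (ac * bc).sum(axis=1) / denom, np.nan)
    return pd.DataFrame({"neuron_id": peri.neuron_ids, "r": r, "defined": denom > 0})


def response_latency(
    peri: PeriEventTensor,
    threshold_sd: float = 2.0,
    sustained: int = 2,
) -> pd.DataFrame:
    """Time from event onset to threshold crossing, per neuron.

    Operates on z-scored peri-event snippets (event-averaged): latency
    is the time of the first post-onset frame whose value reaches
    ``threshold_sd`` and stays there for at least ``sustained``
    consecutive frames.  Neurons that never cross are flagged undefined
    (NaN latency).
    """
    z = peri.mean_over_events()
    t = peri.rel_times
    post = t >= -1e-9
    zp = z[:, post]
    tp = t[post]
    lat = np.full(peri.n_neurons, np.nan)
    above = zp >= threshold_sd
    for i in range(peri.n_neurons):
        run = 0
        for j in range(above.shape[1]):
            run = run + 1 if above[i, j] else 0
            if run >= sustained:
                lat[i] = tp[j - sustained + 1]
                break
    return pd.DataFrame(
        {"neuron_id": peri.neuron_ids, "latency_s": lat, "defined": ~np.isnan(lat)}
    )


@dataclass(frozen=True)
class ProportionEstimate:
    """Responsive fraction with a neuron-resampling bootstrap."""

    n_responsive: int
    n_total: int
    p_hat: float
    boot_mean: float
    boot_sd: float
    n_boot: int


def population_proportions(
    labels: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
    positive: str = "excited",
) -> ProportionEstimate:
    """Bootstrapped proportion of responsive neurons.

    Resamples neurons with replacement ``n_boot`` times; the bar and
    error reported downstream are the bootstrap mean and SD.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    calls = labels["call"].to_numpy() if isinstance(labels, pd.DataFrame) else np.asarray(labels)
    n = calls.size
    if n < 1:
        raise InsufficientDataError("need at least one neuron")
    hits = (calls == positive).astype(float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = hits[idx].mean(axis=1)
    return ProportionEstimate(
        n_responsive=int(hits.sum()),
        n_total=n,
        p_hat=float(hits.mean()),
        boot_mean=float(boot.mean()),
        boot_sd=float(boot.std(ddof=0)),
        n_boot=n_boot,
    )


def compare_event_conditions(
    condition_a: np.ndarray, condition_b: np.ndarray
) -> tuple[float, float, str]:
    """Paired two-sided signed-rank comparison of per-neuron magnitudes.

    e.g. response during cued versus uncued freezing bouts.  Returns
    (statistic, p, direction) with direction in {"higher", "lower",
    "none"} describing condition_a relative to condition_b.  Identical
    pairs give p = 1.
    """
    a = np.asarray(condition_a, dtype=float)
    b = np.asarray(condition_b, dtype=float)
    if a.shape != b.shape:
        raise SchemaError("paired conditions must have equal shape")
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if a.size < 2:
        raise InsufficientDataError("need >= 2 complete pairs")
    diff = a - b
    if np.all(diff == 0):
        return float("nan"), 1.0, "none"
    res = stats.wilcoxon(diff, zero_method="wilcox", alternative="two-sided", method="auto")
    med = float(np.median(diff))
    direction = "higher" if med > 0 else ("lower" if med < 0 else "none")
    return float(res.statistic), float(res.pvalue), direction
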