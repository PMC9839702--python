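"""Tracing-topography statistics.

Retrograde cohorts arrive as tidy tables of per-subject labeled-cell
counts by brain region (plus starter-cell AP/subnucleus distributions
and per-section paired counts); anterograde cohorts as per-subject
injection-normalized fluorescence by AP level.  This module implements:

* the 0.5% expression cutoff for region inclusion;
* the region x region input-connectivity correlation matrix (Pearson,
  across subjects, on per-subject fractions of total labeled cells);
* hierarchical clustering of that matrix (average linkage on 1 - r);
* per-cluster correlation of mean cluster penetrance against the
  count-weighted starter-cell AP centroid, mapping the sign onto a
  rostral/caudal direction (more negative AP = more caudal);
* the in-plane section-wise correlation test against an AP-shuffled
  permutation null, summarized across subjects by a paired two-sided
  signed-rank test;
* local-connectivity regressions of neighboring labeled cells on the
  starter subnucleus mix;
* per-subject anterograde AP-bias slopes and rostral-vs-caudal target
  comparisons (two-way ANOVA with Sidak-adjusted per-target tests);
* the connectivity-incidence comparison on binary outcomes
  (Mann-Whitney with tie correction, plus Fisher exact cross-check).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datatypes import InsufficientDataError, SchemaError

REGION_COLUMNS = ("subject_id", "region", "hemisphere", "count")


def _check_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table missing column(s) {missing}")


def subject_fractions(region_counts: pd.DataFrame) -> pd.DataFrame:
    """Subject x region matrix of per-subject fractions of total labeled cells.

    Hemispheres are summed.  Subjects with zero total labeled cells are
    dropped with a warning (their fractions are undefined).
    """
    _check_columns(region_counts, ("subject_id", "region", "count"), "region count")
    wide = (
        region_counts.groupby(["subject_id", "region"], sort=True)["count"]
        .sum()
        .unstack(fill_value=0)
    )
    totals = wide.sum(axis=1)
    empty = totals[totals == 0].index.tolist()
    if empty:
        warnings.warn(f"subject(s) {empty} have zero labeled cells; excluded", stacklevel=2)
        wide = wide.drop(index=empty)
        totals = totals.drop(index=empty)
    return wide.div(totals, axis=0)


def filter_regions(region_counts: pd.DataFrame, cutoff_fraction: float = 0.005) -> list[str]:
    """Apply the expression cutoff: retain regions whose mean
    across-subject fraction of labeled cells strictly exceeds
    ``cutoff_fraction`` (default 0.5%).

    Idempotent and invariant to subject order.
    """
    if region_counts.empty:
        return []
    frac = subject_fractions(region_counts)
    if frac.empty:
        return []
    mean_frac = frac.mean(axis=0)
    return sorted(mean_frac.index[mean_frac > cutoff_fraction])


def connectivity_correlation_matrix(
    region_counts: pd.DataFrame, retained_regions: list[str] | None = None
) -> pd.DataFrame:
    """Region x region Pearson correlation of fractions across subjects.

    Normalizing to per-subject fractions first removes the
    injection-efficiency scale, so the matrix is invariant to rescaling
    any subject's total count.  Regions with zero variance across
    subjects have undefined correlations and are excluded with a
    warning.
    """
    frac = subject_fractions(region_counts)
    if retained_regions is not None:
        frac = frac[[r for r in retained_regions if r in frac.columns]]
    if frac.shape[0] < 3:
        raise InsufficientDataError("need >= 3 subjects to correlate across subjects")
    sd = frac.std(axis=0, ddof=0)
    flat = sd[sd <= 1e-12].index.tolist()  # tolerate float error in exact ratios
    if flat:
        warnings.warn(
            f"region(s) {flat} have zero variance across subjects; excluded", stacklevel=2
        )
        frac = frac.drop(columns=flat)
    corr = frac.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass
class ClusterAssignment:
    """Result of hierarchical clustering of the correlation matrix."""

    labels: pd.Series  # region -> cluster id (1-based, scipy convention)
    linkage: np.ndarray
    n_clusters: int

    @classmethod
    def from_labels(cls, labels: dict[str, int] | pd.Series) -> "ClusterAssignment":
        """Build an assignment from known region -> cluster labels
        (e.g. a planted ground truth), without a linkage tree."""
        s = pd.Series(labels, name="cluster")
        return cls(s, np.empty((0, 4)), int(s.nunique()))

    def members(self, cluster_id: int) -> list[str]:
        return sorted(self.labels.index[self.labels == cluster_id])

    def as_sets(self) -> list[frozenset]:
        return [frozenset(self.members(c)) for c in sorted(self.labels.unique())]


def hierarchical_cluster(
    corr: pd.DataFrame,
    n_clusters: int | None = None,
    height: float | None = None,
) -> ClusterAssignment:
    """Agglomerative clustering of regions on distance 1 - r.

    Average linkage; cut either at ``n_clusters`` or at cophenetic
    ``height``.  Deterministic given the input matrix.
    """
    values = corr.to_numpy()
    if values.shape[0] != values.shape[1] or not np.allclose(values, values.T, atol=1e-10):
        raise ValueError("correlation matrix must be square and symmetric")
    regions = list(corr.index)
    if len(regions) == 1:
        return ClusterAssignment(pd.Series([1], index=regions), np.empty((0, 4)), 1)
    dist = 1.0 - values
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    if n_clusters is not None:
        flat = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
    elif height is not None:
        flat = hierarchy.fcluster(link, t=height, criterion="distance")
    else:
        raise ValueError("specify n_clusters or height")
    labels = pd.Series(flat, index=regions, name="cluster")
    return ClusterAssignment(labels, link, int(labels.nunique()))


def starter_ap_centroid(starters: pd.DataFrame) -> pd.Series:
    """Count-weighted mean AP level per subject (mm relative to bregma)."""
    _check_columns(starters, ("subject_id", "ap_level", "count"), "starter cell")

    def _centroid(g: pd.DataFrame) -> float:
        w = g["count"].to_numpy(float)
        return float(np.average(g["ap_level"].to_numpy(float), weights=w))

    return starters.groupby("subject_id").apply(_centroid, include_groups=False)


def cluster_starter_relationship(
    clusters: ClusterAssignment,
    region_counts: pd.DataFrame,
    starters: pd.DataFrame,
) -> pd.DataFrame:
    """Correlate each cluster's mean penetrance with starter AP centroid.

    Per cluster: mean fraction over member regions per subject, Pearson
    correlation against the subject's count-weighted starter AP
    centroid.  Positive r means penetrance rises toward less-negative
    (rostral) AP, so direction = "rostral"; negative r = "caudal".
    """
    frac = subject_fractions(region_counts)
    centroid = starter_ap_centroid(starters)
    subjects = frac.index.intersection(centroid.index)
    if len(subjects) < 3:
        raise InsufficientDataError("need >= 3 subjects with counts and starter cells")
    frac = frac.loc[subjects]
    x = centroid.loc[subjects].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("all subjects share the same starter AP centroid; undefined")
    rows = []
    for cid in sorted(clusters.labels.unique()):
        members = [r for r in clusters.members(cid) if r in frac.columns]
        if not members:
            continue
        y = frac[members].mean(axis=1).to_numpy(float)
        if np.ptp(y) == 0:
            rows.append((cid, len(members), np.nan, np.nan, "undefined"))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((cid, len(members), float(r), float(p), "rostral" if r > 0 else "caudal"))
    return pd.DataFrame(rows, columns=["cluster", "n_regions", "r", "p", "direction"])


def _pearson_with_shuffles(
    x: np.ndarray, y: np.ndarray, n_shuffle: int, rng: np.random.Generator
) -> tuple[float, np.ndarray]:
    """Pearson r(x, y) plus r over AP-shuffled x (y fixed), vectorized."""
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    r = float((xc * yc).sum() / denom)
    perms = np.argsort(rng.random((n_shuffle, x.size)), axis=1)
    shuffled = (xc[perms] @ yc) / denom
    return r, shuffled


def inplane_correlation_test(
    sections: pd.DataFrame,
    n_shuffle: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Section-wise input/starter correlation versus an AP-shuffled null.

    Per subject: Pearson correlation of (input_count, starter_count)
    over AP-ordered sections, and the mean correlation after permuting
    the input counts' section assignment within subject (starter counts
    fixed).  Across subjects, real and mean-shuffled r are compared by
    a paired two-sided signed-rank test.

    Returns (per-subject table, paired p).  Subjects with zero-variance
    counts are flagged and excluded from the paired test.
    """
    _check_columns(sections, ("subject_id", "section_ap", "input_count", "starter_count"), "section")
    rng = np.random.default_rng(seed)
    rows = []
    for subject, g in sections.sort_values("section_ap").groupby("subject_id", sort=True):
        x = g["input_count"].to_numpy(float)
        y = g["starter_count"].to_numpy(float)
        if x.size < 3:
            raise InsufficientDataError(f"subject {subject}: need >= 3 sections")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(f"subject {subject}: zero-variance counts; excluded", stacklevel=2)
            rows.append((subject, np.nan, np.nan, False))
            continue
        r, shuffled = _pearson_with_shuffles(x, y, n_shuffle, rng)
        rows.append((subject, r, float(shuffled.mean()), True))
    table = pd.DataFrame(rows, columns=["subject_id", "r_real", "r_shuffled_mean", "included"])
    ok = table[table["included"]]
    if len(ok) < 6:
        raise InsufficientDataError("need >= 6 usable subjects for the paired test")
    diff = ok["r_real"].to_numpy() - ok["r_shuffled_mean"].to_numpy()
    if np.all(diff == 0):
        return table, 1.0
    res = stats.wilcoxon(diff, alternative="two-sided", method="auto")
    return table, float(res.pvalue)


def local_connectivity_regression(
    neighbor_counts: pd.DataFrame,
    starter_mix: pd.DataFrame,
) -> pd.DataFrame:
    """Regress neighboring labeled-cell counts on starter subnucleus mix.

    ``neighbor_counts``: subjects x source structures; ``starter_mix``:
    subjects x target subnuclei (counts).  For every (source, target)
    pair, a simple OLS with two-sided slope p and 95% CI.  Predictors
    with zero variance are flagged (NaN results).
    """
    subjects = neighbor_counts.index.intersection(starter_mix.index)
    if len(subjects) < 4:
        raise InsufficientDataError("need >= 4 subjects")
    rows = []
    for target in starter_mix.columns:
        x = starter_mix.loc[subjects, target].to_numpy(float)
        for source in neighbor_counts.columns:
            y = neighbor_counts.loc[subjects, source].to_numpy(float)
            if np.ptp(x) == 0:
                rows.append((source, target, np.nan, np.nan, np.nan, np.nan, False))
                continue
            fit = stats.linregress(x, y)
            tcrit = stats.t.ppf(0.975, len(subjects) - 2)
            rows.append(
                (
                    source,
                    target,
                    float(fit.slope),
                    float(fit.pvalue),
                    float(fit.slope - tcrit * fit.stderr),
                    float(fit.slope + tcrit * fit.stderr),
                    True,
                )
            )
    return pd.DataFrame(
        rows, columns=["source", "target", "slope", "p", "ci_low", "ci_high", "defined"]
    )


def projection_bias(proj: pd.DataFrame, region: str | None = None) -> pd.Series:
    """Per-subject AP-bias: OLS slope of normalized fluorescence on AP level.

    Negative bias = rostrally weighted expression.  Raises if any
    subject has a single AP level (slope undefined).
    """
    _check_columns(proj, ("subject_id", "ap_level", "normalized_fluorescence"), "projection")
    df = proj if region is None else proj[proj["region"] == region]
    out = {}
    for subject, g in df.groupby("subject_id", sort=True):
        ap = g["ap_level"].to_numpy(float)
        if np.unique(ap).size < 2:
            raise InsufficientDataError(f"subject {subject}: need >= 2 AP levels")
        fit = stats.linregress(ap, g["normalized_fluorescence"].to_numpy(float))
        out[subject] = float(fit.slope)
    return pd.Series(out, name="bias")


def sidak_adjust(p: float | np.ndarray, m: int) -> np.ndarray | float:
    """Sidak correction for ``m`` comparisons: 1 - (1 - p)^m."""
    return 1.0 - (1.0 - np.asarray(p, dtype=float)) ** m


def compare_projection_targets(
    rostral: pd.DataFrame, caudal: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way (group x target) ANOVA with Sidak-adjusted per-target tests.

    Input frames follow the projection schema; fluorescence is averaged
    over AP levels per (subject, region) before testing.  Returns
    (anova_table, per_target) where per_target carries the group mean
    difference (rostral - caudal) and the Sidak-adjusted p.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    frames = []
    for name, df in (("rostral", rostral), ("caudal", caudal)):
        _check_columns(df, ("subject_id", "region", "normalized_fluorescence"), "projection")
        if df["subject_id"].nunique() < 2:
            raise InsufficientDataError(f"{name} group needs >= 2 subjects")
        mean = (
            df.groupby(["subject_id", "region"], sort=True)["normalized_fluorescence"]
            .mean()
            .reset_index()
        )
        mean["group"] = name
        frames.append(mean)
    data = pd.concat(frames, ignore_index=True)
    model = ols("normalized_fluorescence ~ C(group) * C(region)", data=data).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    targets = sorted(data["region"].unique())
    rows = []
    for target in targets:
        a = data.query("group == 'rostral' and region == @target")["normalized_fluorescence"]
        b = data.query("group == 'caudal' and region == @target")["normalized_fluorescence"]
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            p_raw = 1.0 if a.mean() == b.mean() else 0.0
        else:
            p_raw = float(stats.ttest_ind(a, b).pvalue)
        rows.append((target, float(a.mean() - b.mean()), p_raw))
    per_target = pd.DataFrame(rows, columns=["target", "difference", "p_raw"])
    per_target["p_adjusted"] = np.minimum(sidak_adjust(per_target["p_raw"], len(targets)), 1.0)
    return anova, per_target


def incidence_comparison(
    group_a: tuple[int, int], group_b: tuple[int, int]
) -> dict[str, float]:
    """Compare connectivity incidence between two groups of tested neurons.

    ``group_a`` and ``group_b`` are (responders, n) pairs of binary
    outcomes (e.g. 13/20 rostral neurons inhibited versus 1/21 caudal).
    Returns two-sided p from a Mann-Whitney rank test on the 0/1
    outcomes (tie-corrected) and from Fisher's exact test as a
    cross-check.
    """
    (ka, na), (kb, nb) = group_a, group_b
    if na < 1 or nb < 1:
        raise InsufficientDataError("both groups need n >= 1")
    if not (0 <= ka <= na and 0 <= kb <= nb):
        raise ValueError("responders must lie in [0, n]")
    a = np.r_[np.ones(ka), np.zeros(na - ka)]
    b = np.r_[np.ones(kb), np.zeros(nb - kb)]
    if ka / na == kb / nb:
        p_mw = 1.0
    else:
        p_mw = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)
    table = [[ka, na - ka], [kb, nb - kb]]
    p_fisher = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return {"p_mannwhitney": p_mw, "p_fisher": p_fisher}
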