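"""Group-level inference for nested (trials-within-subjects) measures.

The central tool is a hierarchical bootstrap: each replicate resamples
subjects with replacement, then resamples each drawn subject's trials with
replacement, and records the grand mean with subjects weighted equally, so
inference targets the subject level rather than pooled trials. Two groups'
replicate distributions are compared by the joint probability
p_boot = Pr(B >= A) over all replicate pairs, converted to a two-tailed
p-value as 2*min(p_boot, 1-p_boot).

Curve-shaped data (PSD, coherence; one curve per subject) are compared with
functional F tests: the frequency-averaged pointwise between/within variance
ratio, calibrated by permuting subject group labels. Within-subject
comparisons of the four hippocampal–prefrontal circuits use a
repeated-measures one-way ANOVA with Tukey post hoc when residuals pass a
Shapiro–Wilk normality screen, otherwise a Friedman test with Dunn post hoc.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupedValues",
    "BootstrapComparison",
    "FunctionalTestResult",
    "CircuitComparison",
    "hierarchical_bootstrap",
    "joint_prob_pboot",
    "two_tailed",
    "compare_grouped",
    "functional_two_sample_F",
    "functional_anova",
    "circuit_comparison",
    "alpha_policy",
]

ESTROUS_COMPARISON_STAGES = ("diestrus", "proestrus", "estrus")  # metestrus excluded


@dataclass
class GroupedValues:
    """Per-subject lists of per-trial scalar values for one group."""

    label: str
    values_by_subject: dict[str, np.ndarray]

    def __post_init__(self):
        if not self.values_by_subject:
            raise ValueError(f"group {self.label!r} is empty")
        clean = {}
        for sid, v in self.values_by_subject.items():
            v = np.asarray(v, dtype=np.float64).ravel()
            if v.size < 1:
                raise ValueError(f"subject {sid} in group {self.label!r} has no trials")
            clean[sid] = v
        self.values_by_subject = clean

    @property
    def n_subjects(self) -> int:
        return len(self.values_by_subject)

    @property
    def n_trials(self) -> int:
        return sum(len(v) for v in self.values_by_subject.values())

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str, value_col: str,
                   subject_col: str = "subject_id") -> "GroupedValues":
        groups = {sid: g[value_col].to_numpy() for sid, g in df.groupby(subject_col)}
        return cls(label=label, values_by_subject=groups)


@dataclass
class BootstrapComparison:
    group_a: str
    group_b: str
    n_boot: int
    seed: int
    reps_a: np.ndarray
    reps_b: np.ndarray
    p_boot: float
    p_two: float


@dataclass
class FunctionalTestResult:
    statistic: float
    p: float
    n_perm: int
    seed: int
    freq_range: tuple[float, float]


@dataclass
class CircuitComparison:
    method: str              # "rm_anova_tukey" or "friedman_dunn"
    statistic: float
    p: float
    posthoc: pd.DataFrame    # columns: pair_a, pair_b, statistic, p
    normality_p: float
    details: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# hierarchical bootstrap
# --------------------------------------------------------------------------

def hierarchical_bootstrap(group: GroupedValues, n_boot: int = 10_000,
                           seed: int = 0) -> np.ndarray:
    """Replicate means from the two-level (subjects, then trials) bootstrap.

    Each replicate draws ``n_subjects`` subjects with replacement; each drawn
    subject contributes the mean of a same-size resample of its own trials;
    the replicate value is the unweighted mean of those subject means.
    """
    subjects = list(group.values_by_subject)
    n_subj = len(subjects)
    if n_subj < 2:
        warnings.warn(f"group {group.label!r} has {n_subj} subject(s); "
                      "hierarchical bootstrap is degenerate", stacklevel=2)
    rng = np.random.default_rng(seed)
    subj_idx = rng.integers(n_subj, size=(n_boot, n_subj))
    # pre-draw, for every subject, a bootstrap trial-mean for each (replicate, slot)
    pool = np.empty((n_subj, n_boot, n_subj))
    for s, sid in enumerate(subjects):
        v = group.values_by_subject[sid]
        draws = rng.integers(len(v), size=(n_boot, n_subj, len(v)))
        pool[s] = v[draws].mean(axis=-1)
    gathered = pool[subj_idx, np.arange(n_boot)[:, None], np.arange(n_subj)[None, :]]
    return gathered.mean(axis=1)


def joint_prob_pboot(reps_a: np.ndarray, reps_b: np.ndarray) -> float:
    """p_boot = Pr(B >= A) over the full cross product of replicate pairs.

    Computed with a rank trick (equivalent to the Mann–Whitney count), the
    bin-width-to-zero limit of a joint-probability matrix.
    """
    a = np.sort(np.asarray(reps_a, dtype=np.float64).ravel())
    b = np.asarray(reps_b, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty replicate array")
    # for each b_j, count a_i <= b_j
    count = np.searchsorted(a, b, side="right").sum()
    return float(count) / (a.size * b.size)


def two_tailed(p_boot: float) -> float:
    """Convert a one-tailed joint probability to a two-tailed p-value,
    2*min(p_boot, 1-p_boot)."""
    if not 0.0 <= p_boot <= 1.0:
        raise ValueError(f"p_boot must lie in [0, 1], got {p_boot}")
    return 2.0 * min(p_boot, 1.0 - p_boot)


def compare_grouped(group_a: GroupedValues, group_b: GroupedValues,
                    n_boot: int = 10_000, seed: int = 0) -> BootstrapComparison:
    """Hierarchical-bootstrap comparison of two groups of nested values."""
    ss = np.random.SeedSequence(seed).spawn(2)
    seed_a = int(ss[0].generate_state(1)[0] % (2**31))
    seed_b = int(ss[1].generate_state(1)[0] % (2**31))
    reps_a = hierarchical_bootstrap(group_a, n_boot, seed_a)
    reps_b = hierarchical_bootstrap(group_b, n_boot, seed_b)
    pb = joint_prob_pboot(reps_a, reps_b)
    return BootstrapComparison(group_a=group_a.label, group_b=group_b.label,
                               n_boot=n_boot, seed=seed, reps_a=reps_a,
                               reps_b=reps_b, p_boot=pb, p_two=two_tailed(pb))


# --------------------------------------------------------------------------
# functional (curve-shape) tests
# --------------------------------------------------------------------------

def _pointwise_F(curves: np.ndarray, labels: np.ndarray) -> float:
    """Frequency-averaged pointwise one-way F statistic.

    ``curves`` is (n_curves x n_freqs); ``labels`` assigns each curve to a
    group. Pointwise F = MS_between / MS_within; the statistic integrates
    (averages) it over the frequency grid.
    """
    groups = np.unique(labels)
    k = len(groups)
    n = len(labels)
    grand = curves.mean(axis=0)
    ss_b = np.zeros(curves.shape[1])
    ss_w = np.zeros(curves.shape[1])
    for g in groups:
        sub = curves[labels == g]
        m = sub.mean(axis=0)
        ss_b += len(sub) * (m - grand) ** 2
        ss_w += ((sub - m) ** 2).sum(axis=0)
    ms_b = ss_b / (k - 1)
    ms_w = ss_w / max(n - k, 1)
    return float(np.mean(ms_b / np.maximum(ms_w, np.finfo(float).tiny)))


def functional_anova(curves_by_group: dict[str, np.ndarray], n_perm: int = 2000,
                     seed: int = 0,
                     freq_range: tuple[float, float] = (0.5, 100.0)
                     ) -> FunctionalTestResult:
    """Permutation functional ANOVA on k groups of curves (one per subject).

    The observed statistic is the frequency-integrated pointwise F; the null
    is built by permuting group labels across curves; the p-value uses the
    add-one rule (1 + #{perm >= obs}) / (1 + n_perm).
    """
    labels = []
    rows = []
    for g, arr in curves_by_group.items():
        arr = np.atleast_2d(np.asarray(arr, dtype=np.float64))
        if arr.shape[0] < 1:
            raise ValueError(f"group {g!r} has no curves")
        rows.append(arr)
        labels.extend([g] * arr.shape[0])
    widths = {r.shape[1] for r in rows}
    if len(widths) > 1:
        raise ValueError("all curves must share the frequency grid")
    curves = np.vstack(rows)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 groups")
    for g in np.unique(labels):
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} needs >= 2 curves")
    obs = _pointwise_F(curves, labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _pointwise_F(curves, perm) >= obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return FunctionalTestResult(statistic=obs, p=p, n_perm=n_perm, seed=seed,
                                freq_range=freq_range)


def functional_two_sample_F(curves_a: np.ndarray, curves_b: np.ndarray,
                            n_perm: int = 2000, seed: int = 0,
                            freq_range: tuple[float, float] = (0.5, 100.0)
                            ) -> FunctionalTestResult:
    """Two-group functional F test (the k=2 case of :func:`functional_anova`)."""
    return functional_anova({"a": curves_a, "b": curves_b}, n_perm=n_perm,
                            seed=seed, freq_range=freq_range)


# --------------------------------------------------------------------------
# within-subject circuit omnibus
# --------------------------------------------------------------------------

def _tukey_posthoc(data: np.ndarray, names: list[str], ms_error: float,
                   df_error: int) -> pd.DataFrame:
    """Tukey HSD on repeated-measures cell means via the studentized range."""
    n_subj, k = data.shape
    se = math.sqrt(ms_error / n_subj)
    rows = []
    means = data.mean(axis=0)
    for i, j in itertools.combinations(range(k), 2):
        q = abs(means[i] - means[j]) / se
        p = float(sps.studentized_range.sf(q, k, df_error))
        rows.append({"pair_a": names[i], "pair_b": names[j],
                     "statistic": q, "p": p})
    return pd.DataFrame(rows)


def _dunn_posthoc(data: np.ndarray, names: list[str]) -> pd.DataFrame:
    """Dunn's post hoc on Friedman within-subject ranks, Bonferroni-adjusted."""
    n_subj, k = data.shape
    ranks = sps.rankdata(data, axis=1)
    mean_ranks = ranks.mean(axis=0)
    se = math.sqrt(k * (k + 1) / (6.0 * n_subj))
    n_comp = k * (k - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        z = abs(mean_ranks[i] - mean_ranks[j]) / se
        p = min(1.0, 2.0 * sps.norm.sf(z) * n_comp)
        rows.append({"pair_a": names[i], "pair_b": names[j],
                     "statistic": z, "p": p})
    return pd.DataFrame(rows)


def circuit_comparison(subject_means: pd.DataFrame,
                       alpha_normality: float = 0.05) -> CircuitComparison:
    """Omnibus + post hoc comparison of circuits within subjects.

    ``subject_means`` is (subjects x circuits); a Shapiro–Wilk screen on the
    two-way residuals selects repeated-measures ANOVA with Tukey post hoc
    (normal) or Friedman with Dunn post hoc (non-normal).
    """
    data = subject_means.to_numpy(dtype=np.float64)
    names = list(subject_means.columns)
    n_subj, k = data.shape
    if n_subj < 3:
        raise ValueError("need >= 3 subjects for a within-subject comparison")
    if k < 2:
        raise ValueError("need >= 2 circuits")
    resid = data - data.mean(axis=1, keepdims=True) - data.mean(axis=0) + data.mean()
    if np.allclose(resid, 0.0, atol=1e-30):
        # degenerate: an additive subject+circuit model fits exactly
        cond_var = float(((data.mean(axis=0) - data.mean()) ** 2).sum())
        f = math.inf if cond_var > 0 else 0.0
        p = 0.0 if cond_var > 0 else 1.0
        posthoc = pd.DataFrame([
            {"pair_a": names[i], "pair_b": names[j],
             "statistic": math.inf if data[:, i].mean() != data[:, j].mean() else 0.0,
             "p": 0.0 if data[:, i].mean() != data[:, j].mean() else 1.0}
            for i, j in itertools.combinations(range(k), 2)])
        return CircuitComparison(method="rm_anova_tukey", statistic=f, p=p,
                                 posthoc=posthoc, normality_p=1.0)
    sw_p = float(sps.shapiro(resid.ravel()).pvalue)

    if sw_p >= alpha_normality:
        # repeated-measures one-way ANOVA
        ss_subj = k * ((data.mean(axis=1) - data.mean()) ** 2).sum()
        ss_cond = n_subj * ((data.mean(axis=0) - data.mean()) ** 2).sum()
        ss_err = (resid ** 2).sum()
        df_cond = k - 1
        df_err = (k - 1) * (n_subj - 1)
        ms_cond = ss_cond / df_cond
        ms_err = ss_err / df_err
        f = ms_cond / ms_err
        p = float(sps.f.sf(f, df_cond, df_err))
        posthoc = _tukey_posthoc(data, names, ms_err, df_err)
        return CircuitComparison(method="rm_anova_tukey", statistic=float(f), p=p,
                                 posthoc=posthoc, normality_p=sw_p,
                                 details={"df": (df_cond, df_err),
                                          "ss_subject": ss_subj})
    stat, p = sps.friedmanchisquare(*[data[:, i] for i in range(k)])
    posthoc = _dunn_posthoc(data, names)
    return CircuitComparison(method="friedman_dunn", statistic=float(stat),
                             p=float(p), posthoc=posthoc, normality_p=sw_p)


def alpha_policy(comparison_family: str) -> float:
    """Significance threshold per comparison family.

    ``two-group`` (independent data, e.g. male vs female) uses 0.05;
    ``estrous-pairwise`` uses 0.0167, correcting for the three pairwise
    stage comparisons.
    """
    if comparison_family == "two-group":
        return 0.05
    if comparison_family == "estrous-pairwise":
        return 0.0167
    raise ValueError(f"unknown comparison family {comparison_family!r}")
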