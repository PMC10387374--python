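"""Session statistics for nested (session -> neuron -> trial) neural data.

Implements the analysis battery used on recorded sessions: paired Wilcoxon
signed-rank task-modulation tests with Benjamini-Hochberg FDR control,
post-perturbation recovery-time estimation, across-trial ramping
classification by regression-slope confidence interval, the hierarchical
bootstrap for nested data, and the evidence-integration statistic on the
final 2 s window of a trial.

Conventions (the source procedures leave these open; they are frozen here):

* Wilcoxon: zero differences are dropped; ties get average ranks. For
  n <= 25 the p-value is exact, from a dynamic program over all 2^n sign
  assignments of the (possibly tied) ranks; above that, the normal
  approximation with tie correction is used. Two-sided p doubles the smaller
  tail (capped at 1).
* Hierarchical bootstrap: resample sessions with replacement, then for each
  drawn session that session's neuron count of neurons, then for each drawn
  neuron its trial count of trials — matching the size and shape of the
  original dataset. One-sided p uses the direction of the observed statistic
  with add-one smoothing, (k + 1)/(B + 1), so p is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

_EXACT_N_MAX = 25


# --------------------------------------------------------------------------
# Nested container
# --------------------------------------------------------------------------

@dataclass
class NestedRates:
    """Per-trial scalar rates nested as session -> neuron -> trials array.

    ``values[session_id][neuron_id]`` is a 1-D array of per-trial rates (Hz or
    any per-window mean). Convertible to/from a long-format DataFrame with
    columns (session, neuron, trial, rate).
    """

    values: dict

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("empty nesting")
        for s, neurons in self.values.items():
            if not neurons:
                raise ValueError(f"session {s!r} has no neurons")
            for nid in neurons:
                arr = np.asarray(neurons[nid], float)
                if arr.size == 0:
                    raise ValueError(f"neuron {nid!r} has no trials")
                neurons[nid] = arr

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "NestedRates":
        values: dict = {}
        for (s, n), grp in df.groupby(["session", "neuron"], sort=True):
            values.setdefault(s, {})[n] = grp.sort_values("trial")["rate"].to_numpy(float)
        return cls(values)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s, neurons in self.values.items():
            for n, arr in neurons.items():
                for t, r in enumerate(arr):
                    rows.append((s, n, t, r))
        return pd.DataFrame(rows, columns=["session", "neuron", "trial", "rate"])

    def flat(self) -> np.ndarray:
        return np.concatenate(
            [arr for neurons in self.values.values() for arr in neurons.values()]
        )


# --------------------------------------------------------------------------
# Wilcoxon signed-rank
# --------------------------------------------------------------------------

def _signed_ranks(diff: np.ndarray) -> np.ndarray:
    """Average ranks of |diff| (zeros already removed)."""
    return sstats.rankdata(np.abs(diff))


def _exact_sf_cdf(ranks2: np.ndarray, w2: int) -> tuple[float, float]:
    """P(W+ >= w2) and P(W+ <= w2) under the exact null, ranks doubled to ints."""
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    return float(counts[w2:].sum()), float(counts[: w2 + 1].sum())


def wilcoxon_signed_rank(
    paired_a, paired_b, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test; returns (W+ statistic, p-value).

    ``alternative='greater'`` tests a > b (positive differences).
    """
    a = np.asarray(paired_a, float)
    b = np.asarray(paired_b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diff = a - b
    diff = diff[diff != 0]
    n = diff.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    if n < 5:
        raise ValueError("need >= 5 nonzero paired differences")
    ranks = _signed_ranks(diff)
    w_pos = float(ranks[diff > 0].sum())

    if n <= _EXACT_N_MAX:
        ranks2 = np.round(2 * ranks).astype(int)
        w2 = int(round(2 * w_pos))
        sf, cdf = _exact_sf_cdf(ranks2, w2)
        if alternative == "greater":
            p = sf
        elif alternative == "less":
            p = cdf
        else:
            p = min(1.0, 2.0 * min(sf, cdf))
    else:
        mean = n * (n + 1) / 4.0
        # tie correction for the variance of W+
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z_hi = (w_pos - 0.5 - mean) / np.sqrt(var)
        z_lo = (w_pos + 0.5 - mean) / np.sqrt(var)
        sf = float(sstats.norm.sf(z_hi))
        cdf = float(sstats.norm.cdf(z_lo))
        if alternative == "greater":
            p = sf
        elif alternative == "less":
            p = cdf
        else:
            p = min(1.0, 2.0 * min(sf, cdf))
    return w_pos, float(p)


def benjamini_hochberg(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR procedure: (reject mask, adjusted p)."""
    p = np.asarray(pvals, float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


# --------------------------------------------------------------------------
# Task modulation / recovery / ramping
# --------------------------------------------------------------------------

def task_modulated(
    baseline: np.ndarray,
    windows: np.ndarray,
    alpha: float = 0.01,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Flag task-modulated neurons for one trial type.

    ``baseline`` is (neurons, trials): mean rate in the 1 s pre-cue window.
    ``windows`` is (neurons, n_windows, trials): mean rates in the sequential
    1 s windows from cue onset. A neuron is modulated iff any window differs
    from baseline (two-sided Wilcoxon) at ``alpha`` after BH correction
    pooled across all neurons x windows.
    """
    baseline = np.asarray(baseline, float)
    windows = np.asarray(windows, float)
    if windows.ndim != 3 or windows.shape[0] != baseline.shape[0]:
        raise ValueError("windows must be (neurons, n_windows, trials)")
    if baseline.shape[1] < 5:
        raise ValueError("need >= 5 trials")
    n_neurons, n_windows, _ = windows.shape
    pvals = np.ones((n_neurons, n_windows))
    for i in range(n_neurons):
        for w in range(n_windows):
            try:
                _, pvals[i, w] = wilcoxon_signed_rank(windows[i, w], baseline[i])
            except ValueError:  # all differences zero -> no evidence of change
                pvals[i, w] = 1.0
    reject, p_adj = benjamini_hochberg(pvals.ravel(), alpha=alpha)
    reject = reject.reshape(n_neurons, n_windows)
    p_adj = p_adj.reshape(n_neurons, n_windows)
    table = pd.DataFrame(
        {
            "neuron": np.repeat(np.arange(n_neurons), n_windows),
            "window": np.tile(np.arange(n_windows), n_neurons),
            "p_raw": pvals.ravel(),
            "p_adj": p_adj.ravel(),
            "significant": reject.ravel(),
        }
    )
    return reject.any(axis=1), table


def recovery_time(
    baseline: np.ndarray,
    post_windows: np.ndarray,
    window_s: float = 0.5,
    alpha: float = 0.01,
    n_consecutive: int = 3,
) -> np.ndarray:
    """Per-neuron time to baseline recovery after a transient perturbation.

    ``baseline`` is (neurons, trials) mean rates over the 2 s pre-perturbation
    window; ``post_windows`` is (neurons, n_windows, trials) over sequential
    ``window_s`` windows from perturbation onset. Recovery time is the start
    of the earliest window whose ``n_consecutive`` consecutive windows all
    show no significant change from baseline (two-sided Wilcoxon, BH across
    neurons x windows at ``alpha``). NaN marks neurons that never recover.
    """
    post_windows = np.asarray(post_windows, float)
    if post_windows.shape[1] < n_consecutive:
        raise ValueError(f"need >= {n_consecutive} post-onset windows")
    n_neurons, n_windows, _ = post_windows.shape
    pvals = np.ones((n_neurons, n_windows))
    for i in range(n_neurons):
        for w in range(n_windows):
            try:
                _, pvals[i, w] = wilcoxon_signed_rank(post_windows[i, w], baseline[i])
            except ValueError:
                pvals[i, w] = 1.0
    reject, _ = benjamini_hochberg(pvals.ravel(), alpha=alpha)
    sig = reject.reshape(n_neurons, n_windows)
    out = np.full(n_neurons, np.nan)
    for i in range(n_neurons):
        for w in range(n_windows - n_consecutive + 1):
            if not sig[i, w : w + n_consecutive].any():
                out[i] = w * window_s
                break
    return out


def classify_ramping(
    baseline_rates_by_trial: np.ndarray, alpha: float = 0.05
) -> tuple[str, float, float]:
    """Classify across-session ramping of pre-cue baseline rate.

    OLS of rate on trial index; two-sided p from the t-based confidence
    interval of the slope. Returns (label in {up, down, none}, slope, p).
    """
    y = np.asarray(baseline_rates_by_trial, float)
    if y.size < 10:
        raise ValueError("need >= 10 trials for ramping classification")
    x = np.arange(y.size, dtype=float)
    res = sstats.linregress(x, y)
    if res.pvalue < alpha:
        label = "up" if res.slope > 0 else "down"
    else:
        label = "none"
    return label, float(res.slope), float(res.pvalue)


# --------------------------------------------------------------------------
# Hierarchical bootstrap
# --------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    resampled_means: np.ndarray
    mean: float
    sem: float  # SD of the resampled means
    p_one_sided: float

    def __post_init__(self) -> None:
        if self.sem < 0 or not 0 <= self.p_one_sided <= 1:
            raise ValueError("invalid bootstrap result")


def hierarchical_bootstrap(
    data: NestedRates,
    statistic=None,
    n_iter: int = 100,
    seed: int = 0,
) -> BootstrapResult:
    """Three-level (session -> neuron -> trial) bootstrap with replacement.

    Each resample draws sessions to the original session count; within each
    drawn session, that session's neuron count of neurons; within each drawn
    neuron, that neuron's trial count of trials. ``statistic`` maps the
    resampled flat value array to a scalar (default: mean).
    """
    stat = statistic or np.mean
    rng = np.random.default_rng(seed)
    sessions = list(data.values.keys())
    resampled = np.empty(n_iter)
    for b in range(n_iter):
        chunks = []
        s_draw = rng.choice(len(sessions), size=len(sessions), replace=True)
        for si in s_draw:
            neurons = list(data.values[sessions[si]].values())
            n_draw = rng.choice(len(neurons), size=len(neurons), replace=True)
            for ni in n_draw:
                trials = neurons[ni]
                t_draw = rng.integers(0, trials.size, size=trials.size)
                chunks.append(trials[t_draw])
        resampled[b] = stat(np.concatenate(chunks))
    mean = float(resampled.mean())
    sem = float(resampled.std())
    observed = float(stat(data.flat()))
    if observed >= 0:
        k = int(np.sum(resampled <= 0))
    else:
        k = int(np.sum(resampled >= 0))
    p = (k + 1) / (n_iter + 1)  # add-one smoothing: p is never exactly 0
    return BootstrapResult(
        resampled_means=resampled, mean=mean, sem=sem, p_one_sided=float(p)
    )


def integration_statistic(
    traces: dict,
    bin_size: float,
    onset_bin: int,
    baseline_s: float = 2.0,
    final_window_s: tuple = (5.0, 7.0),
    n_iter: int = 100,
    seed: int = 0,
) -> BootstrapResult:
    """Evidence-integration statistic on the final 2 s window of a trial.

    ``traces[session][neuron]`` is (trials, bins) of rates; ``onset_bin``
    marks cue/perturbation onset. Per trial, the mean over the
    ``baseline_s`` pre-onset window is subtracted and the mean over the
    ``final_window_s`` (seconds from onset) window is taken; the hierarchical
    bootstrap of the grand mean gives SEM and a one-sided p for the null of
    zero integration.
    """
    nb = int(round(baseline_s / bin_size))
    f0 = onset_bin + int(round(final_window_s[0] / bin_size))
    f1 = onset_bin + int(round(final_window_s[1] / bin_size))
    if onset_bin - nb < 0:
        raise ValueError("baseline window does not fit before onset")
    values: dict = {}
    for s, neurons in traces.items():
        values[s] = {}
        for nid, arr in neurons.items():
            arr = np.asarray(arr, float)
            if arr.shape[1] < f1:
                raise ValueError("trials shorter than the final window")
            base = arr[:, onset_bin - nb : onset_bin].mean(axis=1)
            final = arr[:, f0:f1].mean(axis=1)
            values[s][nid] = final - base
    nested = NestedRates(values)
    return hierarchical_bootstrap(nested, n_iter=n_iter, seed=seed)
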