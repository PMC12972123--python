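"""Performance metrics and architecture comparison statistics.

Closed-loop predictions are scored per channel, in original units, over
the eval-masked samples with the relative root-mean-squared error
(rRMSE; RMSE divided by the target's range) and Pearson's correlation
coefficient.  Aggregation runs per channel -> mean within signal group ->
mean over groups -> mean over instance seeds, with correlations averaged
through Fisher's z.  Architecture contrasts use paired Wilcoxon
signed-rank tests on seed-matched aggregates after IQR outlier removal,
Holm–Bonferroni corrected; full generalised mixed-model analysis is
delegated to external tools via the exported long-format table.
"""

from __future__ import annotations

import itertools
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .architectures import (ArchitectureSpec, init_architecture,
                            run_test_closed_loop, train_teacher_forced)
from .partition import ExperimentSeries
from .rls import TrainConfig

__all__ = [
    "rrmse",
    "pearson_r",
    "fisher_z",
    "fisher_mean",
    "remove_outliers_iqr",
    "holm_bonferroni",
    "evaluate_architecture",
    "seed_summary",
    "architecture_summary",
    "compare_architectures",
]

PREDICTED_GROUPS = ("efference", "afference")


def rrmse(pred: np.ndarray, target: np.ndarray,
          mask: np.ndarray | None = None) -> float:
    """RMSE normalised by the range of the target, over masked samples."""
    pred = np.asarray(pred, dtype=float).ravel()
    target = np.asarray(target, dtype=float).ravel()
    if mask is not None:
        pred, target = pred[mask], target[mask]
    if pred.size < 2:
        raise ValueError("need at least 2 samples")
    span = target.max() - target.min()
    if span == 0:
        raise ValueError("zero target range: rRMSE undefined")
    return float(np.sqrt(np.mean((pred - target) ** 2)) / span)


def pearson_r(pred: np.ndarray, target: np.ndarray,
              mask: np.ndarray | None = None) -> float:
    """Product-moment correlation over masked samples; NaN if either series
    is constant (reported as missing and excluded from aggregation)."""
    pred = np.asarray(pred, dtype=float).ravel()
    target = np.asarray(target, dtype=float).ravel()
    if mask is not None:
        pred, target = pred[mask], target[mask]
    if pred.size < 2:
        raise ValueError("need at least 2 samples")
    if np.std(pred) == 0 or np.std(target) == 0:
        return float("nan")
    return float(np.corrcoef(pred, target)[0, 1])


def fisher_z(r) -> float:
    """Fisher transform atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1 for the Fisher transform")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def fisher_mean(rs) -> float:
    """Fisher-z average of correlations, back-transformed; ignores NaNs."""
    rs = np.asarray(rs, dtype=float)
    rs = rs[np.isfinite(rs)]
    if rs.size == 0:
        return float("nan")
    rs = np.clip(rs, -1 + 1e-15, 1 - 1e-15)
    return float(np.tanh(np.mean(np.arctanh(rs))))


def remove_outliers_iqr(values) -> np.ndarray:
    """Drop points outside 1.5 x the (0.25, 0.75) interquartile range."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values for IQR fences")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    keep = (v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)
    return v[keep]


def _iqr_keep_mask(v: np.ndarray) -> np.ndarray:
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)


def holm_bonferroni(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Holm adjustment; returns (adjusted p, reject flags)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj, adj <= alpha


def _train_seed(instance_seed: int) -> int:
    return int(np.random.SeedSequence([instance_seed, 101])
               .generate_state(1)[0] % (2 ** 31))


def evaluate_architecture(spec: ArchitectureSpec, series: ExperimentSeries,
                          train_cfg: TrainConfig, seed_list: list[int],
                          splits: tuple[str, ...] = ("basic", "morphing", "natural"),
                          ) -> pd.DataFrame:
    """Train and test one architecture across matched instance seeds.

    For each seed: fresh reservoir draw, teacher-forced training, then
    closed-loop execution on each requested test series.  Metrics are
    computed per channel in original (de-normalised) units over the
    eval mask.  A diverged instance is recorded with NaN metrics and
    ``diverged=True`` rather than aborting the sweep.
    """
    rows = []
    gw_train = series.goal_window(series.train)
    for inst_seed in seed_list:
        params = init_architecture(spec, inst_seed)
        cfg = replace(train_cfg, seed=_train_seed(inst_seed))
        try:
            trained = train_teacher_forced(spec, series.train, cfg,
                                           params=params, goal_window=gw_train)
        except FloatingPointError:
            for split in splits:
                rows.append(dict(architecture=spec.name, seed=inst_seed,
                                 split=split, series=-1, group="", channel="",
                                 rrmse=np.nan, correlation=np.nan, diverged=True))
            continue
        for split in splits:
            for series_idx, (test_series, mask) in enumerate(series.tests[split]):
                gw = series.goal_window(test_series)
                prefix_len = int(np.argmax(mask)) if not mask[0] else 0
                outputs, eval_mask = run_test_closed_loop(
                    trained, test_series.goal, gw, init_prefix_len=prefix_len)
                norm = series.normalizer
                groups = [g for g in ("goal", "efference", "afference")
                          if g in outputs]
                for g in groups:
                    pred = norm.inverse_group(g, outputs[g])
                    tgt = norm.inverse_group(g, test_series.group(g))
                    degen = norm.degenerate(g)
                    for ch in range(pred.shape[0]):
                        if degen[ch]:
                            continue  # constant training channel (tabletop z)
                        rows.append(dict(
                            architecture=spec.name, seed=inst_seed, split=split,
                            series=series_idx, group=g, channel=f"{g}_{ch + 1}",
                            rrmse=rrmse(pred[ch], tgt[ch], eval_mask),
                            correlation=pearson_r(pred[ch], tgt[ch], eval_mask),
                            diverged=False))
    return pd.DataFrame(rows)


def seed_summary(results: pd.DataFrame,
                 groups: tuple[str, ...] = PREDICTED_GROUPS) -> pd.DataFrame:
    """One row per (architecture, split, seed): group means, then the mean
    over groups (correlations pooled via Fisher z)."""
    df = results[results["group"].isin(groups) & ~results["diverged"]]
    out = []
    for (arch, split, seed), g in df.groupby(["architecture", "split", "seed"]):
        per_group = g.groupby("group").agg(
            rrmse=("rrmse", "mean"),
            correlation=("correlation", fisher_mean))
        out.append(dict(architecture=arch, split=split, seed=seed,
                        rrmse=float(per_group["rrmse"].mean()),
                        correlation=fisher_mean(per_group["correlation"])))
    return pd.DataFrame(out)


def architecture_summary(results: pd.DataFrame,
                         groups: tuple[str, ...] = PREDICTED_GROUPS) -> pd.DataFrame:
    """Seed-averaged headline numbers per architecture and split."""
    per_seed = seed_summary(results, groups)
    out = []
    for (arch, split), g in per_seed.groupby(["architecture", "split"]):
        out.append(dict(architecture=arch, split=split, n_seeds=len(g),
                        rrmse=float(g["rrmse"].mean()),
                        correlation=fisher_mean(g["correlation"])))
    return pd.DataFrame(out)


def compare_architectures(results: pd.DataFrame, alpha: float = 0.05,
                          groups: tuple[str, ...] = PREDICTED_GROUPS) -> pd.DataFrame:
    """Pairwise seed-matched architecture contrasts per split and metric.

    Per metric and split: seed-level aggregates, IQR outlier removal
    (a pair is dropped when either member is an outlier within its
    architecture's sample), Fisher transform for correlations, paired
    Wilcoxon signed-rank tests, Holm–Bonferroni correction across the
    architecture pairs, and a direction-of-effect summary.
    """
    per_seed = seed_summary(results, groups)
    archs = sorted(per_seed["architecture"].unique())
    if len(archs) < 2:
        raise ValueError("need at least two architectures to compare")
    rows = []
    for split in sorted(per_seed["split"].unique()):
        sub = per_seed[per_seed["split"] == split]
        for metric in ("rrmse", "correlation"):
            block = []
            for a, b in itertools.combinations(archs, 2):
                va = sub[sub["architecture"] == a].set_index("seed")[metric]
                vb = sub[sub["architecture"] == b].set_index("seed")[metric]
                seeds = va.index.intersection(vb.index)
                if len(seeds) < 5:
                    raise ValueError(f"fewer than 5 paired seeds for {a} vs {b}")
                xa, xb = va[seeds].to_numpy(), vb[seeds].to_numpy()
                keep = _iqr_keep_mask(xa) & _iqr_keep_mask(xb)
                xa, xb = xa[keep], xb[keep]
                if metric == "correlation":
                    xa = np.arctanh(np.clip(xa, -1 + 1e-15, 1 - 1e-15))
                    xb = np.arctanh(np.clip(xb, -1 + 1e-15, 1 - 1e-15))
                if np.allclose(xa, xb):
                    p, stat = 1.0, 0.0
                else:
                    res = sps.wilcoxon(xa, xb, zero_method="wilcox",
                                       method="auto")
                    p, stat = float(res.pvalue), float(res.statistic)
                diff = float(np.mean(xa - xb))
                better = (a if diff < 0 else b) if metric == "rrmse" else \
                         (a if diff > 0 else b)
                block.append(dict(split=split, metric=metric, arch_a=a, arch_b=b,
                                  n_pairs=int(keep.sum()), statistic=stat,
                                  p_value=p, mean_diff=diff, better=better))
            adj, rej = holm_bonferroni([r["p_value"] for r in block], alpha)
            for r, pa, rj in zip(block, adj, rej):
                r["p_adjusted"], r["significant"] = float(pa), bool(rj)
            rows.extend(block)
    return pd.DataFrame(rows)
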