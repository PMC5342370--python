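"""RPM normalization, low-expression filtering and rank-based DE.

Expression is represented as reads-per-million (RPM = count * 1e6 / library
size, library size = reads passing ingest filters).  Differential expression
between sample groups uses the two-sided Wilcoxon/Mann-Whitney rank-sum test
(exact enumeration when both groups have <= 8 samples, tie-corrected normal
approximation otherwise), fold change as the ratio of group medians, and
Benjamini-Hochberg FDR.  A feature enters the signature when |FC| >= 1.5 and
FDR <= 0.05 (both configurable).  Stage-wise comparisons against the
cirrhotic (CN) and progressed-tumor (pHCC) anchors use raw p <= 0.05 and are
summarized into per-feature expression patterns along hepatocarcinogenesis.
"""
from __future__ import annotations

import math
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from scipy.stats import wilcoxon as _signed_rank
from statsmodels.stats.multitest import multipletests

INTERMEDIATE_STAGES = ("LGDN", "HGDN", "eHCC")


def normalize_rpm(counts: pd.DataFrame, library_sizes: pd.Series | Mapping[str, float]
                  ) -> pd.DataFrame:
    """RPM = count * 1e6 / library size, per sample column."""
    lib = pd.Series(library_sizes)
    missing = [c for c in counts.columns if c not in lib.index]
    if missing:
        raise ValueError(f"no library size for samples: {missing}")
    zero = [c for c in counts.columns if lib[c] <= 0]
    if zero:
        raise ValueError(f"library size is zero for samples: {zero}")
    return counts.div(lib[counts.columns], axis=1) * 1e6


def _stage_groups(meta: pd.DataFrame, columns: Sequence[str]) -> dict[str, list[str]]:
    stage_of = dict(zip(meta["sample"], meta["stage"]))
    groups: dict[str, list[str]] = {}
    for c in columns:
        groups.setdefault(stage_of[c], []).append(c)
    return groups


def filter_low_expression(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    cpm_threshold: float = 1.0,
) -> tuple[list[str], pd.DataFrame]:
    """Retain features whose mean RPM exceeds the threshold in >= 1 stage group.

    Returns (retained feature ids, removal report with each feature's best
    group mean).
    """
    groups = _stage_groups(meta, matrix.columns)
    group_means = pd.DataFrame(
        {st: matrix[cols].mean(axis=1) for st, cols in groups.items()}
    )
    best = group_means.max(axis=1)
    retained = list(matrix.index[best > cpm_threshold])
    removed = matrix.index[best <= cpm_threshold]
    report = pd.DataFrame(
        {
            "best_group_mean_rpm": best[removed],
            "reason": f"mean RPM <= {cpm_threshold} in every group",
        }
    )
    report.index.name = "feature_id"
    return retained, report


# ---------------------------------------------------------------------------
# rank-sum test


def exact_rank_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided exact rank-sum p by full enumeration of C(n+m, n) labelings.

    Midranks handle ties; p = fraction of labelings whose rank-sum deviation
    from its null mean is at least the observed deviation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, N = len(x), len(x) + len(y)
    ranks = tuple(rankdata(np.concatenate([x, y])))
    mean = n * (N + 1) / 2.0
    obs = abs(sum(ranks[:n]) - mean)
    hits = total = 0
    for comb in combinations(range(N), n):
        dev = abs(sum(ranks[i] for i in comb) - mean)
        if dev >= obs - 1e-9:
            hits += 1
        total += 1
    return hits / total


def rank_sum_test(x: Sequence[float], y: Sequence[float], exact_max: int = 8) -> float:
    """Two-sided Mann-Whitney p: exact for small groups, asymptotic otherwise.

    Exact enumeration is used when both groups have at most ``exact_max``
    samples; larger designs use the tie-corrected normal approximation with
    continuity correction.  Identical pooled values give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 samples per group")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    if len(x) <= exact_max and len(y) <= exact_max:
        return exact_rank_p(x, y)
    return float(mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, in [0, 1], >= raw p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _median_fold_change(a: np.ndarray, b: np.ndarray, pseudocount: float = 0.5
                        ) -> tuple[float, float]:
    """(fc, log2fc): ratio of group medians, pseudocount added when either is 0."""
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if med_a == 0.0 or med_b == 0.0:
        med_a += pseudocount
        med_b += pseudocount
    fc = med_b / med_a
    return fc, math.log2(fc)


def wilcoxon_de(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    group_a: str = "CN",
    group_b: str = "pHCC",
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.05,
    paired: bool = False,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-feature rank-sum DE between two stage groups.

    FC = median(group_b) / median(group_a) (pseudocount when a median is 0);
    direction 'up' means overexpressed in ``group_b``.  BH adjustment is
    applied across the tested features; ``in_signature`` requires
    max(FC, 1/FC) >= ``fc_threshold`` and FDR <= ``fdr_threshold``.  With
    ``paired=True`` the Wilcoxon signed-rank test on patient-matched pairs is
    used instead of the unpaired form.
    """
    groups = _stage_groups(meta, matrix.columns)
    for g in (group_a, group_b):
        if g not in groups or len(groups[g]) < 2:
            raise ValueError(f"group {g!r} needs at least 2 samples")
    cols_a, cols_b = groups[group_a], groups[group_b]

    if paired:
        patient_of = dict(zip(meta["sample"], meta["patient"]))
        pa = {patient_of[c]: c for c in cols_a}
        pairs = [(pa[patient_of[c]], c) for c in cols_b if patient_of[c] in pa]
        if len(pairs) < 2:
            raise ValueError("fewer than 2 patient-matched pairs")

    rows = []
    for fid, row in matrix.iterrows():
        a = row[cols_a].to_numpy(dtype=float)
        b = row[cols_b].to_numpy(dtype=float)
        if paired:
            diffs = np.array([row[cb] - row[ca] for ca, cb in pairs], dtype=float)
            if np.all(diffs == 0):
                p = 1.0
            else:
                p = float(_signed_rank(diffs, zero_method="wilcox").pvalue)
        else:
            p = rank_sum_test(a, b)
        fc, log2fc = _median_fold_change(a, b, pseudocount)
        rows.append({"feature_id": fid, "fc": fc, "log2fc": log2fc, "p": p})
    res = pd.DataFrame(rows, columns=["feature_id", "fc", "log2fc", "p"]).set_index("feature_id")
    if res.empty:
        for col in ("fdr", "in_signature", "direction"):
            res[col] = pd.Series(dtype=object)
        return res
    res["fdr"] = bh_adjust(res["p"].to_numpy())
    abs_fc = np.maximum(res["fc"], 1.0 / res["fc"])
    res["in_signature"] = (abs_fc >= fc_threshold) & (res["fdr"] <= fdr_threshold)
    res["direction"] = np.where(res["fc"] >= 1.0, "up", "down")
    return res


# ---------------------------------------------------------------------------
# stage-wise patterns


def _compare(ref_vals: np.ndarray, vals: np.ndarray, alpha: float) -> str:
    """'up'/'down' if vals differ significantly from ref_vals, else 'ns'."""
    p = rank_sum_test(ref_vals, vals)
    if p > alpha:
        return "ns"
    delta = np.median(vals) - np.median(ref_vals)
    if delta == 0:
        delta = vals.mean() - ref_vals.mean()
    return "up" if delta > 0 else "down"


def _classify_pattern(vs_cn: Mapping[str, str], vs_phcc: Mapping[str, str],
                      end: str) -> str:
    inter = list(INTERMEDIATE_STAGES)
    if end == "ns" and all(vs_cn[s] == "ns" for s in inter) and all(
        vs_phcc[s] == "ns" for s in inter
    ):
        return "flat"
    # stage-restricted: one intermediate stage deviates from both anchors,
    # the others are quiet and the anchors agree with each other
    if end == "ns":
        hot = [s for s in inter if vs_cn[s] != "ns"]
        if len(hot) == 1 and vs_phcc[hot[0]] == vs_cn[hot[0]]:
            return f"{hot[0]}-restricted"
    if end != "ns":
        sig = [s for s in inter if vs_cn[s] == end]
        other = [s for s in inter if vs_cn[s] not in ("ns", end)]
        if not other:
            if not sig:
                return "pHCC-restricted"
            onset = None
            for i, s in enumerate(inter):
                if all(vs_cn[t] == end for t in inter[i:]) and all(
                    vs_cn[t] == "ns" for t in inter[:i]
                ):
                    onset = s
                    break
            if onset is not None:
                return f"{end}-from-{onset}"
    return "mixed"


def stage_patterns(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    alpha: float = 0.05,
    ref_stage: str = "CN",
    terminal_stage: str = "pHCC",
) -> pd.DataFrame:
    """Per-feature stage comparison table and pattern label.

    Each intermediate stage (LGDN, HGDN, eHCC) is tested against the
    cirrhotic reference and against progressed HCC with the two-sided
    rank-sum test at raw p <= ``alpha``; features are then labeled with a
    pattern string: 'flat', '<stage>-restricted', 'up-from-<stage>' /
    'down-from-<stage>' (deviating from CN from that stage onward, at
    pHCC-like levels), 'pHCC-restricted', or 'mixed'.
    """
    groups = _stage_groups(meta, matrix.columns)
    needed = [ref_stage, terminal_stage, *INTERMEDIATE_STAGES]
    missing = [s for s in needed if s not in groups]
    if missing:
        raise ValueError(f"stages missing from metadata: {missing}")

    rows = []
    for fid, row in matrix.iterrows():
        vals = {st: row[cols].to_numpy(dtype=float) for st, cols in groups.items()}
        vs_cn = {s: _compare(vals[ref_stage], vals[s], alpha) for s in INTERMEDIATE_STAGES}
        vs_phcc = {s: _compare(vals[terminal_stage], vals[s], alpha) for s in INTERMEDIATE_STAGES}
        end = _compare(vals[ref_stage], vals[terminal_stage], alpha)
        rec = {"feature_id": fid}
        for s in INTERMEDIATE_STAGES:
            rec[f"{s}_vs_{ref_stage}"] = vs_cn[s]
            rec[f"{s}_vs_{terminal_stage}"] = vs_phcc[s]
        rec[f"{terminal_stage}_vs_{ref_stage}"] = end
        rec["pattern"] = _classify_pattern(vs_cn, vs_phcc, end)
        rows.append(rec)
    return pd.DataFrame(rows).set_index("feature_id")


def flag_high_expression(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    rpm_cutoff: float = 5000.0,
) -> tuple[list[str], float]:
    """Features whose mean RPM within any one stage reaches the cutoff, and
    the flagged set's share of total RPM (the 'most of the piRNome' fraction)."""
    if matrix.empty:
        return [], 0.0
    groups = _stage_groups(meta, matrix.columns)
    group_means = pd.DataFrame(
        {st: matrix[cols].mean(axis=1) for st, cols in groups.items()}
    )
    flagged = list(matrix.index[group_means.max(axis=1) >= rpm_cutoff])
    total = float(matrix.to_numpy().sum())
    share = float(matrix.loc[flagged].to_numpy().sum()) / total if total > 0 else 0.0
    return flagged, share
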