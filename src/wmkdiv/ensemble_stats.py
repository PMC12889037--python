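"""Trajectory preprocessing, per-ensemble descriptors, and distribution tests.

The preprocessing conventions follow common MD practice for this kind of
comparative study: the first 20 ns of each trajectory are treated as the
equilibration offset, and cross-homolog comparisons use eight evenly spaced
conformations sampled between 25 and 95 ns at 10 ns intervals. Ensemble
descriptors (RMSD to a reference conformation, radius of gyration) are
summarized robustly as median and unscaled median absolute deviation, and
compared across homologs with pairwise Wilcoxon rank-sum tests under a
configurable multiple-testing adjustment (Holm by default).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .geometry import kabsch_superpose, radius_of_gyration
from .structio import Ensemble, Structure


@dataclass(frozen=True)
class EnsembleSummary:
    homolog_id: str
    metric: str  # "rmsd" | "rg"
    values: tuple
    median: float
    mad: float


def apply_equilibration_offset(ensemble: Ensemble, offset_ns: float = 20.0) -> Ensemble:
    """Drop frames before ``offset_ns`` (boundary inclusive: t >= offset kept)."""
    keep = [i for i, t in enumerate(ensemble.times_ns) if t >= offset_ns]
    if not keep:
        raise ValueError(
            f"{ensemble.homolog_id}: no frames at or after {offset_ns} ns "
            f"(trajectory ends at {ensemble.times_ns[-1]} ns)"
        )
    return ensemble.with_frames(
        [ensemble.frames[i] for i in keep], [ensemble.times_ns[i] for i in keep]
    )


def sample_frames(ensemble: Ensemble, start_ns: float = 25.0, stop_ns: float = 95.0, step_ns: float = 10.0) -> Ensemble:
    """Pick one frame per requested time on the regular grid start..stop/step.

    The nearest frame within ``step_ns / 2`` of each grid time is used; a grid
    time with no frame in tolerance is an error listing all missing times.
    """
    if stop_ns < start_ns or step_ns <= 0:
        raise ValueError("invalid sampling grid")
    wanted = np.arange(start_ns, stop_ns + step_ns / 2, step_ns)
    times = np.asarray(ensemble.times_ns)
    picked, missing = [], []
    for t in wanted:
        j = int(np.argmin(np.abs(times - t)))
        if abs(times[j] - t) <= step_ns / 2:
            picked.append(j)
        else:
            missing.append(float(t))
    if missing:
        raise ValueError(
            f"{ensemble.homolog_id}: no frame within {step_ns / 2} ns of requested "
            f"times {missing}"
        )
    if len(set(picked)) != len(picked):
        raise ValueError(f"{ensemble.homolog_id}: sampling grid maps two times to one frame")
    return ensemble.with_frames(
        [ensemble.frames[j] for j in picked], [ensemble.times_ns[j] for j in picked]
    )


def descriptor_series(ensemble: Ensemble, metric: str, reference: Structure | None = None) -> np.ndarray:
    """Per-frame descriptor values.

    ``rmsd_vs_reference`` superposes each frame independently onto the
    reference before measuring (so rigid-body motion contributes nothing);
    ``rg`` is the per-frame Cα radius of gyration in nm.
    """
    if metric == "rg":
        return np.array([radius_of_gyration(fr.coords) for fr in ensemble.frames])
    if metric == "rmsd_vs_reference":
        if reference is None:
            raise ValueError("rmsd_vs_reference requires a reference structure")
        if reference.residue_numbers != ensemble.residue_numbers:
            raise ValueError("reference residue set differs from ensemble")
        return np.array(
            [kabsch_superpose(fr.coords, reference.coords).rmsd for fr in ensemble.frames]
        )
    raise ValueError(f"unknown metric {metric!r}")


def summarize_median_mad(values) -> tuple:
    """(median, unscaled MAD): mad = median(|x − median(x)|), no 1.4826 factor."""
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("empty value sequence")
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med, mad


def summarize_ensemble(ensemble: Ensemble, metric: str, reference: Structure | None = None) -> EnsembleSummary:
    key = "rg" if metric == "rg" else "rmsd"
    series = descriptor_series(
        ensemble, "rg" if metric == "rg" else "rmsd_vs_reference", reference
    )
    med, mad = summarize_median_mad(series)
    return EnsembleSummary(ensemble.homolog_id, key, tuple(series), med, mad)


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> float:
    """Wilcoxon rank-sum (Mann–Whitney) p-value.

    Exact null enumeration when n_x + n_y <= 12 and the pooled sample is
    tie-free; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == pooled.size
    method = "exact" if (x.size + y.size <= 12 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method, use_continuity=True)
    return float(res.pvalue)


def pairwise_wilcoxon(groups: dict, adjust: str = "holm", alternative: str = "two-sided") -> list:
    """All unordered pairs of labeled samples, with adjusted p-values.

    Groups with fewer than 2 values are flagged (``skipped=True``) and not
    tested. ``adjust`` is one of none|holm|bonferroni|BH.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    usable = {k: np.asarray(v, float) for k, v in groups.items() if len(v) >= 2}
    skipped = sorted(set(groups) - set(usable))
    rows = []
    for a, b in itertools.combinations(sorted(usable), 2):
        rows.append(
            {"group_a": a, "group_b": b,
             "p_raw": wilcoxon_rank_sum(usable[a], usable[b], alternative)}
        )
    if rows and adjust != "none":
        key = {"holm": "holm", "bonferroni": "bonferroni", "BH": "fdr_bh"}[adjust]
        padj = multipletests([r["p_raw"] for r in rows], method=key)[1]
        for r, p in zip(rows, padj):
            r["p_adjusted"] = float(p)
    else:
        for r in rows:
            r["p_adjusted"] = r["p_raw"]
    for name in skipped:
        rows.append({"group_a": name, "group_b": "", "p_raw": float("nan"),
                     "p_adjusted": float("nan"), "skipped": True})
    return rows
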