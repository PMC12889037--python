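"""Per-ensemble descriptors after the 20 ns equilibration offset.

For every homolog: RMSD to its first equilibrated conformation and radius
of gyration per frame, summarized as median ± MAD, plus pairwise Wilcoxon
rank-sum tests (Holm-adjusted) on the Rg distributions. Mirrors the
comparison of within-protein conformational change across homologs.
"""

from pathlib import Path

from wmkdiv.cli import load_homolog_set
from wmkdiv.ensemble_stats import (
    apply_equilibration_offset, pairwise_wilcoxon, summarize_ensemble,
)
from wmkdiv.structio import write_table

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "family"
OUT = ROOT / "results" / "ensembles"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    hset = load_homolog_set(DATA)
    rows, rg = [], {}
    for r in hset:
        eq = apply_equilibration_offset(r.ensemble, 20.0)
        for metric in ("rg", "rmsd"):
            s = summarize_ensemble(eq, metric,
                                   reference=eq.frames[0] if metric == "rmsd" else None)
            rows.append({"homolog_id": r.id, "metric": s.metric,
                         "median": s.median, "mad": s.mad})
            if metric == "rg":
                rg[r.id] = list(s.values)
                print(f"{r.id}: median Rg {s.median:.2f} nm (mad {s.mad:.2f})")
    write_table(rows, OUT / "summary.tsv")
    wx = pairwise_wilcoxon(rg)
    write_table(wx, OUT / "wilcoxon_rg.tsv")
    sig = sum(1 for w in wx if not w.get("skipped") and w["p_adjusted"] < 0.05)
    print(f"Rg distributions differ (Holm-adjusted p < 0.05) in {sig}/{len(wx)} homolog pairs")


if __name__ == "__main__":
    main()
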