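"""Cross-homolog structural comparison.

TM-scores here are evaluated over a *fixed* residue correspondence taken
from the multiple sequence alignment (columns where neither sequence is
gapped), not from a structure-alignment search. Consequently absolute
values need not match a search-based aligner, which optimizes the
correspondence itself; the pipeline's claims are about orderings and
group contrasts, which are robust to this choice.

The score is the standard length-normalized similarity

    TM = (1/L) Σ_pairs 1 / (1 + (d_i/d0)²),
    d0 = max(1.24·(L−15)^(1/3) − 1.8, 0.5),

maximized over rigid superpositions of the fixed pair set by deterministic
iterative reweighted fitting seeded from fragment fits of length n, n/2 and
n/4: each iteration keeps pairs with d_i < 2·d0, refits on them, and
rescores; the best superposition seen wins.

Core residues — positions of minimal positional variability across
superposed conformations from many homologs — are found greedily: superpose
on the current set, remove the position of largest across-conformation
variance, repeat; the per-iteration trace is the analogue of a core
residue identification graph, and the default stopping rule cuts at the
knee of that trace.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .geometry import kabsch_superpose
from .structio import GAP, HomologSet, MSA, Structure
from .dynamics import PCAResult, _pca_from_coords

D0_MIN = 0.5


@dataclass(frozen=True)
class TMScoreResult:
    score: float
    d0: float
    n_pairs: int
    correspondence: tuple  # ((posA, posB), ...) as residue numbers
    normalization_length: int
    rotation: np.ndarray = None
    translation: np.ndarray = None


@dataclass(frozen=True)
class PairRecord:
    id_a: str
    conf_a: int
    id_b: str
    conf_b: int
    score: float
    comparison_class: str  # within_homolog | within_group | between_group


def tm_d0(normalization_length: int) -> float:
    if normalization_length < 1:
        raise ValueError("normalization_length must be >= 1")
    if normalization_length <= 15:
        return D0_MIN
    return max(1.24 * (normalization_length - 15) ** (1 / 3) - 1.8, D0_MIN)


def tm_score_at(A: np.ndarray, B: np.ndarray, rotation, translation, d0: float, L: int) -> float:
    """Evaluate the TM sum for A transformed by (rotation, translation) vs B."""
    moved = A @ np.asarray(rotation).T + translation
    d2 = np.sum((moved - B) ** 2, axis=1)
    return float(np.sum(1.0 / (1.0 + d2 / d0**2)) / L)


def tm_score_fixed(A: Structure, B: Structure, correspondence, normalization_length: int) -> TMScoreResult:
    """TM-score over a fixed correspondence, maximized over superpositions.

    ``correspondence`` is a sequence of (residue_number_A, residue_number_B)
    pairs. Deterministic: fragment-seeded iterative reweighted fitting.
    """
    corr = list(correspondence)
    if not corr:
        raise ValueError("empty correspondence")
    if normalization_length < 1:
        raise ValueError("normalization_length must be >= 1")
    idx_a = {n: i for i, n in enumerate(A.residue_numbers)}
    idx_b = {n: i for i, n in enumerate(B.residue_numbers)}
    ia = np.array([idx_a[p] for p, _ in corr])
    ib = np.array([idx_b[q] for _, q in corr])
    XA = A.coords[ia]
    XB = B.coords[ib]
    n = len(corr)
    L = normalization_length
    d0 = tm_d0(L)

    # seed superpositions: contiguous fragments of length n, n/2, n/4 at
    # half-fragment offsets (a sliding-fragment search in miniature)
    seeds = []
    if n <= 12:
        # tiny problems: every contiguous fragment is a seed
        frag_lens = range(3, n + 1)
    else:
        frag_lens = sorted({n, max(n // 2, 3), max(n // 4, 3)}, reverse=True)
    for frag_len in frag_lens:
        if frag_len > n:
            continue
        step = max(frag_len // 2, 1) if n > 12 else 1
        for start in range(0, n - frag_len + 1, step):
            seeds.append(np.arange(start, start + frag_len))

    best = (-1.0, None, None)
    for sel in seeds:
        try:
            sup = kabsch_superpose(XA[sel], XB[sel])
        except ValueError:
            continue
        R, t = sup.rotation, sup.translation
        score = tm_score_at(XA, XB, R, t, d0, L)
        if score > best[0]:
            best = (score, R, t)
        # iteratively reweighted fitting: TM-score weights concentrate the
        # superposition on the pairs that can still contribute
        for _ in range(20):
            moved = XA @ R.T + t
            d2 = np.sum((moved - XB) ** 2, axis=1)
            w = 1.0 / (1.0 + d2 / d0**2) ** 2
            try:
                sup = kabsch_superpose(XA, XB, weights=w)
            except ValueError:
                break
            new_score = tm_score_at(XA, XB, sup.rotation, sup.translation, d0, L)
            if new_score > best[0]:
                best = (new_score, sup.rotation, sup.translation)
            if new_score <= score + 1e-12:
                break
            score, R, t = new_score, sup.rotation, sup.translation
    score, R, t = best
    if R is None:
        # all seeds degenerate; fall back to whole-set fit
        sup = kabsch_superpose(XA, XB)
        R, t = sup.rotation, sup.translation
        score = tm_score_at(XA, XB, R, t, d0, L)
    return TMScoreResult(
        score=score,
        d0=d0,
        n_pairs=n,
        correspondence=tuple((int(p), int(q)) for p, q in corr),
        normalization_length=L,
        rotation=R,
        translation=t,
    )


def msa_correspondence(msa: MSA, id_a: str, id_b: str) -> list:
    """(posA, posB) pairs from MSA columns where neither sequence is gapped.

    Positions are 1-based indices into each ungapped sequence, matching the
    residue numbering of synthetic and freshly read structures.
    """
    row_a = msa.row(id_a)
    row_b = msa.row(id_b)
    pairs = []
    pa = pb = 0
    for ca, cb in zip(row_a, row_b):
        if ca != GAP:
            pa += 1
        if cb != GAP:
            pb += 1
        if ca != GAP and cb != GAP:
            pairs.append((pa, pb))
    return pairs


def tm_score_msa(A: Structure, B: Structure, msa: MSA, id_a: str | None = None,
                 id_b: str | None = None, normalize: str = "shorter") -> TMScoreResult:
    """MSA-guided TM-score between two conformations.

    Normalization length is the shorter chain by default (``normalize`` in
    {"shorter", "longer", "a", "b"}).
    """
    id_a = id_a or A.id
    id_b = id_b or B.id
    corr = msa_correspondence(msa, id_a, id_b)
    if len(corr) < 3:
        raise ValueError(f"fewer than 3 shared ungapped columns for {id_a}/{id_b}")
    la = len(msa.ungapped(id_a))
    lb = len(msa.ungapped(id_b))
    L = {"shorter": min(la, lb), "longer": max(la, lb), "a": la, "b": lb}[normalize]
    return tm_score_fixed(A, B, corr, L)


def pairwise_matrix(homolog_set: HomologSet, mode: str = "between_homolog",
                    normalize: str = "shorter", warn=None) -> list:
    """Exhaustive pairwise TM-scores over sampled conformations.

    ``mode`` selects within_homolog (all unordered conformation pairs inside
    each homolog) or between_homolog (all conformation pairs across distinct
    homologs). Homologs without an ensemble are skipped with a warning.
    Comparison classes on between rows are within_group / between_group from
    the records' group labels.
    """
    if mode not in ("within_homolog", "between_homolog"):
        raise ValueError(f"unknown mode {mode!r}")
    recs = []
    for rec in homolog_set:
        if rec.ensemble is None:
            if warn:
                warn(f"{rec.id}: no ensemble; skipped")
            continue
        recs.append(rec)
    counts = {len(r.ensemble) for r in recs}
    if len(counts) > 1:
        raise ValueError(f"ensembles have unequal frame counts: {sorted(counts)}")
    rows = []
    msa = homolog_set.msa
    if mode == "within_homolog":
        for rec in recs:
            frames = rec.ensemble.frames
            for i, j in itertools.combinations(range(len(frames)), 2):
                res = tm_score_msa(frames[i], frames[j], msa, rec.id, rec.id, normalize)
                rows.append(PairRecord(rec.id, i, rec.id, j, res.score, "within_homolog"))
        return rows
    group = {r.id: ("type-I" if r.group == "reference" else r.group) for r in recs}
    for ra, rb in itertools.combinations(recs, 2):
        cls = "within_group" if group[ra.id] == group[rb.id] else "between_group"
        for i, fa in enumerate(ra.ensemble.frames):
            for j, fb in enumerate(rb.ensemble.frames):
                res = tm_score_msa(fa, fb, msa, ra.id, rb.id, normalize)
                rows.append(PairRecord(ra.id, i, rb.id, j, res.score, cls))
    return rows


def group_summary(pair_table: list) -> dict:
    """Per-comparison-class (median, min, max, n) of scores."""
    out = {}
    classes = sorted({r.comparison_class for r in pair_table})
    for cls in classes:
        scores = np.array([r.score for r in pair_table if r.comparison_class == cls])
        out[cls] = {
            "median": float(np.median(scores)),
            "min": float(scores.min()),
            "max": float(scores.max()),
            "n": int(scores.size),
        }
    return out


# ---------------------------------------------------------------------------
# Core-residue finding and joint PCA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoreFindResult:
    core_positions: tuple  # reference positions retained
    trace: tuple  # (removed_position, max_variance_before_removal) per iteration
    stop: str


def _shared_column_positions(msa: MSA, ids) -> list:
    """Reference (first id) positions of columns ungapped in every given row."""
    rows = [msa.row(i) for i in ids]
    ref_pos = 0
    shared = []
    for j in range(msa.width):
        col = [r[j] for r in rows]
        if rows[0][j] != GAP:
            ref_pos += 1
        if all(c != GAP for c in col):
            shared.append((j, ref_pos))
    return shared


def stack_shared_coords(conformations: list, ids: list, msa: MSA):
    """Map conformations onto shared ungapped MSA columns.

    ``conformations`` is a list of Structures; ``ids`` gives each one's MSA
    row id (repeats allowed for several conformations of one homolog).
    Returns (coords (C, M, 3), reference_positions (M,)) where reference
    numbering follows the first id's ungapped sequence.
    """
    uniq = list(dict.fromkeys(ids))
    shared = _shared_column_positions(msa, uniq)
    if len(shared) < 4:
        raise ValueError("fewer than 4 shared ungapped columns")
    cols = [j for j, _ in shared]
    ref_positions = [p for _, p in shared]
    per_id_index = {}
    for uid in uniq:
        row = msa.row(uid)
        pos = 0
        col_to_pos = {}
        for j, c in enumerate(row):
            if c != GAP:
                pos += 1
                col_to_pos[j] = pos
        per_id_index[uid] = [col_to_pos[j] for j in cols]
    coords = np.empty((len(conformations), len(cols), 3))
    for k, (st, uid) in enumerate(zip(conformations, ids)):
        num_index = {n: i for i, n in enumerate(st.residue_numbers)}
        rows_idx = [num_index[p] for p in per_id_index[uid]]
        coords[k] = st.coords[rows_idx]
    return coords, ref_positions


def _superpose_stack(coords: np.ndarray, sel: np.ndarray, n_mean_iter: int = 3) -> np.ndarray:
    """Fit every conformation onto the iterated mean over selected columns."""
    out = coords.copy()
    target = out[0, sel]
    for _ in range(n_mean_iter):
        for k in range(out.shape[0]):
            sup = kabsch_superpose(out[k, sel], target)
            out[k] = sup.apply(out[k])
        target = out[:, sel].mean(0)
    return out


def core_find(conformations: list, ids: list, msa: MSA, stop: str = "knee",
              target_count: int | None = None, min_size: int = 4) -> CoreFindResult:
    """Iteratively superpose and strip high-variance positions to find a core.

    Each iteration superposes all conformations on the current position set,
    measures per-position variance (mean squared deviation from the
    across-conformation mean position), and removes the argmax. ``stop`` is
    ``"knee"`` (cut at the largest second difference of the max-variance
    trace) or ``"count"`` (stop when ``target_count`` positions remain).
    """
    if len(conformations) < 2:
        raise ValueError("need at least 2 conformations")
    if stop not in ("knee", "count"):
        raise ValueError(f"unknown stop rule {stop!r}")
    if stop == "count":
        if target_count is None:
            raise ValueError("stop='count' requires target_count")
        if target_count < 3:
            raise ValueError("target_count must be >= 3")
    coords, ref_positions = stack_shared_coords(conformations, ids, msa)
    m = coords.shape[1]
    active = np.ones(m, dtype=bool)
    trace = []  # (removed ref position, max variance at time of removal)
    states = [np.flatnonzero(active).copy()]
    limit = target_count if stop == "count" else min_size
    while active.sum() > limit:
        sel = np.flatnonzero(active)
        sup = _superpose_stack(coords, sel)
        var = ((sup[:, sel] - sup[:, sel].mean(0)) ** 2).sum(-1).mean(0)
        worst = int(np.argmax(var))
        trace.append((ref_positions[sel[worst]], float(var[worst])))
        active[sel[worst]] = False
        states.append(np.flatnonzero(active).copy())
    if stop == "count":
        core_idx = states[-1]
    else:
        # knee of the removal trace: the core is the terminal low-variance
        # plateau, so cut after the LAST removal that drops the remaining
        # maximal variance by a large factor; fall back to the largest
        # second difference of the log trace when no such drop exists
        vmax = np.array([v for _, v in trace])
        cut = len(vmax)
        if len(vmax) and vmax[0] <= 1e-10:
            cut = 0  # no positional variability at all: everything is core
        elif len(vmax) >= 2:
            logv = np.log(np.maximum(vmax, 1e-12))
            drops = logv[:-1] - logv[1:]
            big = np.flatnonzero(drops >= np.log(3.0))
            if len(big):
                cut = int(big[-1]) + 1
            elif len(vmax) >= 3:
                second_diff = logv[:-2] - 2 * logv[1:-1] + logv[2:]
                cut = int(np.argmax(second_diff)) + 1
        core_idx = states[cut]
    core = tuple(ref_positions[i] for i in core_idx)
    return CoreFindResult(core_positions=core, trace=tuple(trace), stop=stop)


def joint_pca(conformations: list, ids: list, msa: MSA, core_positions) -> PCAResult:
    """PCA over shared ungapped columns after superposition on the core set."""
    coords, ref_positions = stack_shared_coords(conformations, ids, msa)
    core = set(core_positions)
    sel = np.array([i for i, p in enumerate(ref_positions) if p in core])
    if len(sel) < 3:
        raise ValueError("core set covers fewer than 3 shared columns")
    sup = _superpose_stack(coords, sel)
    return _pca_from_coords(sup, ref_positions, labels=ids, core_positions=sorted(core))


def outlier_rank(pca: PCAResult, n_components: int = 3) -> list:
    """Rank homologs by distance from the global medoid and internal spread.

    Uses per-homolog centroids of projections onto the first ``n_components``
    PCs; the global medoid is the homolog centroid minimizing total distance
    to the others. Returns rows sorted by (centroid_distance, spread)
    descending, ties by id.
    """
    if pca.labels is None:
        raise ValueError("joint PCA result with homolog labels required")
    labels = list(pca.labels)
    homologs = sorted(set(labels))
    if len(homologs) < 3:
        raise ValueError("need at least 3 homologs")
    k = min(n_components, pca.projections.shape[1])
    proj = pca.projections[:, :k]
    centroids = {}
    spreads = {}
    for h in homologs:
        idx = [i for i, l in enumerate(labels) if l == h]
        pts = proj[idx]
        centroids[h] = pts.mean(0)
        if len(idx) < 2:
            spreads[h] = 0.0
        else:
            d = [np.linalg.norm(pts[i] - pts[j]) for i, j in itertools.combinations(range(len(idx)), 2)]
            spreads[h] = float(np.mean(d))
    cents = np.array([centroids[h] for h in homologs])
    total = np.array([np.linalg.norm(cents - c, axis=1).sum() for c in cents])
    medoid = homologs[int(np.argmin(total))]
    rows = []
    for h in homologs:
        rows.append(
            {
                "homolog_id": h,
                "centroid_distance": float(np.linalg.norm(centroids[h] - centroids[medoid])),
                "spread": spreads[h],
            }
        )
    rows.sort(key=lambda r: (-r["centroid_distance"], -r["spread"], r["homolog_id"]))
    return rows


def progressive_removal(pair_table: list, k: int) -> dict:
    """Greedily remove homologs to maximize the between-homolog median score.

    At each of ``k`` steps the homolog whose removal maximizes the median of
    remaining between-homolog scores is dropped (ties broken by lexicographic
    id). Returns the removal order and the median trajectory (baseline first,
    then after each removal).
    """
    between = [r for r in pair_table if r.comparison_class != "within_homolog"]
    homologs = sorted({r.id_a for r in between} | {r.id_b for r in between})
    if k >= len(homologs) - 1:
        raise ValueError(f"k={k} too large for {len(homologs)} homologs")

    def median_without(removed: set) -> float:
        scores = [r.score for r in between if r.id_a not in removed and r.id_b not in removed]
        return float(np.median(scores)) if scores else float("nan")

    removed: set = set()
    order = []
    medians = [median_without(removed)]
    for _ in range(k):
        candidates = sorted(set(homologs) - removed)
        best_id, best_med = None, -np.inf
        for h in candidates:  # sorted, so ties keep the lexicographically first
            med = median_without(removed | {h})
            if med > best_med + 1e-15:
                best_id, best_med = h, med
        removed.add(best_id)
        order.append(best_id)
        medians.append(best_med)
    return {"removal_order": order, "medians": medians}
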