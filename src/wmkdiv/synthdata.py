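"""Seeded generator of homolog families with known ground truth.

The generator emulates the design of a two-domain (two-HTH) homolog family
study: a reference protein with an N-terminal extension, two four-helix
domains separated by a long inter-domain linker (IDL) and a C-terminal
extension carrying accessory helices; a "type-I" group of close homologs
(substitution-only, 72–100% identity to the reference, same fold up to
small perturbations); and a "distant" group carrying ~32–36-residue IDL
deletions adjacent to the second domain, ~7–9-residue insertions
immediately downstream of it, low identity to the reference (~26–50%) but
appreciable identity to each other, and a repositioned second domain.

Every homolog gets a conformational ensemble with hinge motion: the region
C-terminal of a hinge residue inside the linker rotates about an axis
through the hinge by amplitude·sin(2π·t/period + phase), on top of small
per-atom jitter; terminal extensions and the linker receive extra
loop-flexibility noise, as flexible regions do in real trajectories. All
ground truth (labels, target identities, planted indels, per-frame hinge
angles, stable-domain positions) is recorded, so every pipeline stage has a
recovery test without external data. A single RNG stream per call makes
identical seeds reproduce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .seqdiv import DomainAnnotation, pairwise_identity
from .structio import AMINO_ACIDS, GAP, Ensemble, HomologRecord, HomologSet, MSA, Structure

CA_STEP = 3.8  # consecutive Cα–Cα distance, Å


@dataclass(frozen=True)
class SyntheticFamily:
    homolog_set: HomologSet
    truth: dict


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------

def make_helix(n: int, rise: float = 1.5, twist_deg: float = 100.0, radius: float = 2.3) -> np.ndarray:
    """Cα trace of an ideal α-helix (defaults: 1.5 Å rise, 100° twist, 2.3 Å radius)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n)
    theta = np.deg2rad(twist_deg) * i
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta), rise * i])


def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _append_helix(points: list, n: int, rng) -> None:
    local = make_helix(n)
    R = _random_rotation(rng)
    placed = local @ R.T
    if points:
        start = points[-1] + CA_STEP * _random_unit(rng)
    else:
        start = np.zeros(3)
    placed = placed - placed[0] + start
    points.extend(placed)


def _append_loop(points: list, n: int, rng) -> None:
    for _ in range(n):
        if points:
            points.append(points[-1] + CA_STEP * _random_unit(rng))
        else:
            points.append(np.zeros(3))


def arc_bridge(p: np.ndarray, q: np.ndarray, n_points: int, normal_hint: np.ndarray,
               step: float = CA_STEP) -> np.ndarray:
    """``n_points`` intermediate points on a circular arc from p to q.

    The arc length is (n_points + 1)·step so every consecutive distance,
    including the junctions at p and q, is ≈ step. Raises if the gap is too
    wide to bridge with the given number of residues.
    """
    chord = float(np.linalg.norm(q - p))
    arc = (n_points + 1) * step
    if arc < chord * 1.0001:
        raise ValueError(f"cannot bridge {chord:.1f} Å with {n_points} residues")
    if chord < 1e-9:
        raise ValueError("coincident arc endpoints")
    ratio = chord / arc

    def f(half):  # sinc(half) − ratio, half = θ/2 ∈ (0, π)
        return math.sin(half) / half - ratio

    half = brentq(f, 1e-9, math.pi - 1e-9)
    theta = 2 * half
    R = arc / theta
    u = (q - p) / chord
    v = normal_hint - np.dot(normal_hint, u) * u
    if np.linalg.norm(v) < 1e-9:
        v = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(v) < 1e-9:
            v = np.cross(u, [0.0, 1.0, 0.0])
    v = v / np.linalg.norm(v)
    mid = (p + q) / 2
    center = mid - v * R * math.cos(half)
    e1 = (p - center) / R
    e2 = (q - center - math.cos(theta) * (p - center)) / (R * math.sin(theta))
    alphas = theta * np.arange(1, n_points + 1) / (n_points + 1)
    return center + R * (np.cos(alphas)[:, None] * e1 + np.sin(alphas)[:, None] * e2)


def _append_domain(points: list, helices, loops, rng) -> None:
    for k, h in enumerate(helices):
        _append_helix(points, h, rng)
        if k < len(loops):
            _append_loop(points, loops[k], rng)


def make_two_domain_fold(n_domain_a: int = 55, n_linker: int = 62, n_domain_b: int = 55,
                         seed: int = 0, n_term_ext: int = 20, c_term_ext: int = 30):
    """Two multi-helix domains joined by a helix/loop linker, with extensions.

    Returns (Structure, [DomainAnnotation]) with annotations tiling the chain.
    Consecutive Cα distances stay within [3.6, 4.0] Å by construction.
    """
    for n in (n_domain_a, n_linker, n_domain_b):
        if n < 4:
            raise ValueError("segment sizes must be >= 4")
    rng = np.random.default_rng(seed)
    points: list = []

    def domain_plan(n):
        # four helices with short turns; absorb remainder into the last helix
        h = max((n - 7) // 4, 1)
        helices = [h, h, h, n - 7 - 3 * h]
        return helices, [2, 2, 3]

    def segment_plan(n, unit=15):
        plan = []
        remaining = n
        toggle = "loop"
        while remaining > 0:
            take = min(unit if toggle == "helix" else max(unit // 2, 4), remaining)
            plan.append((toggle, take))
            remaining -= take
            toggle = "helix" if toggle == "loop" else "loop"
        return plan

    _append_loop(points, n_term_ext, rng)
    ha, la = domain_plan(n_domain_a)
    _append_domain(points, ha, la, rng)
    for kind, n in segment_plan(n_linker):
        (_append_helix if kind == "helix" else _append_loop)(points, n, rng)
    hb, lb = domain_plan(n_domain_b)
    _append_domain(points, hb, lb, rng)
    for kind, n in segment_plan(c_term_ext, unit=10):
        (_append_helix if kind == "helix" else _append_loop)(points, n, rng)

    coords = np.array(points)
    total = len(coords)
    a0 = n_term_ext + 1
    a1 = n_term_ext + n_domain_a
    l1 = a1 + n_linker
    b1 = l1 + n_domain_b
    annotations = [
        DomainAnnotation("N-ext", 1, n_term_ext, "extension"),
        DomainAnnotation("N-domain", a0, a1, "HTH"),
        DomainAnnotation("linker", a1 + 1, l1, "IDL"),
        DomainAnnotation("C-domain", l1 + 1, b1, "HTH"),
        DomainAnnotation("C-ext", b1 + 1, total, "extension"),
    ]
    st = Structure("fold", tuple(range(1, total + 1)), "A" * total, coords)
    return st, annotations


def _swing_axis(coords: np.ndarray, hinge_idx: int) -> np.ndarray:
    # perpendicular to both domain directions: open/close swing motion with
    # visible counter-rotation of the two blocks after whole-chain fitting
    h = coords[hinge_idx]
    ca = coords[:hinge_idx].mean(0)
    cb = coords[hinge_idx + 1 :].mean(0)
    axis = np.cross(cb - h, ca - h)
    nrm = np.linalg.norm(axis)
    if nrm < 1e-9:
        return np.array([0.0, 0.0, 1.0])
    return axis / nrm


def _enforce_v_angle(coords: np.ndarray, hinge_idx: int, target_deg: float = 60.0,
                     n_iter: int = 4) -> np.ndarray:
    """Rotate the tail so the two blocks form a V of ``target_deg`` at the hinge.

    A closing-hinge architecture needs both blocks on the same side of the
    swing axis; random chain growth often leaves them at an obtuse angle.
    """
    out = coords.copy()
    for _ in range(n_iter):
        h = out[hinge_idx]
        ca = out[:hinge_idx].mean(0)
        cb = out[hinge_idx + 1 :].mean(0)
        va, vb = ca - h, cb - h
        cosang = np.dot(va, vb) / (np.linalg.norm(va) * np.linalg.norm(vb))
        ang = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
        delta = ang - target_deg
        if abs(delta) < 1.0:
            break
        axis = np.cross(vb, va)
        nrm = np.linalg.norm(axis)
        if nrm < 1e-9:
            break
        out = _rotate_tail(out, hinge_idx, axis / nrm, delta)
    return out


def _rotate_tail(coords: np.ndarray, hinge_idx: int, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    out = coords.copy()
    R = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()
    pivot = coords[hinge_idx]
    out[hinge_idx + 1 :] = (coords[hinge_idx + 1 :] - pivot) @ R.T + pivot
    return out


def make_hinge_ensemble(structure: Structure, hinge_position: int, amplitude_deg: float,
                        n_frames: int | None = None, times_ns=None, jitter_sigma: float = 0.0,
                        seed: int = 0, period_ns: float = 100.0, phase: float = 0.0,
                        flexible_positions=None, flexible_sigma: float = 0.0,
                        soft_positions=None, soft_sigma: float = 0.0):
    """Hinge-motion ensemble: tail rotation angle_t = A·sin(2π t/period + φ).

    Residues after ``hinge_position`` rotate about an axis through the hinge
    Cα; every atom gets Gaussian jitter of ``jitter_sigma`` Å. Residues in
    ``flexible_positions`` get extra loop-flexibility noise of
    ``flexible_sigma`` Å, and ``soft_positions`` (e.g. the mobile domain,
    internally less ordered than the anchor domain) get ``soft_sigma`` Å.
    Returns (Ensemble, truth_angles).
    """
    if times_ns is None:
        if n_frames is None:
            raise ValueError("give times_ns or n_frames")
        times_ns = np.linspace(0.0, 100.0, n_frames)
    times_ns = np.asarray(times_ns, float)
    numbers = structure.residue_numbers
    if hinge_position not in numbers:
        raise ValueError(f"hinge position {hinge_position} not in structure")
    hinge_idx = numbers.index(hinge_position)
    if hinge_idx < 1 or hinge_idx >= len(numbers) - 1:
        raise ValueError("hinge must be interior")
    rng = np.random.default_rng(seed)
    axis = _swing_axis(structure.coords, hinge_idx)
    def _indices(positions):
        if not positions:
            return None
        wanted = set(positions)
        return np.array([i for i, n in enumerate(numbers) if n in wanted])

    flex_idx = _indices(flexible_positions)
    soft_idx = _indices(soft_positions)
    frames, angles = [], []
    for t in times_ns:
        angle = amplitude_deg * math.sin(2 * math.pi * t / period_ns + phase)
        coords = _rotate_tail(structure.coords, hinge_idx, axis, angle)
        if jitter_sigma > 0:
            coords = coords + rng.normal(scale=jitter_sigma, size=coords.shape)
        if flex_idx is not None and flexible_sigma > 0 and len(flex_idx):
            coords[flex_idx] += rng.normal(scale=flexible_sigma, size=(len(flex_idx), 3))
        if soft_idx is not None and soft_sigma > 0 and len(soft_idx):
            coords[soft_idx] += rng.normal(scale=soft_sigma, size=(len(soft_idx), 3))
        frames.append(structure.with_coords(coords))
        angles.append(angle)
    return Ensemble(structure.id, frames, times_ns), angles


# ---------------------------------------------------------------------------
# Sequence mutation toward a target identity
# ---------------------------------------------------------------------------

def _similar_residues():
    blosum = substitution_matrices.load("BLOSUM62")
    sim = {}
    for a in AMINO_ACIDS:
        sim[a] = [b for b in AMINO_ACIDS if b != a and blosum[a, b] >= 0]
        if not sim[a]:
            sim[a] = [b for b in AMINO_ACIDS if b != a]
    return sim


_SIMILAR = _similar_residues()


def _substitute(aa: str, rng, copy_char: str | None = None, copy_prob: float = 0.0) -> str:
    if copy_char is not None and copy_char != aa and rng.random() < copy_prob:
        return copy_char
    if rng.random() < 0.7:
        choices = _SIMILAR[aa]
    else:
        choices = [b for b in AMINO_ACIDS if b != aa]
    return choices[rng.integers(len(choices))]


def mutate_to_identity(reference: str, base: str, target: float, rng,
                       mutable_indices=None, tol: float = 0.02, max_rounds: int = 60,
                       copy_map: dict | None = None, copy_prob: float = 0.0,
                       prefer_indices=None) -> str:
    """Mutate ``base`` until pairwise_identity(reference, result) ≈ target.

    ``base`` may already carry indels relative to ``reference``. ``copy_map``
    optionally maps base indices to residues of a sibling sequence, copied
    with probability ``copy_prob``, and ``prefer_indices`` are mutated first —
    together these correlate two mutants as shared ancestry would. Raises if
    the target is unattainable within tolerance.
    """
    if not (0.0 < target <= 1.0):
        raise ValueError("target identity must be in (0, 1]")
    base_chars = list(base)
    n = len(base_chars)
    mutable = list(mutable_indices) if mutable_indices is not None else list(range(n))
    if prefer_indices:
        pref = set(prefer_indices)
        first = [k for k, i in enumerate(mutable) if i in pref]
        rest = [k for k, i in enumerate(mutable) if i not in pref]
        order = [first[j] for j in rng.permutation(len(first))] + \
                [rest[j] for j in rng.permutation(len(rest))]
    else:
        order = list(rng.permutation(len(mutable)))
    mutated: dict = {}  # index -> original char
    current = list(base_chars)
    ident = pairwise_identity(reference, "".join(current))
    est_cols = max(len(reference), n)
    for _ in range(max_rounds):
        if abs(ident - target) <= tol:
            return "".join(current)
        delta = max(1, round(abs(ident - target) * est_cols * 0.8))
        if ident > target:
            # mutate more positions
            added = 0
            while order and added < delta:
                i = mutable[order.pop(0)]
                if i in mutated:
                    continue
                mutated[i] = current[i]
                copy_char = copy_map.get(i) if copy_map else None
                current[i] = _substitute(current[i], rng, copy_char, copy_prob)
                added += 1
            if added == 0:
                break
        else:
            # revert some mutations
            reverted = 0
            for i in list(mutated):
                if reverted >= delta:
                    break
                current[i] = mutated.pop(i)
                order.append(mutable.index(i))
                reverted += 1
            if reverted == 0:
                break
        ident = pairwise_identity(reference, "".join(current))
    if abs(ident - target) <= 0.03:
        return "".join(current)
    raise ValueError(
        f"could not reach identity {target:.2f} (achieved {ident:.2f}) "
        f"for sequence of length {n}"
    )


# ---------------------------------------------------------------------------
# Family generation
# ---------------------------------------------------------------------------

def _band_draw(rng, band, margin: float = 0.03) -> float:
    lo, hi = band
    lo2, hi2 = lo + margin, hi - margin
    if lo2 >= hi2:
        lo2, hi2 = lo, hi
    return float(rng.uniform(lo2, hi2))


def make_family(reference=None, n_type1: int = 5, n_distant: int = 2,
                identity_band_type1=(0.72, 1.0), identity_band_distant=(0.26, 0.50),
                linker_deletion=(32, 36), post_domain_insertion=(7, 9), seed: int = 0,
                times_ns=None, hinge_amplitude_deg: float = 15.0,
                jitter_sigma: float = 0.15, struct_jitter_sigma: float = 0.25,
                distant_pose_offset_deg: float = 50.0, flexible_sigma: float = 0.9,
                soft_sigma: float = 0.8, segment_conf_sigma: float = 2.0,
                pose_wobble_deg: float = 18.0, cext_scatter_deg: float = 60.0,
                domain_b_conf_sigma: float = 1.0) -> SyntheticFamily:
    """Generate a homolog family with full ground truth.

    The family comprises the reference, ``n_type1`` substitution-only close
    homologs and ``n_distant`` divergent homologs with planted IDL deletions,
    post-domain insertions and a repositioned C-domain. Each homolog carries
    a hinge-motion ensemble on the time grid ``times_ns`` (default 0–100 ns
    every 5 ns, so a 20 ns equilibration offset and a 25–95/10 sampling grid
    both apply cleanly).
    """
    for band in (identity_band_type1, identity_band_distant):
        if not (0.0 < band[0] <= band[1] <= 1.0):
            raise ValueError(f"identity band {band} outside (0, 1]")
    rng = np.random.default_rng(seed)
    if times_ns is None:
        times_ns = np.arange(0.0, 100.0 + 1e-9, 5.0)
    times_ns = np.asarray(times_ns, float)

    if reference is None:
        # accept only folds in which both domains have a real lever arm at
        # the hinge (>= 20 Å from domain centroid to the hinge residue):
        # the open/close hinge architecture presumes both blocks swing
        for _ in range(50):
            ref_struct, annotations = make_two_domain_fold(seed=int(rng.integers(2**31)))
            ann = {a.name: a for a in annotations}
            linker = ann["linker"]
            hinge = linker.start + linker.length // 2
            coords = _enforce_v_angle(ref_struct.coords, hinge - 1)
            h = coords[hinge - 1]
            da, db = ann["N-domain"], ann["C-domain"]
            r_a = np.linalg.norm(coords[da.start - 1 : da.end].mean(0) - h)
            r_b = np.linalg.norm(coords[db.start - 1 : db.end].mean(0) - h)
            if r_a >= 20.0 and r_b >= 20.0:
                break
        else:
            raise RuntimeError("could not draw a fold with hinge lever arms")
        ref_struct = ref_struct.with_coords(coords)
    else:
        ref_struct, annotations = reference
    ann = {a.name: a for a in annotations}
    total = len(ref_struct)
    ref_seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=total))
    ref_struct = Structure("ref", ref_struct.residue_numbers, ref_seq, ref_struct.coords)

    linker = ann["linker"]
    dom_a = ann["N-domain"]
    dom_b = ann["C-domain"]
    ref_hinge = linker.start + linker.length // 2
    if reference is not None:
        ref_struct = ref_struct.with_coords(
            _enforce_v_angle(ref_struct.coords, ref_hinge - 1)
        )

    groups = {"ref": "reference"}
    targets = {"ref": 1.0}
    sequences = {"ref": ref_seq}
    structures = {"ref": ref_struct}
    indels: dict = {"ref": []}
    hinge_positions = {"ref": ref_hinge}
    domain_maps = {"ref": annotations}

    # --- type-I homologs: substitutions only, reference fold + jitter
    for k in range(n_type1):
        hid = f"t{k + 1}"
        target = _band_draw(rng, identity_band_type1)
        seq = mutate_to_identity(ref_seq, ref_seq, target, rng)
        coords = ref_struct.coords + rng.normal(scale=struct_jitter_sigma, size=(total, 3))
        structures[hid] = Structure(hid, ref_struct.residue_numbers, seq, coords)
        sequences[hid] = seq
        groups[hid] = "type-I"
        targets[hid] = target
        indels[hid] = []
        hinge_positions[hid] = hinge_positions["ref"]
        domain_maps[hid] = annotations

    # --- distant homologs: IDL deletion + post-domain insertion + repositioned C-domain
    del_lengths, ins_lengths, ins_chars_all = [], [], []
    first_distant_seq = None
    first_distant_refmap = None
    for k in range(n_distant):
        hid = f"d{k + 1}"
        d = int(rng.integers(linker_deletion[0], linker_deletion[1] + 1))
        ins = int(rng.integers(post_domain_insertion[0], post_domain_insertion[1] + 1))
        if d >= linker.length - 4:
            raise ValueError("deletion leaves too little linker")
        del_start = linker.end - d + 1  # adjacent to the C-domain
        del_positions = list(range(del_start, linker.end + 1))
        ins_anchor = dom_b.end

        coords = ref_struct.coords.copy()
        # close the deletion gap: translate the post-deletion part next to the
        # last kept linker residue, preserving C-domain internal geometry
        prev_idx = del_start - 2  # 0-based index of last kept residue
        post = coords[linker.end :]  # C-domain onward (0-based linker.end == pos linker.end+1)
        u = post[0] - coords[prev_idx]
        u = u / np.linalg.norm(u)
        shift = coords[prev_idx] + CA_STEP * u - post[0]
        post = post + shift
        kept = np.vstack([coords[: del_start - 1], post])
        # repositioned C-domain: rotate the post-junction part about the hinge
        pose = distant_pose_offset_deg + float(rng.uniform(-3.0, 3.0))
        kept = _rotate_tail(kept, prev_idx, _random_unit(rng), pose)
        # insertion bulge immediately downstream of the C-domain
        ins_at = ins_anchor - d - 1  # 0-based index of the anchor residue in kept
        hint = kept[ins_at] - kept.mean(0)
        bridge = arc_bridge(kept[ins_at], kept[ins_at + 1], ins, hint)
        coords_new = np.vstack([kept[: ins_at + 1], bridge, kept[ins_at + 1 :]])
        coords_new = coords_new + rng.normal(scale=struct_jitter_sigma, size=coords_new.shape)

        # sequence: apply the same indels, then mutate toward the target identity
        base_chars = [c for p, c in enumerate(ref_seq, start=1) if p not in set(del_positions)]
        ins_chars = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=ins))
        ins_base_at = ins_anchor - d  # chars before the insertion in base coordinates
        base = "".join(base_chars[:ins_base_at]) + ins_chars + "".join(base_chars[ins_base_at:])
        # map base indices -> reference positions (for correlating the mutants)
        ref_positions_of_base = [p for p in range(1, total + 1) if p not in set(del_positions)]
        refmap = {}
        for i in range(len(base)):
            if i < ins_base_at:
                refmap[i] = ref_positions_of_base[i]
            elif i >= ins_base_at + ins:
                refmap[i] = ref_positions_of_base[i - ins]
        mutable = [i for i in range(len(base)) if i in refmap]  # inserts stay as drawn
        target = _band_draw(rng, identity_band_distant)
        copy_map = None
        prefer = None
        if first_distant_seq is not None:
            inv_first = {p: j for j, p in first_distant_refmap.items()}
            copy_map = {
                i: first_distant_seq[inv_first[refmap[i]]]
                for i in mutable
                if refmap[i] in inv_first
            }
            prefer = [
                i for i in mutable
                if refmap[i] in inv_first
                and first_distant_seq[inv_first[refmap[i]]] != ref_seq[refmap[i] - 1]
            ]
        seq = mutate_to_identity(
            ref_seq, base, target, rng, mutable_indices=mutable,
            copy_map=copy_map, copy_prob=0.35, prefer_indices=prefer,
        )
        if first_distant_seq is None:
            first_distant_seq = seq
            first_distant_refmap = refmap

        L = len(seq)
        structures[hid] = Structure(hid, tuple(range(1, L + 1)), seq, coords_new)
        sequences[hid] = seq
        groups[hid] = "distant"
        targets[hid] = target
        indels[hid] = [("deletion", del_start, d), ("insertion", ins_anchor, ins)]
        del_lengths.append(d)
        ins_lengths.append(ins)
        ins_chars_all.append(ins_chars)
        new_linker_len = linker.length - d
        hinge_positions[hid] = linker.start + new_linker_len // 2
        domain_maps[hid] = [
            DomainAnnotation("N-ext", 1, ann["N-ext"].end, "extension"),
            DomainAnnotation("N-domain", dom_a.start, dom_a.end, "HTH"),
            DomainAnnotation("linker", linker.start, linker.end - d, "IDL"),
            DomainAnnotation("C-domain", dom_b.start - d, dom_b.end - d, "HTH"),
            DomainAnnotation("C-ext", dom_b.end - d + 1, L, "extension"),
        ]

    # --- ground-truth MSA: reference columns plus one insertion block
    ins_block = max(ins_lengths) if ins_lengths else 0
    ins_anchor = dom_b.end
    rows, ids = [], []
    order = ["ref"] + [f"t{k + 1}" for k in range(n_type1)] + [f"d{k + 1}" for k in range(n_distant)]
    for hid in order:
        seq = sequences[hid]
        if groups[hid] != "distant":
            row = seq[:ins_anchor] + GAP * ins_block + seq[ins_anchor:]
        else:
            dels = {p for kind, start, ln in indels[hid] if kind == "deletion"
                    for p in range(start, start + ln)}
            ins_len = next(ln for kind, _, ln in indels[hid] if kind == "insertion")
            chars = []
            si = 0
            for p in range(1, total + 1):
                if p in dels:
                    chars.append(GAP)
                else:
                    chars.append(seq[si])
                    si += 1
                if p == ins_anchor:
                    chars.append(seq[si : si + ins_len] + GAP * (ins_block - ins_len))
                    si += ins_len
            row = "".join(chars)
        rows.append(row)
        ids.append(hid)
    msa = MSA(tuple(ids), tuple(rows))

    # --- ensembles with hinge motion and flexible-region noise
    records = []
    hinge_angles = {}
    for hid in order:
        st = structures[hid]
        dmap = {a.name: a for a in domain_maps[hid]}
        # each homolog adopts its own static conformation of the flexible
        # parts: a pose wobble of the post-hinge block (about the axis that
        # spares the N-terminal anchor), its own C-extension orientation, and
        # its own linker / C-extension backbone noise — flexible segments are
        # not shared rigid bodies across homologs
        coords = st.coords.copy()
        hinge_idx = hinge_positions[hid] - 1
        wobble = float(rng.uniform(-pose_wobble_deg, pose_wobble_deg))
        coords = _rotate_tail(coords, hinge_idx, _random_unit(rng), wobble)
        # closing-hinge V at this homolog's own hinge: pose offset and wobble
        # keep only their azimuthal components, so every homolog swings
        # open/close about its hinge
        coords = _enforce_v_angle(coords, hinge_idx)
        ce = dmap["C-ext"]
        if ce.length >= 2 and ce.start >= 3:
            scatter = float(rng.uniform(-cext_scatter_deg, cext_scatter_deg))
            coords = _rotate_tail(coords, ce.start - 2, _random_unit(rng), scatter)
        seg = set(dmap["linker"].positions) | set(ce.positions)
        seg_idx = [i for i, n in enumerate(st.residue_numbers) if n in seg]
        coords[seg_idx] += rng.normal(scale=segment_conf_sigma, size=(len(seg_idx), 3))
        # the mobile domain is its own body in every homolog: small static
        # internal deformation (well under the TM-score distance scale)
        b_idx = [i for i, n in enumerate(st.residue_numbers) if n in set(dmap["C-domain"].positions)]
        coords[b_idx] += rng.normal(scale=domain_b_conf_sigma, size=(len(b_idx), 3))
        st = st.with_coords(coords)
        structures[hid] = st
        flex = (list(dmap["N-ext"].positions) + list(dmap["linker"].positions)
                + list(dmap["C-ext"].positions))
        soft = list(dmap["C-domain"].positions)
        amp = hinge_amplitude_deg * float(rng.uniform(0.8, 1.2))
        phase = float(rng.uniform(0, 2 * math.pi))
        ens, angles = make_hinge_ensemble(
            st, hinge_positions[hid], amp, times_ns=times_ns,
            jitter_sigma=jitter_sigma, seed=int(rng.integers(2**31)),
            phase=phase, flexible_positions=flex, flexible_sigma=flexible_sigma,
            soft_positions=soft, soft_sigma=soft_sigma,
        )
        hinge_angles[hid] = angles
        records.append(HomologRecord(hid, sequences[hid], groups[hid], ens))

    hset = HomologSet(records, msa, "ref")
    achieved = {hid: pairwise_identity(ref_seq, sequences[hid]) for hid in order}
    truth = {
        "seed": int(seed),
        "groups": groups,
        "target_identities": targets,
        "achieved_identities": achieved,
        "indels": indels,
        "stable_domain": (dom_a.start, dom_a.end),
        "hinge_positions": hinge_positions,
        "hinge_angles": hinge_angles,
        "times_ns": times_ns.tolist(),
        "domains": {hid: [(a.name, a.start, a.end, a.role) for a in domain_maps[hid]]
                    for hid in order},
    }
    return SyntheticFamily(homolog_set=hset, truth=truth)
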