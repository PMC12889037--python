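"""Sequence-level divergence: identity, grouping, conservation, indels, motifs.

Homologs are classified relative to a reference sequence: identity >= 0.72
puts a homolog in the type-I group; below that, a homolog joins the distant
group if it reaches >= 0.35 identity to at least one seed distant homolog,
and is otherwise left unassigned (sequences divergent to both classes are
excluded from typing).

Per-column conservation uses the Shannon-entropy score
``1 − H/log2(20)`` with gaps excluded from the frequencies, and the
conservation differential maps the scores of two alignments (all homologs
vs. a subset) onto reference numbering so that regions uniquely divergent in
the removed sequences show up as positive deltas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .structio import AMINO_ACIDS, GAP, MSA

TYPE1_MIN_IDENTITY = 0.72
DISTANT_MIN_IDENTITY = 0.35

# residue classes for HTH fingerprint patterns; the field's own canonical
# examples sit one violation outside strict membership, hence the default
# max_violations = 1 in motif_scan
RESIDUE_CLASSES = {
    "s": set("GASCT"),  # small
    "h": set("AVLIMFWYC"),  # hydrophobic
    "p": set("STNQHKRDEYW"),  # polar
}

CHARGE = {"K": 1, "R": 1, "D": -1, "E": -1}


@dataclass(frozen=True)
class ConservationProfile:
    reference_id: str
    positions: tuple  # reference numbering, within window
    score_all: tuple
    score_subset: tuple
    delta: tuple  # score_subset − score_all
    window: tuple


@dataclass(frozen=True)
class DomainAnnotation:
    name: str
    start: int  # 1-based inclusive
    end: int
    role: str = "HTH"  # HTH | DNA_binding | IDL | extension

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"domain {self.name}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def positions(self) -> range:
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class IndelBlock:
    kind: str  # insertion | deletion
    reference_position: int
    length: int

    def __post_init__(self):
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"bad indel kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("indel length must be >= 1")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: identical pairs / alignment columns.

    Alignment uses BLOSUM62 with affine gaps (open 11, extend 1). Pairwise
    alignments have no double-gap columns, so the denominator is simply the
    alignment length.
    """
    for seq in (seq_a, seq_b):
        if not seq:
            raise ValueError("empty sequence")
        bad = set(seq) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-standard residues {sorted(bad)}")
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    a, b = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(a, b) if x == y and x != GAP)
    columns = sum(1 for x, y in zip(a, b) if not (x == GAP and y == GAP))
    return matches / columns


def classify_homologs(identities_to_reference: dict, identities_to_distant_set: dict,
                      type1_min: float = TYPE1_MIN_IDENTITY,
                      distant_min: float = DISTANT_MIN_IDENTITY) -> dict:
    """Assign type-I / distant / unassigned labels from identity fractions.

    ``identities_to_distant_set`` maps homolog id -> iterable of identities to
    the seed distant homologs (may be empty).
    """
    labels = {}
    for hid, ident in identities_to_reference.items():
        if ident >= type1_min:
            labels[hid] = "type-I"
            continue
        to_distant = list(identities_to_distant_set.get(hid, []))
        if to_distant and max(to_distant) >= distant_min:
            labels[hid] = "distant"
        else:
            labels[hid] = "unassigned"
    return labels


def conservation_profile(msa: MSA, max_gap_fraction: float = 0.5):
    """Per-column conservation score 1 − H/log2(20); gaps excluded from H.

    Returns (scores, flagged) where ``flagged[j]`` is True for columns whose
    gap fraction exceeds ``max_gap_fraction`` (score still reported) and
    scores are ``nan`` for all-gap columns.
    """
    scores, flagged = [], []
    log2_20 = math.log2(20)
    for j in range(msa.width):
        col = msa.column(j)
        residues = [c for c in col if c != GAP]
        gap_frac = 1 - len(residues) / len(col)
        flagged.append(gap_frac > max_gap_fraction)
        if not residues:
            scores.append(float("nan"))
            continue
        n = len(residues)
        H = 0.0
        for aa in set(residues):
            p = residues.count(aa) / n
            H -= p * math.log2(p)
        scores.append(1.0 - H / log2_20)
    return scores, flagged


def _reference_column_map(msa: MSA, reference_id: str) -> dict:
    """Map 1-based reference positions to MSA column indices."""
    row = msa.row(reference_id)
    mapping, pos = {}, 0
    for j, c in enumerate(row):
        if c != GAP:
            pos += 1
            mapping[pos] = j
    return mapping


def conservation_differential(msa_all: MSA, msa_subset: MSA, reference_id: str,
                              window: tuple = (10, 268)) -> ConservationProfile:
    """Per-reference-position conservation delta between two alignments.

    ``delta = score_subset − score_all``: positions where removing the
    designated sequences raises conservation mark segments uniquely divergent
    in those sequences. Only reference positions inside ``window`` (clipped
    to the reference length) are reported; window ends exclude alignment-end
    ambiguities.
    """
    scores_all, _ = conservation_profile(msa_all)
    scores_sub, _ = conservation_profile(msa_subset)
    map_all = _reference_column_map(msa_all, reference_id)
    map_sub = _reference_column_map(msa_subset, reference_id)
    ref_len = len(msa_all.ungapped(reference_id))
    lo, hi = max(window[0], 1), min(window[1], ref_len)
    positions, s_all, s_sub, delta = [], [], [], []
    for p in range(lo, hi + 1):
        a = scores_all[map_all[p]]
        b = scores_sub[map_sub[p]]
        positions.append(p)
        s_all.append(a)
        s_sub.append(b)
        delta.append(b - a)
    return ConservationProfile(
        reference_id, tuple(positions), tuple(s_all), tuple(s_sub), tuple(delta), (lo, hi)
    )


def indel_blocks(msa: MSA, reference_id: str, query_id: str, min_length: int = 3) -> list:
    """Maximal indel runs of the query relative to the reference.

    A run of columns where the query is gapped and the reference is not is a
    deletion (positioned at the reference position of its first column); a
    run where the reference is gapped and the query is not is an insertion
    (anchored to the preceding reference position, 0 for an N-terminal
    insertion). Columns gapped in both rows are skipped without breaking
    runs. Runs shorter than ``min_length`` are dropped.
    """
    ref = msa.row(reference_id)
    qry = msa.row(query_id)
    blocks = []
    ref_pos = 0
    open_kind = None
    open_start = None
    open_len = 0

    def close():
        nonlocal open_kind, open_start, open_len
        if open_kind is not None and open_len >= min_length:
            blocks.append(IndelBlock(open_kind, open_start, open_len))
        open_kind, open_start, open_len = None, None, 0

    for r, q in zip(ref, qry):
        if r == GAP and q == GAP:
            continue
        if r != GAP and q == GAP:
            kind = "deletion"
            anchor = ref_pos + 1  # first deleted reference position
        elif r == GAP and q != GAP:
            kind = "insertion"
            anchor = ref_pos  # preceding reference position
        else:
            kind = None
        if kind != open_kind:
            close()
            if kind is not None:
                open_kind, open_start, open_len = kind, anchor, 0
        if kind is not None:
            open_len += 1
        if r != GAP:
            ref_pos += 1
    close()
    return blocks


def motif_scan(sequence: str, pattern: str, region: tuple | None = None,
               max_violations: int = 1, classes: dict | None = None) -> list:
    """Sliding 3-mer scan against a residue-class pattern like ``shs``/``phs``.

    Returns (position, triplet, violations) tuples with at most
    ``max_violations`` class violations, sorted by (violations, position).
    Positions are 1-based within the full sequence; ``region`` is an
    inclusive 1-based (start, end) window of triplet start positions.
    """
    classes = classes or RESIDUE_CLASSES
    if len(pattern) != 3 or any(c not in classes for c in pattern):
        raise ValueError(f"pattern must be 3 class codes from {sorted(classes)}")
    lo, hi = (1, len(sequence) - 2) if region is None else region
    if lo < 1 or hi > len(sequence):
        raise ValueError("region outside sequence")
    hi = min(hi, len(sequence) - 2)
    matches = []
    for start in range(lo, hi + 1):
        triplet = sequence[start - 1 : start + 2]
        violations = sum(1 for aa, cls in zip(triplet, pattern) if aa not in classes[cls])
        if violations <= max_violations:
            matches.append((start, triplet, violations))
    matches.sort(key=lambda m: (m[2], m[0]))
    return matches


def charge_profile(sequence: str, window: int = 10) -> list:
    """Sliding net formal charge (K,R = +1; D,E = −1; H and others 0)."""
    if window < 1 or window > len(sequence):
        raise ValueError("window must be within sequence length")
    charges = [CHARGE.get(aa, 0) for aa in sequence]
    total = sum(charges[:window])
    out = [total]
    for i in range(window, len(sequence)):
        total += charges[i] - charges[i - window]
        out.append(total)
    return out


def domain_arithmetic(annotations: list) -> dict:
    """Lengths of domains and gaps between consecutive non-overlapping domains."""
    doms = sorted(annotations, key=lambda d: d.start)
    for a, b in zip(doms, doms[1:]):
        if b.start <= a.end:
            raise ValueError(f"domains {a.name} and {b.name} overlap")
    lengths = {d.name: d.length for d in doms}
    gaps = {
        f"{a.name}..{b.name}": b.start - a.end - 1 for a, b in zip(doms, doms[1:])
    }
    return {"lengths": lengths, "gaps": gaps}


def positions_in_ranges(ranges: list) -> set:
    """Union of 1-based inclusive (start, end) ranges as a position set."""
    out = set()
    for start, end in ranges:
        out.update(range(start, end + 1))
    return out
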