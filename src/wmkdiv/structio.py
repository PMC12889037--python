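"""Domain types and file I/O for the divergence pipeline.

All structural analyses in this package are Cα-based: a :class:`Structure`
is an ordered Cα trace with 1-based residue numbering and 1-letter residue
codes, a :class:`Ensemble` is a time-stamped series of such traces (an MD
trajectory or a synthetic stand-in), and a :class:`HomologSet` bundles the
homolog records of a family together with a shared multiple sequence
alignment.

Trajectories are exchanged as multi-model PDB files (MODEL/ENDMDL); frame
times come from a sidecar JSON/CLI flag because the PDB format has no
standard time field. Sequences are FASTA; alignments are aligned FASTA or
Clustal. Tabular outputs are TSV or JSON with stable column order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from biotite.structure import Atom, array as atom_array
from biotite.structure.io.pdb import PDBFile

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


class FormatError(ValueError):
    """Raised when an input file violates the expected format contract."""


@dataclass(frozen=True)
class Structure:
    """One conformation as an ordered Cα trace.

    Attributes
    ----------
    id : str
        Identifier (homolog id, optionally with a frame suffix).
    residue_numbers : tuple of int
        Strictly increasing 1-based residue numbers.
    residue_codes : str
        1-letter amino-acid codes, same length as ``residue_numbers``.
    coords : (N, 3) ndarray
        Cα coordinates in Å; all finite.
    """

    id: str
    residue_numbers: tuple
    residue_codes: str
    coords: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "residue_numbers", tuple(int(r) for r in self.residue_numbers))
        n = len(self.residue_numbers)
        if len(self.residue_codes) != n or coords.shape != (n, 3):
            raise ValueError(
                f"Structure {self.id!r}: inconsistent lengths "
                f"(numbers={n}, codes={len(self.residue_codes)}, coords={coords.shape})"
            )
        if n > 1 and any(b <= a for a, b in zip(self.residue_numbers, self.residue_numbers[1:])):
            raise ValueError(f"Structure {self.id!r}: residue_numbers not strictly increasing")
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"Structure {self.id!r}: non-finite coordinates")
        bad = set(self.residue_codes) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"Structure {self.id!r}: non-standard residue codes {sorted(bad)}")

    def __len__(self):
        return len(self.residue_numbers)

    def with_coords(self, coords: np.ndarray, id: str | None = None) -> "Structure":
        return Structure(id or self.id, self.residue_numbers, self.residue_codes, coords)


@dataclass(frozen=True)
class Ensemble:
    """A homolog's time-stamped sequence of conformations."""

    homolog_id: str
    frames: tuple
    times_ns: tuple

    def __post_init__(self):
        object.__setattr__(self, "frames", tuple(self.frames))
        object.__setattr__(self, "times_ns", tuple(float(t) for t in self.times_ns))
        if len(self.frames) != len(self.times_ns):
            raise ValueError(f"Ensemble {self.homolog_id!r}: frame/time count mismatch")
        if not self.frames:
            raise ValueError(f"Ensemble {self.homolog_id!r}: empty")
        if any(t2 <= t1 for t1, t2 in zip(self.times_ns, self.times_ns[1:])):
            raise ValueError(f"Ensemble {self.homolog_id!r}: times_ns not strictly increasing")
        ref = self.frames[0]
        for fr in self.frames[1:]:
            if fr.residue_numbers != ref.residue_numbers or fr.residue_codes != ref.residue_codes:
                raise ValueError(
                    f"Ensemble {self.homolog_id!r}: frames do not share residue numbering/codes"
                )

    def __len__(self):
        return len(self.frames)

    @property
    def residue_numbers(self):
        return self.frames[0].residue_numbers

    @property
    def residue_codes(self):
        return self.frames[0].residue_codes

    def coords_array(self) -> np.ndarray:
        """Stack frame coordinates into an (F, N, 3) array."""
        return np.stack([fr.coords for fr in self.frames])

    def with_frames(self, frames, times_ns) -> "Ensemble":
        return Ensemble(self.homolog_id, frames, times_ns)


@dataclass(frozen=True)
class MSA:
    """Multiple sequence alignment over the 20 amino acids plus '-'."""

    ids: tuple
    rows: tuple

    def __post_init__(self):
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "rows", tuple(self.rows))
        if len(self.ids) != len(self.rows):
            raise ValueError("MSA: ids/rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("MSA: duplicate ids")
        if not self.rows:
            raise ValueError("MSA: empty")
        width = len(self.rows[0])
        allowed = set(AMINO_ACIDS + GAP)
        for sid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise FormatError(f"MSA: row {sid!r} has length {len(row)}, expected {width}")
            bad = set(row) - allowed
            if bad:
                raise FormatError(f"MSA: row {sid!r} contains invalid symbols {sorted(bad)}")

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"id {seq_id!r} not in MSA") from None

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)


@dataclass(frozen=True)
class HomologRecord:
    id: str
    sequence: str
    group: str = "unassigned"  # reference | type-I | distant | unassigned
    ensemble: Ensemble | None = None


@dataclass
class HomologSet:
    """Homolog records of one family plus a shared MSA and a reference id."""

    records: list
    msa: MSA
    reference_id: str

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if self.reference_id not in ids:
            raise ValueError(f"reference_id {self.reference_id!r} not among records")
        for rec in self.records:
            if rec.id in self.msa.ids and self.msa.ungapped(rec.id) != rec.sequence:
                raise ValueError(f"MSA row for {rec.id!r} does not match its sequence")
            if rec.ensemble is not None and rec.ensemble.residue_codes != rec.sequence:
                raise ValueError(f"ensemble residue codes for {rec.id!r} do not match sequence")

    def __iter__(self):
        return iter(self.records)

    def get(self, homolog_id: str) -> HomologRecord:
        for rec in self.records:
            if rec.id == homolog_id:
                return rec
        raise KeyError(homolog_id)

    @property
    def ids(self):
        return [r.id for r in self.records]

    @property
    def reference(self) -> HomologRecord:
        return self.get(self.reference_id)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_multi_model_pdb(path, frame_times: Sequence[float], homolog_id: str | None = None) -> Ensemble:
    """Read a multi-model Cα PDB file into an :class:`Ensemble`.

    Every MODEL must contain a CA atom for every residue and all models must
    cover the same residue set; violations are hard errors naming the first
    offending residue.
    """
    path = Path(path)
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models < 1:
        raise FormatError(f"{path}: no MODEL records")
    if len(frame_times) != n_models:
        raise FormatError(
            f"{path}: {n_models} models but {len(frame_times)} frame times supplied"
        )
    frames = []
    ref_key = None
    for m in range(1, n_models + 1):
        atoms = pdb.get_structure(model=m)
        ca = atoms[atoms.atom_name == "CA"]
        # detect residues present without CA
        res_with_atoms = set(zip(atoms.res_id.tolist(), atoms.chain_id.tolist()))
        res_with_ca = set(zip(ca.res_id.tolist(), ca.chain_id.tolist()))
        missing = sorted(res_with_atoms - res_with_ca)
        if missing:
            raise FormatError(f"{path}: model {m} residue {missing[0][0]} has no CA atom")
        if len(set(ca.chain_id)) > 1:
            raise FormatError(f"{path}: model {m} has multiple chains; expected one")
        order = np.argsort(ca.res_id, kind="stable")
        ca = ca[order]
        numbers = tuple(int(r) for r in ca.res_id)
        codes = "".join(_THREE_TO_ONE.get(rn, "?") for rn in ca.res_name)
        if "?" in codes:
            i = codes.index("?")
            raise FormatError(f"{path}: model {m} residue {numbers[i]} has non-standard name")
        key = (numbers, codes)
        if ref_key is None:
            ref_key = key
        elif key != ref_key:
            extra = sorted(set(numbers) ^ set(ref_key[0]))
            which = extra[0] if extra else numbers[0]
            raise FormatError(
                f"{path}: model {m} residue set differs from model 1 (e.g. residue {which})"
            )
        sid = homolog_id or path.stem
        frames.append(Structure(f"{sid}", numbers, codes, ca.coord.astype(float)))
    return Ensemble(homolog_id or path.stem, frames, frame_times)


def write_pdb(obj: Ensemble | Structure, path) -> None:
    """Write a Structure (single model) or Ensemble (multi-model) as Cα PDB."""
    if isinstance(obj, Structure):
        frames = [obj]
    else:
        frames = list(obj.frames)
    pdb = PDBFile()
    stacks = []
    for fr in frames:
        atoms = []
        for i, (num, code) in enumerate(zip(fr.residue_numbers, fr.residue_codes)):
            atoms.append(
                Atom(
                    fr.coords[i],
                    chain_id="A",
                    res_id=num,
                    res_name=_ONE_TO_THREE[code],
                    atom_name="CA",
                    element="C",
                )
            )
        stacks.append(atom_array(atoms))
    if len(stacks) == 1:
        pdb.set_structure(stacks[0])
    else:
        from biotite.structure import stack as _stack

        pdb.set_structure(_stack(stacks))
    pdb.write(str(path))


def read_fasta(path) -> list:
    """Parse FASTA into a list of (id, sequence) pairs."""
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    for sid, seq in records:
        bad = set(seq) - set(AMINO_ACIDS)
        if bad:
            raise FormatError(f"{path}: record {sid!r} contains invalid symbols {sorted(bad)}")
    return records


def read_msa(path, fmt: str | None = None) -> MSA:
    """Read an alignment (aligned FASTA or Clustal) into an :class:`MSA`."""
    path = Path(path)
    if fmt is None:
        fmt = "clustal" if path.suffix.lower() in {".aln", ".clustal", ".clw"} else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return MSA(tuple(rec.id for rec in aln), tuple(str(rec.seq).upper() for rec in aln))


def write_fasta(records: Iterable, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_msa(msa: MSA, path) -> None:
    write_fasta(zip(msa.ids, msa.rows), path)


def write_table(records: Sequence[Mapping], path, format: str = "tsv") -> None:
    """Write a list of homogeneous dicts as TSV or JSON with stable columns."""
    records = list(records)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(records, fh, indent=2, default=_json_default)
            fh.write("\n")
        return
    if format != "tsv":
        raise ValueError(f"unknown table format {format!r}")
    if not records:
        Path(path).write_text("")
        return
    cols = list(records[0].keys())
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in records:
            fh.write("\t".join(_fmt_cell(rec[c]) for c in cols) + "\n")


def read_table(path) -> list:
    """Read a TSV written by :func:`write_table` back into dicts (strings/floats)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        return []
    cols = lines[0].split("\t")
    out = []
    for line in lines[1:]:
        vals = line.split("\t")
        rec = {}
        for c, v in zip(cols, vals):
            try:
                rec[c] = int(v)
            except ValueError:
                try:
                    rec[c] = float(v)
                except ValueError:
                    rec[c] = v
        out.append(rec)
    return out


def _fmt_cell(v) -> str:
    if isinstance(v, float):
        return format(v, ".6g")
    return str(v)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
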