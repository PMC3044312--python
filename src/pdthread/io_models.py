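"""Input models and file I/O: the query profile, the template structure,
and derivation of template structural annotations (secondary structure,
burial, structural-alphabet string).

Conventions: coordinates in Angstroms; residue positions 1-based at every
interface; sequences are uppercase 1-letter codes with unknowns mapped to X.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from ._geometry import dihedral

logger = logging.getLogger(__name__)

#: Canonical 20-letter amino-acid alphabet; profile columns use this order.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

BACKBONE_ATOMS = ("N", "CA", "C", "O", "CB")

#: 16-letter structural alphabet: 4x4 grid of 90-degree (phi, psi) bins,
#: phi and psi each binned over [-180, 180). '-' marks undefined termini.
CLE_LETTERS = "ABCDEFGHIJKLMNOP"
CLE_UNDEF = "-"

#: Dihedral windows for 3-state secondary structure assignment.
_H_PHI = (-100.0, -30.0)
_H_PSI = (-80.0, -5.0)
_E_PHI = (-180.0, -90.0)

BURIAL_CONTACT_CUTOFF = 10.0  # A, Cbeta contact-number sphere


class ParseError(ValueError):
    """A file could not be parsed."""


class ValidationError(ValueError):
    """Parsed content violates a model invariant."""


@dataclass(frozen=True)
class TemplateResidue:
    name: str                 # 3-letter residue code
    residue_index: int        # author residue number
    icode: str                # insertion code, "" if none
    atoms: dict               # atom name -> np.ndarray(3,)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


@dataclass
class Template:
    """A single-chain template: residues with backbone/Cbeta coordinates
    plus derived annotation strings (all of length m)."""

    chain_id: str
    residues: list
    ss: str = ""
    burial: str = ""
    cle: str = ""

    @property
    def m(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def coord(self, t: int, atom: str) -> np.ndarray:
        """Coordinate of `atom` in residue at 1-based chain position t."""
        return self.residues[t - 1].atoms[atom]

    def rep_coords(self) -> np.ndarray:
        """Per-residue representative coordinates: CB, falling back to CA
        (glycine). Shape (m, 3)."""
        out = np.empty((self.m, 3))
        for i, r in enumerate(self.residues):
            out[i] = r.atoms.get("CB", r.atoms["CA"])
        return out

    def ca_coords(self) -> np.ndarray:
        return np.array([r.atoms["CA"] for r in self.residues])

    def subset(self, positions) -> "Template":
        """New Template keeping the given 1-based chain positions
        (order preserved); annotation strings are subset alongside."""
        idx = [p - 1 for p in positions]
        res = [self.residues[i] for i in idx]
        pick = lambda s: "".join(s[i] for i in idx) if s else s
        return Template(self.chain_id, res, pick(self.ss),
                        pick(self.burial), pick(self.cle))

    def transformed(self, r: np.ndarray, t: np.ndarray) -> "Template":
        res = [
            replace(rr, atoms={k: r @ v + t for k, v in rr.atoms.items()})
            for rr in self.residues
        ]
        return Template(self.chain_id, res, self.ss, self.burial, self.cle)


@dataclass
class QueryProfile:
    """Query sequence with a per-position 20-dim log-odds profile and
    optional predicted structural annotations."""

    sequence: str
    profile: np.ndarray                    # (n, 20) log-odds
    predicted_ss: str = ""                 # 3-state H/E/C, default all-C
    predicted_burial: str = ""             # 2-state B/E, default all-E
    predicted_cle: Optional[str] = None    # structural-alphabet string

    def __post_init__(self):
        n = len(self.sequence)
        if n == 0:
            raise ValidationError("empty query sequence")
        self.profile = np.asarray(self.profile, dtype=float)
        if self.profile.shape != (n, 20):
            raise ValidationError(
                f"profile shape {self.profile.shape} != ({n}, 20)")
        if not self.predicted_ss:
            self.predicted_ss = "C" * n
        if not self.predicted_burial:
            self.predicted_burial = "E" * n
        for name, s in (("predicted_ss", self.predicted_ss),
                        ("predicted_burial", self.predicted_burial)):
            if len(s) != n:
                raise ValidationError(f"{name} length {len(s)} != {n}")
        if self.predicted_cle is not None and len(self.predicted_cle) != n:
            raise ValidationError("predicted_cle length mismatch")

    @property
    def n(self) -> int:
        return len(self.sequence)

    def profile_probabilities(self) -> np.ndarray:
        """Rows converted to probability vectors by softmax of the
        log-odds scores (used by the contact-preference score)."""
        z = self.profile - self.profile.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------
# substitution-matrix fallback profile

def _blosum62_profile_rows() -> dict:
    from Bio.Align import substitution_matrices
    m = substitution_matrices.load("BLOSUM62")
    rows = {}
    for a in AA_ALPHABET:
        rows[a] = np.array([float(m[a][b]) for b in AA_ALPHABET])
    rows["X"] = np.zeros(20)
    return rows


_BLOSUM_ROWS = None


def substitution_profile(sequence: str) -> np.ndarray:
    """Fallback profile: row for residue a is the BLOSUM62 column for a
    (zeros for X)."""
    global _BLOSUM_ROWS
    if _BLOSUM_ROWS is None:
        _BLOSUM_ROWS = _blosum62_profile_rows()
    return np.array([_BLOSUM_ROWS.get(a, _BLOSUM_ROWS["X"])
                     for a in sequence])


def _clean_sequence(raw: str) -> str:
    return "".join(c if c in AA_INDEX else "X" for c in raw.upper())


def read_fasta(path) -> QueryProfile:
    """First record of a FASTA file as a QueryProfile with the
    substitution-matrix fallback profile."""
    from Bio import SeqIO
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    if len(records) > 1:
        logger.warning("%s: %d records, using the first", path, len(records))
    seq = _clean_sequence(str(records[0].seq))
    if not seq:
        raise ValidationError(f"{path}: zero-length sequence")
    return QueryProfile(sequence=seq, profile=substitution_profile(seq))


def read_pssm(path, sequence: Optional[str] = None) -> np.ndarray:
    """PSI-BLAST ASCII PSSM: returns the (n, 20) log-odds matrix.

    Header lines are skipped; a data row is `index letter` followed by at
    least 20 integers (trailing percentage columns ignored). When a
    sequence is supplied, row letters are cross-checked against it.
    """
    rows = []
    letters = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) < 22 or not parts[0].isdigit():
                continue
            try:
                vals = [float(v) for v in parts[2:22]]
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: malformed PSSM row: {exc}") from exc
            if len(parts[1]) != 1:
                raise ParseError(f"{path}:{lineno}: bad residue field")
            letters.append(parts[1].upper())
            rows.append(vals)
    if not rows:
        raise ParseError(f"{path}: no PSSM data rows found")
    mat = np.array(rows)
    if sequence is not None:
        if len(sequence) != len(rows):
            raise ValidationError(
                f"PSSM has {len(rows)} rows but sequence length is "
                f"{len(sequence)}")
        for i, (a, b) in enumerate(zip(letters, sequence)):
            if a != b and "X" not in (a, b):
                raise ValidationError(
                    f"PSSM residue {a} at position {i + 1} does not match "
                    f"sequence residue {b}")
    return mat


# --------------------------------------------------------------------------
# PDB

def read_pdb_template(path, chain: str = "A") -> Template:
    """Minimal single-chain PDB reader: first MODEL, ATOM records only,
    altloc blank or 'A', atoms restricted to N/CA/C/O/CB. Residues missing
    any of N, CA, C are dropped with a warning."""
    residues: dict = {}
    order: list = []
    seen_chains = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("ENDMDL"):
                break
            if not line.startswith("ATOM"):
                continue
            altloc = line[16]
            if altloc not in (" ", "A"):
                continue
            ch = line[21]
            seen_chains.add(ch)
            if ch != chain:
                continue
            atom = line[12:16].strip()
            if atom not in BACKBONE_ATOMS:
                continue
            resname = line[17:20].strip()
            resseq = int(line[22:26])
            icode = line[26].strip()
            key = (resseq, icode)
            xyz = np.array([float(line[30:38]), float(line[38:46]),
                            float(line[46:54])])
            if key not in residues:
                residues[key] = (resname, {})
                order.append(key)
            residues[key][1].setdefault(atom, xyz)
    if not order:
        if chain not in seen_chains:
            raise LookupError(f"{path}: chain {chain!r} not present "
                              f"(found {sorted(seen_chains)})")
        raise ValidationError(f"{path}: chain {chain!r} has no residues")
    kept = []
    for key in order:
        resname, atoms = residues[key]
        if not {"N", "CA", "C"} <= atoms.keys():
            logger.warning("%s: residue %s%s missing backbone atoms, dropped",
                           path, key[0], key[1])
            continue
        kept.append(TemplateResidue(resname, key[0], key[1], atoms))
    if not kept:
        raise ValidationError(f"{path}: no residues with complete backbone")
    return Template(chain_id=chain, residues=kept)


def write_pdb(residues, path, chain_id: str = "A") -> None:
    """Write (resname3, resnum, atoms-dict) triples as a minimal PDB."""
    serial = 1
    lines = []
    for resname, resnum, atoms in residues:
        for atom in BACKBONE_ATOMS:
            if atom not in atoms:
                continue
            x, y, z = atoms[atom]
            name = atom if len(atom) == 4 else f" {atom:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name}{'':1s}{resname:>3s} "
                f"{chain_id}{resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom[0]:>2s}")
            serial += 1
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_template_pdb(template: Template, path) -> None:
    write_pdb([(r.name, r.residue_index, r.atoms) for r in template.residues],
              path, template.chain_id)


# --------------------------------------------------------------------------
# template annotations

def backbone_dihedrals(template: Template):
    """(phi, psi) per residue in degrees; None where undefined (termini)."""
    res = template.residues
    phi = [None] * len(res)
    psi = [None] * len(res)
    for i in range(len(res)):
        if i > 0:
            phi[i] = dihedral(res[i - 1].atoms["C"], res[i].atoms["N"],
                              res[i].atoms["CA"], res[i].atoms["C"])
        if i < len(res) - 1:
            psi[i] = dihedral(res[i].atoms["N"], res[i].atoms["CA"],
                              res[i].atoms["C"], res[i + 1].atoms["N"])
    return phi, psi


def _ss_state(phi, psi) -> str:
    if phi is None or psi is None:
        return "C"
    if _H_PHI[0] <= phi <= _H_PHI[1] and _H_PSI[0] <= psi <= _H_PSI[1]:
        return "H"
    if _E_PHI[0] <= phi <= _E_PHI[1] and (90.0 <= psi <= 180.0
                                          or -180.0 <= psi <= -170.0):
        return "E"
    return "C"


def _smooth_ss(ss: str, min_run: int = 3) -> str:
    out = list(ss)
    i = 0
    while i < len(out):
        j = i
        while j < len(out) and out[j] == out[i]:
            j += 1
        if out[i] in "HE" and j - i < min_run:
            for k in range(i, j):
                out[k] = "C"
        i = j
    return "".join(out)


def _cle_letter(phi, psi) -> str:
    if phi is None or psi is None:
        return CLE_UNDEF
    pb = min(int((phi + 180.0) // 90.0), 3)
    sb = min(int((psi + 180.0) // 90.0), 3)
    return CLE_LETTERS[4 * pb + sb]


def derive_template_features(template: Template) -> Template:
    """Fill ss, burial and cle from coordinates.

    Secondary structure comes from dihedral windows smoothed to runs of at
    least 3; burial class from the Cbeta (Calpha for Gly) 10 A contact
    number against the chain median; the structural-alphabet letter from a
    fixed 4x4 grid of 90-degree (phi, psi) bins.
    """
    if template.m < 3:
        raise ValidationError(
            f"need at least 3 residues to define dihedrals, got {template.m}")
    phi, psi = backbone_dihedrals(template)
    ss = _smooth_ss("".join(_ss_state(p, q) for p, q in zip(phi, psi)))
    cle = "".join(_cle_letter(p, q) for p, q in zip(phi, psi))

    rep = template.rep_coords()
    d = np.linalg.norm(rep[:, None, :] - rep[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    contact_number = (d <= BURIAL_CONTACT_CUTOFF).sum(axis=1)
    med = float(np.median(contact_number))
    burial = "".join("B" if c >= med else "E" for c in contact_number)

    return Template(template.chain_id, template.residues, ss, burial, cle)


def write_annotations(template: Template, path) -> None:
    """4-line annotation text file: sequence / ss / burial / cle."""
    Path(path).write_text("\n".join(
        [template.sequence, template.ss, template.burial, template.cle]
    ) + "\n")


def read_annotation_strings(path):
    """Read a 4-line annotation file -> (sequence, ss, burial, cle)."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 4:
        raise ParseError(f"{path}: expected 4 annotation lines")
    seq, ss, burial, cle = lines[:4]
    if not len(seq) == len(ss) == len(burial) == len(cle):
        raise ValidationError(f"{path}: annotation line lengths differ")
    return seq, ss, burial, cle
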