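"""Partial decoys: the matched-residue substructure of an alignment.

A partial decoy keeps one residue per match state, typed by the QUERY
residue but with coordinates copied verbatim from the paired TEMPLATE
residue — this is what makes the global energy depend on the alignment.
Building a full-length model per alignment would be far too slow for the
thousands of alignments the search evaluates.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple, Union

import numpy as np

from ._geometry import ideal_cb
from .alignment_core import AlignmentMapping, match_states
from .io_models import ONE_TO_THREE, QueryProfile, Template, write_pdb


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class DecoyResidue:
    seq_pos: int      # query position s (1-based)
    res_type: str     # query residue, 1-letter
    atoms: dict       # atom name -> np.ndarray(3,)


@dataclass
class PartialDecoy:
    residues: List[DecoyResidue]
    source_pairs: List[Tuple[int, int]]   # the match states used

    def __len__(self) -> int:
        return len(self.residues)

    def coords(self) -> np.ndarray:
        return np.array([xyz for r in self.residues
                         for xyz in r.atoms.values()])

    def transformed(self, rot: np.ndarray, trans: np.ndarray) \
            -> "PartialDecoy":
        res = [DecoyResidue(r.seq_pos, r.res_type,
                            {k: rot @ v + trans for k, v in r.atoms.items()})
               for r in self.residues]
        return PartialDecoy(res, list(self.source_pairs))


def build_partial_decoy(a: AlignmentMapping, template: Template,
                        query: QueryProfile) -> PartialDecoy:
    """One decoy residue per match state (t, s): query residue type at s,
    atom coordinates copied from template residue t.

    Cbeta is dropped when the query residue is glycine; when the query
    residue needs a Cbeta the template residue (glycine) lacks, an ideal
    Cbeta is reconstructed from the backbone so the atom set stays uniform
    for the potential.
    """
    residues = []
    pairs = match_states(a)
    for t, s in pairs:
        qtype = query.sequence[s - 1]
        atoms = {k: v.copy() for k, v in template.residues[t - 1].atoms.items()}
        if qtype == "G":
            atoms.pop("CB", None)
        elif "CB" not in atoms:
            atoms["CB"] = ideal_cb(atoms["N"], atoms["CA"], atoms["C"])
        residues.append(DecoyResidue(s, qtype, atoms))
    return PartialDecoy(residues, pairs)


def excise_random(structure: Union[Template, PartialDecoy],
                  keep_fraction: float, seed: int):
    """Randomly excise residues, keeping round(keep_fraction * size)
    uniformly chosen residues in their original order (seeded)."""
    if not 0 < keep_fraction <= 1:
        raise ValidationError(f"keep_fraction {keep_fraction} not in (0, 1]")
    size = structure.m if isinstance(structure, Template) else len(structure)
    keep = int(round(keep_fraction * size))
    if keep < 1:
        raise ValidationError("excision would leave zero residues")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(size, size=keep, replace=False))
    if isinstance(structure, Template):
        return structure.subset([int(i) + 1 for i in idx])
    res = [structure.residues[int(i)] for i in idx]
    pairs = [structure.source_pairs[int(i)] for i in idx] \
        if structure.source_pairs else []
    return PartialDecoy(res, pairs)


def write_decoy_pdb(decoy: PartialDecoy, path) -> None:
    """Minimal PDB for a decoy: chain A, residue numbers are the query
    positions."""
    if not decoy.residues:
        raise ValidationError("cannot write an empty decoy")
    write_pdb([(ONE_TO_THREE.get(r.res_type, "UNK"), r.seq_pos, r.atoms)
               for r in decoy.residues], path, chain_id="A")
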