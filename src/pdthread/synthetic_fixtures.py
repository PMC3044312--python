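"""Deterministic toy proteins, decoy sets and threading pairs.

The fixtures are geometric idealizations — backbones built from ideal bond
lengths and angles with motif (phi, psi) values — not physically realistic
proteins. They exist so that every algorithmic property of the package can
be exercised without external structure downloads.
"""
from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from ._geometry import (ANGLE_CA_C_N, ANGLE_CA_C_O, ANGLE_C_N_CA,
                        ANGLE_N_CA_C, BOND_CA_C, BOND_C_N, BOND_C_O,
                        BOND_N_CA, OMEGA_TRANS, ideal_cb, place_atom)
from .alignment_core import AlignmentMapping, from_match_states
from .io_models import (AA_ALPHABET, ONE_TO_THREE, QueryProfile, Template,
                        TemplateResidue, derive_template_features,
                        write_template_pdb)
from .global_energy import PairPotentialTable
from .local_scoring import LocalWeights

MOTIF_DIHEDRALS = {
    "helix": (-57.0, -47.0),
    "strand": (-120.0, 120.0),
}
MIXED_RUN = 7  # residues per alternating helix/strand run in 'mixed'


class ValidationError(ValueError):
    pass


def _motif_angles(n: int, motif: str) -> List[Tuple[float, float]]:
    if motif in MOTIF_DIHEDRALS:
        return [MOTIF_DIHEDRALS[motif]] * n
    if motif == "mixed":
        out = []
        for i in range(n):
            kind = "helix" if (i // MIXED_RUN) % 2 == 0 else "strand"
            out.append(MOTIF_DIHEDRALS[kind])
        return out
    raise ValidationError(f"unknown motif {motif!r}")


def make_ideal_structure(n: int, motif: str = "helix", seed: int = 0,
                         pdb_path=None) -> Template:
    """Ideal-geometry backbone of n residues with motif dihedrals
    (helix -57/-47, strand -120/+120, mixed alternating runs), ideal
    Cbeta, uniformly sampled residue types, derived annotations."""
    if n < 4:
        raise ValidationError("need n >= 4")
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(AA_ALPHABET), size=n))
    angles = _motif_angles(n, motif)

    residues = []
    # first residue in the xy-plane
    nn = np.array([0.0, 0.0, 0.0])
    ca = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.radians(ANGLE_N_CA_C)
    c = ca + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n):
        atoms = {"N": nn, "CA": ca, "C": c}
        psi = angles[i][1]
        atoms["O"] = place_atom(atoms["N"], atoms["CA"], atoms["C"],
                                BOND_C_O, ANGLE_CA_C_O, psi - 180.0)
        if seq[i] != "G":
            atoms["CB"] = ideal_cb(atoms["N"], atoms["CA"], atoms["C"])
        residues.append(TemplateResidue(ONE_TO_THREE[seq[i]], i + 1, "",
                                        atoms))
        if i + 1 < n:
            nxt_n = place_atom(nn, ca, c, BOND_C_N, ANGLE_CA_C_N, psi)
            nxt_ca = place_atom(ca, c, nxt_n, BOND_N_CA, ANGLE_C_N_CA,
                                OMEGA_TRANS)
            nxt_c = place_atom(c, nxt_n, nxt_ca, BOND_CA_C, ANGLE_N_CA_C,
                               angles[i + 1][0])
            nn, ca, c = nxt_n, nxt_ca, nxt_c
    template = derive_template_features(Template("A", residues))
    if pdb_path is not None:
        write_template_pdb(template, pdb_path)
    return template


def make_decoy_set(native: Template, count: int, noise_sigma: float,
                   seed: int = 0) -> List[Template]:
    """Decoys as the native with isotropic per-atom Gaussian noise and a
    re-idealized Cbeta; same sequence, seeded."""
    if count < 1:
        raise ValidationError("count must be >= 1")
    if noise_sigma <= 0:
        raise ValidationError("noise_sigma must be > 0")
    rng = np.random.default_rng(seed)
    decoys = []
    for _ in range(count):
        residues = []
        for r in native.residues:
            atoms = {k: v + rng.normal(0.0, noise_sigma, 3)
                     for k, v in r.atoms.items()}
            if "CB" in atoms:
                atoms["CB"] = ideal_cb(atoms["N"], atoms["CA"], atoms["C"])
            residues.append(TemplateResidue(r.name, r.residue_index,
                                            r.icode, atoms))
        decoys.append(derive_template_features(
            Template(native.chain_id, residues)))
    return decoys


def _point_mass_profile(sequence: str, softness: float = 0.1) -> np.ndarray:
    """Log-odds rows concentrated on the given residue, softened by a
    mutation rate: row = ln((1 - mu) * onehot + mu / 20) - ln(1 / 20)."""
    n = len(sequence)
    prof = np.full((n, 20), np.log(softness / 20.0) - np.log(1.0 / 20.0))
    for i, a in enumerate(sequence):
        j = AA_ALPHABET.index(a)
        prof[i, j] = np.log(1.0 - softness + softness / 20.0) \
            - np.log(1.0 / 20.0)
    return prof


def make_threading_pair(seed: int = 0, length: int = 48,
                        identity: float = 0.6, deletion_length: int = 3,
                        insertion_length: int = 3,
                        noise_sigma: float = 0.3,
                        profile_softness: float = 0.1
                        ) -> Tuple[QueryProfile, Template, AlignmentMapping,
                                   Template]:
    """A synthetic query-template pair with a known reference alignment.

    A parent ideal structure is built; the template drops an interior
    segment of `insertion_length` parent residues (those become query-side
    insertions) and the query drops a disjoint interior segment of
    `deletion_length` residues (template-side deletions). The query
    sequence is mutated down to the requested identity, its coordinates
    are perturbed with Gaussian noise, and its profile is a softened
    point-mass on the query sequence. Predicted query annotations are the
    true-structure annotations (a perfect-predictor stand-in).
    """
    rng = np.random.default_rng(seed)
    parent = make_ideal_structure(length, "mixed",
                                  seed=int(rng.integers(2 ** 31 - 1)))
    third = length // 3
    ins_start = int(rng.integers(2, third - insertion_length)) \
        if insertion_length else 2
    del_start = int(rng.integers(2 * third,
                                 length - deletion_length - 2)) \
        if deletion_length else 2 * third
    ins_seg = set(range(ins_start, ins_start + insertion_length))
    del_seg = set(range(del_start, del_start + deletion_length))

    tmpl_parent = [i for i in range(1, length + 1) if i not in ins_seg]
    qry_parent = [i for i in range(1, length + 1) if i not in del_seg]
    template = parent.subset(tmpl_parent)
    template = Template("A", [
        TemplateResidue(r.name, k + 1, "", r.atoms)
        for k, r in enumerate(template.residues)
    ], template.ss, template.burial, template.cle)

    # true query structure: parent minus the deleted segment, renumbered,
    # mutated sequence, noisy coordinates
    qry_sub = parent.subset(qry_parent)
    qseq = []
    for r in qry_sub.residues:
        a = r.one_letter
        if rng.random() > identity:
            a = str(rng.choice([x for x in AA_ALPHABET if x != a]))
        qseq.append(a)
    residues = []
    for k, (r, a) in enumerate(zip(qry_sub.residues, qseq)):
        atoms = {key: v + rng.normal(0.0, noise_sigma, 3)
                 for key, v in r.atoms.items()}
        if a == "G":
            atoms.pop("CB", None)
        else:
            atoms["CB"] = ideal_cb(atoms["N"], atoms["CA"], atoms["C"])
        residues.append(TemplateResidue(ONE_TO_THREE[a], k + 1, "", atoms))
    query_structure = derive_template_features(Template("A", residues))

    # reference alignment from the shared parent positions
    tmpl_pos = {p: k + 1 for k, p in enumerate(tmpl_parent)}
    qry_pos = {p: k + 1 for k, p in enumerate(qry_parent)}
    pairs = [(tmpl_pos[p], qry_pos[p]) for p in range(1, length + 1)
             if p in tmpl_pos and p in qry_pos]
    reference = from_match_states(pairs, template.m, query_structure.m)

    query = QueryProfile(
        sequence="".join(qseq),
        profile=_point_mass_profile("".join(qseq), profile_softness),
        predicted_ss=query_structure.ss,
        predicted_burial=query_structure.burial,
        predicted_cle=query_structure.cle,
    )
    return query, template, reference, query_structure


def make_rescue_pair() -> Tuple[QueryProfile, Template, AlignmentMapping,
                                PairPotentialTable, LocalWeights, float]:
    """A hand-built pair on which the reference alignment is locally
    suboptimal (the profile slightly prefers a shifted alignment) but a
    planted long-range contact makes it the combined-score optimum.

    Template residues 1 and 6 carry the only Cbeta pair within the
    potential cutoff; the planted table rewards the (W, V) residue-type
    pair that only the reference alignment places at those positions.
    Returns (query, template, reference, table, weights, omega_L).
    """
    tmpl_seq = "ACDEFG"
    m, n = 6, 7
    cb = np.array([
        [0.0, 0.0, 0.0],
        [40.0, 0.0, 0.0],
        [80.0, 0.0, 0.0],
        [120.0, 0.0, 0.0],
        [160.0, 0.0, 0.0],
        [5.0, 0.0, 0.0],       # residue 6 folds back next to residue 1
    ])
    residues = []
    for i, a in enumerate(tmpl_seq):
        base = cb[i]
        atoms = {
            "N": base + np.array([1.2, 1.0, 0.0]),
            "CA": base + np.array([0.0, 1.5, 0.0]),
            "C": base + np.array([-1.2, 1.0, 0.3]),
            "O": base + np.array([-1.2, 1.0, 1.5]),
            "CB": base.copy(),
        }
        residues.append(TemplateResidue(ONE_TO_THREE[a], i + 1, "", atoms))
    template = Template("A", residues, ss="C" * m, burial="E" * m,
                        cle="-" * m)

    qseq = "WAAAAVA"
    profile = np.zeros((n, 20))
    for t in range(1, m + 1):          # reference pairs (t, t): score 3.0
        profile[t - 1, AA_ALPHABET.index(tmpl_seq[t - 1])] = 3.0
    for t in range(1, m + 1):          # shifted pairs (t, t+1): 3.05
        profile[t, AA_ALPHABET.index(tmpl_seq[t - 1])] = 3.05
    query = QueryProfile(sequence=qseq, profile=profile)
    reference = AlignmentMapping(m, n, tuple(range(1, m + 1)))

    table = PairPotentialTable.zeros(typer="cb", r_cut=15.0, n_bins=30)
    k = int(np.searchsorted(table.bin_edges, 5.0, side="right")) - 1
    iw, iv = table.type_index["W"], table.type_index["V"]
    table.energies[iw, iv, k] = -10.0
    table.energies[iv, iw, k] = -10.0

    weights = LocalWeights(w_m=1.0, w_ss=0.0, w_cle=0.0, w_sa=0.0,
                           w_go=3.0, w_ge=0.5)
    return query, template, reference, table, weights, 1.0


def write_fixture_set(out_dir, seed: int = 0) -> None:
    """Write a browsable fixture set (PDB / FASTA / PSSM-dialect files)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for motif in ("helix", "strand", "mixed"):
        make_ideal_structure(24, motif, seed=seed,
                             pdb_path=out / f"ideal_{motif}.pdb")
    query, template, reference, qstruct = make_threading_pair(seed=seed)
    write_template_pdb(template, out / "pair_template.pdb")
    write_template_pdb(qstruct, out / "pair_query_true.pdb")
    (out / "pair_query.fasta").write_text(
        f">query\n{query.sequence}\n")
    with open(out / "pair_query.pssm", "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        fh.write("    " + "  ".join(AA_ALPHABET) * 2 + "\n")
        for i, (a, row) in enumerate(zip(query.sequence, query.profile), 1):
            vals = " ".join(f"{int(round(v)):3d}" for v in row)
            fh.write(f"{i:5d} {a}  {vals}  {vals}\n")
    from .alignment_core import write_gapped_fasta
    write_gapped_fasta(reference, template.sequence, query.sequence,
                       out / "pair_reference.fasta")
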