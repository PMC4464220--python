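import numpy as np
import pytest

from ribopmf.structure_io import Atom, Residue, StructureModel

PDB_2RES_2MODEL = """\
MODEL        1
ATOM      1  P     G A   1       0.000   0.000   0.000  1.00  0.00           P
ATOM      2  C4'   G A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  P     C A   2       5.000   0.000   0.000  1.00  0.00           P
ATOM      4  C4'   C A   2       6.000   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  P     G A   1       0.000   0.000   1.000  1.00  0.00           P
ATOM      2  C4'   G A   1       1.000   0.000   1.000  1.00  0.00           C
ATOM      3  P     C A   2       5.000   0.000   1.000  1.00  0.00           P
ATOM      4  C4'   C A   2       6.000   0.000   1.000  1.00  0.00           C
ENDMDL
END
"""

PDB_SINGLE = """\
ATOM      1  P     G A   1       0.000   0.000   0.000  1.00  0.00           P
ATOM      2  C4'   G A   1       1.500   0.000   0.000  1.00  0.00           C
HETATM    3  N1  ADE A  90       9.000   9.000   9.000  1.00  0.00           N
END
"""


@pytest.fixture
def pdb_two_models(tmp_path):
    path = tmp_path / "two_models.pdb"
    path.write_text(PDB_2RES_2MODEL)
    return path


@pytest.fixture
def pdb_single_model(tmp_path):
    path = tmp_path / "single.pdb"
    path.write_text(PDB_SINGLE)
    return path


def make_model(atom_specs, model_id=1):
    """Build a StructureModel from (residue_index, name, atom_name, pos, mass)."""
    residues = {}
    for res_idx, res_name, atom_name, pos, mass in atom_specs:
        if res_idx not in residues:
            residues[res_idx] = Residue(index=res_idx, name=res_name)
        residues[res_idx].atoms.append(
            Atom(atom_name, res_idx, res_name, np.asarray(pos, float), mass)
        )
    return StructureModel(
        model_id=model_id, residues=[residues[k] for k in sorted(residues)]
    )


def random_rigid_motion(rng):
    """A uniformly random rotation matrix and a translation vector."""
    from scipy.stats import special_ortho_group

    rot = special_ortho_group.rvs(3, random_state=rng)
    trans = rng.uniform(-50, 50, size=3)
    return rot, trans


def transform_model(model, rot, trans):
    out = StructureModel(model_id=model.model_id, residues=[])
    for res in model.residues:
        new = Residue(index=res.index, name=res.name, chain=res.chain,
                      is_nucleotide=res.is_nucleotide)
        for a in res.atoms:
            new.atoms.append(
                Atom(a.name, a.residue_index, a.residue_name,
                     rot @ a.position + trans, a.mass)
            )
        out.residues.append(new)
    return out
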