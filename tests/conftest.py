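import numpy as np
import pytest

from solvshell.io import AtomRecord, Trajectory


def make_trajectory(coords, box=5.0, dt=1.0, atoms=None, resname="BRW",
                    mol_class="solvent"):
    """Trajectory from raw coords (frames, atoms, 3); one atom = one
    molecule unless an explicit atom table is given."""
    coords = np.asarray(coords, dtype=float)
    n_frames, n_atoms = coords.shape[:2]
    if atoms is None:
        atoms = [
            AtomRecord(index=i, name="S", element="X", resid=i + 1,
                       resname=resname, mol_id=i, mol_class=mol_class)
            for i in range(n_atoms)
        ]
    box = np.asarray(box, dtype=float)
    if box.ndim == 0:
        box = np.full(3, float(box))
    return Trajectory(atoms=atoms, coords=coords,
                      box=np.tile(box, (n_frames, 1)), dt=dt)


def water_molecule_atoms(n_waters=1, start_index=0, start_resid=1,
                         start_mol=0):
    atoms = []
    for w in range(n_waters):
        for j, (name, elem) in enumerate(
            [("OW", "O"), ("HW1", "H"), ("HW2", "H")]
        ):
            atoms.append(AtomRecord(
                index=start_index + 3 * w + j, name=name, element=elem,
                resid=start_resid + w, resname="SOL",
                mol_id=start_mol + w, mol_class="solvent",
            ))
    return atoms


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
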