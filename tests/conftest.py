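import itertools
import math

import numpy as np
import pytest

from afscreen.structure_io import BoundPrediction


def oracle_contacts(pred: BoundPrediction, chain_a: str, chain_b: str,
                    min_avg_plddt: float = 50.0, max_min_pae: float = 15.0,
                    max_heavy_dist: float = 8.0) -> set:
    """Independent brute-force contact finder: a plain double loop over
    residue pairs and heavy-atom pairs, no spatial index, no shared code
    with the contacts module."""
    found = set()
    for ra in pred.model.chain(chain_a):
        for rb in pred.model.chain(chain_b):
            dmin = math.inf
            for aa, ab in itertools.product(ra.atoms, rb.atoms):
                if not (aa.is_heavy and ab.is_heavy):
                    continue
                d = math.dist(aa.position, ab.position)
                dmin = min(dmin, d)
            if not dmin < max_heavy_dist:
                continue
            if not (ra.plddt + rb.plddt) / 2.0 > min_avg_plddt:
                continue
            i = pred.model.concat_index[ra.key]
            j = pred.model.concat_index[rb.key]
            pae = min(pred.pae.values[i, j], pred.pae.values[j, i])
            if not pae < max_min_pae:
                continue
            found.add(tuple(sorted((ra.key, rb.key))))
    return found


def random_cloud_prediction(rng: np.random.Generator, n_a: int = 10,
                            n_b: int = 10, box: float = 25.0,
                            atoms_per_residue: int = 2) -> BoundPrediction:
    """A fully random two-chain prediction: uniform atom positions in a box,
    uniform pLDDT in [0, 100], uniform PAE in [0, 30].  Nothing planted —
    only the brute-force oracle knows the truth."""
    from afscreen.structure_io import (AtomRecord, PAEMatrix, ResidueRecord,
                                       StructureModel, bind)
    chains = []
    for cid, n in (("A", n_a), ("B", n_b)):
        residues = []
        for i in range(n):
            center = rng.uniform(0, box, size=3)
            atoms = [AtomRecord(name=f"C{k}", element="C",
                                position=center + rng.normal(0, 1.0, size=3),
                                is_heavy=True)
                     for k in range(atoms_per_residue)]
            residues.append(ResidueRecord(
                chain_id=cid, seq_num=i + 1, icode=" ", res_name="ALA",
                atoms=atoms, plddt=float(rng.uniform(0, 100))))
        chains.append((cid, residues))
    model = StructureModel(model_id="cloud", chains=chains)
    n = n_a + n_b
    pae = PAEMatrix(values=rng.uniform(0, 30, size=(n, n)))
    return bind(model, pae)


@pytest.fixture
def simple_spec():
    """One planted contact: A1-B1 at 5 Å, pLDDT 80/60, pAE 10 both ways."""
    from afscreen.synthetic import FixtureSpec, PlantedContact
    return FixtureSpec(
        chains=[("A", 3), ("B", 3)],
        planted_contacts=[PlantedContact(("A", 1), ("B", 1), 5.0,
                                         80.0, 60.0, 10.0, 10.0)])


@pytest.fixture
def simple_prediction(simple_spec):
    from afscreen.synthetic import build_prediction
    return build_prediction(simple_spec)
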