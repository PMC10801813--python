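"""Synthetic prediction fixtures with analytically known interfaces.

Generates valid coordinate + PAE file pairs in which every inter-chain
contact is planted by construction: chains sit on well-separated lattices
(every background inter-chain atom pair further apart than
``background_min_dist``), and each planted contact moves one designated
residue along +z to exactly its target heavy-atom distance from its partner
residue.  Because the offset is purely in z and lattice rows are far apart,
a moved residue approaches only its own partner, so the set of residue
pairs within the distance cutoff equals the planted set exactly, and the
truth manifest can state the expected contact set (and, for ensembles, the
exact avg_n_models / max_n_models) analytically.

Multi-model ensembles plant a per-contact model-membership pattern: model m
realises exactly the planted contacts whose membership includes m.

No attempt is made at realistic protein geometry; analytic control is the
point.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

from .contacts import DEFAULT_THRESHOLDS, ContactThresholds, contact_key
from .structure_io import (AtomRecord, BoundPrediction, PAEMatrix,
                           ResidueRecord, StructureModel, bind)

#: planted residue identity: (chain_id, 1-based residue number)
PlantedRes = tuple[str, int]


class InfeasibleGeometryError(ValueError):
    """Two planted contacts demand contradictory residue placements."""


@dataclass(frozen=True)
class PlantedContact:
    """One planted inter-chain contact with its full evidence."""

    res_a: PlantedRes
    res_b: PlantedRes
    heavy_dist: float   # target closest heavy-atom distance, Å (< 8)
    plddt_a: float
    plddt_b: float
    pae_ab: float       # directional pAE a→b, Å
    pae_ba: float

    @property
    def key(self):
        a = (self.res_a[0], self.res_a[1], " ")
        b = (self.res_b[0], self.res_b[1], " ")
        return contact_key(a, b)

    @property
    def avg_plddt(self) -> float:
        return 0.5 * (self.plddt_a + self.plddt_b)

    @property
    def min_pae(self) -> float:
        return min(self.pae_ab, self.pae_ba)

    def passes(self, thresholds: ContactThresholds = DEFAULT_THRESHOLDS) -> bool:
        return (self.avg_plddt > thresholds.min_avg_plddt
                and self.min_pae < thresholds.max_min_pae
                and self.heavy_dist < thresholds.max_heavy_dist)

    def failed_filters(self, thresholds: ContactThresholds = DEFAULT_THRESHOLDS
                       ) -> list[str]:
        failed = []
        if not self.avg_plddt > thresholds.min_avg_plddt:
            failed.append("plddt")
        if not self.min_pae < thresholds.max_min_pae:
            failed.append("pae")
        if not self.heavy_dist < thresholds.max_heavy_dist:
            failed.append("distance")
        return failed


@dataclass
class FixtureSpec:
    """Blueprint for one synthetic two-or-more-chain prediction.

    Background (unplanted) residues carry ``background_plddt`` (≤ 50, so any
    pair involving two of them fails the pLDDT filter) and pairwise pAE
    ``background_pae``; geometry keeps all background inter-chain pairs
    further apart than ``background_min_dist`` (> 8 Å), so planted truth is
    unambiguous at default thresholds.
    """

    chains: list[tuple[str, int]]
    planted_contacts: list[PlantedContact] = field(default_factory=list)
    background_min_dist: float = 20.0
    background_pae: float = 30.0
    background_plddt: float = 40.0
    atoms_per_residue: int = 1   # 1 = CA only; 3 = N, CA, C
    add_hydrogens: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        sizes = dict(self.chains)
        if len(sizes) != len(self.chains):
            raise ValueError("duplicate chain ids")
        if any(n < 1 for n in sizes.values()):
            raise ValueError("chains must have at least one residue")
        if not self.background_min_dist > 8.0:
            raise ValueError("background_min_dist must exceed 8 Å")
        if self.background_plddt > 50.0:
            raise ValueError("background_plddt must be ≤ 50 so background "
                             "pairs fail the pLDDT filter")
        if self.atoms_per_residue not in (1, 3):
            raise ValueError("atoms_per_residue must be 1 or 3")
        used: set[PlantedRes] = set()
        for pc in self.planted_contacts:
            for res in (pc.res_a, pc.res_b):
                cid, num = res
                if cid not in sizes:
                    raise ValueError(f"planted contact names unknown chain {cid!r}")
                if not 1 <= num <= sizes[cid]:
                    raise ValueError(f"planted residue {res} out of range")
                if res in used:
                    raise InfeasibleGeometryError(
                        f"residue {res} appears in more than one planted "
                        f"contact; placements would conflict")
                used.add(res)
            if pc.res_a[0] == pc.res_b[0]:
                raise ValueError(f"planted contact within one chain: {pc}")
            if not 0 < pc.heavy_dist < 8.0:
                raise ValueError(
                    f"planted heavy_dist must lie in (0, 8) Å, got {pc.heavy_dist}")
            if not (0 <= pc.plddt_a <= 100 and 0 <= pc.plddt_b <= 100):
                raise ValueError("planted pLDDT must lie in [0, 100]")

    @property
    def n_residues(self) -> int:
        return sum(n for _, n in self.chains)


# one-atom residues use CA; three-atom residues add N and C offset in the
# xy-plane so the CA-CA separation stays the minimum heavy-atom distance
_ATOM_OFFSETS = {
    1: [("CA", "C", np.zeros(3))],
    3: [("N", "N", np.array([-1.2, 0.5, 0.0])),
        ("CA", "C", np.zeros(3)),
        ("C", "C", np.array([1.2, 0.5, 0.0]))],
}
_H_OFFSET = np.array([0.4, -0.2, 0.0])


def _layout(spec: FixtureSpec) -> dict[PlantedRes, np.ndarray]:
    """Residue reference (CA) positions realizing the planted geometry."""
    grid = spec.background_min_dist + (3.0 if spec.atoms_per_residue == 3
                                       or spec.add_hydrogens else 0.0)
    pos: dict[PlantedRes, np.ndarray] = {}
    for k, (cid, n) in enumerate(spec.chains):
        for i in range(n):
            pos[(cid, i + 1)] = np.array([k * grid, i * grid, 0.0])
    chain_order = {cid: k for k, (cid, _) in enumerate(spec.chains)}
    for pc in spec.planted_contacts:
        # move the residue on the later chain onto its partner's z-axis
        base, moved = sorted((pc.res_a, pc.res_b),
                             key=lambda r: chain_order[r[0]])
        pos[moved] = pos[base] + np.array([0.0, 0.0, pc.heavy_dist])
    return pos


def _plddt_track(spec: FixtureSpec) -> dict[PlantedRes, float]:
    track = {(cid, i + 1): spec.background_plddt
             for cid, n in spec.chains for i in range(n)}
    for pc in spec.planted_contacts:
        track[pc.res_a] = pc.plddt_a
        track[pc.res_b] = pc.plddt_b
    return track


def _pae_matrix(spec: FixtureSpec) -> np.ndarray:
    index: dict[PlantedRes, int] = {}
    for cid, n in spec.chains:
        for i in range(n):
            index[(cid, i + 1)] = len(index)
    pae = np.full((len(index), len(index)), float(spec.background_pae))
    np.fill_diagonal(pae, 0.0)
    for pc in spec.planted_contacts:
        ia, ib = index[pc.res_a], index[pc.res_b]
        pae[ia, ib] = pc.pae_ab
        pae[ib, ia] = pc.pae_ba
    return pae


def fixture_manifest(spec: FixtureSpec,
                     thresholds: ContactThresholds = DEFAULT_THRESHOLDS) -> dict:
    """The analytic truth: expected contact keys at the given thresholds,
    planted-but-filtered contacts, and per-contact evidence."""
    planted = []
    expected = []
    filtered = []
    for pc in spec.planted_contacts:
        a, b = pc.key
        entry = {
            "res_a": list(a[:2]), "res_b": list(b[:2]),
            "heavy_dist": pc.heavy_dist,
            "avg_plddt": pc.avg_plddt, "min_pae": pc.min_pae,
            "passes": pc.passes(thresholds),
            "failed_filters": pc.failed_filters(thresholds),
        }
        planted.append(entry)
        (expected if entry["passes"] else filtered).append(
            [list(a[:2]), list(b[:2])])
    return {
        "chains": [[cid, n] for cid, n in spec.chains],
        "seed": spec.seed,
        "planted": planted,
        "expected_contacts": expected,
        "planted_but_filtered": filtered,
        "n_expected_contacts": len(expected),
    }


def build_prediction(spec: FixtureSpec, model_id: str = "model") -> BoundPrediction:
    """Realize a FixtureSpec in memory (no files)."""
    pos = _layout(spec)
    plddt = _plddt_track(spec)
    offsets = list(_ATOM_OFFSETS[spec.atoms_per_residue])
    chains = []
    for cid, n in spec.chains:
        residues = []
        for i in range(n):
            key = (cid, i + 1)
            atoms = [AtomRecord(name=name, element=el,
                                position=pos[key] + off, is_heavy=True)
                     for name, el, off in offsets]
            if spec.add_hydrogens:
                atoms.append(AtomRecord(name="H", element="H",
                                        position=pos[key] + _H_OFFSET,
                                        is_heavy=False))
            residues.append(ResidueRecord(chain_id=cid, seq_num=i + 1,
                                          icode=" ", res_name="ALA",
                                          atoms=atoms, plddt=plddt[key]))
        chains.append((cid, residues))
    model = StructureModel(model_id=model_id, chains=chains)
    return bind(model, PAEMatrix(values=_pae_matrix(spec)))


def _write_structure(spec: FixtureSpec, path: Path) -> None:
    pos = _layout(spec)
    plddt = _plddt_track(spec)
    offsets = list(_ATOM_OFFSETS[spec.atoms_per_residue])
    st = gemmi.Structure()
    st.add_model(gemmi.Model("1"))
    for cid, n in spec.chains:
        chain = gemmi.Chain(cid)
        for i in range(n):
            key = (cid, i + 1)
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(i + 1, " ")
            res.het_flag = "A"
            atom_specs = list(offsets)
            if spec.add_hydrogens:
                atom_specs = atom_specs + [("H", "H", _H_OFFSET)]
            for name, el, off in atom_specs:
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(el)
                p = pos[key] + off
                atom.pos = gemmi.Position(*np.round(p, 3))
                atom.b_iso = plddt[key]
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        st[0].add_chain(chain)
    st.setup_entities()
    if path.suffix in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


def _write_pae(spec: FixtureSpec, path: Path) -> None:
    pae = _pae_matrix(spec)
    doc = {"pae": pae.tolist(),
           "max_predicted_aligned_error": float(max(spec.background_pae,
                                                    pae.max()))}
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True)


@dataclass(frozen=True)
class FixturePaths:
    structure: Path
    pae: Path
    manifest: Path


def generate_fixture(spec: FixtureSpec, outdir: str | Path,
                     basename: str = "fixture",
                     structure_format: str = "pdb") -> FixturePaths:
    """Write one coordinate file (pLDDT in B-factors), its PAE JSON, and the
    truth manifest.  Deterministic: the same spec yields byte-identical
    files.  Raises :class:`InfeasibleGeometryError` before writing anything
    if planted placements conflict."""
    spec.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = {"pdb": ".pdb", "mmcif": ".cif"}[structure_format]
    paths = FixturePaths(structure=outdir / f"{basename}{ext}",
                         pae=outdir / f"{basename}_pae.json",
                         manifest=outdir / f"{basename}_manifest.json")
    _write_structure(spec, paths.structure)
    _write_pae(spec, paths.pae)
    with open(paths.manifest, "w") as fh:
        json.dump(fixture_manifest(spec), fh, sort_keys=True, indent=1)
    return paths


@dataclass
class EnsembleSpec:
    """M models over one base fixture, with a per-contact membership map
    stating which models realise each planted contact.  Contacts missing
    from the map default to membership in every model."""

    M: int
    base: FixtureSpec
    membership: dict[tuple, set[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be ≥ 1")
        keys = {pc.key for pc in self.base.planted_contacts}
        for key, models in self.membership.items():
            if key not in keys:
                raise ValueError(f"membership names unplanted contact {key}")
            if not models or not set(models) <= set(range(1, self.M + 1)):
                raise ValueError(
                    f"membership for {key} must be a non-empty subset of "
                    f"1..{self.M}, got {sorted(models)}")

    def models_of(self, pc: PlantedContact) -> set[int]:
        return set(self.membership.get(pc.key, range(1, self.M + 1)))

    def model_spec(self, m: int) -> FixtureSpec:
        """The fixture spec for model m: only member contacts are planted."""
        kept = [pc for pc in self.base.planted_contacts
                if m in self.models_of(pc)]
        return replace(self.base, planted_contacts=kept)


def ensemble_manifest(spec: EnsembleSpec,
                      thresholds: ContactThresholds = DEFAULT_THRESHOLDS) -> dict:
    """Analytic cross-model truth: per-contact model counts over the
    detectable (filter-passing) planted contacts, and the implied
    avg_n_models / max_n_models."""
    counts = {}
    for pc in spec.base.planted_contacts:
        if pc.passes(thresholds):
            counts[pc.key] = len(spec.models_of(pc))
    manifest = {
        "M": spec.M,
        "contacts": [{"res_a": list(k[0][:2]), "res_b": list(k[1][:2]),
                      "n_models": n} for k, n in sorted(counts.items())],
        "n_unique_contacts": len(counts),
        "avg_n_models": (float(np.mean(list(counts.values())))
                         if counts else None),
        "max_n_models": max(counts.values()) if counts else None,
    }
    return manifest


@dataclass(frozen=True)
class EnsemblePaths:
    models: tuple[FixturePaths, ...]
    manifest: Path


def generate_ensemble(spec: EnsembleSpec, outdir: str | Path,
                      basename: str = "ensemble") -> EnsemblePaths:
    """Write M structure/PAE file pairs plus the ensemble truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model_paths = tuple(
        generate_fixture(spec.model_spec(m), outdir,
                         basename=f"{basename}_model{m}")
        for m in range(1, spec.M + 1))
    manifest_path = outdir / f"{basename}_manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(ensemble_manifest(spec), fh, sort_keys=True, indent=1)
    return EnsemblePaths(models=model_paths, manifest=manifest_path)


def build_ensemble_predictions(spec: EnsembleSpec) -> list[BoundPrediction]:
    """Realize all M models of an ensemble in memory."""
    return [build_prediction(spec.model_spec(m), model_id=f"model{m}")
            for m in range(1, spec.M + 1)]


def random_fixture_spec(seed: int | np.random.Generator,
                        chain_ids: tuple[str, str] = ("A", "B"),
                        n_res_range: tuple[int, int] = (4, 25),
                        n_contacts_range: tuple[int, int] = (0, 8),
                        plddt_range: tuple[float, float] = (0.0, 100.0),
                        pae_range: tuple[float, float] = (0.0, 30.0),
                        dist_range: tuple[float, float] = (2.5, 7.9),
                        ) -> FixtureSpec:
    """Draw a random two-chain FixtureSpec: random chain lengths, random
    planted contacts with pLDDT, pAE and distances drawn uniformly from the
    given ranges (so planted contacts may or may not survive the filters)."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    ca, cb = chain_ids
    na = int(rng.integers(n_res_range[0], n_res_range[1] + 1))
    nb = int(rng.integers(n_res_range[0], n_res_range[1] + 1))
    k_max = min(n_contacts_range[1], na, nb)
    k = int(rng.integers(n_contacts_range[0], k_max + 1))
    res_a = rng.choice(na, size=k, replace=False) + 1
    res_b = rng.choice(nb, size=k, replace=False) + 1
    contacts = []
    for ra, rb in zip(res_a, res_b):
        contacts.append(PlantedContact(
            res_a=(ca, int(ra)), res_b=(cb, int(rb)),
            heavy_dist=round(float(rng.uniform(*dist_range)), 3),
            plddt_a=round(float(rng.uniform(*plddt_range)), 2),
            plddt_b=round(float(rng.uniform(*plddt_range)), 2),
            pae_ab=round(float(rng.uniform(*pae_range)), 3),
            pae_ba=round(float(rng.uniform(*pae_range)), 3),
        ))
    seed_val = int(rng.integers(2**31))
    return FixtureSpec(chains=[(ca, na), (cb, nb)], planted_contacts=contacts,
                       seed=seed_val)


def random_ensemble_spec(seed: int | np.random.Generator, M: int = 5,
                         **fixture_kwargs) -> EnsembleSpec:
    """Random ensemble: a random base fixture plus, per planted contact, a
    uniformly drawn non-empty membership subset of the M models."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    base = random_fixture_spec(rng, **fixture_kwargs)
    membership = {}
    for pc in base.planted_contacts:
        size = int(rng.integers(1, M + 1))
        models = rng.choice(M, size=size, replace=False) + 1
        membership[pc.key] = {int(m) for m in models}
    return EnsembleSpec(M=M, base=base, membership=membership)
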