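"""Shared fixtures: every structure/alignment fixture is generated at test
time by the synthetic module; nothing is downloaded or stored."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tklscan.superpose import RigidTransform
from tklscan.synthetic import PlantedHBond, ToyComplexSpec, make_toy_dimer

#: six H-bonds planted on distinct donors of the default seed-1 sequence
#: (QQFMAKDMETYVEYENGHSAYFYHDTVDKT): K6, T10, N16, H18, S19, K29
PLANTED_SIX = (
    PlantedHBond(6, "NZ", "O1", 2.9),
    PlantedHBond(10, "OG1", "O2", 2.8),
    PlantedHBond(16, "ND2", "O3", 3.0),
    PlantedHBond(18, "NE2", "N1", 3.1),
    PlantedHBond(19, "OG", "O4", 2.85),
    PlantedHBond(29, "NZ", "O5", 2.95),
)


def rotation(deg_xyz) -> np.ndarray:
    return Rotation.from_euler("xyz", deg_xyz, degrees=True).as_matrix()


@pytest.fixture(scope="session")
def planted_transform() -> RigidTransform:
    return RigidTransform(rotation([20.0, -35.0, 60.0]), np.array([5.0, -3.0, 8.0]))


@pytest.fixture(scope="session")
def toy_complex():
    """Template dimer with six planted H-bonds, identity query."""
    spec = ToyComplexSpec(seed=1, n_residues_per_chain=30, planted_hbonds=PLANTED_SIX)
    return make_toy_dimer(spec)


@pytest.fixture(scope="session")
def toy_pair(planted_transform):
    """Template/query pair related by a known transform, noise and deletion."""
    spec = ToyComplexSpec(
        seed=1,
        n_residues_per_chain=30,
        planted_hbonds=PLANTED_SIX,
        planted_transform=planted_transform,
        noise_sigma=0.1,
        planted_deletion=(22, 26),
    )
    return make_toy_dimer(spec)


def write_fixture_files(tmp_path, template, query, truth):
    """PDB + FASTA files for pipeline-level tests."""
    from tklscan.structure_io import write_structure

    write_structure(template, tmp_path / "template.pdb")
    write_structure(query, tmp_path / "query.pdb")
    aln = truth["alignment"]
    (tmp_path / "aln.fasta").write_text(
        "".join(f">{n}\n{r}\n" for n, r in zip(aln.names, aln.rows))
    )
    return tmp_path
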