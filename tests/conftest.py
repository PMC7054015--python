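"""Shared fixtures: small simulated ensembles and toy data, built once."""

from __future__ import annotations

import numpy as np
import pytest

from yeastnuc.geometry import NuclearGeometry
from yeastnuc.karyotype import Karyotype, simple_chromosome
from yeastnuc.simulate import (
    Ensemble,
    ForceField,
    SimulationSchedule,
    build_topology,
    run_ensemble,
)


@pytest.fixture(scope="session")
def geometry() -> NuclearGeometry:
    return NuclearGeometry()


@pytest.fixture(scope="session")
def small_karyotype() -> Karyotype:
    """Three short chromosomes (141 beads) for fast ensemble runs."""
    chroms = [
        simple_chromosome("c1", 200_000, 100_000),
        simple_chromosome("c2", 150_000, 60_000),
        simple_chromosome("c3", 100_000, 50_000),
    ]
    return Karyotype(chromosomes=chroms, name="small")


@pytest.fixture(scope="session")
def forcefield() -> ForceField:
    return ForceField()


@pytest.fixture(scope="session")
def small_ensemble(small_karyotype, geometry, forcefield) -> Ensemble:
    """60 equilibrated conformations of the small karyotype."""
    schedule = SimulationSchedule(
        prelim_duration=420.0,
        production_duration=300.0,
        sample_every=30.0,
        n_replicates=6,
    )
    ens = run_ensemble(
        small_karyotype, geometry, forcefield, schedule, master_seed=2024
    )
    assert ens.provenance["n_failed"] == 0
    return ens


@pytest.fixture(scope="session")
def small_topology(small_karyotype, forcefield):
    return build_topology(small_karyotype.build_chains(), forcefield)


@pytest.fixture(scope="session")
def toy_ensemble() -> Ensemble:
    """Five handcrafted conformations of 6 'beads' for brute-force checks."""
    rng = np.random.default_rng(99)
    confs = []
    from yeastnuc.simulate import Conformation

    for i in range(5):
        pos = rng.uniform(-550.0, 550.0, size=(6, 3))
        confs.append(Conformation(positions=pos, karyotype_name="toy", replicate=i))
    return Ensemble(conformations=confs, karyotype_name="toy")
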