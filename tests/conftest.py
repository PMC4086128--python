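"""Shared fixtures: synthetic systems generated at test time."""

import pathlib

import numpy as np
import pytest

from sitedock.cli import load_templates
from sitedock.fixtures import FixtureSpec, build_ligand, build_target, make_system
from sitedock.structio import read_protein


@pytest.fixture(scope="session")
def noisy_system(tmp_path_factory):
    """Three noisy templates (sigma 0.3 A) with a planted rigid ligand."""
    d = tmp_path_factory.mktemp("noisy")
    truth = make_system(FixtureSpec(template_noise=0.3, n_templates=3,
                                    seed=11), d)
    return d, truth


@pytest.fixture(scope="session")
def clean_system(tmp_path_factory):
    """Single noise-free template identical to the target (self-template)."""
    d = tmp_path_factory.mktemp("clean")
    truth = make_system(FixtureSpec(template_noise=0.0, n_templates=1,
                                    seed=5), d)
    return d, truth


@pytest.fixture(scope="session")
def clean_templates(clean_system):
    d, truth = clean_system
    target = read_protein(d / "target.pdb")
    tpls = load_templates(target, d / "templates", d / "alignments",
                          d / "scores.tsv")
    return target, tpls, truth


@pytest.fixture(scope="session")
def noisy_templates(noisy_system):
    d, truth = noisy_system
    target = read_protein(d / "target.pdb")
    tpls = load_templates(target, d / "templates", d / "alignments",
                          d / "scores.tsv")
    return target, tpls, truth


@pytest.fixture(scope="session")
def triatomic():
    return build_ligand("rigid_triatomic")


@pytest.fixture(scope="session")
def benzene():
    return build_ligand("benzene_like")


@pytest.fixture(scope="session")
def chain2():
    return build_ligand("flexible_chain", n_torsions=2)


@pytest.fixture(scope="session")
def small_target():
    return build_target(FixtureSpec(n_residues=20))
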