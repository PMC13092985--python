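"""Shared fixtures: the structural spec lattice and a simulated dataset."""

from __future__ import annotations

import itertools

import pytest

from stemscan.synthetic import TRNASpec, simulate_dataset


def lattice_specs(seeds=range(3)):
    """Every valid combination of AS pairs, unpinned end, bulge and mutations."""
    specs = []
    for as_pairs, unpinned, bulge, a9c, g24a, seed in itertools.product(
        range(2, 8),
        ("none", "top", "bottom"),
        ("none", "five_prime", "three_prime"),
        (False, True),
        (False, True),
        seeds,
    ):
        if unpinned != "none" and as_pairs != 4:
            continue
        specs.append(
            TRNASpec(
                as_pairs=as_pairs,
                unpinned=unpinned,
                bulge=bulge,
                plant_A9C=a9c,
                plant_G24A=g24a,
                seed=seed,
            )
        )
    return specs


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    path = tmp_path_factory.mktemp("dataset")
    simulate_dataset(path, seed=11)
    return path
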