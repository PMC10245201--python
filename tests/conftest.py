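import numpy as np
import pytest

from warnsig.distances import GlobalMatrix
from warnsig.synth import (PopulationSpec, RegionColorSpec, StudySpec,
                           default_render_spec, generate_phenotypes)


def region_colors(hue, hue_sd=5.0, sat=0.8, sat_sd=0.03):
    return {k: RegionColorSpec(hue_mean=hue, hue_sd=hue_sd,
                               sat_mean=sat, sat_sd=sat_sd)
            for k in ("head", "back", "limb")}


def make_population(species="A", locality="X", n=5, hue=45.0, hue_sd=5.0,
                    sat=0.8, sat_sd=0.03, dorsal=3.0, dorsal_sd=0.6,
                    limb=1.0, limb_sd=0.4, pattern_class="spotted",
                    convergence=0.0, partner=None):
    return PopulationSpec(
        species=species, locality=locality, n_individuals=n,
        colors=region_colors(hue, hue_sd, sat, sat_sd),
        dorsal_band_count_mean=dorsal, dorsal_band_count_sd=dorsal_sd,
        limb_band_count_mean=limb, limb_band_count_sd=limb_sd,
        pattern_class=pattern_class, convergence=convergence,
        partner_species=partner)


@pytest.fixture
def two_locality_study():
    """2 species x 2 localities, every population with allopatric conspecifics."""
    pops = [
        make_population("A", "X", hue=30.0, pattern_class="spotted"),
        make_population("B", "X", hue=150.0, pattern_class="striped"),
        make_population("A", "Y", hue=90.0, pattern_class="lined"),
        make_population("B", "Y", hue=270.0, pattern_class="diffuse"),
    ]
    sympatry = {"X": ["A", "B"], "Y": ["A", "B"]}
    return StudySpec(populations=pops, sympatry=sympatry, seed=11).validate()


@pytest.fixture
def phenotype_table(two_locality_study):
    return generate_phenotypes(two_locality_study)


@pytest.fixture
def render_spec():
    return default_render_spec()


def euclidean_global(coords, labels=None) -> GlobalMatrix:
    """Exact Euclidean distance matrix from planted coordinates."""
    coords = np.asarray(coords, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=-1))
    labels = labels or [f"i{k}" for k in range(len(coords))]
    return GlobalMatrix(list(labels), d)
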