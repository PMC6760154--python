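import numpy as np
import pytest

from mmc.model_core import (
    BiomassComposition,
    MetabolicNetwork,
    ModelVariant,
    build_toy_model,
    replete_heterotrophic_composition,
    replete_autotrophic_composition,
)


@pytest.fixture
def toy_auto() -> ModelVariant:
    return build_toy_model(replete_autotrophic_composition(), "autotrophic")


@pytest.fixture
def toy_het() -> ModelVariant:
    return build_toy_model(replete_heterotrophic_composition(), "heterotrophic")


@pytest.fixture
def aa16_composition() -> BiomassComposition:
    """Composition with nitrogen only in its 16% amino-acid share."""
    return BiomassComposition(
        fractions={
            "amino_acid": 0.16,
            "carbohydrate": 0.30,
            "lipid": 0.38,
            "chlorophyll": 0.01,
            "nucleotide": 0.03,
            "other": 0.12,
        },
        n_content={"amino_acid": 11.1},
        c_content={"amino_acid": 40.0, "carbohydrate": 37.0, "lipid": 63.0},
    )


@pytest.fixture
def aa16_variant(aa16_composition) -> ModelVariant:
    """Autotrophic toy whose biomass N demand is exactly 0.16*11.1 = 1.776."""
    return build_toy_model(aa16_composition, "autotrophic")


@pytest.fixture
def chain_variant() -> ModelVariant:
    """Minimal chain: uptake -> A, biomass consumes 2 A (yield 0.5 per A)."""
    network = MetabolicNetwork(
        metabolite_ids=["A"],
        reaction_ids=["UP", "GROW"],
        S=np.array([[1.0, -2.0]]),
        lb=np.array([0.0, 0.0]),
        ub=np.array([10.0, 1000.0]),
        biomass_rxn="GROW",
        uptake_rxns={"a": "UP"},
    )
    return ModelVariant(
        name="chain",
        network=network,
        composition=replete_autotrophic_composition(),
        trophic_mode="autotrophic",
    )
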