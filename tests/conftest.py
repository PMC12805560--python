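import pytest

from molforge import (
    add_hydrogens,
    build_model,
    default_style,
    embed_conformer,
    layout_grid,
    parse_smiles,
)
from molforge.styles import StyleSet
from dataclasses import replace


@pytest.fixture(scope="session")
def coarse_style() -> StyleSet:
    """Building-kit style at desk-scale tessellation for fast tests."""
    return replace(
        default_style("building_kit"), sphere_lat=4, sphere_lon=6, cyl_segments=5
    )


@pytest.fixture(scope="session")
def cyclohexane():
    """Hydrogen-explicit cyclohexane graph + a seed-7 conformer."""
    graph = add_hydrogens(parse_smiles("C1CCCCC1"))
    return graph, embed_conformer(graph, seed=7)


@pytest.fixture(scope="session")
def ethanol_scene(coarse_style):
    """A small labeled two-model scene (ethanol + methanol)."""
    models = []
    for smi in ("CCO", "CO"):
        graph = add_hydrogens(parse_smiles(smi))
        conf = embed_conformer(graph, seed=3)
        models.append((smi, build_model(graph, conf, coarse_style)))
    return layout_grid(models)
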