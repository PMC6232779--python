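"""Shared fixtures: study-sized PCR panels and a small pangenome config."""

import pytest

from cosymbio.infection_stats import call_panel
from cosymbio.synthetic_data import (
    ExpansionSpec,
    HgtSpec,
    SimulationConfig,
    TaxonSpec,
)
from cosymbio.types import PanelRow, PcrPanel


def make_panel(n_both: int, n_first_only: int, n_second_only: int, n_neither: int,
               host: str = "pos") -> PcrPanel:
    """Panel with the given coinfection 2x2 counts, all host controls `host`."""
    rows = []
    i = 0
    for count, (c, w) in (
        (n_both, ("pos", "pos")),
        (n_first_only, ("pos", "neg")),
        (n_second_only, ("neg", "pos")),
        (n_neither, ("neg", "neg")),
    ):
        for _ in range(count):
            i += 1
            rows.append(
                PanelRow(f"ind{i:05d}", "F", c, w, host)
            )
    return PcrPanel(rows).validate()


@pytest.fixture
def study_panel() -> PcrPanel:
    """The focal population's observed pattern: 62 coinfected, 61 first-only,
    no second-only, 4 uninfected (123/127 and 62/127 positive)."""
    return make_panel(62, 61, 0, 4)


@pytest.fixture
def study_calls(study_panel):
    return call_panel(study_panel)


def tiny_pangenome_config(seed: int = 7, **overrides) -> SimulationConfig:
    """Small, fast pangenome: 3 ingroup + 2 outgroup taxa, modest planted sets."""
    defaults = dict(
        seed=seed,
        taxa=(
            TaxonSpec("foc", 1_300_000, "focal"),
            TaxonSpec("inA", 900_000, "ingroup"),
            TaxonSpec("inB", 1_000_000, "ingroup"),
            TaxonSpec("outA", 1_900_000, "outgroup"),
            TaxonSpec("outB", 4_400_000, "outgroup"),
        ),
        n_core_universal=12,
        n_ingroup_core=5,
        n_taxon_unique={"foc": 4, "inA": 2, "inB": 2, "outA": 2, "outB": 2},
        expansion=ExpansionSpec(n_clusters=3, copy_range=(3, 6)),
        hgt=HgtSpec(n_recent=10, n_older=5, n_non=20),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults).validate()


@pytest.fixture
def tiny_config() -> SimulationConfig:
    return tiny_pangenome_config()
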