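"""Shared fixtures: one study-like synthetic dikaryon per session."""

from __future__ import annotations

import pytest

from meiospore.synthetic_data import DikaryonConfig, generate_dikaryon


@pytest.fixture(scope="session")
def dikaryon():
    """Default study-like dikaryon with sequences (seed fixed)."""
    return generate_dikaryon(DikaryonConfig(rng_seed=7))


@pytest.fixture(scope="session")
def genome_a(dikaryon):
    return dikaryon[0]


@pytest.fixture(scope="session")
def genome_b(dikaryon):
    return dikaryon[1]


@pytest.fixture(scope="session")
def truth(dikaryon):
    return dikaryon[2]


@pytest.fixture(scope="session")
def coord_dikaryon():
    """Sequence-free dikaryon for coordinate-only work (faster)."""
    return generate_dikaryon(DikaryonConfig(rng_seed=11, emit_sequence=False))
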