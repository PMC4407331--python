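"""Shared fixtures: the demo synthetic genome and its scan, built once."""

from __future__ import annotations

import pytest

from tequadscan.context import FullLengthRule, assign_zones
from tequadscan.scanner import ScanParams, scan_genome
from tequadscan.simulate import demo_spec, make_genome

DEMO_SEED = 7


@pytest.fixture(scope="session")
def demo_bundle():
    """(genome, annotations, truth) of the documented demo synthetic genome."""
    spec = demo_spec(seed=DEMO_SEED)
    return make_genome(spec)


@pytest.fixture(scope="session")
def demo_scan(demo_bundle):
    """(hits, assignments) of the default scan over the demo genome."""
    genome, annotations, _ = demo_bundle
    hits = scan_genome(genome, ScanParams())
    assignments = assign_zones(hits, annotations, flank=200)
    return hits, assignments


@pytest.fixture(scope="session")
def small_bundle():
    """A scaled-down genome for fast end-to-end runs."""
    spec = demo_spec(seed=3, scale=0.15)
    return make_genome(spec)
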