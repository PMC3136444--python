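"""Shared fixtures: small simulated data sets built at test time."""

import pandas as pd
import pytest

from ril_atlas import sim
from ril_atlas.genotypes import DIRECTION_FWD, DIRECTION_REV, GenotypeMatrix


@pytest.fixture(scope="session")
def tiny_sim():
    """8 lines x 24 markers across reciprocal directions, fixed seed."""
    return sim.make_fixture("tiny", seed=11)


@pytest.fixture(scope="session")
def medium_sim():
    """Neutral AI-RIL simulation big enough for map building (120 lines)."""
    genome = sim.default_genome(markers_per_chromosome=12)
    a = sim.simulate_cross(genome, sim.airil_design(DIRECTION_FWD, 60), seed=101)
    b = sim.simulate_cross(genome, sim.airil_design(DIRECTION_REV, 60), seed=102)
    return sim.merge_results(a, b)


def make_matrix(rows, markers=None, directions=None):
    """Small GenotypeMatrix from a dict of line -> list of call tokens."""
    line_ids = list(rows)
    n = len(rows[line_ids[0]])
    markers = markers or [f"m{i}" for i in range(n)]
    calls = pd.DataFrame([rows[l] for l in line_ids], index=line_ids, columns=markers)
    if directions is None:
        directions = {l: DIRECTION_FWD for l in line_ids}
    return GenotypeMatrix(calls, pd.Series(directions))


def make_marker_table(markers, chromosome="I", start_bp=1_000_000, step_bp=1_000_000,
                      genetic=None):
    rows = []
    for i, m in enumerate(markers):
        rows.append((m, chromosome, start_bp + i * step_bp,
                     0.0 if genetic is None else genetic[i], f"sctg_{i}", 100))
    return pd.DataFrame(rows, columns=["marker", "chromosome", "physical_bp",
                                       "genetic_cM", "supercontig", "supercontig_bp"])
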