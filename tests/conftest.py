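"""Shared fixtures: cohorts, tiny rendered studies, and constructed tables.

Simulation-backed fixtures are session-scoped because rendering a study and
running the embedding pipeline is the expensive part of the suite; every test
that can share a study does.
"""

import numpy as np
import pandas as pd
import pytest

import fibromorph as fm
from fibromorph.pipeline import well_embedding_table
from fibromorph.simulate import ExperimentPlan


@pytest.fixture(scope="session")
def default_cohort():
    lines, pairs = fm.build_cohort(fm.CohortSpec())
    return lines, pairs


@pytest.fixture(scope="session")
def default_layouts(default_cohort):
    lines, _ = default_cohort
    return fm.build_layouts(lines, seed=0)


@pytest.fixture(scope="session")
def micro_study():
    """Tiny rendered study with moderate line signal; no disease effect."""
    spec = fm.CohortSpec(line_effect_scale=1.5, donor_effect_scale=1.0,
                         disease_effect_scale=0.0, seed=7)
    return fm.SyntheticStudy(spec, fm.micro_plan(), seed=7)


@pytest.fixture(scope="session")
def micro_wells(micro_study):
    """Centered well-mean embedding profiles of the micro study."""
    return well_embedding_table(micro_study)


@pytest.fixture(scope="session")
def signal_study():
    """Strong planted line effects: between-line variance of the well
    profiles exceeds twice the within-line variance (checked in the
    acceptance tests), so line identity is recoverable across batch+layout."""
    spec = fm.CohortSpec(line_effect_scale=3.0, donor_effect_scale=1.0,
                         disease_effect_scale=0.0, seed=11)
    plan = ExperimentPlan(n_batches=2, plates_per_layout_per_batch=2,
                          tiles_per_well=6, image_height=96, image_width=96,
                          cells_per_tile_mean=12.0)
    return fm.SyntheticStudy(spec, plan, seed=11)


@pytest.fixture(scope="session")
def signal_wells(signal_study):
    return well_embedding_table(signal_study)


@pytest.fixture(scope="session")
def donor_study():
    """Strong shared donor effects, modest line effects: the repeat-biopsy
    lines resemble their donor's first biopsy."""
    spec = fm.CohortSpec(line_effect_scale=0.5, donor_effect_scale=2.0,
                         disease_effect_scale=0.0, seed=13)
    plan = ExperimentPlan(n_batches=2, plates_per_layout_per_batch=1,
                          tiles_per_well=4, image_height=96, image_width=96,
                          cells_per_tile_mean=10.0)
    return fm.SyntheticStudy(spec, plan, seed=13)


@pytest.fixture(scope="session")
def donor_wells(donor_study):
    return well_embedding_table(donor_study)


def make_well_table(n_batches=2, n_layouts=2, n_lines=8, wells_per=1,
                    n_dims=4, seed=0):
    """Constructed well-level table with Gaussian line signatures (no images)."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, 2, size=(n_lines, n_dims))
    rows = []
    plate = 0
    for b in range(1, n_batches + 1):
        for l in range(1, n_layouts + 1):
            plate += 1
            for rep in range(wells_per):
                for line in range(1, n_lines + 1):
                    vec = centers[line - 1] + rng.normal(0, 0.1, n_dims)
                    rows.append({
                        "batch": b, "plate": plate, "layout": l,
                        "well": f"A{line:02d}", "line_id": line,
                        "donor_id": line, "biopsy_index": 1,
                        "disease_state": "PD" if line % 2 else "healthy",
                        "mutation_group": "sporadic" if line % 2 else "none",
                        "age": 60.0, "sex": "M", "pair_id": (line + 1) // 2,
                        **{f"v{d}": vec[d] for d in range(n_dims)},
                    })
    return pd.DataFrame(rows)


@pytest.fixture
def toy_well_table():
    return make_well_table()
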