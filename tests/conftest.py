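from dataclasses import replace

import numpy as np
import pytest

from comireg import comi_core
from comireg.data_model import CoMiIndex, CoMiPattern, CoMiProfile
from comireg.synthetic_data import (
    Annotation,
    PlantedEffect,
    SimulationSpec,
    generate_annotation,
    generate_disease_cohort,
    generate_drug_library,
)


@pytest.fixture(scope="session")
def default_spec() -> SimulationSpec:
    return SimulationSpec(seed=11)


@pytest.fixture(scope="session")
def annotation(default_spec) -> Annotation:
    return generate_annotation(default_spec)


@pytest.fixture(scope="session")
def patterns(default_spec, annotation):
    return comi_core.discover_patterns(
        annotation.targets, annotation.sets, annotation.universe, alpha=0.05
    )


@pytest.fixture(scope="session")
def disease_profile(default_spec, annotation, patterns) -> CoMiProfile:
    case, control = generate_disease_cohort(default_spec, annotation)
    fc = comi_core.fold_change(case, control, paired=True)
    return comi_core.compute_profile(
        patterns, fc, mode="differential", condition_id="disease"
    )


@pytest.fixture(scope="session")
def drug_library(default_spec, annotation, patterns):
    case, control = generate_disease_cohort(default_spec, annotation)
    fc = comi_core.fold_change(case, control, paired=True)
    return generate_drug_library(default_spec, annotation, patterns, disease_fc=fc)


@pytest.fixture(scope="session")
def small_power_spec() -> SimulationSpec:
    """One planted repression with the canonical 20-target / 80-non-target
    split, in a compact 200-gene universe (fast enough for many replicates)."""
    return SimulationSpec(
        n_genes=200,
        n_mirnas=5,
        n_terms=6,
        term_size_range=(30, 80),
        target_density=0.12,
        planted_effects=(PlantedEffect("mir-001", "go-001", -1.0, "disease"),),
        seed=5,
    )


def make_pattern(mirna="mir-x", term="go-x", n_t=3, n_nt=4, prefix="g"):
    t_genes = frozenset(f"{prefix}T{i}" for i in range(n_t))
    nt_genes = frozenset(f"{prefix}N{i}" for i in range(n_nt))
    return CoMiPattern(
        mirna=mirna,
        term=term,
        target_in_set=t_genes,
        nontarget_in_set=nt_genes,
        overlap_p=0.01,
    )


def profile_from_stats(stats: dict, condition_id="toy") -> CoMiProfile:
    """Build a profile whose indices carry the given {key: statistic} map."""
    indices = {}
    for (mirna, term), stat in stats.items():
        pattern = CoMiPattern(
            mirna=mirna,
            term=term,
            target_in_set=frozenset(),
            nontarget_in_set=frozenset(),
            overlap_p=0.01,
            n_T=3,
            n_NT=4,
        )
        indices[pattern.key] = CoMiIndex(
            pattern=pattern, statistic=float(stat), p_value=0.5 if stat == 0 else 0.01
        )
    return CoMiProfile(condition_id=condition_id, indices=indices)
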