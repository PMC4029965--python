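"""Seeded synthetic fixtures with the statistical structure the CoMi method
assumes.

The generators emulate, at desk scale, the three data layers the pipeline
consumes: (a) a paired tumor/normal expression cohort in which planted
miRNA effects repress (or induce) the miRNA's target genes *inside* specific
gene sets, (b) a drug-profile library in which a few "true drug" instances
invert the planted disease effects among random decoys, and (c) a patient
cohort with class-imbalanced binary outcomes in which responders carry
expression shifts on a subset of patterns.

Everything is a pure function of (spec, seed): the same spec yields
byte-identical fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from . import comi_core
from .data_model import (
    CoMiPattern,
    CoMiProfile,
    DrugInstance,
    ExpressionMatrix,
    GeneSetCollection,
    PatternKey,
    TargetMap,
)
from .response_predictor import CohortMatrix

Condition = Literal["disease", "drug", "response"]


@dataclass(frozen=True)
class PlantedEffect:
    """An expression shift (in units of noise SD) applied to the target genes
    of one (miRNA, term) pair under one condition."""

    mirna: str
    term: str
    shift: float
    condition: Condition = "disease"


def _default_effects() -> list[PlantedEffect]:
    # three repressive disease effects + ten inductive response effects,
    # each on its own term so the forced overlaps never collide
    effects = [
        PlantedEffect(f"mir-{i:03d}", f"go-{i:03d}", -1.0, "disease") for i in (1, 2, 3)
    ]
    effects += [
        PlantedEffect(f"mir-{(i - 4) % 10 + 1:03d}", f"go-{i:03d}", 1.0, "response")
        for i in range(4, 14)
    ]
    return effects


@dataclass(frozen=True)
class SimulationSpec:
    """All knobs of the synthetic study, with defaults matching the study
    conditions the pipeline is calibrated for.

    The planted (miRNA, term) pairs get a forced target/non-target split of
    ``planted_overlap`` / ``planted_term_size - planted_overlap`` genes
    (20/80 by default) so their hypergeometric gate passes by construction.
    """

    n_genes: int = 800
    n_mirnas: int = 10
    n_terms: int = 40
    term_size_range: tuple[int, int] = (30, 100)
    target_density: float = 0.08
    planted_effects: tuple[PlantedEffect, ...] = field(
        default_factory=lambda: tuple(_default_effects())
    )
    noise_sd: float = 1.0
    pair_effect_sd: float = 1.0
    n_case: int = 43
    n_control: int = 43
    n_patients: int = 178
    pcr_fraction: float = 26 / 178
    n_true_drugs: int = 5
    n_decoys: int = 50
    instances_per_drug: int = 1
    planted_overlap: int = 20
    planted_term_size: int = 100
    term_enrich_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genes", "n_mirnas", "n_terms", "n_case", "n_control",
            "n_patients", "n_true_drugs", "n_decoys", "instances_per_drug",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.pcr_fraction < 1):
            raise ValueError("pcr_fraction must lie in (0, 1)")
        if not (0 < self.target_density < 1):
            raise ValueError("target_density must lie in (0, 1)")
        lo, hi = self.term_size_range
        if not (1 <= lo <= hi <= self.n_genes):
            raise ValueError("term_size_range infeasible for n_genes")
        if self.planted_term_size > self.n_genes:
            raise ValueError("planted_term_size exceeds n_genes")
        if not (1 <= self.planted_overlap < self.planted_term_size):
            raise ValueError("planted_overlap must leave both subsets non-empty")
        for eff in self.planted_effects:
            if not math.isfinite(eff.shift):
                raise ValueError("planted shift must be finite")

    @property
    def drug_fc_noise_sd(self) -> float:
        """SD of a synthetic drug fold-change vector: matches the sampling
        noise of a paired cohort of n_case pairs."""
        return self.noise_sd * math.sqrt(2.0 / self.n_case)

    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(1, self.n_genes + 1)]

    def mirna_ids(self) -> list[str]:
        return [f"mir-{i:03d}" for i in range(1, self.n_mirnas + 1)]

    def term_ids(self) -> list[str]:
        return [f"go-{i:03d}" for i in range(1, self.n_terms + 1)]

    def effects(self, condition: Condition) -> list[PlantedEffect]:
        return [e for e in self.planted_effects if e.condition == condition]


@dataclass
class Annotation:
    """Target map + gene sets + declared universe, as one consistent bundle."""

    targets: TargetMap
    sets: GeneSetCollection
    universe: frozenset[str]


def generate_annotation(spec: SimulationSpec) -> Annotation:
    """Random target sets and gene sets with controlled overlap.

    Non-planted terms are seeded with an enriched overlap for a random
    subset of miRNAs (probability ``term_enrich_prob`` each, at most two per
    term) so the discovered pattern count is realistic; planted terms get
    their exact forced split.  Every planted (miRNA, term) pair is verified
    to pass the hypergeometric gate at alpha = 0.05 (redrawn otherwise).
    """
    genes = spec.gene_ids()
    mirnas = spec.mirna_ids()
    terms = spec.term_ids()
    planted_by_term = {e.term: e for e in spec.planted_effects}
    unknown = set(planted_by_term) - set(terms)
    if unknown:
        raise ValueError(f"planted effects reference unknown terms: {sorted(unknown)}")
    if len(planted_by_term) != len(spec.planted_effects):
        raise ValueError("at most one planted effect per term is supported")
    rng = np.random.default_rng(spec.seed)
    for attempt in range(20):
        targets: dict[str, frozenset[str]] = {}
        for mirna in mirnas:
            mask = rng.random(spec.n_genes) < spec.target_density
            tset = {g for g, m in zip(genes, mask) if m}
            while len(tset) < spec.planted_overlap + 1:
                tset.add(genes[int(rng.integers(spec.n_genes))])
            targets[mirna] = frozenset(tset)
        targeted_by_any: set[str] = set().union(*targets.values())
        # planted terms isolate their regulator: the forced target genes
        # prefer genes targeted only by the planted miRNA, and the
        # non-target fill prefers genes no miRNA targets, so no sibling
        # miRNA is spuriously enriched on a planted term
        planted_supports: dict[str, frozenset[str]] = {}
        sets: dict[str, tuple[str, frozenset[str]]] = {}
        used_support: set[str] = set()
        used_fill: set[str] = set()

        def draw(pools: list[set[str]], k: int) -> list[str]:
            # take k genes walking preference tiers, shuffled within a tier
            chosen: list[str] = []
            for pool in pools:
                remaining = sorted(pool - set(chosen))
                if not remaining:
                    continue
                take = min(k - len(chosen), len(remaining))
                chosen.extend(rng.choice(remaining, size=take, replace=False))
                if len(chosen) == k:
                    break
            if len(chosen) < k:
                raise RuntimeError("gene pools exhausted for a planted term")
            return chosen

        for term in terms:
            if term not in planted_by_term:
                sets[term] = (term, frozenset())  # filled after supports are fixed
                continue
            mirna = planted_by_term[term].mirna
            others: set[str] = set().union(
                frozenset(), *(t for m, t in targets.items() if m != mirna)
            )
            exclusive = targets[mirna] - others
            shared = targets[mirna] & others
            chosen_t = draw(
                [exclusive - used_support, shared - used_support, exclusive, shared],
                spec.planted_overlap,
            )
            used_support |= set(chosen_t)
            untargeted = set(genes) - targeted_by_any
            other_nt = set(genes) - targets[mirna] - untargeted
            chosen_nt = draw(
                [untargeted - used_fill, untargeted, other_nt - used_support],
                spec.planted_term_size - spec.planted_overlap,
            )
            used_fill |= set(chosen_nt)
            sets[term] = (term, frozenset(chosen_t) | frozenset(chosen_nt))
            planted_supports[term] = frozenset(chosen_t)
        # decoy terms avoid the planted (shifted) gene supports so planted
        # effects stay attributable to their own pattern
        shifted_genes: set[str] = set().union(*planted_supports.values()) if planted_supports else set()
        for term in terms:
            if term in planted_by_term:
                continue
            size = int(rng.integers(spec.term_size_range[0], spec.term_size_range[1] + 1))
            members_set: set[str] = set()
            n_enriched = 0
            for mirna in mirnas:
                if n_enriched >= 2:
                    break
                if rng.random() < spec.term_enrich_prob:
                    n_enriched += 1
                    mu = spec.target_density * size
                    k_force = int(math.ceil(mu + 3.0 * math.sqrt(mu) + 2))
                    pool = sorted(targets[mirna] - shifted_genes)
                    k_force = min(k_force, len(pool), max(size - 5, 1))
                    members_set |= set(rng.choice(pool, size=k_force, replace=False))
            fill = [g for g in genes if g not in members_set and g not in shifted_genes]
            n_fill = min(max(size - len(members_set), 0), len(fill))
            if n_fill:
                members_set |= set(rng.choice(fill, size=n_fill, replace=False))
            sets[term] = (term, frozenset(members_set))
        annotation = Annotation(
            targets=TargetMap(targets=targets),
            sets=GeneSetCollection(sets=sets),
            universe=frozenset(genes),
        )
        if _planted_pass_gate(spec, annotation):
            return annotation
    raise RuntimeError("could not satisfy planted overlap gates in 20 redraws")


def _planted_pass_gate(spec: SimulationSpec, annotation: Annotation) -> bool:
    N = len(annotation.universe)
    for eff in spec.planted_effects:
        m = annotation.targets.targets[eff.mirna]
        g = annotation.sets.genes(eff.term)
        k = len(m & g)
        if k < 1 or len(g - m) < 1:
            return False
        p = comi_core.hypergeom_overlap_p(k, len(m), len(g), N)
        if p > 0.05:
            return False
    return True


def planted_genes(annotation: Annotation, effect: PlantedEffect) -> frozenset[str]:
    """The genes an effect acts on: targets of its miRNA inside its term."""
    return annotation.targets.targets[effect.mirna] & annotation.sets.genes(effect.term)


def generate_disease_cohort(
    spec: SimulationSpec, annotation: Annotation
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Paired case/control expression on a log2-like scale.

    Pair i shares a per-(gene, pair) baseline (between-subject variation,
    SD ``pair_effect_sd``); each tissue adds independent N(0, noise_sd)
    noise.  Each planted disease effect shifts the case values of its
    target-in-term genes by ``shift`` noise-SD units.  Pairing is by column
    order (tumor_i with normal_i).
    """
    if spec.n_case != spec.n_control:
        raise ValueError("paired cohort requires n_case == n_control")
    rng = np.random.default_rng(spec.seed + 1)
    genes = spec.gene_ids()
    n = spec.n_case
    baseline = rng.normal(0.0, spec.pair_effect_sd, size=(spec.n_genes, n))
    control = baseline + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n))
    case = baseline + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n))
    gene_index = {g: i for i, g in enumerate(genes)}
    for eff in spec.effects("disease"):
        rows = [gene_index[g] for g in sorted(planted_genes(annotation, eff))]
        case[rows, :] += eff.shift * spec.noise_sd
    case_m = ExpressionMatrix(
        gene_ids=genes,
        sample_ids=[f"tumor_{i:03d}" for i in range(1, n + 1)],
        values=case,
    )
    control_m = ExpressionMatrix(
        gene_ids=genes,
        sample_ids=[f"normal_{i:03d}" for i in range(1, n + 1)],
        values=control,
    )
    return case_m, control_m


def generate_drug_library(
    spec: SimulationSpec,
    annotation: Annotation,
    patterns: Sequence[CoMiPattern],
    disease_fc: comi_core.FoldChangeVector | None = None,
) -> list[DrugInstance]:
    """A drug-profile library with planted treatments among decoys.

    True drugs counteract the disease: when ``disease_fc`` (the realized
    case-vs-control fold-change vector) is given, a true drug's fold-change
    effect is its negation; otherwise only the planted disease shifts are
    negated.  Decoys carry one random effect of comparable magnitude on a
    randomly chosen pattern.  Every instance's fold-change vector gets
    sampling noise matching a cohort of ``n_case`` pairs and is converted to
    a CoMi profile over ``patterns``.
    """
    if not patterns:
        raise ValueError("no patterns supplied")
    rng = np.random.default_rng(spec.seed + 2)
    genes = spec.gene_ids()
    gene_index = {g: i for i, g in enumerate(genes)}
    disease_effects = spec.effects("disease")
    mean_mag = (
        float(np.mean([abs(e.shift) for e in disease_effects])) if disease_effects else 1.0
    )
    base_fc = None
    if disease_fc is not None:
        if disease_fc.gene_ids != genes:
            raise ValueError("disease_fc gene universe differs from the spec's")
        base_fc = disease_fc.values
    pattern_list = sorted(patterns, key=lambda p: p.key)
    library: list[DrugInstance] = []

    def build_instance(inst_id: str, name: str, positive: bool, fc: np.ndarray) -> DrugInstance:
        profile = comi_core.compute_profile(
            pattern_list,
            dict(zip(genes, fc)),
            mode="differential",
            condition_id=inst_id,
        )
        return DrugInstance(
            instance_id=inst_id,
            drug_name=name,
            cell_line="SYN1",
            concentration="1uM",
            profile=profile,
            is_positive=positive,
        )

    for d in range(1, spec.n_true_drugs + 1):
        for j in range(1, spec.instances_per_drug + 1):
            fc = rng.normal(0.0, spec.drug_fc_noise_sd, size=spec.n_genes)
            if base_fc is not None:
                fc -= base_fc
            else:
                for eff in disease_effects:
                    rows = [gene_index[g] for g in sorted(planted_genes(annotation, eff))]
                    fc[rows] -= eff.shift * spec.noise_sd
            library.append(
                build_instance(f"true{d:03d}_i{j}", f"truedrug-{d:03d}", True, fc)
            )
    for d in range(1, spec.n_decoys + 1):
        for j in range(1, spec.instances_per_drug + 1):
            fc = rng.normal(0.0, spec.drug_fc_noise_sd, size=spec.n_genes)
            pat = pattern_list[int(rng.integers(len(pattern_list)))]
            sign = 1.0 if rng.random() < 0.5 else -1.0
            rows = [gene_index[g] for g in sorted(pat.target_in_set)]
            fc[rows] += sign * mean_mag * spec.noise_sd
            library.append(
                build_instance(f"decoy{d:03d}_i{j}", f"decoy-{d:03d}", False, fc)
            )
    return library


def generate_patient_cohort(
    spec: SimulationSpec,
    annotation: Annotation,
    patterns: Sequence[CoMiPattern],
    predictive_patterns: Sequence[PatternKey] | None = None,
) -> CohortMatrix:
    """Patient expression → per-sample CoMi statistics with pCR labels.

    Responders (label 1, ``pcr_fraction`` of patients) carry the planted
    response shifts on the predictive patterns' target-in-term genes; all
    other expression is N(0, noise_sd).  ``predictive_patterns`` defaults to
    the spec's response-condition effects and must be a subset of the
    discovered patterns.
    """
    if not patterns:
        raise ValueError("no patterns supplied")
    pattern_keys = {p.key for p in patterns}
    response_effects = spec.effects("response")
    if predictive_patterns is None:
        predictive = [(e.mirna, e.term) for e in response_effects]
    else:
        predictive = list(predictive_patterns)
    missing = set(predictive) - pattern_keys
    if missing:
        raise ValueError(f"predictive patterns not discovered: {sorted(missing)}")
    effect_by_key = {(e.mirna, e.term): e for e in response_effects}
    rng = np.random.default_rng(spec.seed + 3)
    genes = spec.gene_ids()
    gene_index = {g: i for i, g in enumerate(genes)}
    n_pos = int(round(spec.pcr_fraction * spec.n_patients))
    labels = np.zeros(spec.n_patients, dtype=int)
    labels[rng.choice(spec.n_patients, size=n_pos, replace=False)] = 1
    expr = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, spec.n_patients))
    responders = np.flatnonzero(labels == 1)
    for key in predictive:
        eff = effect_by_key.get(key)
        if eff is None:
            continue
        rows = [gene_index[g] for g in sorted(planted_genes(annotation, eff))]
        expr[np.ix_(rows, responders)] += eff.shift * spec.noise_sd
    sample_ids = [f"patient_{i:03d}" for i in range(1, spec.n_patients + 1)]
    pattern_list = sorted(patterns, key=lambda p: p.key)
    values = np.empty((len(pattern_list), spec.n_patients))
    for j in range(spec.n_patients):
        sample = dict(zip(genes, expr[:, j]))
        profile = comi_core.compute_profile(
            pattern_list, sample, mode="per_sample", condition_id=sample_ids[j]
        )
        for i, pat in enumerate(pattern_list):
            values[i, j] = profile.indices[pat.key].statistic
    return CohortMatrix(
        feature_keys=[p.key for p in pattern_list],
        sample_ids=sample_ids,
        values=values,
        labels=labels,
    )
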