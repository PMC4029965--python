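"""Domain types and file formats shared by every stage of the CoMi pipeline.

A *CoMi pattern* is a fixed (miRNA, gene-set) pair whose target-gene overlap
inside the set is significant by a hypergeometric test; the pattern freezes the
target / non-target partition of the set.  A *CoMi index* quantifies, for one
condition or one sample, how differently the pattern's target genes behave
relative to its non-target genes (a signed two-sample statistic).  A *CoMi
profile* collects the indices of all patterns for one condition; profiles feed
network construction, drug screening and response prediction.

File formats handled here are deliberately plain: tab-delimited expression
matrices, Broad-dialect GMT gene sets, two-column miRNA→target maps, and a
versioned tab-delimited profile format.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROFILE_FORMAT_VERSION = 1

#: direction labels for a CoMi index
TARGET_UP = "target_up"
TARGET_DOWN = "target_down"
NULL_DIRECTION = "null"

PatternKey = tuple[str, str]


class FormatError(ValueError):
    """A malformed input file (bad cell, wrong field count, bad version tag)."""


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A genes × samples matrix of log-scale expression values."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    sample_labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def column(self, sample_id: str) -> dict[str, float]:
        """Per-gene values of one sample, as a gene → value mapping."""
        j = self.sample_ids.index(sample_id)
        return dict(zip(self.gene_ids, self.values[:, j]))


@dataclass
class GeneSetCollection:
    """term_id → (term_name, set of gene symbols)."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for term, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {term!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def genes(self, term: str) -> frozenset[str]:
        return self.sets[term][1]

    def term_ids(self) -> list[str]:
        return sorted(self.sets)

    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.sets.values():
            out |= genes
        return frozenset(out)


@dataclass
class TargetMap:
    """miRNA id → set of target gene symbols."""

    targets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for mirna, genes in self.targets.items():
            if not genes:
                raise ValueError(f"miRNA {mirna!r} has an empty target set")

    def __len__(self) -> int:
        return len(self.targets)

    def mirna_ids(self) -> list[str]:
        return sorted(self.targets)


@dataclass(frozen=True)
class CoMiPattern:
    """A (miRNA, term) pair with its frozen target / non-target partition.

    ``target_in_set`` are the genes of the term hit by the miRNA,
    ``nontarget_in_set`` the remaining genes of the term (restricted to the
    declared universe); ``overlap_p`` is the upper-tail hypergeometric
    p-value of the overlap.  Patterns read back from a profile file are
    *detached*: they keep the counts but carry empty gene sets.
    """

    mirna: str
    term: str
    target_in_set: frozenset[str]
    nontarget_in_set: frozenset[str]
    overlap_p: float
    n_T: int = -1
    n_NT: int = -1

    def __post_init__(self) -> None:
        if self.target_in_set & self.nontarget_in_set:
            raise ValueError("target and non-target subsets must be disjoint")
        if self.n_T < 0:
            object.__setattr__(self, "n_T", len(self.target_in_set))
        if self.n_NT < 0:
            object.__setattr__(self, "n_NT", len(self.nontarget_in_set))
        if self.target_in_set and self.n_T != len(self.target_in_set):
            raise ValueError("n_T inconsistent with target_in_set")
        if self.nontarget_in_set and self.n_NT != len(self.nontarget_in_set):
            raise ValueError("n_NT inconsistent with nontarget_in_set")
        if self.n_T < 1 or self.n_NT < 1:
            raise ValueError("pattern needs at least one target and one non-target gene")

    @property
    def key(self) -> PatternKey:
        return (self.mirna, self.term)

    @property
    def genes(self) -> frozenset[str]:
        return self.target_in_set | self.nontarget_in_set

    def detached(self) -> "CoMiPattern":
        """A copy that keeps only counts (used after round-tripping files)."""
        return CoMiPattern(
            mirna=self.mirna,
            term=self.term,
            target_in_set=frozenset(),
            nontarget_in_set=frozenset(),
            overlap_p=self.overlap_p,
            n_T=self.n_T,
            n_NT=self.n_NT,
        )


@dataclass(frozen=True)
class CoMiIndex:
    """Signed statistic + p-value for one pattern under one condition/sample.

    ``statistic`` > 0 means the pattern's target genes are up-regulated
    relative to the non-targets; < 0 means repressed.  ``degenerate`` flags
    indices whose variance structure did not admit a proper t p-value.
    """

    pattern: CoMiPattern
    statistic: float
    p_value: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if not math.isfinite(self.statistic):
            raise ValueError("statistic must be finite (degenerate cases are capped)")

    @property
    def direction(self) -> str:
        if self.statistic > 0:
            return TARGET_UP
        if self.statistic < 0:
            return TARGET_DOWN
        return NULL_DIRECTION

    @property
    def key(self) -> PatternKey:
        return self.pattern.key


@dataclass
class CoMiProfile:
    """All CoMi indices of one condition or one sample."""

    condition_id: str
    indices: dict[PatternKey, CoMiIndex]

    def __post_init__(self) -> None:
        for key, idx in self.indices.items():
            if key != idx.key:
                raise ValueError(f"index stored under wrong key {key}")

    def __len__(self) -> int:
        return len(self.indices)

    def keys(self) -> list[PatternKey]:
        return sorted(self.indices)

    def statistics(self) -> dict[PatternKey, float]:
        return {k: self.indices[k].statistic for k in self.keys()}


@dataclass(frozen=True)
class CoMiSignature:
    """Query signature: the k most up- and k most down-regulated patterns."""

    k: int
    up_tags: tuple[PatternKey, ...]
    down_tags: tuple[PatternKey, ...]

    def __post_init__(self) -> None:
        if len(self.up_tags) != self.k or len(self.down_tags) != self.k:
            raise ValueError("up/down tags must each contain exactly k patterns")
        if set(self.up_tags) & set(self.down_tags):
            raise ValueError("up and down tags overlap")

    @property
    def patterns(self) -> tuple[PatternKey, ...]:
        return self.up_tags + self.down_tags


@dataclass
class DrugInstance:
    """One perturbation profile (drug × concentration × cell line)."""

    instance_id: str
    drug_name: str
    cell_line: str
    concentration: str
    profile: CoMiProfile
    is_positive: bool


@dataclass
class RankedDrugList:
    """Library instances ranked ascending by connectivity (Spearman) score."""

    instances: list[DrugInstance]
    scores: list[float]
    positive_positions: list[int]
    N: int
    n_pos: int

    def __post_init__(self) -> None:
        if len(self.instances) != self.N or len(self.scores) != self.N:
            raise ValueError("instances/scores length must equal N")
        if sorted(self.scores) != self.scores:
            raise ValueError("scores must be sorted ascending")
        if len(self.positive_positions) != self.n_pos:
            raise ValueError("positive_positions length must equal n_pos")
        if any(not (1 <= v <= self.N) for v in self.positive_positions):
            raise ValueError("positive positions outside 1..N")


@dataclass(frozen=True)
class DSPResult:
    """Drug Screening Performance: KS enrichment score + permutation p-value."""

    ks_score: float
    p_value: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        if abs(self.ks_score) > 1:
            raise ValueError("KS score outside [-1, 1]")
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value outside (0, 1]")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a tab-delimited expression matrix (first column = gene ids).

    Duplicate gene rows are collapsed by arithmetic mean (with a logged
    warning).  Non-numeric cells raise :class:`FormatError` naming the cell;
    missing values are rejected.
    """
    if dialect != "tsv":
        raise ValueError(f"unsupported dialect {dialect!r}")
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    if raw.empty or raw.shape[1] == 0:
        raise FormatError(f"{path}: empty expression matrix")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {raw.iat[i, j]!r} at gene "
            f"{raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: missing value at gene {numeric.index[i]!r}, "
            f"sample {numeric.columns[j]!r}"
        )
    if numeric.index.has_duplicates:
        n_dup = int(numeric.index.duplicated().sum())
        logger.warning("%s: collapsing %d duplicate gene rows by mean", path, n_dup)
        numeric = numeric.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(
        gene_ids=[str(g) for g in numeric.index],
        sample_ids=[str(s) for s in numeric.columns],
        values=numeric.to_numpy(dtype=float),
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(Path(path), sep="\t", index_label="gene_id", float_format="%.12g")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: term TAB description TAB gene1 TAB ..."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            term, name = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {term!r} has no genes")
            sets[term] = (name, genes)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        for term in collection.term_ids():
            name, genes = collection.sets[term]
            fh.write("\t".join([term, name, *sorted(genes)]) + "\n")


def read_target_map(path: str | Path) -> TargetMap:
    """Read a two-column (miRNA, target gene) tab-delimited map."""
    targets: dict[str, set[str]] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            mirna, gene = fields
            targets.setdefault(mirna, set()).add(gene)
    return TargetMap(targets={m: frozenset(g) for m, g in targets.items()})


def write_target_map(tmap: TargetMap, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        for mirna in tmap.mirna_ids():
            for gene in sorted(tmap.targets[mirna]):
                fh.write(f"{mirna}\t{gene}\n")


def read_sample_labels(path: str | Path) -> dict[str, str]:
    """Two-column (sample_id, label) tab-delimited metadata."""
    labels: dict[str, str] = {}
    with open(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields")
            labels[fields[0]] = fields[1]
    return labels


def restrict_collection(
    collection: GeneSetCollection, universe: Iterable[str]
) -> GeneSetCollection:
    """Drop genes outside ``universe`` from every set; drop emptied sets.

    Used to align a gene-set collection with the measured gene universe
    before pattern discovery.
    """
    uni = frozenset(universe)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    dropped = 0
    for term, (name, genes) in collection.sets.items():
        kept = genes & uni
        if kept:
            sets[term] = (name, kept)
        else:
            dropped += 1
    if dropped:
        logger.warning("dropped %d gene sets with no measured genes", dropped)
    return GeneSetCollection(sets=sets)


# pattern serialization: versioned TSV carrying the frozen partitions

_PATTERN_COLUMNS = [
    "mirna", "term", "n_T", "n_NT", "overlap_p", "target_genes", "nontarget_genes",
]


def write_patterns(
    patterns: Sequence[CoMiPattern], path: str | Path, header_extra: str = ""
) -> None:
    with open(Path(path), "w") as fh:
        fh.write(f"# comireg-patterns\tversion={PROFILE_FORMAT_VERSION}\tn={len(patterns)}")
        if header_extra:
            fh.write(f"\t{header_extra}")
        fh.write("\n")
        fh.write("\t".join(_PATTERN_COLUMNS) + "\n")
        for p in sorted(patterns, key=lambda p: p.key):
            fh.write(
                f"{p.mirna}\t{p.term}\t{p.n_T}\t{p.n_NT}\t{p.overlap_p:.17g}\t"
                f"{','.join(sorted(p.target_in_set))}\t"
                f"{','.join(sorted(p.nontarget_in_set))}\n"
            )


def read_patterns(path: str | Path) -> list[CoMiPattern]:
    path = Path(path)
    patterns: list[CoMiPattern] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("# comireg-patterns"):
            raise FormatError(f"{path}: not a comireg pattern file")
        meta = dict(part.split("=", 1) for part in header.split("\t")[1:] if "=" in part)
        if int(meta.get("version", -1)) != PROFILE_FORMAT_VERSION:
            raise FormatError(f"{path}: unsupported pattern file version")
        columns = fh.readline().rstrip("\n").split("\t")
        if columns != _PATTERN_COLUMNS:
            raise FormatError(f"{path}: unexpected column header")
        for lineno, line in enumerate(fh, start=3):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_PATTERN_COLUMNS):
                raise FormatError(f"{path}:{lineno}: wrong field count")
            mirna, term, n_t, n_nt, p, t_genes, nt_genes = fields
            patterns.append(
                CoMiPattern(
                    mirna=mirna,
                    term=term,
                    target_in_set=frozenset(t_genes.split(",")) if t_genes else frozenset(),
                    nontarget_in_set=frozenset(nt_genes.split(",")) if nt_genes else frozenset(),
                    overlap_p=float(p),
                    n_T=int(n_t),
                    n_NT=int(n_nt),
                )
            )
    if int(meta.get("n", -1)) != len(patterns):
        raise FormatError(f"{path}: declared pattern count mismatch (truncated?)")
    return patterns


# profile serialization: one versioned TSV, diff-able and language-neutral

_PROFILE_COLUMNS = ["mirna", "term", "n_T", "n_NT", "statistic", "p_value", "direction"]


def write_profile(profile: CoMiProfile, path: str | Path, header_extra: str = "") -> None:
    """Write a profile as a versioned tab-delimited file."""
    with open(Path(path), "w") as fh:
        fh.write(
            f"# comireg-profile\tversion={PROFILE_FORMAT_VERSION}"
            f"\tcondition={profile.condition_id}\tn={len(profile)}"
        )
        if header_extra:
            fh.write(f"\t{header_extra}")
        fh.write("\n")
        fh.write("\t".join(_PROFILE_COLUMNS) + "\n")
        for key in profile.keys():
            idx = profile.indices[key]
            fh.write(
                f"{idx.pattern.mirna}\t{idx.pattern.term}\t{idx.pattern.n_T}\t"
                f"{idx.pattern.n_NT}\t{idx.statistic:.17g}\t{idx.p_value:.17g}\t"
                f"{idx.direction}\n"
            )


def read_profile(path: str | Path) -> CoMiProfile:
    """Read a profile written by :func:`write_profile`.

    Patterns come back *detached* (counts only, no gene memberships).
    Raises :class:`FormatError` on a version-tag mismatch or a truncated file.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("# comireg-profile"):
            raise FormatError(f"{path}: not a comireg profile file")
        meta = dict(
            part.split("=", 1) for part in header.split("\t")[1:] if "=" in part
        )
        if int(meta.get("version", -1)) != PROFILE_FORMAT_VERSION:
            raise FormatError(
                f"{path}: profile format version {meta.get('version')!r} "
                f"!= {PROFILE_FORMAT_VERSION}"
            )
        columns = fh.readline().rstrip("\n").split("\t")
        if columns != _PROFILE_COLUMNS:
            raise FormatError(f"{path}: unexpected column header {columns}")
        indices: dict[PatternKey, CoMiIndex] = {}
        for lineno, line in enumerate(fh, start=3):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_PROFILE_COLUMNS):
                raise FormatError(f"{path}:{lineno}: wrong field count")
            mirna, term, n_t, n_nt, stat, p, direction = fields
            pattern = CoMiPattern(
                mirna=mirna,
                term=term,
                target_in_set=frozenset(),
                nontarget_in_set=frozenset(),
                overlap_p=float("nan"),
                n_T=int(n_t),
                n_NT=int(n_nt),
            )
            idx = CoMiIndex(pattern=pattern, statistic=float(stat), p_value=float(p))
            if idx.direction != direction:
                raise FormatError(
                    f"{path}:{lineno}: direction {direction!r} inconsistent with "
                    f"statistic {stat}"
                )
            indices[pattern.key] = idx
    n_declared = int(meta.get("n", -1))
    if n_declared != len(indices):
        raise FormatError(
            f"{path}: header declares {n_declared} indices but file holds "
            f"{len(indices)} (truncated or tampered)"
        )
    return CoMiProfile(condition_id=meta.get("condition", ""), indices=indices)
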