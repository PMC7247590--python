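"""Gene-level and drug-level gene-wise variant burden (GVB).

The gene-level burden of gene *j* for one individual is the geometric mean of
the normalized scores of the retained nonsynonymous coding variants the
individual carries in the gene, and 1 when no such variant is carried::

    GVB(G_j) = 1                          if |G_j| = 0
             = (prod_{v in G_j} S_v)^(1/|G_j|)   otherwise

The drug-level burden of drug *k* is the geometric mean of the gene-level
burdens of the drug's pharmacokinetic and pharmacodynamic (PK/PD) genes::

    GVB(D_k) = (prod_{g in D_k} GVB(g))^(1/|D_k|)

All burdens live in [0, 1]; lower values mean a more severely affected gene
or a drug more likely to show an altered response.  Geometric means are
computed in log space; a score of exactly 0 yields burden 0 (no epsilon
flooring).  Unaffected genes are not materialized — profiles store only
genes with at least one retained carried variant and report 1 elsewhere.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .variant_annotation import (
    AnnotatedVariant,
    CohortGenotypes,
    ConfigError,
    DataError,
    METHODS,
    ScoringMethod,
    format_score,
    normalize_scores,
    retain_deleterious,
)

ATC_MAIN_GROUPS = "ABCDGHJLMNPRSV"  # the 14 anatomical main groups


class RelationType(str, enum.Enum):
    ENZYME = "enzyme"
    TRANSPORTER = "transporter"
    CARRIER = "carrier"
    TARGET = "target"


@dataclass(frozen=True)
class Relation:
    drug_id: str
    gene_id: str
    relation_type: RelationType


@dataclass
class DrugGeneMap:
    """Bipartite drug-gene relation map with optional ATC main-group letters.

    Genes appearing under multiple relation types for one drug are
    deduplicated before the geometric mean (set semantics); relation types
    are carried through for reporting but never weight the mean.
    """

    relations: frozenset[Relation]
    atc_main_group: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.relations:
            raise DataError("drug-gene map has no relations")
        for drug, letter in self.atc_main_group.items():
            if letter is not None and (len(letter) != 1 or letter not in ATC_MAIN_GROUPS):
                raise DataError(
                    f"drug {drug}: ATC main group {letter!r} is not one of "
                    f"{ATC_MAIN_GROUPS}"
                )
        genes_of: dict[str, set[str]] = {}
        for r in self.relations:
            genes_of.setdefault(r.drug_id, set()).add(r.gene_id)
        self._genes_of = {d: frozenset(g) for d, g in genes_of.items()}

    @property
    def drugs(self) -> frozenset[str]:
        return frozenset(self._genes_of)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(r.gene_id for r in self.relations)

    def genes_of(self, drug_id: str) -> frozenset[str]:
        return self._genes_of[drug_id]

    def drugs_in_atc(self, letter: str) -> frozenset[str]:
        if letter not in ATC_MAIN_GROUPS:
            raise ConfigError(f"unknown ATC main group {letter!r}")
        return frozenset(
            d for d, g in self.atc_main_group.items() if g == letter
        ) & self.drugs

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DrugGeneMap":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        required = {"drug_id", "gene_id", "relation_type"}
        missing = required - set(df.columns)
        if missing:
            raise DataError(f"drug-gene map {path}: missing column(s) {sorted(missing)}")
        relations = set()
        atc: dict[str, str] = {}
        for row in df.itertuples(index=False):
            try:
                rtype = RelationType(row.relation_type)
            except ValueError:
                raise DataError(
                    f"drug-gene map {path}: drug {row.drug_id}: relation_type "
                    f"{row.relation_type!r} not one of "
                    f"{[t.value for t in RelationType]}"
                ) from None
            relations.add(Relation(row.drug_id, row.gene_id, rtype))
            if "atc_main_group" in df.columns:
                letter = row.atc_main_group
                if letter not in {"", "."}:
                    atc[row.drug_id] = letter
        return cls(relations=frozenset(relations), atc_main_group=atc)

    def to_tsv(self, path: str | Path) -> None:
        rows = sorted(
            (r.drug_id, r.gene_id, r.relation_type.value) for r in self.relations
        )
        with open(path, "wt") as fh:
            fh.write("drug_id\tgene_id\trelation_type\tatc_main_group\n")
            for drug, gene, rtype in rows:
                fh.write(f"{drug}\t{gene}\t{rtype}\t{self.atc_main_group.get(drug, '.')}\n")


# ---------------------------------------------------------------------------
# Geometric-mean burdens
# ---------------------------------------------------------------------------


def _geometric_mean(scores: Sequence[float]) -> float:
    """Geometric mean in log space; empty -> 1; any exact 0 -> 0."""
    if not scores:
        return 1.0
    if any(s == 0.0 for s in scores):
        return 0.0
    return math.exp(math.fsum(math.log(s) for s in scores) / len(scores))


def gvb_gene(retained_scores: Iterable[float]) -> float:
    """Gene-level GVB of one individual from the retained variant scores.

    Returns 1 for an empty multiset (no retained variant carried) and the
    geometric mean otherwise.
    """
    scores = list(retained_scores)
    for s in scores:
        if not 0.0 <= s <= 1.0:
            raise DataError(f"retained variant score outside [0, 1]: {s}")
    return _geometric_mean(scores)


def gvb_drug(gene_burdens: Mapping[str, float], drug_genes: frozenset[str] | set[str]) -> float:
    """Drug-level GVB: geometric mean of the burdens of the drug's PK/PD genes.

    Every gene of the drug must have a burden value (1 if unaffected).
    """
    if not drug_genes:
        raise DataError("drug has an empty gene set")
    missing = set(drug_genes) - set(gene_burdens)
    if missing:
        raise DataError(f"no burden value for gene(s) {sorted(missing)}")
    return _geometric_mean([gene_burdens[g] for g in drug_genes])


@dataclass
class GeneBurdenProfile:
    """Sparse per-cohort gene burdens for one scoring method.

    Only genes with at least one retained carried variant are stored;
    :meth:`value` reports 1 for every other (sample, gene) pair in the
    universe.
    """

    method: str
    cutoff: float
    samples: list[str]
    gene_universe: frozenset[str]
    _values: dict[tuple[str, str], float]

    def value(self, sample_id: str, gene_id: str) -> float:
        if gene_id not in self.gene_universe:
            raise DataError(f"gene {gene_id!r} absent from the annotation universe")
        return self._values.get((sample_id, gene_id), 1.0)

    def sample_burdens(self, sample_id: str) -> dict[str, float]:
        """Stored (non-unit) burdens of one sample."""
        return {
            g: v for (s, g), v in self._values.items() if s == sample_id
        }

    def items(self):
        return self._values.items()

    def gene_cohort_means(self) -> dict[str, float]:
        """Per-gene mean burden over all samples (unaffected samples count as 1)."""
        n = len(self.samples)
        sums: dict[str, float] = {g: 0.0 for g in self.gene_universe}
        counts: dict[str, int] = {g: 0 for g in self.gene_universe}
        for (s, g), v in self._values.items():
            sums[g] += v
            counts[g] += 1
        return {g: (sums[g] + (n - counts[g]) * 1.0) / n for g in self.gene_universe}


def gene_burden_profile(
    cohort: CohortGenotypes,
    variants: Sequence[AnnotatedVariant],
    method: ScoringMethod | str,
    cutoff: float = 0.7,
) -> GeneBurdenProfile:
    """Per-individual gene burdens for one method across the cohort.

    Normalizes the method's raw scores, applies the retention rule, then
    aggregates each sample's retained carried variants per gene with the
    geometric mean.  Every gene named in the annotation has a burden for
    every sample; genes without retained carried variants are implicit 1s.
    """
    if isinstance(method, str):
        method = METHODS[method]
    normalized = normalize_scores(variants, method)
    retained = retain_deleterious(normalized, variants, cutoff)

    gene_universe = frozenset(v.gene_id for v in variants)
    # gene -> retained variants in it (one variant may hit several genes)
    gene_of: dict[str, list[tuple[str, float]]] = {}
    for v in variants:
        if v.variant_id in retained:
            gene_of.setdefault(v.gene_id, []).append((v.variant_id, retained[v.variant_id]))

    scores_by_pair: dict[tuple[str, str], list[float]] = {}
    for gene, var_scores in gene_of.items():
        for vid, score in var_scores:
            for sample_id in cohort.carriers.get(vid, frozenset()):
                scores_by_pair.setdefault((sample_id, gene), []).append(score)

    values = {pair: _geometric_mean(scores) for pair, scores in scores_by_pair.items()}
    return GeneBurdenProfile(
        method=method.name,
        cutoff=cutoff,
        samples=cohort.sample_ids,
        gene_universe=gene_universe,
        _values=values,
    )


def drug_burden_profile(
    gene_burdens: Mapping[str, float],
    dgmap: DrugGeneMap,
    gene_universe: Optional[frozenset[str]] = None,
) -> dict[str, float]:
    """Drug burdens of one sample from its gene burdens (sparse, default 1).

    ``gene_burdens`` holds the sample's non-unit burdens; every gene of the
    map must be inside ``gene_universe`` (defaults to the keys of
    ``gene_burdens``, i.e. a dense mapping).
    """
    universe = gene_universe if gene_universe is not None else frozenset(gene_burdens)
    missing = dgmap.genes - universe
    if missing:
        raise DataError(
            f"gene(s) {sorted(missing)[:5]} referenced by the drug-gene map are "
            "absent from the annotation universe"
        )
    out: dict[str, float] = {}
    for drug in sorted(dgmap.drugs):
        genes = dgmap.genes_of(drug)
        out[drug] = _geometric_mean([gene_burdens.get(g, 1.0) for g in genes])
    return out


def drug_burden_profiles(
    profile: GeneBurdenProfile, dgmap: DrugGeneMap
) -> dict[str, dict[str, float]]:
    """Drug burdens for every sample of a cohort profile."""
    missing = dgmap.genes - profile.gene_universe
    if missing:
        raise DataError(
            f"gene(s) {sorted(missing)[:5]} referenced by the drug-gene map are "
            "absent from the annotation universe"
        )
    per_sample: dict[str, dict[str, float]] = {s: {} for s in profile.samples}
    for (sample, gene), v in profile.items():
        per_sample[sample][gene] = v
    return {
        sample: drug_burden_profile(burdens, dgmap, profile.gene_universe)
        for sample, burdens in per_sample.items()
    }


# ---------------------------------------------------------------------------
# Long-format burden IO
# ---------------------------------------------------------------------------


def write_burdens(
    rows: Iterable[tuple[str, str, str, float]], path: str | Path
) -> None:
    """Write long-format burdens: sample_id, entity_id, method, gvb."""
    with open(path, "wt") as fh:
        fh.write("sample_id\tentity_id\tmethod\tgvb\n")
        for sample, entity, method, value in rows:
            fh.write(f"{sample}\t{entity}\t{method}\t{format_score(value)}\n")


def read_burdens(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gvb": float})
    required = {"sample_id", "entity_id", "method", "gvb"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"burden table {path}: missing column(s) {sorted(missing)}")
    return df
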