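"""Genotype and annotation ingestion, score normalization, and variant retention.

This module turns the two upstream inputs of a gene-wise variant burden (GVB)
analysis into in-memory objects:

* a cohort VCF plus a sample sheet -> :class:`CohortGenotypes`, a
  presence/absence map from variant key to the set of samples carrying at
  least one ALT allele;
* a variant annotation table -> a list of :class:`AnnotatedVariant`, each
  carrying a gene assignment, a consequence class, and raw scores from up to
  six in-silico deleteriousness predictors (SIFT, MutationTaster,
  PolyPhen-2 HDIV, PolyPhen-2 HVAR, phyloP, GERP++).

Raw predictor outputs live on heterogeneous scales and orientations; they are
normalized here onto a common [0, 1] scale on which *lower means more
deleterious* (the SIFT convention), and then filtered by the retention rule:
keep nonsynonymous coding variants with normalized score <= cutoff
(default 0.7).
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import pandas as pd

logger = logging.getLogger("gvburden")

MISSING_TOKENS = {"", "."}


class GVBError(Exception):
    """Base class for errors raised by this package."""


class ConfigError(GVBError):
    """Invalid configuration or parameter value (exit code 1 in the CLI)."""


class DataError(GVBError):
    """Malformed or inconsistent input data (exit code 2 in the CLI)."""


class Consequence(str, enum.Enum):
    NONSYNONYMOUS_CODING = "nonsynonymous_coding"
    SYNONYMOUS_CODING = "synonymous_coding"
    NONCODING = "noncoding"


class Orientation(str, enum.Enum):
    LOWER_IS_DELETERIOUS = "lower_is_deleterious"
    HIGHER_IS_DELETERIOUS = "higher_is_deleterious"


@dataclass(frozen=True)
class ScoringMethod:
    """One in-silico deleteriousness predictor.

    ``native_range`` is the closed interval of the method's raw scores when
    the method is bounded (SIFT, both PolyPhen-2 models, MutationTaster) and
    ``None`` for unbounded conservation scores (phyloP, GERP++), which are
    min-max scaled over the observed annotation table instead.
    """

    name: str
    orientation: Orientation
    native_range: Optional[tuple[float, float]] = None

    @property
    def bounded(self) -> bool:
        return self.native_range is not None


SIFT = ScoringMethod("SIFT", Orientation.LOWER_IS_DELETERIOUS, (0.0, 1.0))
MUTATION_TASTER = ScoringMethod(
    "MutationTaster", Orientation.HIGHER_IS_DELETERIOUS, (0.0, 1.0)
)
POLYPHEN2_HDIV = ScoringMethod(
    "PolyPhen2_HDIV", Orientation.HIGHER_IS_DELETERIOUS, (0.0, 1.0)
)
POLYPHEN2_HVAR = ScoringMethod(
    "PolyPhen2_HVAR", Orientation.HIGHER_IS_DELETERIOUS, (0.0, 1.0)
)
PHYLOP = ScoringMethod("phyloP", Orientation.HIGHER_IS_DELETERIOUS, None)
GERPPP = ScoringMethod("GERPpp", Orientation.HIGHER_IS_DELETERIOUS, None)

METHODS: dict[str, ScoringMethod] = {
    m.name: m
    for m in (SIFT, MUTATION_TASTER, POLYPHEN2_HDIV, POLYPHEN2_HVAR, PHYLOP, GERPPP)
}
METHOD_NAMES: tuple[str, ...] = tuple(METHODS)

#: Methods whose raw scores must already lie in [0, 1].
_UNIT_RANGE_METHODS = {"SIFT", "PolyPhen2_HDIV", "PolyPhen2_HVAR", "MutationTaster"}

ANNOTATION_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene_id",
    "consequence",
) + METHOD_NAMES


@dataclass
class AnnotatedVariant:
    """One variant allele assigned to one gene, with per-method raw scores.

    A variant hitting two genes appears as two instances (one per gene).
    ``raw_scores`` maps method name -> raw score; a method absent from the
    map simply contributes nothing to that method's burden.
    """

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str
    consequence: Consequence
    raw_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"variant {self.variant_id}: pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise DataError(f"variant {self.variant_id}: ref equals alt ({self.ref})")
        self.consequence = Consequence(self.consequence)
        for name, value in self.raw_scores.items():
            if name not in METHODS:
                raise DataError(f"variant {self.variant_id}: unknown scoring method {name!r}")
            if name in _UNIT_RANGE_METHODS and not 0.0 <= value <= 1.0:
                raise DataError(
                    f"variant {self.variant_id}: raw {name} score {value} outside [0, 1]"
                )


class Sample(NamedTuple):
    sample_id: str
    population: str
    superpopulation: str


@dataclass
class CohortGenotypes:
    """Presence/absence carrier sets for a cohort.

    ``carriers[variant_id]`` is the set of sample ids with at least one ALT
    allele at that variant.  Zygosity is deliberately collapsed: the burden
    model is defined over carried variant *sets*, without genotype dosage.
    """

    samples: list[Sample]
    carriers: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        known = {s.sample_id for s in self.samples}
        for vid, carr in self.carriers.items():
            unknown = set(carr) - known
            if unknown:
                raise DataError(
                    f"variant {vid}: carrier sample(s) {sorted(unknown)} absent "
                    "from the sample list"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def carried_by(self, sample_id: str) -> frozenset[str]:
        """Set of variant ids carried by one sample."""
        return frozenset(v for v, carr in self.carriers.items() if sample_id in carr)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def variant_key(chrom: str, pos: int, ref: str, alt: str, rsid: Optional[str] = None,
                biallelic: bool = True) -> str:
    """Canonical variant identity: rsID when present on a biallelic record,
    else ``chrom:pos:ref:alt`` (1-based VCF coordinates).

    Decomposed multiallelic ALTs always use coordinate keys: a single rsID
    cannot distinguish two ALT alleles of one record.
    """
    if rsid and rsid not in MISSING_TOKENS and biallelic:
        return rsid
    return f"{chrom}:{pos}:{ref}:{alt}"


def read_sample_sheet(path: str | Path) -> list[Sample]:
    """Read a tab-delimited sample sheet (sample_id, population, superpopulation)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "population", "superpopulation"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"sample sheet {path}: missing column(s) {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise DataError(f"sample sheet {path}: duplicate sample_id {dup!r}")
    return [
        Sample(r.sample_id, r.population, r.superpopulation)
        for r in df.itertuples(index=False)
    ]


def _prescan_vcf(path: Path) -> None:
    """Light structural check so malformed data lines fail with a line number."""
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 10:
                raise DataError(
                    f"{path}: malformed VCF line {lineno}: expected >= 10 "
                    f"tab-separated fields, got {len(fields)}"
                )
            try:
                int(fields[1])
            except ValueError:
                raise DataError(
                    f"{path}: malformed VCF line {lineno}: POS {fields[1]!r} "
                    "is not an integer"
                ) from None


def read_vcf(path: str | Path, sample_sheet: str | Path) -> CohortGenotypes:
    """Read GT fields of a VCF into presence/absence carrier sets.

    A sample carries a variant iff at least one of its GT alleles indexes
    that ALT.  Multiallelic records are decomposed into one variant key per
    ALT allele, with carriers split by ALT index.
    """
    import cyvcf2

    path = Path(path)
    samples = read_sample_sheet(sample_sheet)
    by_id = {s.sample_id: s for s in samples}
    _prescan_vcf(path)

    vcf = cyvcf2.VCF(str(path), gts012=False)
    for sid in vcf.samples:
        if sid not in by_id:
            raise DataError(
                f"{path}: sample {sid!r} in VCF is missing from the sample sheet"
            )
    vcf_samples = list(vcf.samples)

    carriers: dict[str, set[str]] = {}
    for rec in vcf:
        alts = rec.ALT or []
        biallelic = len(alts) == 1
        keys = {
            idx + 1: variant_key(rec.CHROM, rec.POS, rec.REF, alt, rec.ID, biallelic)
            for idx, alt in enumerate(alts)
        }
        for sample_idx, genotype in enumerate(rec.genotypes):
            alleles = genotype[:-1]  # last entry is phasedness
            for allele in alleles:
                if allele is not None and allele > 0:
                    carriers.setdefault(keys[allele], set()).add(vcf_samples[sample_idx])
    vcf.close()
    return CohortGenotypes(
        samples=samples, carriers={k: frozenset(v) for k, v in carriers.items()}
    )


def read_annotation(path: str | Path) -> list[AnnotatedVariant]:
    """Read a tab-delimited variant annotation table.

    Unparseable score cells keep the variant with that score absent; a
    consequence outside the declared enum or a duplicated
    (variant_id, gene_id) row is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"annotation {path}: missing column(s) {sorted(missing)}")
    dup_mask = df.duplicated(subset=["variant_id", "gene_id"], keep=False)
    if dup_mask.any():
        first = df.loc[dup_mask, ["variant_id", "gene_id"]].iloc[0]
        raise DataError(
            f"annotation {path}: duplicate (variant_id, gene_id) row "
            f"({first.variant_id}, {first.gene_id})"
        )

    valid_consequences = {c.value for c in Consequence}
    variants: list[AnnotatedVariant] = []
    for row in df.itertuples(index=False):
        if row.consequence not in valid_consequences:
            raise DataError(
                f"annotation {path}: variant {row.variant_id}: consequence "
                f"{row.consequence!r} not one of {sorted(valid_consequences)}"
            )
        raw_scores: dict[str, float] = {}
        for name in METHOD_NAMES:
            cell = getattr(row, name)
            if cell in MISSING_TOKENS:
                continue
            try:
                raw_scores[name] = float(cell)
            except ValueError:
                logger.debug(
                    "annotation %s: variant %s: unparseable %s score %r -> absent",
                    path, row.variant_id, name, cell,
                )
        variants.append(
            AnnotatedVariant(
                variant_id=row.variant_id,
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                gene_id=row.gene_id,
                consequence=Consequence(row.consequence),
                raw_scores=raw_scores,
            )
        )
    return variants


def format_score(x: float) -> str:
    """Canonical score formatting shared by all writers (round-trip stable)."""
    return format(float(x), "g")


def write_annotation(variants: Sequence[AnnotatedVariant], path: str | Path) -> None:
    """Write the annotation table; inverse of :func:`read_annotation` on
    canonically formatted files."""
    with open(path, "wt") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for v in variants:
            cells = [v.variant_id, v.chrom, str(v.pos), v.ref, v.alt, v.gene_id,
                     v.consequence.value]
            cells += [
                format_score(v.raw_scores[m]) if m in v.raw_scores else "."
                for m in METHOD_NAMES
            ]
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Normalization and retention
# ---------------------------------------------------------------------------


def normalize_scores(
    variants: Sequence[AnnotatedVariant], method: ScoringMethod | str
) -> dict[str, float]:
    """Normalize one method's raw scores to [0, 1], lower = more deleterious.

    SIFT already has the target orientation and range and passes through
    unchanged.  Bounded higher-is-deleterious methods are flipped affinely
    over their native range (x -> 1 - x on [0, 1]).  Unbounded methods
    (phyloP, GERP++) are min-max scaled over the raw scores observed in
    ``variants`` and then flipped, so one variant has one normalized score
    cohort-wide.  Variants without a raw score for the method are absent from
    the result.
    """
    if isinstance(method, str):
        method = METHODS[method]

    observed: dict[str, float] = {}
    for v in variants:
        if method.name in v.raw_scores and v.variant_id not in observed:
            observed[v.variant_id] = v.raw_scores[method.name]
    if not observed:
        raise DataError(f"no variant has a raw {method.name} score")

    if method.bounded:
        lo, hi = method.native_range
        for vid, x in observed.items():
            if not lo <= x <= hi:
                raise DataError(
                    f"variant {vid}: raw {method.name} score {x} outside "
                    f"native range [{lo}, {hi}]"
                )
    else:
        lo, hi = min(observed.values()), max(observed.values())
        if hi == lo:
            raise DataError(
                f"{method.name}: degenerate scale, all {len(observed)} observed "
                f"raw scores equal {lo}"
            )

    span = hi - lo
    out: dict[str, float] = {}
    for vid, x in observed.items():
        s = (x - lo) / span
        if method.orientation is Orientation.HIGHER_IS_DELETERIOUS:
            s = 1.0 - s
        out[vid] = min(1.0, max(0.0, s))
    return out


def retain_deleterious(
    normalized: Mapping[str, float],
    variants: Sequence[AnnotatedVariant],
    cutoff: float = 0.7,
) -> dict[str, float]:
    """Apply the deleteriousness retention rule.

    Keeps exactly the variants that are nonsynonymous coding AND have
    normalized score <= cutoff (boundary included), scores unchanged.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ConfigError(f"retention cutoff must lie in [0, 1], got {cutoff}")
    for vid, s in normalized.items():
        if not 0.0 <= s <= 1.0:
            raise DataError(f"normalized score for {vid} outside [0, 1]: {s}")
    nonsyn = {
        v.variant_id for v in variants
        if v.consequence is Consequence.NONSYNONYMOUS_CODING
    }
    return {
        vid: s for vid, s in normalized.items() if vid in nonsyn and s <= cutoff
    }
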