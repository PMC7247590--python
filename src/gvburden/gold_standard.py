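"""Per-individual gold standards from a variant-drug association catalog.

A variant-drug association (VDA) catalog links genetic variants (mostly
noncoding markers) to drugs with known response associations.  Because the
burden score is built exclusively from coding variants, coding VDAs are
excluded first so that the evaluation never scores a drug against the very
variants that produced its burden.  The per-individual gold standard is then
the set of drugs whose (noncoding) VDA variants the individual carries —
optionally restricted to VDAs reported in the individual's own OMB ethnicity
group (ethnicity-specific mode).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .variant_annotation import DataError, MISSING_TOKENS, Sample

logger = logging.getLogger("gvburden")


class GSMode(str, enum.Enum):
    ETHNICITY_SPECIFIC = "ethnicity_specific"
    NON_SPECIFIC = "non_specific"


class RegionClass(str, enum.Enum):
    CODING = "coding"
    NONCODING = "noncoding"


@dataclass(frozen=True)
class VDARecord:
    """One variant-drug association with region class and optional OMB label."""

    variant_id: str
    drug_id: str
    region_class: RegionClass
    ethnicity: Optional[str] = None  # OMB label, None = unspecified


@dataclass
class GoldStandard:
    sample_id: str
    mode: GSMode
    drugs: frozenset[str]


class UnmappedSuperpopulation(DataError):
    """Sample's superpopulation has no OMB label under the ethnicity map."""

    def __init__(self, sample_id: str, superpopulation: str):
        self.sample_id = sample_id
        self.superpopulation = superpopulation
        super().__init__(
            f"sample {sample_id}: superpopulation {superpopulation!r} has no "
            "OMB ethnicity mapping; excluded from ethnicity-specific evaluation"
        )


#: Default superpopulation -> OMB ethnicity label table.  AMR is deliberately
#: unmapped: admixed American panels have no single OMB label.  Editable via
#: the run configuration.
DEFAULT_ETHNICITY_MAP: dict[str, Optional[str]] = {
    "AFR": "African-American",
    "EAS": "Asian",
    "SAS": "Asian",
    "EUR": "Caucasian",
    "AMR": None,
}


@dataclass
class EthnicityMap:
    """Superpopulation -> OMB ethnicity label; ``None`` marks unmapped groups."""

    pairs: dict[str, Optional[str]] = field(
        default_factory=lambda: dict(DEFAULT_ETHNICITY_MAP)
    )

    def label_for(self, sample: Sample) -> Optional[str]:
        if sample.superpopulation not in self.pairs:
            raise UnmappedSuperpopulation(sample.sample_id, sample.superpopulation)
        label = self.pairs[sample.superpopulation]
        if label is None:
            raise UnmappedSuperpopulation(sample.sample_id, sample.superpopulation)
        return label


# ---------------------------------------------------------------------------
# Catalog IO
# ---------------------------------------------------------------------------


def read_vda_catalog(path: str | Path) -> list[VDARecord]:
    """Read the VDA catalog TSV (variant_id, drug_id, region_class, ethnicity).

    Duplicate (variant_id, drug_id) pairs are deduplicated keeping the first
    occurrence.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"variant_id", "drug_id", "region_class"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"VDA catalog {path}: missing column(s) {sorted(missing)}")
    records: list[VDARecord] = []
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        key = (row.variant_id, row.drug_id)
        if key in seen:
            continue
        seen.add(key)
        try:
            region = RegionClass(row.region_class)
        except ValueError:
            raise DataError(
                f"VDA catalog {path}: variant {row.variant_id}: region_class "
                f"{row.region_class!r} not one of "
                f"{[c.value for c in RegionClass]}"
            ) from None
        ethnicity = getattr(row, "ethnicity", "")
        records.append(
            VDARecord(
                variant_id=row.variant_id,
                drug_id=row.drug_id,
                region_class=region,
                ethnicity=None if ethnicity in MISSING_TOKENS else ethnicity,
            )
        )
    return records


def write_vda_catalog(records: Sequence[VDARecord], path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write("variant_id\tdrug_id\tregion_class\tethnicity\n")
        for r in records:
            fh.write(
                f"{r.variant_id}\t{r.drug_id}\t{r.region_class.value}\t"
                f"{r.ethnicity if r.ethnicity is not None else '.'}\n"
            )


def write_gold_standards(
    standards: Iterable[GoldStandard], path: str | Path
) -> None:
    with open(path, "wt") as fh:
        fh.write("sample_id\tmode\tdrug_id\n")
        for gs in standards:
            for drug in sorted(gs.drugs):
                fh.write(f"{gs.sample_id}\t{gs.mode.value}\t{drug}\n")


# ---------------------------------------------------------------------------
# Gold-standard construction
# ---------------------------------------------------------------------------


def filter_noncoding(catalog: Sequence[VDARecord]) -> list[VDARecord]:
    """Keep only noncoding VDAs (idempotent); logs removed/retained counts."""
    retained = [r for r in catalog if r.region_class is RegionClass.NONCODING]
    removed = len(catalog) - len(retained)
    logger.info(
        "VDA catalog: %d coding association(s) excluded, %d noncoding retained",
        removed, len(retained),
    )
    if catalog and not retained:
        logger.warning("VDA catalog contains no noncoding associations")
    return retained


def build_gold_standard(
    sample: Sample,
    carried_variants: frozenset[str] | set[str],
    catalog: Sequence[VDARecord],
    mode: GSMode | str,
    ethnicity_map: Optional[EthnicityMap] = None,
    drug_universe: Optional[frozenset[str]] = None,
    include_unspecified_in_specific: bool = False,
) -> GoldStandard:
    """Gold-standard drug set of one individual.

    A drug enters the set iff the individual carries a catalog variant
    associated with it.  In ethnicity-specific mode the VDA's OMB label must
    additionally equal the individual's mapped label; VDAs with no label are
    excluded there by default (``include_unspecified_in_specific`` relaxes
    this).  Raises :class:`UnmappedSuperpopulation` when the individual's
    superpopulation has no OMB label — callers flag and exclude such samples
    rather than silently dropping them.
    """
    mode = GSMode(mode)
    if mode is GSMode.ETHNICITY_SPECIFIC:
        label = (ethnicity_map or EthnicityMap()).label_for(sample)

    drugs: set[str] = set()
    for rec in catalog:
        if rec.variant_id not in carried_variants:
            continue
        if mode is GSMode.ETHNICITY_SPECIFIC:
            if rec.ethnicity is None:
                if not include_unspecified_in_specific:
                    continue
            elif rec.ethnicity != label:
                continue
        drugs.add(rec.drug_id)
    if drug_universe is not None:
        drugs &= drug_universe
    return GoldStandard(sample_id=sample.sample_id, mode=mode, drugs=frozenset(drugs))


def build_cohort_gold_standards(
    samples: Sequence[Sample],
    carried_by: Mapping[str, frozenset[str]],
    catalog: Sequence[VDARecord],
    mode: GSMode | str,
    ethnicity_map: Optional[EthnicityMap] = None,
    drug_universe: Optional[frozenset[str]] = None,
    include_unspecified_in_specific: bool = False,
) -> tuple[dict[str, GoldStandard], list[str]]:
    """Gold standards for a whole cohort.

    Returns ``(standards, flagged)`` where ``flagged`` lists sample ids
    excluded from ethnicity-specific evaluation because their
    superpopulation is unmapped.  Samples with an *empty* gold standard are
    kept in ``standards`` (the evaluation layer excludes them from AUC
    aggregation, where the statistic is undefined).
    """
    standards: dict[str, GoldStandard] = {}
    flagged: list[str] = []
    for sample in samples:
        try:
            standards[sample.sample_id] = build_gold_standard(
                sample,
                carried_by.get(sample.sample_id, frozenset()),
                catalog,
                mode,
                ethnicity_map,
                drug_universe,
                include_unspecified_in_specific,
            )
        except UnmappedSuperpopulation as exc:
            logger.warning("%s", exc)
            flagged.append(sample.sample_id)
    return standards, flagged
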