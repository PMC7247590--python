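"""Synthetic cohorts with planted variant-drug associations.

The generator emulates the statistical structure the burden analysis
assumes: individuals from several populations carry coding variants whose
in-silico deleteriousness scores follow a two-component mixture (a benign
mass near 1 and a deleterious mass near 0 on the normalized scale), drugs
relate to genes through a bipartite PK/PD map, and a variant-drug
association (VDA) catalog lists noncoding *marker* variants.  Planted VDAs
realize the synthetic-association hypothesis directly: each planted marker
tags a deleterious nonsynonymous variant in one of the drug's genes — a
marker carrier also carries the coding variant with probability
``linkage_fidelity``.  At fidelity 0 the marker is independent of any coding
burden (a pure noise association); at fidelity 1 every marker carrier has a
depressed burden for the associated drug.  Ethnicity-specific plantings
elevate marker (and linked causal) frequency only in one target population
and label the VDA with that population's OMB ethnicity group.

Marker-causal linkage is simulated directly as this carrier-copy
probability rather than via haplotype recombination: the analysis consumes
only carrier sets, so haplotype machinery would add nothing observable.
The six scoring methods are monotone distortions (plus small independent
noise) of one latent deleteriousness per variant, so cross-method rank
agreement is high but not perfect.  Identical seeds yield byte-identical
output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .burden_core import ATC_MAIN_GROUPS, DrugGeneMap, Relation, RelationType
from .gold_standard import DEFAULT_ETHNICITY_MAP, RegionClass, VDARecord, write_vda_catalog
from .variant_annotation import (
    AnnotatedVariant,
    CohortGenotypes,
    ConfigError,
    Consequence,
    Sample,
    write_annotation,
)

#: Relation-type sampling weights, roughly the proportions of target /
#: enzyme / transporter / carrier relations in large drug databases.
_RELATION_WEIGHTS = {
    RelationType.TARGET: 0.71,
    RelationType.ENZYME: 0.18,
    RelationType.TRANSPORTER: 0.09,
    RelationType.CARRIER: 0.02,
}


@dataclass(frozen=True)
class PopulationSpec:
    label: str
    superpopulation: str
    proportion: float


_DEFAULT_POPULATIONS = (
    PopulationSpec("YRI", "AFR", 0.34),
    PopulationSpec("CHB", "EAS", 0.33),
    PopulationSpec("CEU", "EUR", 0.33),
)


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic study; the seed fully determines output.

    Carrier frequencies are drawn from Beta(``allele_freq_alpha``,
    ``allele_freq_beta``) and jittered per population on the logit scale;
    deleterious variants draw instead from Beta(``deleterious_freq_alpha``,
    ``deleterious_freq_beta``), a thin-tailed rare-allele regime (purifying
    selection keeps strongly damaging alleles consistently rare, which is
    the premise of burden collapsing).
    Latent deleteriousness is Beta(``deleterious_beta``) (mass near 0, mean
    ≈ 0.057) for the deleterious component and Beta(``benign_beta``) (mass
    near 1) otherwise.  ``n_core_genes`` genes model core pharmacogenes:
    their deleterious fraction is multiplied by
    ``core_deleterious_multiplier`` and their variant count by
    ``core_variant_multiplier`` (core pharmacogenes are highly
    polymorphic), planting a reliably low-burden gene category.

    ``linkage_fidelity`` is the probability that a carrier of a planted
    noncoding marker also carries the linked deleterious coding variant;
    with ``causal_background_freq`` at its default 0 nobody else carries
    it, so fidelity 0 makes planted and noise associations exactly
    exchangeable.  For ethnicity-specific plantings the marker-causal
    linkage operates only in the target population (mirroring
    population-specific linkage-disequilibrium differences), while
    off-target populations carry the marker at a low base rate with no
    coding linkage.
    """

    seed: int = 0
    n_individuals: int = 200
    populations: tuple[PopulationSpec, ...] = _DEFAULT_POPULATIONS
    n_genes: int = 30
    variants_per_gene_mean: float = 6.0
    nonsynonymous_fraction: float = 0.75
    allele_freq_alpha: float = 0.4
    allele_freq_beta: float = 3.0
    deleterious_freq_alpha: float = 1.0
    deleterious_freq_beta: float = 30.0
    pop_freq_jitter: float = 0.5
    deleterious_fraction: float = 0.3
    deleterious_beta: tuple[float, float] = (1.2, 20.0)
    benign_beta: tuple[float, float] = (12.0, 1.5)
    score_noise_sd: float = 0.03
    missing_rate: float = 0.05
    n_drugs: int = 60
    genes_per_drug_mean: float = 2.0
    n_planted_vdas: int = 15
    frac_ethnicity_specific: float = 0.0
    linkage_fidelity: float = 1.0
    marker_freq: float = 0.35
    marker_freq_offtarget: float = 0.05
    causal_background_freq: float = 0.0
    n_noise_vdas: int = 10
    n_coding_vdas: int = 5
    n_core_genes: int = 8
    core_deleterious_multiplier: float = 3.0
    core_variant_multiplier: float = 2.0

    def __post_init__(self) -> None:
        self.populations = tuple(
            p if isinstance(p, PopulationSpec) else PopulationSpec(*p)
            for p in self.populations
        )
        self.deleterious_beta = tuple(self.deleterious_beta)
        self.benign_beta = tuple(self.benign_beta)
        self.validate()

    def validate(self) -> None:
        if self.seed < 0 or self.seed >= 2**31:
            raise ConfigError(f"seed must lie in [0, 2^31), got {self.seed}")
        if self.n_individuals < 1:
            raise ConfigError("n_individuals must be positive")
        if not self.populations:
            raise ConfigError("at least one population is required")
        total = sum(p.proportion for p in self.populations)
        if abs(total - 1.0) > 1e-6:
            raise ConfigError(f"population proportions sum to {total}, expected 1")
        for name in ("nonsynonymous_fraction", "deleterious_fraction",
                     "frac_ethnicity_specific", "linkage_fidelity", "marker_freq",
                     "marker_freq_offtarget", "causal_background_freq",
                     "missing_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if self.n_genes < 1 or self.n_drugs < 1:
            raise ConfigError("n_genes and n_drugs must be positive")
        if self.n_planted_vdas > self.n_drugs:
            raise ConfigError(
                f"cannot plant {self.n_planted_vdas} VDAs across only "
                f"{self.n_drugs} drugs"
            )
        if self.n_core_genes > self.n_genes:
            raise ConfigError(
                f"n_core_genes ({self.n_core_genes}) exceeds n_genes ({self.n_genes})"
            )
        if self.frac_ethnicity_specific > 0:
            mappable = [
                p for p in self.populations
                if DEFAULT_ETHNICITY_MAP.get(p.superpopulation) is not None
            ]
            if not mappable:
                raise ConfigError(
                    "ethnicity-specific plantings requested but no population's "
                    "superpopulation has an OMB label"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown synthetic-config field(s) {sorted(unknown)}")
        if "populations" in raw:
            raw["populations"] = tuple(
                PopulationSpec(p["label"], p["superpopulation"], float(p["proportion"]))
                for p in raw["populations"]
            )
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["populations"] = [dataclasses.asdict(p) for p in self.populations]
        d["deleterious_beta"] = list(self.deleterious_beta)
        d["benign_beta"] = list(self.benign_beta)
        return d


@dataclass(frozen=True)
class PlantedVDA:
    marker_id: str
    drug_id: str
    causal_variant_id: str
    causal_gene: str
    target_population: Optional[str]  # population label; None = all populations
    ethnicity_label: Optional[str]
    linkage_fidelity: float


@dataclass
class TruthSet:
    planted: list[PlantedVDA]
    core_genes: list[str]

    def to_dict(self) -> dict:
        return {
            "planted": [dataclasses.asdict(p) for p in self.planted],
            "core_genes": list(self.core_genes),
        }


@dataclass
class SyntheticBundle:
    """In-memory simulation output plus writers for the on-disk formats."""

    config: SyntheticConfig
    samples: list[Sample]
    variants: list[AnnotatedVariant]
    genotypes: dict[str, dict[str, str]]  # variant_id -> {sample_id: "0/1"|"1/1"}
    dgmap: DrugGeneMap
    catalog: list[VDARecord]
    truth: TruthSet

    def cohort(self) -> CohortGenotypes:
        return CohortGenotypes(
            samples=list(self.samples),
            carriers={v: frozenset(g) for v, g in self.genotypes.items() if g},
        )

    def carried_by_sample(self) -> dict[str, frozenset[str]]:
        carried: dict[str, set[str]] = {s.sample_id: set() for s in self.samples}
        for vid, gts in self.genotypes.items():
            for sid in gts:
                carried[sid].add(vid)
        return {s: frozenset(v) for s, v in carried.items()}

    # -- writers ----------------------------------------------------------

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "cohort.vcf",
            "sample_sheet": outdir / "samples.tsv",
            "annotation": outdir / "annotation.tsv",
            "drug_gene": outdir / "drug_gene.tsv",
            "vda_catalog": outdir / "vda_catalog.tsv",
            "truth": outdir / "truth.json",
            "manifest": outdir / "manifest.json",
        }
        self._write_vcf(paths["vcf"])
        self._write_sample_sheet(paths["sample_sheet"])
        write_annotation(self.variants, paths["annotation"])
        self.dgmap.to_tsv(paths["drug_gene"])
        write_vda_catalog(self.catalog, paths["vda_catalog"])
        paths["truth"].write_text(
            json.dumps(self.truth.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        manifest = {"seed": self.config.seed, "config": self.config.to_dict()}
        paths["manifest"].write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        return paths

    def _write_sample_sheet(self, path: Path) -> None:
        with open(path, "wt") as fh:
            fh.write("sample_id\tpopulation\tsuperpopulation\n")
            for s in self.samples:
                fh.write(f"{s.sample_id}\t{s.population}\t{s.superpopulation}\n")

    def _write_vcf(self, path: Path) -> None:
        # unique row per (chrom,pos,ref,alt); annotation may repeat a variant
        # across genes but the VCF must not
        seen: set[str] = set()
        rows = []
        for v in self.variants:
            if v.variant_id in seen:
                continue
            seen.add(v.variant_id)
            rsid = v.variant_id if v.variant_id.startswith("rs") else "."
            rows.append((v.chrom, v.pos, rsid, v.ref, v.alt, v.variant_id))
        rows.sort(key=lambda r: (r[0], r[1], r[3], r[4]))
        sample_ids = [s.sample_id for s in self.samples]
        with open(path, "wt") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=gvburden-synthetic\n")
            contigs = sorted({r[0] for r in rows})
            for c in contigs:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(sample_ids) + "\n"
            )
            for chrom, pos, rsid, ref, alt, vid in rows:
                gts = self.genotypes.get(vid, {})
                gt_cells = "\t".join(gts.get(s, "0/0") for s in sample_ids)
                fh.write(
                    f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt_cells}\n"
                )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

_REF_ALT_CYCLE = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))


def _population_counts(config: SyntheticConfig) -> list[int]:
    """Largest-remainder apportionment of individuals to populations."""
    n = config.n_individuals
    quotas = [p.proportion * n for p in config.populations]
    counts = [int(q) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(
        range(len(quotas)), key=lambda i: (quotas[i] - counts[i], -i), reverse=True
    )
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _logit_jitter(rng: np.random.Generator, q: float, sd: float) -> float:
    if sd == 0.0:
        return q
    q = min(max(q, 1e-6), 1 - 1e-6)
    logit = np.log(q / (1 - q)) + rng.normal(0.0, sd)
    return float(1.0 / (1.0 + np.exp(-logit)))


def _latent_to_raw(rng: np.random.Generator, latent: float, sd: float) -> dict[str, float]:
    """Per-method raw scores as monotone distortions of one latent value."""

    def noisy() -> float:
        return float(np.clip(latent + rng.normal(0.0, sd), 0.0, 1.0))

    return {
        "SIFT": round(noisy(), 4),
        "MutationTaster": round(1.0 - noisy(), 4),
        "PolyPhen2_HDIV": round((1.0 - noisy()) ** 0.8, 4),
        "PolyPhen2_HVAR": round((1.0 - noisy()) ** 1.25, 4),
        "phyloP": round(-3.0 + 10.0 * (1.0 - noisy()), 4),
        "GERPpp": round(-4.0 + 10.0 * (1.0 - noisy()), 4),
    }


def _draw_carriers(
    rng: np.random.Generator,
    samples: Sequence[Sample],
    freq_by_population: dict[str, float],
) -> dict[str, str]:
    """Bernoulli carrier draw per individual; carriers are het, hom with p=0.15."""
    gts: dict[str, str] = {}
    u = rng.random(len(samples))
    hom = rng.random(len(samples)) < 0.15
    for i, s in enumerate(samples):
        if u[i] < freq_by_population[s.population]:
            gts[s.sample_id] = "1/1" if hom[i] else "0/1"
    return gts


def simulate_cohort(
    config: SyntheticConfig, outdir: Optional[str | Path] = None
) -> SyntheticBundle:
    """Generate a full synthetic study; optionally write the file bundle.

    Output (files or in-memory equivalents): cohort VCF + sample sheet,
    variant annotation table, drug-gene relation table with ATC letters,
    VDA catalog, and the truth set of planted associations.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- samples ---------------------------------------------------------
    counts = _population_counts(config)
    width = max(4, len(str(config.n_individuals)))
    samples: list[Sample] = []
    idx = 1
    for pop, count in zip(config.populations, counts):
        for _ in range(count):
            samples.append(Sample(f"S{idx:0{width}d}", pop.label, pop.superpopulation))
            idx += 1

    # --- genes and background coding variants ---------------------------
    gene_width = max(3, len(str(config.n_genes)))
    genes = [f"G{i + 1:0{gene_width}d}" for i in range(config.n_genes)]
    core_genes = sorted(
        rng.choice(genes, size=config.n_core_genes, replace=False).tolist()
    )
    core_set = set(core_genes)

    variants: list[AnnotatedVariant] = []
    genotypes: dict[str, dict[str, str]] = {}

    def add_variant(v: AnnotatedVariant, gts: dict[str, str]) -> None:
        variants.append(v)
        genotypes[v.variant_id] = gts

    for g_idx, gene in enumerate(genes):
        block = (g_idx + 1) * 100_000
        vpg_mean = config.variants_per_gene_mean
        del_frac = config.deleterious_fraction
        if gene in core_set:
            vpg_mean *= config.core_variant_multiplier
            del_frac = min(1.0, del_frac * config.core_deleterious_multiplier)
        n_var = max(1, int(rng.poisson(vpg_mean)))
        for k in range(n_var):
            pos = block + (k + 1) * 100
            ref, alt = _REF_ALT_CYCLE[int(rng.integers(len(_REF_ALT_CYCLE)))]
            vid = f"1:{pos}:{ref}:{alt}"
            nonsyn = rng.random() < config.nonsynonymous_fraction
            consequence = (
                Consequence.NONSYNONYMOUS_CODING if nonsyn
                else Consequence.SYNONYMOUS_CODING
            )
            deleterious = rng.random() < del_frac
            latent = float(
                rng.beta(*config.deleterious_beta) if deleterious
                else rng.beta(*config.benign_beta)
            )
            raw = _latent_to_raw(rng, latent, config.score_noise_sd)
            if not nonsyn:  # conservation scores only for synonymous sites
                raw = {m: raw[m] for m in ("phyloP", "GERPpp")}
            # per-method missingness (never drop a method entirely: keep SIFT)
            raw = {
                m: x for m, x in raw.items()
                if m == "SIFT" or rng.random() >= config.missing_rate
            }
            if deleterious:
                q = float(rng.beta(config.deleterious_freq_alpha,
                                   config.deleterious_freq_beta))
            else:
                q = float(rng.beta(config.allele_freq_alpha, config.allele_freq_beta))
            freqs = {
                p.label: _logit_jitter(rng, q, config.pop_freq_jitter)
                for p in config.populations
            }
            add_variant(
                AnnotatedVariant(vid, "1", pos, ref, alt, gene, consequence, raw),
                _draw_carriers(rng, samples, freqs),
            )

    # --- drugs -----------------------------------------------------------
    drug_width = max(3, len(str(config.n_drugs)))
    relations: set[Relation] = set()
    atc: dict[str, str] = {}
    drug_ids = [f"D{i + 1:0{drug_width}d}" for i in range(config.n_drugs)]
    rtypes = list(_RELATION_WEIGHTS)
    rweights = np.array([_RELATION_WEIGHTS[t] for t in rtypes])
    rweights = rweights / rweights.sum()
    for drug in drug_ids:
        n_g = max(1, int(rng.poisson(config.genes_per_drug_mean)))
        n_g = min(n_g, config.n_genes)
        for gene in rng.choice(genes, size=n_g, replace=False):
            rtype = rtypes[int(rng.choice(len(rtypes), p=rweights))]
            relations.add(Relation(drug, str(gene), rtype))
        atc[drug] = ATC_MAIN_GROUPS[int(rng.integers(len(ATC_MAIN_GROUPS)))]
    dgmap = DrugGeneMap(relations=frozenset(relations), atc_main_group=atc)

    # --- planted VDAs ----------------------------------------------------
    catalog: list[VDARecord] = []
    planted: list[PlantedVDA] = []
    planted_drugs = rng.choice(drug_ids, size=config.n_planted_vdas, replace=False)
    mappable_pops = [
        p for p in config.populations
        if DEFAULT_ETHNICITY_MAP.get(p.superpopulation) is not None
    ]
    marker_base = 5_000_000
    for i, drug in enumerate(planted_drugs):
        drug = str(drug)
        drug_genes = sorted(dgmap.genes_of(drug))
        causal_gene = str(drug_genes[int(rng.integers(len(drug_genes)))])

        specific = rng.random() < config.frac_ethnicity_specific
        if specific:
            target = mappable_pops[int(rng.integers(len(mappable_pops)))]
            target_label: Optional[str] = target.label
            ethnicity = DEFAULT_ETHNICITY_MAP[target.superpopulation]
            marker_freqs = {
                p.label: (config.marker_freq if p.label == target.label
                          else config.marker_freq_offtarget)
                for p in config.populations
            }
        else:
            target_label, ethnicity = None, None
            marker_freqs = {p.label: config.marker_freq for p in config.populations}

        # noncoding marker (gets an rsID; no scores)
        pos = marker_base + (i + 1) * 1000
        marker_id = f"rs{9_000_000 + i + 1}"
        marker_gts = _draw_carriers(rng, samples, marker_freqs)
        add_variant(
            AnnotatedVariant(marker_id, "1", pos, "C", "T", causal_gene,
                             Consequence.NONCODING, {}),
            marker_gts,
        )

        # linked deleterious coding variant in the drug's gene
        cpos = marker_base + (i + 1) * 1000 + 1
        causal_id = f"1:{cpos}:G:A"
        latent = float(rng.beta(*config.deleterious_beta))
        raw = _latent_to_raw(rng, latent, config.score_noise_sd)
        causal_gts: dict[str, str] = {}
        u_bg = rng.random(len(samples))
        u_link = rng.random(len(samples))
        hom = rng.random(len(samples)) < 0.15
        for j, s in enumerate(samples):
            carries = u_bg[j] < config.causal_background_freq
            eligible = target_label is None or s.population == target_label
            if (eligible and s.sample_id in marker_gts
                    and u_link[j] < config.linkage_fidelity):
                carries = True
            if carries:
                causal_gts[s.sample_id] = "1/1" if hom[j] else "0/1"
        add_variant(
            AnnotatedVariant(causal_id, "1", cpos, "G", "A", causal_gene,
                             Consequence.NONSYNONYMOUS_CODING, raw),
            causal_gts,
        )

        catalog.append(
            VDARecord(marker_id, drug, RegionClass.NONCODING, ethnicity)
        )
        planted.append(
            PlantedVDA(marker_id, drug, causal_id, causal_gene, target_label,
                       ethnicity, config.linkage_fidelity)
        )

    # --- noise VDAs: noncoding markers with no coding-burden linkage -----
    for i in range(config.n_noise_vdas):
        pos = 8_000_000 + (i + 1) * 1000
        marker_id = f"rs{8_000_000 + i + 1}"
        q = float(rng.uniform(0.05, 0.4))
        freqs = {p.label: _logit_jitter(rng, q, config.pop_freq_jitter)
                 for p in config.populations}
        gene = genes[int(rng.integers(len(genes)))]
        add_variant(
            AnnotatedVariant(marker_id, "1", pos, "A", "C", gene,
                             Consequence.NONCODING, {}),
            _draw_carriers(rng, samples, freqs),
        )
        drug = drug_ids[int(rng.integers(len(drug_ids)))]
        catalog.append(VDARecord(marker_id, drug, RegionClass.NONCODING, None))

    # --- coding VDAs (excluded downstream by the noncoding filter) ------
    nonsyn_ids = [v.variant_id for v in variants
                  if v.consequence is Consequence.NONSYNONYMOUS_CODING]
    existing_pairs = {(r.variant_id, r.drug_id) for r in catalog}
    n_coding = 0
    while n_coding < config.n_coding_vdas and nonsyn_ids:
        vid = nonsyn_ids[int(rng.integers(len(nonsyn_ids)))]
        drug = drug_ids[int(rng.integers(len(drug_ids)))]
        if (vid, drug) in existing_pairs:
            continue
        existing_pairs.add((vid, drug))
        catalog.append(VDARecord(vid, drug, RegionClass.CODING, None))
        n_coding += 1

    bundle = SyntheticBundle(
        config=config,
        samples=samples,
        variants=variants,
        genotypes=genotypes,
        dgmap=dgmap,
        catalog=catalog,
        truth=TruthSet(planted=planted, core_genes=core_genes),
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle


def small_fixture(outdir: Optional[str | Path] = None) -> SyntheticBundle:
    """Deterministic toy study (16 individuals, 12 genes, 20 drugs).

    Small enough for unit tests and documentation examples; its VDA catalog
    contains both coding and noncoding records so the noncoding filter is
    exercised.
    """
    config = SyntheticConfig(
        seed=1234,
        n_individuals=16,
        n_genes=12,
        variants_per_gene_mean=4.0,
        n_drugs=20,
        genes_per_drug_mean=2.0,
        n_planted_vdas=6,
        n_noise_vdas=4,
        n_coding_vdas=2,
        n_core_genes=4,
        linkage_fidelity=1.0,
        frac_ethnicity_specific=0.5,
    )
    return simulate_cohort(config, outdir)
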