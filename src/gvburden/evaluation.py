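"""Rank-threshold evaluation of drug burdens against per-individual gold standards.

Drugs are ranked ascending by burden (lowest burden = most deleterious =
predicted positive).  For a rank threshold *L*, with *D* the full drug set,
*D_L* its first *L* drugs and *GS* the individual's gold-standard drugs::

    sensitivity(L) = |D_L ∩ GS| / |GS|
    specificity(L) = 1 − |D_L − GS| / |D − GS|

The ROC curve sweeps thresholds over the *distinct* burden values, so drugs
tied on burden enter D_L together; the AUC is the trapezoidal area, which
equals the Mann–Whitney concordance probability with ties counted 1/2.
Cohort evaluation computes one AUC per individual and aggregates
(mean ± sample SD) within strata: whole cohort, (super)populations, or ATC
anatomical main groups (restricting both D and GS to the group's drugs).

The module also hosts the gene-category burden comparison: cohort-mean
gene-level burdens of a named category (e.g. ADME Core) against a background
category, with a one-sided Mann–Whitney U test for a downward shift.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from scipy.stats import mannwhitneyu

from .burden_core import DrugGeneMap
from .gold_standard import GoldStandard, GSMode
from .variant_annotation import ConfigError, DataError, Sample

logger = logging.getLogger("gvburden")


@dataclass
class ROCCurve:
    """Threshold sweep of one individual: (L, sensitivity, specificity) points."""

    sample_id: str
    mode: GSMode
    points: list[tuple[int, float, float]]
    auc: float


@dataclass
class EvaluationSummary:
    stratum: str
    stratum_type: str  # "all" | "population" | "superpopulation" | "atc"
    mode: GSMode
    method: str
    n_samples: int
    auc_mean: float
    auc_sd: float
    flag: str = ""  # "", "degenerate_stratum", "no_gold_standard"


@dataclass
class GeneCategoryComparison:
    category_a: str
    category_b: str
    method: str
    statistic: float
    p_value: float
    mean_gvb_a: float
    mean_gvb_b: float


# ---------------------------------------------------------------------------
# Rank sensitivity / specificity and per-individual ROC
# ---------------------------------------------------------------------------


def sensitivity_specificity(
    ranked_drugs: Sequence[str], gs: frozenset[str] | set[str], L: int
) -> tuple[float, float]:
    """Rank sensitivity and specificity at threshold ``L``.

    ``ranked_drugs`` is the full drug list ordered ascending by burden
    (most deleterious first); the first ``L`` drugs are the predicted
    positives.
    """
    D = set(ranked_drugs)
    if len(D) != len(ranked_drugs):
        raise DataError("ranked drug list contains duplicates")
    gs = set(gs)
    if not gs:
        raise DataError("gold standard is empty: sensitivity undefined")
    if not gs <= D:
        raise DataError(f"gold-standard drug(s) {sorted(gs - D)[:5]} not in the ranking")
    if gs == D:
        raise DataError("gold standard equals the full drug set: specificity undefined")
    if not 0 <= L <= len(ranked_drugs):
        raise ConfigError(f"threshold L={L} outside [0, {len(ranked_drugs)}]")
    DL = set(ranked_drugs[:L])
    sensitivity = len(DL & gs) / len(gs)
    specificity = 1.0 - len(DL - gs) / len(D - gs)
    return sensitivity, specificity


def roc_auc(drug_burdens: Mapping[str, float], gs: GoldStandard) -> ROCCurve:
    """ROC curve and AUC of one individual's drug-burden ranking.

    Thresholds sweep the distinct burden values ascending; tied drugs enter
    the predicted-positive set as one block, so the result does not depend
    on input order.  The trapezoidal AUC equals all-pairs concordance with
    ties counted 1/2.
    """
    drugs = set(gs.drugs)
    if not drugs:
        raise DataError(f"sample {gs.sample_id}: gold standard is empty")
    missing = drugs - set(drug_burdens)
    if missing:
        raise DataError(
            f"sample {gs.sample_id}: gold-standard drug(s) {sorted(missing)[:5]} "
            "have no burden value"
        )
    if drugs == set(drug_burdens):
        raise DataError(
            f"sample {gs.sample_id}: gold standard equals the full drug set"
        )

    n_gs = len(drugs)
    n_bg = len(drug_burdens) - n_gs
    points: list[tuple[int, float, float]] = [(0, 0.0, 1.0)]
    auc = 0.0
    L = tp = fp = 0
    prev_sens, prev_fpr = 0.0, 0.0
    # group drugs by burden value, ascending (lower = predicted positive first)
    by_value: dict[float, list[str]] = {}
    for drug, value in drug_burdens.items():
        by_value.setdefault(value, []).append(drug)
    for value in sorted(by_value):
        block = by_value[value]
        tp += sum(1 for d in block if d in drugs)
        fp += len(block) - sum(1 for d in block if d in drugs)
        L += len(block)
        sens = tp / n_gs
        fpr = fp / n_bg
        auc += (fpr - prev_fpr) * (sens + prev_sens) / 2.0
        points.append((L, sens, 1.0 - fpr))
        prev_sens, prev_fpr = sens, fpr
    return ROCCurve(sample_id=gs.sample_id, mode=gs.mode, points=points, auc=auc)


# ---------------------------------------------------------------------------
# Cohort aggregation
# ---------------------------------------------------------------------------


def _restrict_gold_standard(gs: GoldStandard, drugs: frozenset[str]) -> GoldStandard:
    return GoldStandard(gs.sample_id, gs.mode, gs.drugs & drugs)


def _per_sample_aucs(
    drug_burdens: Mapping[str, Mapping[str, float]],
    gold_standards: Mapping[str, GoldStandard],
    restrict_to: Optional[frozenset[str]] = None,
) -> dict[str, float]:
    """AUC per sample, skipping samples whose (restricted) GS is empty or total."""
    aucs: dict[str, float] = {}
    for sample_id, gs in gold_standards.items():
        if sample_id not in drug_burdens:
            continue
        burdens = drug_burdens[sample_id]
        if restrict_to is not None:
            burdens = {d: v for d, v in burdens.items() if d in restrict_to}
            gs = _restrict_gold_standard(gs, restrict_to)
        if not gs.drugs or gs.drugs == set(burdens):
            continue
        aucs[sample_id] = roc_auc(burdens, gs).auc
    return aucs


def _summarize(
    aucs: Mapping[str, float], stratum: str, stratum_type: str,
    mode: GSMode, method: str,
) -> EvaluationSummary:
    n = len(aucs)
    if n == 0:
        return EvaluationSummary(
            stratum, stratum_type, mode, method, 0, float("nan"), float("nan"),
            flag="no_gold_standard",
        )
    values = list(aucs.values())
    mean = statistics.fmean(values)
    if n == 1:
        return EvaluationSummary(
            stratum, stratum_type, mode, method, 1, mean, 0.0,
            flag="degenerate_stratum",
        )
    return EvaluationSummary(
        stratum, stratum_type, mode, method, n, mean, statistics.stdev(values)
    )


def evaluate_cohort(
    drug_burdens: Mapping[str, Mapping[str, float]],
    gold_standards: Mapping[str, GoldStandard],
    samples: Sequence[Sample],
    method: str,
    mode: GSMode | str,
    strata: Sequence[str] = ("all",),
    dgmap: Optional[DrugGeneMap] = None,
) -> list[EvaluationSummary]:
    """Per-stratum mean ± SD of per-individual AUCs.

    ``strata`` entries: ``"all"``, ``"population"``, ``"superpopulation"``,
    ``"atc"`` (requires ``dgmap``; restricts drugs and gold standards to each
    anatomical main group present in the map).  Only samples with a nonempty
    gold standard enter the aggregates; strata where every sample's gold
    standard is empty are reported with ``n_samples = 0`` and flagged.
    SD uses the n−1 (sample) convention; single-sample strata report SD 0
    with a degenerate-stratum flag.
    """
    mode = GSMode(mode)
    by_id = {s.sample_id: s for s in samples}
    full_aucs = _per_sample_aucs(drug_burdens, gold_standards)

    summaries: list[EvaluationSummary] = []
    for stratum_type in strata:
        if stratum_type == "all":
            summaries.append(_summarize(full_aucs, "all", "all", mode, method))
        elif stratum_type in ("population", "superpopulation"):
            groups: dict[str, dict[str, float]] = {}
            for sample_id, auc in full_aucs.items():
                label = getattr(by_id[sample_id], stratum_type)
                groups.setdefault(label, {})[sample_id] = auc
            # report empty groups too, so excluded strata are visible
            all_labels = sorted({getattr(s, stratum_type) for s in samples})
            for label in all_labels:
                summaries.append(
                    _summarize(groups.get(label, {}), label, stratum_type, mode, method)
                )
        elif stratum_type == "atc":
            if dgmap is None:
                raise ConfigError("ATC stratification requires a drug-gene map")
            letters = sorted(set(dgmap.atc_main_group.values()))
            for letter in letters:
                drugs = dgmap.drugs_in_atc(letter)
                aucs = _per_sample_aucs(drug_burdens, gold_standards, restrict_to=drugs)
                summary = _summarize(aucs, letter, "atc", mode, method)
                if summary.flag == "no_gold_standard":
                    logger.warning(
                        "ATC class %s: no sample has a gold-standard drug in the "
                        "class; excluded from aggregation", letter,
                    )
                summaries.append(summary)
        else:
            raise ConfigError(f"unknown stratification {stratum_type!r}")
    return summaries


# ---------------------------------------------------------------------------
# Gene-category burden comparison
# ---------------------------------------------------------------------------


def compare_gene_categories(
    gene_means: Mapping[str, float],
    categories: Mapping[str, Iterable[str]],
    pairs: Optional[Sequence[tuple[str, str]]] = None,
    method: str = "",
) -> list[GeneCategoryComparison]:
    """One-sided Mann–Whitney U tests between named gene categories.

    ``gene_means`` maps gene -> cohort-mean gene-level burden.  For each
    (a, b) pair the alternative is that category *a*'s burdens are shifted
    *lower* than category *b*'s (more deleterious).  Compared categories must
    be disjoint and contain at least 2 genes each.
    """
    cats = {name: sorted(set(genes)) for name, genes in categories.items()}
    if pairs is None:
        names = list(cats)
        if len(names) != 2:
            raise ConfigError(
                "pairs must be given explicitly when there are not exactly "
                "two categories"
            )
        pairs = [(names[0], names[1])]

    results: list[GeneCategoryComparison] = []
    for a, b in pairs:
        for name in (a, b):
            if name not in cats:
                raise ConfigError(f"unknown gene category {name!r}")
            if len(cats[name]) < 2:
                raise DataError(
                    f"gene category {name!r} has {len(cats[name])} gene(s); "
                    "need at least 2"
                )
            missing = [g for g in cats[name] if g not in gene_means]
            if missing:
                raise DataError(
                    f"gene category {name!r}: no cohort-mean burden for "
                    f"{missing[:5]}"
                )
        overlap = set(cats[a]) & set(cats[b])
        if overlap:
            raise DataError(
                f"categories {a!r} and {b!r} are not disjoint: {sorted(overlap)[:5]}"
            )
        x = [gene_means[g] for g in cats[a]]
        y = [gene_means[g] for g in cats[b]]
        stat, p = mannwhitneyu(x, y, alternative="less")
        results.append(
            GeneCategoryComparison(
                category_a=a, category_b=b, method=method,
                statistic=float(stat), p_value=float(p),
                mean_gvb_a=statistics.fmean(x), mean_gvb_b=statistics.fmean(y),
            )
        )
    return results


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def write_summaries(summaries: Sequence[EvaluationSummary], path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write(
            "stratum\tstratum_type\tmode\tmethod\tn_samples\tauc_mean\tauc_sd\tflag\n"
        )
        for s in summaries:
            mean = "nan" if math.isnan(s.auc_mean) else f"{s.auc_mean:.6f}"
            sd = "nan" if math.isnan(s.auc_sd) else f"{s.auc_sd:.6f}"
            fh.write(
                f"{s.stratum}\t{s.stratum_type}\t{s.mode.value}\t{s.method}\t"
                f"{s.n_samples}\t{mean}\t{sd}\t{s.flag}\n"
            )


def write_roc_points(curves: Sequence[ROCCurve], path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write("sample_id\tmode\tL\tsensitivity\tspecificity\n")
        for c in curves:
            for L, sens, spec in c.points:
                fh.write(
                    f"{c.sample_id}\t{c.mode.value}\t{L}\t{sens:.6f}\t{spec:.6f}\n"
                )


def plot_auc_by_stratum(
    summaries: Sequence[EvaluationSummary], path: str | Path
) -> None:
    """Optional bar chart of stratum AUCs (mean ± SD); needs matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    usable = [s for s in summaries if s.n_samples > 0]
    labels = [f"{s.stratum}\n({s.mode.value[:4]},{s.method})" for s in usable]
    fig, ax = plt.subplots(figsize=(max(4, len(usable) * 0.8), 4))
    ax.bar(range(len(usable)), [s.auc_mean for s in usable],
           yerr=[s.auc_sd for s in usable], capsize=3)
    ax.axhline(0.5, linestyle=":", color="grey")
    ax.set_xticks(range(len(usable)), labels, rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("AUC (mean ± SD)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
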