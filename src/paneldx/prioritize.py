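"""Candidate-gene variant prioritization under Mendelian inheritance models.

The diagnostic logic is a two-pass search. Pass 1 restricts attention to the
candidate genes mapped to the case's clinical working diagnosis; a variant
survives if it is rare (or a known pathogenic allele, which overrides
frequency), qualifies on evidence (database-known, or novel and predicted
deleterious / truncating), and the surviving variants in a gene jointly
satisfy that gene's inheritance model (AR: homozygote or two hets as a
putative compound heterozygote; AD: one het; XL: hemizygous male or
homozygous female). Only when pass 1 finds nothing does pass 2 scan the rest
of the panel the same way — "backward inference" from a hit gene to its
disease, reported as a reassigned diagnosis.

Trio genotypes, when available, label each proband variant as inherited
(paternal / maternal / biparental), de novo, or a Mendelian error. A dominant
hit inherited from an unaffected parent is downgraded to *suspected*
(incomplete penetrance cannot be excluded, but neither can non-causality).

Compound heterozygotes are never phased from call sets alone; they are
flagged ``phase_unknown`` and left for parental confirmation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import pandas as pd

from .panel_io import (
    ConfigurationError,
    HEMIZYGOUS,
    HETEROZYGOUS,
    HOMOZYGOUS,
    DiseaseGeneMap,
    MutationEvent,
    SchemaError,
    ValidationError,
    VariantCall,
    parse_hgvs_c,
)

__all__ = [
    "VariantRecord",
    "Case",
    "DiagnosticReport",
    "annotate",
    "frequency_filter",
    "model_consistency",
    "segregation_check",
    "prioritize",
    "MAX_FREQ_DEFAULT",
]

MAX_FREQ_DEFAULT = 0.005

CONSISTENT = "consistent"
INCONSISTENT = "inconsistent"
CARRIER_ONLY = "carrier_only"

VERDICT_CAUSAL = "causal_found"
VERDICT_SUSPECTED = "suspected"
VERDICT_NEGATIVE = "negative"


@dataclass(frozen=True)
class VariantRecord:
    """An annotated variant call."""

    call: VariantCall
    event: MutationEvent | None = None
    local_freq: float | None = None
    pop_freq: float | None = None
    known_pathogenic: bool = False
    deleterious_votes: int = 0
    novel_flag: bool = False

    @property
    def gene(self) -> str:
        return self.call.gene

    @property
    def zygosity(self) -> str:
        return self.call.zygosity

    @property
    def key(self):
        return self.call.key

    def describe(self) -> dict:
        return {
            "chrom": self.call.chrom,
            "pos": self.call.pos,
            "ref": self.call.ref,
            "alt": self.call.alt,
            "gene": self.gene,
            "cdna": self.call.cdna,
            "protein": self.call.protein,
            "zygosity": self.zygosity,
            "novel": self.novel_flag,
            "known_pathogenic": self.known_pathogenic,
            "deleterious_votes": self.deleterious_votes,
        }


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def annotate(
    calls: list[VariantCall], annotation_table: pd.DataFrame | None
) -> list[VariantRecord]:
    """Join calls against a (chrom, pos, ref, alt)-keyed annotation table.

    Calls absent from the table keep missing frequencies and are flagged
    novel; a table hit is novel only if it is not a known pathogenic allele
    and carries no frequency evidence.
    """
    lookup = {}
    if annotation_table is not None and len(annotation_table):
        for col in ("chrom", "pos", "ref", "alt"):
            if col not in annotation_table.columns:
                raise SchemaError(f"annotation table missing column {col!r}")
        for row in annotation_table.itertuples(index=False):
            lookup[(str(row.chrom), int(row.pos), row.ref, row.alt)] = row
    out = []
    for call in calls:
        event = None
        if call.cdna:
            event = parse_hgvs_c(
                call.cdna, call.protein, zygosity=call.zygosity
            )
        row = lookup.get(call.key)
        if row is None:
            out.append(VariantRecord(call, event, novel_flag=True))
            continue
        local = None if _is_missing(row.local_freq) else float(row.local_freq)
        pop = None if _is_missing(row.pop_freq) else float(row.pop_freq)
        known = bool(row.known_pathogenic)
        out.append(
            VariantRecord(
                call,
                event,
                local_freq=local,
                pop_freq=pop,
                known_pathogenic=known,
                deleterious_votes=int(row.deleterious_votes),
                novel_flag=(not known) and local is None and pop is None,
            )
        )
    return out


def frequency_filter(
    records: list[VariantRecord],
    max_freq: float = MAX_FREQ_DEFAULT,
    removal_log: list | None = None,
) -> list[VariantRecord]:
    """Keep rare variants; known pathogenic alleles override frequency.

    A record is kept when every *available* frequency (local cohort and
    population) is <= max_freq — records with no frequency data are retained.
    Monotone in max_freq: raising it can only grow the output.
    """
    kept = []
    for r in records:
        if r.known_pathogenic:
            kept.append(r)
            continue
        offending = [
            (name, f)
            for name, f in (("local_freq", r.local_freq), ("pop_freq", r.pop_freq))
            if f is not None and f > max_freq
        ]
        if offending:
            if removal_log is not None:
                reasons = ", ".join(f"{n}={f:g} > {max_freq:g}" for n, f in offending)
                removal_log.append((r, reasons))
        else:
            kept.append(r)
    return kept


def model_consistency(
    records_in_gene: list[VariantRecord], model: str, sex: str | None = None
) -> str:
    """Judge whether the variants in one gene fit an inheritance model.

    AR: one homozygote, or >= 2 heterozygotes (putative compound het,
    phase unknown) -> consistent; a single het -> carrier_only.
    AD: any record -> consistent.
    XL: hemizygous (male) or homozygous (female) -> consistent;
    heterozygous female -> carrier_only.
    """
    genes = {r.gene for r in records_in_gene}
    if len(genes) > 1:
        raise ValidationError(f"records span multiple genes: {sorted(genes)}")
    if model == "AR":
        if any(r.zygosity == HOMOZYGOUS for r in records_in_gene):
            return CONSISTENT
        hets = [r for r in records_in_gene if r.zygosity == HETEROZYGOUS]
        if len(hets) >= 2:
            return CONSISTENT
        return CARRIER_ONLY if len(hets) == 1 else INCONSISTENT
    if model == "AD":
        return CONSISTENT if records_in_gene else INCONSISTENT
    if model == "XL":
        if any(r.zygosity == HEMIZYGOUS for r in records_in_gene):
            return CONSISTENT
        if sex == "female" and any(r.zygosity == HOMOZYGOUS for r in records_in_gene):
            return CONSISTENT
        if sex == "female" and any(r.zygosity == HETEROZYGOUS for r in records_in_gene):
            return CARRIER_ONLY
        return INCONSISTENT
    raise ConfigurationError(f"unknown inheritance model {model!r}")


INHERITED_PATERNAL = "inherited_paternal"
INHERITED_MATERNAL = "inherited_maternal"
INHERITED_BIPARENTAL = "inherited_biparental"
DE_NOVO = "de_novo"
MENDELIAN_ERROR = "mendelian_error"


def _keyset(calls: list[VariantCall] | None):
    if calls is None:
        return None
    keys = [c.key for c in calls]
    if len(keys) != len(set(keys)):
        raise ValidationError("duplicated locus within one individual")
    return set(keys)


def segregation_check(
    proband_calls: list[VariantCall],
    father_calls: list[VariantCall] | None,
    mother_calls: list[VariantCall] | None,
    proband_sex: str | None = None,
) -> dict:
    """Label each proband variant by its presence in the parents.

    A hemizygous X variant in a male proband is expected from the mother;
    finding it only in the father is a Mendelian error. A homozygote needs
    the allele in both parents (otherwise Mendelian error). Absent from both
    parents -> de novo.
    """
    dad = _keyset(father_calls) or set()
    mom = _keyset(mother_calls) or set()
    _keyset(proband_calls)
    labels = {}
    for call in proband_calls:
        in_dad, in_mom = call.key in dad, call.key in mom
        is_male_x = (
            call.chrom in ("chrX", "X")
            and call.zygosity == HEMIZYGOUS
            and proband_sex in (None, "male")
        )
        if is_male_x:
            if in_mom:
                labels[call.key] = INHERITED_MATERNAL
            elif in_dad:
                labels[call.key] = MENDELIAN_ERROR
            else:
                labels[call.key] = DE_NOVO
        elif call.zygosity == HOMOZYGOUS:
            if in_dad and in_mom:
                labels[call.key] = INHERITED_BIPARENTAL
            else:
                labels[call.key] = MENDELIAN_ERROR
        else:
            if in_dad and in_mom:
                labels[call.key] = INHERITED_BIPARENTAL
            elif in_dad:
                labels[call.key] = INHERITED_PATERNAL
            elif in_mom:
                labels[call.key] = INHERITED_MATERNAL
            else:
                labels[call.key] = DE_NOVO
    return labels


# ---------------------------------------------------------------------------
# Two-pass prioritization
# ---------------------------------------------------------------------------


@dataclass
class Case:
    """One diagnostic case: proband calls, optional trio, clinical context."""

    case_id: str
    clinical_diagnosis: str
    proband_calls: list[VariantCall]
    sex: str | None = None
    father_calls: list[VariantCall] | None = None
    mother_calls: list[VariantCall] | None = None
    father_affected: bool = False
    mother_affected: bool = False

    @property
    def has_trio(self) -> bool:
        return self.father_calls is not None and self.mother_calls is not None


@dataclass
class DiagnosticReport:
    """Tiered prioritization output. ``verdict`` is negative iff all tiers
    are empty; every hit carries its evidence trail."""

    case_id: str
    clinical_diagnosis: str
    tier1: list[dict] = field(default_factory=list)
    tier2: list[dict] = field(default_factory=list)
    tier3: list[dict] = field(default_factory=list)
    verdict: str = VERDICT_NEGATIVE
    consistency: str = "no"
    notes: list[str] = field(default_factory=list)

    def __post_init__(self):
        empty = not (self.tier1 or self.tier2 or self.tier3)
        if empty != (self.verdict == VERDICT_NEGATIVE):
            raise ValidationError("verdict must be negative iff all tiers are empty")

    def all_hits(self) -> list[dict]:
        return [*self.tier1, *self.tier2, *self.tier3]

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "clinical_diagnosis": self.clinical_diagnosis,
            "tier1": self.tier1,
            "tier2": self.tier2,
            "tier3": self.tier3,
            "verdict": self.verdict,
            "consistency": self.consistency,
            "notes": self.notes,
        }


def _qualifies(r: VariantRecord) -> tuple[bool, int, list[str]]:
    """Evidence gate: (qualifies, tier 1 or 2, evidence trail)."""
    if r.known_pathogenic:
        return True, 1, ["known_pathogenic"]
    if r.novel_flag:
        evidence = []
        if r.deleterious_votes >= 1:
            evidence.append(f"deleterious_votes={r.deleterious_votes}")
        if r.event is not None and r.event.is_truncating:
            evidence.append("truncating")
        if evidence:
            return True, 2, ["novel", *evidence]
    return False, 0, []


def _check_hemizygous(records: list[VariantRecord], sex: str | None) -> None:
    for r in records:
        if r.zygosity != HEMIZYGOUS:
            continue
        if r.call.chrom not in ("chrX", "chrY", "X", "Y"):
            raise ValidationError(
                f"hemizygous call on autosome {r.call.chrom}:{r.call.pos}"
            )
        if sex == "female":
            raise ValidationError(
                f"hemizygous call {r.call.chrom}:{r.call.pos} in a female sample"
            )


def _gene_hits(
    records: list[VariantRecord],
    model: str,
    sex: str | None,
    segregation: dict | None,
    parent_affected: dict[str, bool],
) -> tuple[list[dict], str, list[str]]:
    """Evaluate one gene: qualifying hits, verdict contribution, notes."""
    qualified = []
    for r in records:
        ok, tier, evidence = _qualifies(r)
        if ok:
            qualified.append((r, tier, evidence))
    if not qualified:
        return [], VERDICT_NEGATIVE, []

    status = model_consistency([r for r, _, _ in qualified], model, sex)
    if status == INCONSISTENT:
        return [], VERDICT_NEGATIVE, []

    notes = []
    verdict = VERDICT_CAUSAL if status == CONSISTENT else VERDICT_SUSPECTED
    phase_unknown = (
        model == "AR"
        and status == CONSISTENT
        and not any(r.zygosity == HOMOZYGOUS for r, _, _ in qualified)
    )
    hits = []
    for r, tier, evidence in qualified:
        hit = r.describe()
        hit["tier"] = tier
        hit["model"] = model
        hit["evidence"] = list(evidence)
        if phase_unknown:
            hit["flags"] = ["compound_het_phase_unknown"]
            notes.append("compound heterozygote; phase unconfirmed without parents")
        elif status == CARRIER_ONLY:
            hit["flags"] = ["carrier_only"]
            if model == "AR":
                notes.append(
                    f"single {r.gene} heterozygote: possible missed second allele"
                )
        else:
            hit["flags"] = []
        if segregation is not None and r.key in segregation:
            hit["segregation"] = segregation[r.key]
            if segregation[r.key] == DE_NOVO:
                notes.append(f"{r.gene} variant is de novo")
            if model == "AD" and segregation[r.key] in (
                INHERITED_PATERNAL, INHERITED_MATERNAL, INHERITED_BIPARENTAL,
            ):
                parent = {
                    INHERITED_PATERNAL: "father",
                    INHERITED_MATERNAL: "mother",
                    INHERITED_BIPARENTAL: "father",
                }[segregation[r.key]]
                if not parent_affected.get(parent, False):
                    verdict = VERDICT_SUSPECTED
                    hit["flags"] = hit.get("flags", []) + [
                        "incomplete penetrance or non-causal"
                    ]
                    notes.append(
                        f"dominant {r.gene} variant inherited from an "
                        "asymptomatic parent"
                    )
        hits.append(hit)
    return hits, verdict, notes


def prioritize(
    case: Case,
    dmap: DiseaseGeneMap,
    annotation_table: pd.DataFrame | None,
    max_freq: float = MAX_FREQ_DEFAULT,
    allow_unknown_diagnosis: bool = False,
) -> DiagnosticReport:
    """Two-pass candidate-gene prioritization for one case.

    Pass 1 looks only at the candidate genes of the clinical diagnosis; pass
    2 (run only when pass 1 yields nothing) scans every other mapped panel
    gene and, on a hit, reassigns the diagnosis to the hit gene's disease.
    """
    if case.clinical_diagnosis in dmap.genes_by_disease:
        candidates = dmap.candidates(case.clinical_diagnosis)
    elif allow_unknown_diagnosis or case.clinical_diagnosis == "unknown":
        candidates = []
    else:
        raise ConfigurationError(
            f"unknown diagnosis code {case.clinical_diagnosis!r}"
        )

    records = annotate(case.proband_calls, annotation_table)
    _check_hemizygous(records, case.sex)
    removal_log: list = []
    kept = frequency_filter(records, max_freq=max_freq, removal_log=removal_log)

    segregation = None
    if case.has_trio:
        segregation = segregation_check(
            case.proband_calls, case.father_calls, case.mother_calls, case.sex
        )
    parent_affected = {
        "father": case.father_affected, "mother": case.mother_affected
    }

    by_gene: dict[str, list[VariantRecord]] = {}
    for r in kept:
        by_gene.setdefault(r.gene, []).append(r)

    report = DiagnosticReport(
        case_id=case.case_id,
        clinical_diagnosis=case.clinical_diagnosis,
        tier1=[], tier2=[], tier3=[],
        verdict=VERDICT_NEGATIVE, consistency="no",
    )
    report.notes.extend(
        f"filtered {r.call.chrom}:{r.call.pos} {r.call.ref}>{r.call.alt}: {why}"
        for r, why in removal_log
    )

    def _models_for(gene: str) -> tuple[str, ...]:
        return dmap.models_by_gene.get(gene, ())

    # pass 1: candidate genes of the working diagnosis
    pass1_verdicts = []
    for gene in candidates:
        if gene not in by_gene:
            continue
        best = None
        for model in _models_for(gene):
            hits, verdict, notes = _gene_hits(
                by_gene[gene], model, case.sex, segregation, parent_affected
            )
            if hits and (best is None or verdict == VERDICT_CAUSAL):
                best = (hits, verdict, notes)
                if verdict == VERDICT_CAUSAL:
                    break
        if best is None:
            continue
        hits, verdict, notes = best
        for h in hits:
            (report.tier1 if h["tier"] == 1 else report.tier2).append(h)
        report.notes.extend(notes)
        pass1_verdicts.append(verdict)

    if pass1_verdicts:
        report.verdict = (
            VERDICT_CAUSAL if VERDICT_CAUSAL in pass1_verdicts else VERDICT_SUSPECTED
        )
        report.consistency = "yes"
        return report

    # pass 2: backward inference over the rest of the mapped panel
    reassigned = []
    for gene, recs in sorted(by_gene.items()):
        if gene in candidates or not _models_for(gene):
            continue
        best = None
        for model in _models_for(gene):
            hits, verdict, notes = _gene_hits(
                recs, model, case.sex, segregation, parent_affected
            )
            if hits and (best is None or verdict == VERDICT_CAUSAL):
                best = (hits, verdict, notes)
                if verdict == VERDICT_CAUSAL:
                    break
        if best is None:
            continue
        hits, verdict, notes = best
        for h in hits:
            h["tier"] = 3
            report.tier3.append(h)
        report.notes.extend(notes)
        diseases = dmap.diseases_of_gene(gene)
        if diseases:
            reassigned.append(diseases[0])
        if verdict == VERDICT_CAUSAL:
            report.verdict = VERDICT_CAUSAL
        elif report.verdict == VERDICT_NEGATIVE:
            report.verdict = VERDICT_SUSPECTED

    if report.tier3:
        report.consistency = "reassigned:" + ",".join(sorted(set(reassigned)))
    return report
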