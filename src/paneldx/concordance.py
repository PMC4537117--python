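"""Platform-concordance and replicate-stability arithmetic.

Three evaluation statistics for a targeted panel:

* genotype concordance between NGS calls and an orthogonal SNP-array over a
  shared locus set, per sample and averaged;
* replicate stability: the fraction of each replicate's coding SNVs that all
  k replicates agree on (the k-way Venn intersection);
* a sex-sanity screen: genotypes that are impossible given the declared sex
  (any Y-chromosome genotype in a female; a heterozygous X genotype in a
  male outside the pseudoautosomal regions).

Rounding policy: percentages are computed exactly, averaged unrounded, and
rounded half-away-from-zero to two decimals only at presentation. Rounding
earlier changes the mean at the second decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

from .panel_io import ValidationError

__all__ = [
    "ConcordanceSummary",
    "StabilitySummary",
    "genotype_concordance",
    "replicate_overlap",
    "sex_sanity",
    "round2",
    "PAR_INTERVALS_GRCH37",
]

# GRCh37 chrX pseudoautosomal regions (1-based inclusive bounds)
PAR_INTERVALS_GRCH37 = ((60001, 2_699_520), (154_931_044, 155_260_560))

_VALID_CHROMS = {f"chr{i}" for i in range(1, 23)} | {"chrX", "chrY", "chrM"}


def round2(x: float) -> float:
    """Round half away from zero to 2 decimals (presentation only)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class ConcordanceSummary:
    """Per-sample genotype concordance against an orthogonal platform."""

    per_sample: dict[str, tuple[int, int, float]]  # sample -> (n_total, n_conc, pct)
    mean_percent: float
    discordant: list[tuple]  # (sample, locus, ngs genotype, array genotype)
    unshared: list[tuple]  # loci present on only one platform (reported, not counted)

    def to_dict(self) -> dict:
        return {
            "per_sample": {
                s: {"n_total": n, "n_concordant": c, "percent": p}
                for s, (n, c, p) in self.per_sample.items()
            },
            "mean_percent": self.mean_percent,
            "n_discordant": len(self.discordant),
            "n_unshared": len(self.unshared),
        }


def genotype_concordance(
    pairs: Mapping[str, tuple[Mapping, Mapping]]
) -> ConcordanceSummary:
    """Concordance per sample from (ngs, array) genotype tables.

    Genotypes are unordered allele tuples; loci present on only one platform
    are excluded from the denominator and reported separately. Per-sample
    percentages and their mean are computed on exact fractions and rounded
    last. Symmetric in the two tables.
    """
    if not pairs:
        raise ValidationError("no samples to compare")
    per_sample = {}
    discordant, unshared = [], []
    exact = []
    for sample, (ngs, array) in pairs.items():
        shared = set(ngs) & set(array)
        if not shared:
            raise ValidationError(f"sample {sample!r}: no shared loci")
        for locus in sorted(set(ngs) ^ set(array)):
            unshared.append((sample, locus))
        n_conc = 0
        for locus in sorted(shared):
            if tuple(ngs[locus]) == tuple(array[locus]):
                n_conc += 1
            else:
                discordant.append((sample, locus, tuple(ngs[locus]), tuple(array[locus])))
        pct_exact = 100.0 * n_conc / len(shared)
        exact.append(pct_exact)
        per_sample[sample] = (len(shared), n_conc, round2(pct_exact))
    return ConcordanceSummary(
        per_sample=per_sample,
        mean_percent=round2(sum(exact) / len(exact)),
        discordant=discordant,
        unshared=unshared,
    )


@dataclass
class StabilitySummary:
    """k-way replicate SNV overlap."""

    totals: list[int]
    intersection_size: int
    per_replicate_percent: list[float]
    mean_percent: float

    def to_dict(self) -> dict:
        return {
            "totals": self.totals,
            "intersection_size": self.intersection_size,
            "per_replicate_percent": self.per_replicate_percent,
            "mean_percent": self.mean_percent,
        }


def replicate_overlap(snv_sets: Sequence[set]) -> StabilitySummary:
    """Share of each replicate's SNVs found in all k replicates.

    Proportion_i = |intersection of all sets| / |set_i|; the mean is taken
    over unrounded proportions and rounded last. Invariant under permutation
    of the input sets (up to reordering of the per-set proportions).
    """
    if len(snv_sets) < 2:
        raise ValidationError("need at least two replicate SNV sets")
    if any(len(s) == 0 for s in snv_sets):
        raise ValidationError("replicate with zero SNVs: proportion undefined")
    inter = set.intersection(*map(set, snv_sets))
    exact = [100.0 * len(inter) / len(s) for s in snv_sets]
    return StabilitySummary(
        totals=[len(s) for s in snv_sets],
        intersection_size=len(inter),
        per_replicate_percent=[round2(p) for p in exact],
        mean_percent=round2(sum(exact) / len(exact)),
    )


def sex_sanity(
    genotypes: Mapping[tuple[str, int], tuple],
    declared_sex: str,
    par_intervals: tuple = PAR_INTERVALS_GRCH37,
) -> list[tuple]:
    """Flag genotypes impossible under the declared sex.

    Female: any chrY genotype is an error (there is no Y to genotype).
    Male: a heterozygous chrX genotype outside the pseudoautosomal regions
    is an error (the X is hemizygous there).
    """
    if declared_sex not in ("female", "male"):
        raise ValidationError(f"declared_sex must be female or male, got {declared_sex!r}")
    flagged = []
    for (chrom, pos), gt in sorted(genotypes.items()):
        if chrom not in _VALID_CHROMS:
            raise ValidationError(f"unknown chromosome name {chrom!r}")
        gt = tuple(gt)
        if declared_sex == "female" and chrom == "chrY" and gt:
            flagged.append(((chrom, pos), gt, "chrY genotype in a female"))
        elif (
            declared_sex == "male"
            and chrom == "chrX"
            and len(set(gt)) > 1
            and not any(lo <= pos <= hi for lo, hi in par_intervals)
        ):
            flagged.append(((chrom, pos), gt, "heterozygous chrX genotype in a male"))
    return flagged
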