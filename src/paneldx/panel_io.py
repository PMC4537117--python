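"""Panel data model, on-disk formats, and an HGVS-lite mutation classifier.

This module owns the target-region universe (the capture panel), the
machine-readable clinical mutation table bundled with the package, and the
readers/writers for the simple text dialects used throughout:

* BED (0-based half-open) for target regions, with the name field encoding
  ``GENE|EXONLABEL``;
* TSV mutation tables in the layout of the bundled clinical summary
  (one row per case and gene, mutation strings carrying inline ``(Hom)`` /
  ``(Hem)`` zygosity marks and ``novel`` flags);
* TSV genotype tables, annotation tables, disease->gene maps and variant
  call sets;
* JSON diagnostic reports.

Coordinate conventions: BED input is 0-based half-open; variant loci are
1-based (VCF convention). Conversion happens here, at the format boundary.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PanelFormatError",
    "ClassificationError",
    "SchemaError",
    "ValidationError",
    "ConfigurationError",
    "TargetRegion",
    "Panel",
    "MutationEvent",
    "MutationRecord",
    "DiseaseGeneMap",
    "VariantCall",
    "read_panel",
    "write_panel",
    "parse_hgvs_c",
    "classify_structural",
    "parse_mutation_string",
    "read_mutation_table",
    "load_case_mutation_table",
    "mutation_summary",
    "read_disease_map",
    "read_genotype_table",
    "write_genotype_table",
    "read_annotation_table",
    "read_variant_calls",
    "write_variant_calls",
    "write_report",
    "read_report",
]

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))
SEX_CHROMOSOMES = ("chrX", "chrY")

SNV = "SNV"
INSERTION = "insertion"
DELETION = "deletion"
DELINS = "delins"
DUPLICATION = "duplication"
CHROMOSOMAL_GAIN = "chromosomal_gain"
CHROMOSOMAL_LOSS = "chromosomal_loss"

CODING = "coding"
SPLICE_INTRONIC = "splice/intronic"

HETEROZYGOUS = "heterozygous"
HOMOZYGOUS = "homozygous"
HEMIZYGOUS = "hemizygous"

INDEL_CATEGORIES = frozenset({INSERTION, DELETION, DELINS})
CHROMOSOME_SCALE_CATEGORIES = frozenset(
    {CHROMOSOMAL_GAIN, CHROMOSOMAL_LOSS, DUPLICATION}
)


class PanelFormatError(ValueError):
    """A BED line could not be parsed."""


class ClassificationError(ValueError):
    """A mutation description could not be classified; carries the raw string."""

    def __init__(self, raw: str, reason: str = "unparseable description"):
        self.raw = raw
        super().__init__(f"{reason}: {raw!r}")


class SchemaError(ValueError):
    """A tabular input is missing mandatory columns."""


class ValidationError(ValueError):
    """An input value violates a documented invariant."""


class ConfigurationError(ValueError):
    """A requested analysis configuration is impossible."""


# ---------------------------------------------------------------------------
# Panel model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetRegion:
    """One captured interval. ``start`` 0-based inclusive, ``end`` exclusive."""

    chrom: str
    start: int
    end: int
    gene: str
    exon_label: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"region {self.chrom}:{self.start}-{self.end} requires 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def _merged_length(intervals: Iterable[tuple[int, int]]) -> int:
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    if cur_e is not None:
        total += cur_e - cur_s
    return total


@dataclass
class Panel:
    """The target-region universe against which depth and variants are read.

    ``total_size`` is the number of distinct targeted bases, i.e. region
    lengths after merging overlaps, so it is invariant under permutation
    and duplication of input lines.
    """

    regions: list[TargetRegion] = field(default_factory=list)

    def __post_init__(self):
        self.regions = sorted(
            self.regions, key=lambda r: (_chrom_sort_key(r.chrom), r.start, r.end)
        )
        seen: set[tuple[str, str]] = set()
        for r in self.regions:
            key = (r.gene, r.exon_label)
            if key in seen:
                raise ValidationError(
                    f"exon label {r.exon_label!r} duplicated within gene {r.gene!r}"
                )
            seen.add(key)

    @property
    def total_size(self) -> int:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for r in self.regions:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        return sum(_merged_length(iv) for iv in by_chrom.values())

    @property
    def genes(self) -> set[str]:
        return {r.gene for r in self.regions}

    @property
    def chromosomes(self) -> set[str]:
        return {r.chrom for r in self.regions}

    def footprint(self, chrom: str) -> int:
        """Merged on-target bases on one chromosome."""
        return _merged_length(
            (r.start, r.end) for r in self.regions if r.chrom == chrom
        )

    def regions_of_gene(self, gene: str) -> list[TargetRegion]:
        return [r for r in self.regions if r.gene == gene]

    def exon_index(self) -> list[tuple[str, str]]:
        """(gene, exon_label) pairs in genomic order — the row index of depth matrices."""
        return [(r.gene, r.exon_label) for r in self.regions]


def _chrom_sort_key(chrom: str):
    body = chrom[3:] if chrom.startswith("chr") else chrom
    if body.isdigit():
        return (0, int(body), "")
    return (1, 0, body)


def read_panel(path) -> Panel:
    """Read a 4+ column BED file whose name field is ``GENE|EXONLABEL``."""
    regions = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 4:
                raise PanelFormatError(
                    f"line {lineno}: expected >= 4 BED columns, got {len(fields)}"
                )
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise PanelFormatError(
                    f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from exc
            if start >= end:
                raise ValidationError(f"line {lineno}: start {start} >= end {end}")
            gene, _, exon_label = name.partition("|")
            if not exon_label:
                raise PanelFormatError(
                    f"line {lineno}: name field {name!r} is not GENE|EXONLABEL"
                )
            regions.append(TargetRegion(chrom, start, end, gene, exon_label))
    return Panel(regions)


def write_panel(panel: Panel, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for r in panel.regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}|{r.exon_label}\n")


# ---------------------------------------------------------------------------
# HGVS-lite mutation classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutationEvent:
    """A classified mutation description.

    ``category`` is a total function of the description string: every entry
    of the bundled clinical table maps to exactly one category. Descriptions
    whose coding position carries an intronic offset (``+1``, ``-2``, ...)
    are classed ``splice/intronic``; everything else is ``coding``.
    """

    raw_cdna: str
    raw_protein: str | None = None
    category: str = SNV
    region_class: str = CODING
    novel_flag: bool = False
    zygosity: str = HETEROZYGOUS
    affected_length: int | None = None

    @property
    def is_indel(self) -> bool:
        return self.category in INDEL_CATEGORIES

    @property
    def splice_offset(self) -> int | None:
        """Absolute intronic offset of the first position, if any."""
        m = _OFFSET_RE.search(self.raw_cdna)
        return abs(int(m.group(1))) if m else None

    @property
    def is_truncating(self) -> bool:
        """Nonsense, frameshift, or canonical +/-2 splice disruption."""
        if self.raw_protein:
            p = self.raw_protein
            if "fs" in p or p.rstrip(")").endswith("*"):
                return True
        off = self.splice_offset
        return off is not None and off <= 2

    def format(self) -> str:
        """Canonical table string; parsing it back reproduces this event."""
        parts = [self.raw_cdna]
        if self.raw_protein:
            parts.append(f"({self.raw_protein})")
        if self.zygosity == HOMOZYGOUS:
            parts.append("(Hom)")
        elif self.zygosity == HEMIZYGOUS:
            parts.append("(Hem)")
        out = " ".join(parts)
        return out + ", novel" if self.novel_flag else out


_OFFSET_RE = re.compile(r"c\.[\d*]+([+-]\d+)")
_DEL_SEQ_RE = re.compile(r"del([ACGTN]+)$")
_INS_SEQ_RE = re.compile(r"ins>?([ACGTN]+)$")
_RANGE_RE = re.compile(r"c\.(\d+)(?:[+-]\d+)?_(\d+)")


def _affected_length(desc: str, category: str) -> int | None:
    if category == DELETION:
        m = _DEL_SEQ_RE.search(desc)
        if m:
            return len(m.group(1))
        m = _RANGE_RE.search(desc)
        if m:
            return int(m.group(2)) - int(m.group(1)) + 1
        return 1
    if category in (INSERTION, DELINS):
        m = _INS_SEQ_RE.search(desc)
        if m:
            return len(m.group(1))
    return None


def parse_hgvs_c(
    desc: str,
    protein: str | None = None,
    *,
    zygosity: str = HETEROZYGOUS,
    novel: bool = False,
) -> MutationEvent:
    """Classify a coding-level ``c.`` description into a :class:`MutationEvent`.

    Raises :class:`ClassificationError` (carrying the raw string) rather than
    silently dropping anything it cannot read.
    """
    desc = desc.strip()
    if not desc.startswith("c.") or len(desc) <= 2:
        raise ClassificationError(desc, "not a c. description")

    has_del = "del" in desc
    has_ins = "ins" in desc
    if "delins" in desc or (has_del and has_ins) or "ins>" in desc or (
        protein and "delins" in protein
    ):
        category = DELINS
    elif has_del:
        category = DELETION
    elif "dup" in desc:
        category = DUPLICATION
    elif has_ins:
        category = INSERTION
    elif ">" in desc:
        category = SNV
    else:
        raise ClassificationError(desc)

    region_class = SPLICE_INTRONIC if _OFFSET_RE.search(desc) else CODING
    length = _affected_length(desc, category)
    if length is not None and length <= 0:
        raise ClassificationError(desc, "non-positive affected length")
    return MutationEvent(
        raw_cdna=desc,
        raw_protein=protein,
        category=category,
        region_class=region_class,
        novel_flag=novel,
        zygosity=zygosity,
        affected_length=length,
    )


_KARYOTYPE_GAIN_RE = re.compile(r"^4[67][.,]\s*X[XNY]{1,2}\s*,\s*\+(\d+)$")
_KARYOTYPE_LOSS_RE = re.compile(
    r"^4[56]\s*,\s*X[XNY]{1,2}\s*,\s*del\((\w+)\)\(([^)]*)\)$"
)
_CDS_DUP_RE = re.compile(r"^CDS(\d+)(?:-(\d+))?\s+dup$")


def classify_structural(
    desc: str, *, novel: bool = False, zygosity: str = HETEROZYGOUS
) -> MutationEvent:
    """Classify chromosome-scale and exon-run descriptions.

    ``47,XX,+10`` -> chromosomal_gain; ``46,XN,del(17)(p11.2)`` ->
    chromosomal_loss; ``CDS1-4 dup`` -> duplication. These are counted
    separately from SNVs/indels.
    """
    desc = desc.strip()
    m = _KARYOTYPE_GAIN_RE.match(desc)
    if m:
        return MutationEvent(desc, None, CHROMOSOMAL_GAIN, CODING, novel, zygosity)
    m = _KARYOTYPE_LOSS_RE.match(desc)
    if m:
        return MutationEvent(desc, None, CHROMOSOMAL_LOSS, CODING, novel, zygosity)
    m = _CDS_DUP_RE.match(desc)
    if m:
        first = int(m.group(1))
        last = int(m.group(2)) if m.group(2) else first
        return MutationEvent(
            desc, None, DUPLICATION, CODING, novel, zygosity,
            affected_length=last - first + 1,
        )
    raise ClassificationError(desc, "not a recognized structural description")


_CDNA_TOKEN_RE = re.compile(r"c\.[^\s,;]+")
_PROTEIN_RE = re.compile(r"\(p\.([^)]*)\)")
_ZYG_RE = re.compile(r"\((Hom|Hem)\)")
_NOVEL_RE = re.compile(r"\bnovel\b")


def parse_mutation_string(text: str) -> list[MutationEvent]:
    """Split a clinical-table mutation string into classified events.

    A string may carry several ``c.`` descriptions (compound heterozygotes);
    each keeps its own protein description, zygosity mark and novel flag.
    ``(Hom)``/``(Hem)`` mark homo-/hemizygous records; unmarked records are
    heterozygous. ``negative result`` yields no events.
    """
    text = text.strip()
    if not text:
        raise ClassificationError(text, "empty mutation string")
    if text.lower() == "negative result":
        return []

    starts = [m.start() for m in _CDNA_TOKEN_RE.finditer(text)]
    if not starts:
        return [classify_structural(text)]

    events = []
    for i, s in enumerate(starts):
        seg = text[s : starts[i + 1] if i + 1 < len(starts) else len(text)]
        desc = _CDNA_TOKEN_RE.match(seg).group(0)
        pm = _PROTEIN_RE.search(seg)
        protein = f"p.{pm.group(1)}" if pm else None
        zm = _ZYG_RE.search(seg)
        zygosity = (
            HOMOZYGOUS if zm and zm.group(1) == "Hom"
            else HEMIZYGOUS if zm
            else HETEROZYGOUS
        )
        events.append(
            parse_hgvs_c(
                desc, protein, zygosity=zygosity, novel=bool(_NOVEL_RE.search(seg))
            )
        )
    return events


# ---------------------------------------------------------------------------
# Clinical mutation table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutationRecord:
    """One mutation occurrence in one case."""

    case_id: str
    gene: str
    event: MutationEvent
    sex: str | None = None
    diagnosis: str | None = None
    consistency: str | None = None


_MUTATION_TABLE_REQUIRED = ("case_id", "gene", "mutations")


def read_mutation_table(path) -> list[MutationRecord]:
    """Read a TSV mutation table into per-occurrence records.

    A row whose mutation string holds two compound-heterozygous descriptions
    yields two records; ``negative result`` rows yield none.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _MUTATION_TABLE_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"mutation table missing mandatory column(s): {missing}")
    records = []
    for row in df.itertuples(index=False):
        for event in parse_mutation_string(row.mutations):
            records.append(
                MutationRecord(
                    case_id=row.case_id,
                    gene=row.gene,
                    event=event,
                    sex=getattr(row, "sex", None),
                    diagnosis=getattr(row, "diagnosis", None),
                    consistency=getattr(row, "consistency", None),
                )
            )
    return records


def load_case_mutation_table() -> list[MutationRecord]:
    """The bundled 90-case clinical mutation summary, as parsed records."""
    ref = resources.files("paneldx.data").joinpath("case_mutations.tsv")
    with resources.as_file(ref) as p:
        return read_mutation_table(p)


def mutation_summary(records: Sequence[MutationRecord]) -> dict:
    """Category tallies over mutation records.

    SNVs are reported both per record occurrence and per unique
    (gene, description) allele, since families can share one allele.
    Novel counting is per occurrence.
    """
    by_cat: dict[str, int] = {}
    for r in records:
        by_cat[r.event.category] = by_cat.get(r.event.category, 0) + 1
    snv_alleles = {
        (r.gene, r.event.raw_cdna) for r in records if r.event.category == SNV
    }
    return {
        "n_records": len(records),
        "category_counts": by_cat,
        "snv_record_count": by_cat.get(SNV, 0),
        "snv_unique_allele_count": len(snv_alleles),
        "indel_record_count": sum(
            by_cat.get(c, 0) for c in INDEL_CATEGORIES
        ),
        "novel_record_count": sum(r.event.novel_flag for r in records),
        "chromosome_scale_count": sum(
            by_cat.get(c, 0) for c in CHROMOSOME_SCALE_CATEGORIES
        ),
    }


# ---------------------------------------------------------------------------
# Disease -> candidate-gene map
# ---------------------------------------------------------------------------


@dataclass
class DiseaseGeneMap:
    """Ordered candidate genes per disease code, plus inheritance models per gene."""

    genes_by_disease: dict[str, list[str]]
    models_by_gene: dict[str, tuple[str, ...]]

    VALID_MODELS = ("AD", "AR", "XL")

    def __post_init__(self):
        for gene, models in self.models_by_gene.items():
            bad = [m for m in models if m not in self.VALID_MODELS]
            if bad:
                raise ValidationError(f"gene {gene!r}: unknown model(s) {bad}")

    def candidates(self, disease: str) -> list[str]:
        if disease not in self.genes_by_disease:
            raise ConfigurationError(f"unknown disease code {disease!r}")
        return self.genes_by_disease[disease]

    def diseases_of_gene(self, gene: str) -> list[str]:
        return [
            d for d, genes in self.genes_by_disease.items() if gene in genes
        ]

    def validate_against_panel(self, panel: Panel) -> None:
        missing = {
            g for genes in self.genes_by_disease.values() for g in genes
        } - panel.genes
        if missing:
            raise ValidationError(
                f"candidate genes absent from panel: {sorted(missing)}"
            )


def read_disease_map(path) -> DiseaseGeneMap:
    """TSV with columns disease, gene, models (';'-separated AD/AR/XL)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("disease", "gene", "models"):
        if col not in df.columns:
            raise SchemaError(f"disease map missing column {col!r}")
    genes_by_disease: dict[str, list[str]] = {}
    models_by_gene: dict[str, tuple[str, ...]] = {}
    for row in df.itertuples(index=False):
        genes_by_disease.setdefault(row.disease, []).append(row.gene)
        models_by_gene[row.gene] = tuple(row.models.split(";"))
    return DiseaseGeneMap(genes_by_disease, models_by_gene)


# ---------------------------------------------------------------------------
# Genotype tables, annotation tables, variant calls
# ---------------------------------------------------------------------------


def normalize_genotype(alleles: str | Sequence[str]) -> tuple[str, ...]:
    """Unordered allele pair (or single allele) as a sorted tuple."""
    if isinstance(alleles, str):
        alleles = alleles.replace("|", "/").split("/")
    return tuple(sorted(a.strip() for a in alleles if a.strip()))


def read_genotype_table(path) -> dict[str, dict[tuple[str, int], tuple[str, ...]]]:
    """TSV (sample, chrom, pos, alleles) -> {sample: {(chrom, pos): genotype}}."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample", "chrom", "pos", "alleles"):
        if col not in df.columns:
            raise SchemaError(f"genotype table missing column {col!r}")
    out: dict[str, dict[tuple[str, int], tuple[str, ...]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.sample, {})[(row.chrom, int(row.pos))] = (
            normalize_genotype(row.alleles)
        )
    return out


def write_genotype_table(
    genotypes: Mapping[str, Mapping[tuple[str, int], Sequence[str]]], path
) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample\tchrom\tpos\talleles\n")
        for sample in sorted(genotypes):
            for (chrom, pos), gt in sorted(genotypes[sample].items()):
                fh.write(f"{sample}\t{chrom}\t{pos}\t{'/'.join(gt)}\n")


_ANNOTATION_COLUMNS = (
    "chrom", "pos", "ref", "alt",
    "local_freq", "pop_freq", "known_pathogenic", "deleterious_votes",
)


def read_annotation_table(path) -> pd.DataFrame:
    """Annotation TSV keyed by (chrom, pos, ref, alt).

    Empty frequency fields stay missing (NaN) — downstream, a variant with no
    frequency data is treated as rare/novel.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"annotation table missing column(s): {missing}")
    if df[["chrom", "pos", "ref", "alt"]].isna().any().any():
        raise SchemaError("annotation table has malformed key rows")
    df["known_pathogenic"] = df["known_pathogenic"].fillna(0).astype(bool)
    df["deleterious_votes"] = df["deleterious_votes"].fillna(0).astype(int)
    return df


@dataclass(frozen=True)
class VariantCall:
    """One called variant, pre-annotation. Position is 1-based (VCF dialect)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    zygosity: str = HETEROZYGOUS
    cdna: str | None = None
    protein: str | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def read_variant_calls(path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("chrom", "pos", "ref", "alt", "gene", "zygosity"):
        if col not in df.columns:
            raise SchemaError(f"variant call table missing column {col!r}")
    return [
        VariantCall(
            chrom=row.chrom, pos=int(row.pos), ref=row.ref, alt=row.alt,
            gene=row.gene, zygosity=row.zygosity,
            cdna=getattr(row, "cdna", "") or None,
            protein=getattr(row, "protein", "") or None,
        )
        for row in df.itertuples(index=False)
    ]


def write_variant_calls(calls: Sequence[VariantCall], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\tzygosity\tcdna\tprotein\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.pos}\t{c.ref}\t{c.alt}\t{c.gene}\t{c.zygosity}"
                f"\t{c.cdna or ''}\t{c.protein or ''}\n"
            )


# ---------------------------------------------------------------------------
# Diagnostic report serialization
# ---------------------------------------------------------------------------


def write_report(report, path) -> None:
    """Serialize a diagnostic report (anything with ``to_dict``) as stable JSON.

    Output is deterministic and diff-stable: sorted keys, two-space indent,
    UTF-8, LF line endings, trailing newline. serialize -> parse -> serialize
    is byte-identical.
    """
    payload = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    text = json.dumps(payload, indent=2, sort_keys=True, ensure_ascii=False)
    Path(path).write_text(text + "\n", encoding="utf-8", newline="\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
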