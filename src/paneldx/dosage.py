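"""Copy-number dosage calling from depth matrices and read counts.

Two granularities, one idea: a sample's sequencing signal at a region,
normalized for its own library size, is compared against in-batch control
samples. On autosomes the resulting dosage ratio has expectation
``copies / 2`` — 1.5 for a heterozygous duplication or trisomy, 0.5 for a
heterozygous loss, 0 for a homozygous deletion.

* Exon level: per-exon mean depths, normalized within-sample by the sample's
  median exon depth and across samples by the in-batch control median.
  Medians (not means) throughout, so the test sample's own event does not
  drag its normalizer.
* Chromosome level: per-chromosome on-target read counts, normalized by the
  autosomal total *excluding the chromosome under test*, so a trisomy's
  expected ratio is exactly 1.5 rather than 1.5 / (1 + 0.5 w_c).
* Segment level: binned counts along one chromosome, median-normalized like
  exons, for megabase-scale microdeletions/microduplications.

Default decision thresholds sit midway between the diploid ratio (1.0) and
the heterozygous-event expectations (1.5 / 0.5): gain >= 1.35, loss <= 0.65.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_io import (
    AUTOSOMES,
    ConfigurationError,
    Panel,
    SchemaError,
    ValidationError,
)

__all__ = [
    "DepthMatrix",
    "ChromCounts",
    "BinnedCounts",
    "DosageCall",
    "GAIN_THRESHOLD",
    "LOSS_THRESHOLD",
    "normalize_exon_ratios",
    "call_exon_cnv",
    "chrom_dosage",
    "segment_dosage",
    "infer_sex",
    "expected_copy_ratio",
]

GAIN_THRESHOLD = 1.35
LOSS_THRESHOLD = 0.65


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class DepthMatrix:
    """Per-exon mean depth, exons (gene, exon_label) x samples, plus batch labels.

    Row order follows the panel's genomic order; ``regions`` maps each row to
    its genomic interval.
    """

    depths: pd.DataFrame  # index: MultiIndex (gene, exon_label); columns: samples
    batches: dict[str, str] = field(default_factory=dict)
    regions: dict[tuple[str, str], tuple[str, int, int]] = field(default_factory=dict)

    def __post_init__(self):
        if (self.depths.to_numpy() < 0).any():
            raise ValidationError("depth matrix has negative entries")
        for s in self.depths.columns:
            self.batches.setdefault(s, "batch1")

    @property
    def samples(self) -> list[str]:
        return list(self.depths.columns)

    def in_batch_controls(self, sample: str) -> list[str]:
        b = self.batches[sample]
        return [s for s in self.samples if s != sample and self.batches[s] == b]

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(
                "#batches\t"
                + "\t".join(f"{s}={self.batches[s]}" for s in self.samples)
                + "\n"
            )
            fh.write("gene\texon\tchrom\tstart\tend\t" + "\t".join(self.samples) + "\n")
            for (gene, exon), row in self.depths.iterrows():
                chrom, start, end = self.regions.get((gene, exon), ("NA", 0, 0))
                vals = "\t".join(format(v, "g") for v in row)
                fh.write(f"{gene}\t{exon}\t{chrom}\t{start}\t{end}\t{vals}\n")

    @classmethod
    def read_tsv(cls, path) -> "DepthMatrix":
        batches: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            first = fh.readline().rstrip("\n")
            if first.startswith("#batches"):
                for tok in first.split("\t")[1:]:
                    s, _, b = tok.partition("=")
                    batches[s] = b
                header_line = fh.readline().rstrip("\n")
            else:
                header_line = first
            cols = header_line.split("\t")
            if cols[:5] != ["gene", "exon", "chrom", "start", "end"]:
                raise SchemaError("depth matrix header must start gene/exon/chrom/start/end")
            samples = cols[5:]
            idx, regions, data = [], {}, []
            for line in fh:
                f = line.rstrip("\n").split("\t")
                idx.append((f[0], f[1]))
                regions[(f[0], f[1])] = (f[2], int(f[3]), int(f[4]))
                data.append([float(x) for x in f[5:]])
        df = pd.DataFrame(
            data, index=pd.MultiIndex.from_tuples(idx, names=["gene", "exon"]),
            columns=samples,
        )
        return cls(df, batches, regions)


@dataclass
class ChromCounts:
    """Per-chromosome on-target read counts per sample."""

    counts: pd.DataFrame  # index: chromosome names; columns: samples
    declared_sex: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("chromosome counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.counts.index)

    def autosomal_total(self, sample: str, exclude: str | None = None) -> float:
        rows = [
            c for c in self.counts.index
            if c in AUTOSOMES and c != exclude
        ]
        return float(self.counts.loc[rows, sample].sum())

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("chrom\t" + "\t".join(self.samples) + "\n")
            for chrom, row in self.counts.iterrows():
                fh.write(chrom + "\t" + "\t".join(format(v, "g") for v in row) + "\n")

    @classmethod
    def read_tsv(cls, path) -> "ChromCounts":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)


@dataclass
class BinnedCounts:
    """Read counts in fixed-width bins tiling one chromosome's target footprint."""

    chrom: str
    intervals: list[tuple[int, int]]  # genomic (start, end) per bin, 0-based half-open
    counts: pd.DataFrame  # index: bin ordinal; columns: samples

    def __post_init__(self):
        if len(self.intervals) != len(self.counts):
            raise ValidationError("bin intervals and count rows differ in length")
        if len(self.intervals) == 0:
            raise ValidationError("bins do not cover any target")


@dataclass(frozen=True)
class DosageCall:
    """One called dosage event."""

    scope: str  # "exon_run" | "chromosome" | "segment"
    location: str
    observed_ratio: float
    expected_copies: int
    classification: str  # "gain" | "loss" | "normal"
    n_units: int
    gene: str | None = None
    exons: tuple[str, ...] = ()
    interval: tuple[int, int] | None = None
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "location": self.location,
            "observed_ratio": self.observed_ratio,
            "expected_copies": self.expected_copies,
            "classification": self.classification,
            "n_units": self.n_units,
            "gene": self.gene,
            "exons": list(self.exons),
            "interval": list(self.interval) if self.interval else None,
            "flags": list(self.flags),
        }


# ---------------------------------------------------------------------------
# Exon-level CNV
# ---------------------------------------------------------------------------


def normalize_exon_ratios(
    dm: DepthMatrix, test_sample: str, controls: list[str] | None = None
) -> pd.Series:
    """Per-exon dosage ratio of one sample against in-batch controls.

    ratio(e) = (d(e, test) / median_e d(., test))
             / median_c (d(e, c) / median_e d(., c))

    Exons whose across-control median is zero cannot be normalized and come
    back NaN (flagged, never silently zero). Invariant to rescaling any
    sample's depths by a positive constant.
    """
    if controls is None:
        controls = dm.in_batch_controls(test_sample)
        if not controls:
            raise ConfigurationError(
                f"no in-batch controls for {test_sample!r} "
                f"(batch {dm.batches[test_sample]!r})"
            )
    if not controls:
        raise ConfigurationError("empty control list")
    if test_sample in controls:
        raise ConfigurationError("controls must exclude the test sample")

    test = dm.depths[test_sample].astype(float)
    test_med = float(test.median())
    if test_med == 0:
        raise ValidationError(f"test sample {test_sample!r} has all-zero median depth")
    test_norm = test / test_med

    ctrl = dm.depths[controls].astype(float)
    ctrl_norm = ctrl / ctrl.median(axis=0)
    ctrl_med = ctrl_norm.median(axis=1)

    ratios = test_norm / ctrl_med.where(ctrl_med > 0)
    ratios.name = test_sample
    return ratios


def _runs_beyond(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) half-open index pairs."""
    runs = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def call_exon_cnv(
    ratios: pd.Series,
    gain_threshold: float = GAIN_THRESHOLD,
    loss_threshold: float = LOSS_THRESHOLD,
    min_run: int = 1,
    regions: dict[tuple[str, str], tuple[str, int, int]] | None = None,
) -> list[DosageCall]:
    """Turn a per-exon ratio vector into CNV calls.

    Maximal runs of consecutive exons (within one gene, in panel order) all
    beyond one threshold become a single call; the call's ratio is the median
    over the run and its copy number the nearest integer of 2 x ratio.
    Single-exon calls carry the ``single_unit_call`` caveat flag.
    """
    if not (0 < loss_threshold < 1 < gain_threshold):
        raise ValidationError("thresholds must satisfy 0 < loss < 1 < gain")
    calls: list[DosageCall] = []
    if len(ratios) == 0:
        return calls
    for gene in ratios.index.get_level_values(0).unique():
        sub = ratios.xs(gene, level=0, drop_level=False)
        vals = sub.to_numpy(dtype=float)
        exons = [e for _, e in sub.index]
        for kind, mask in (
            ("gain", vals >= gain_threshold),
            ("loss", vals <= loss_threshold),
        ):
            mask = mask & ~np.isnan(vals)
            for a, b in _runs_beyond(mask):
                if b - a < min_run:
                    continue
                run_ratio = float(np.median(vals[a:b]))
                run_exons = tuple(exons[a:b])
                interval = None
                if regions:
                    spans = [regions[(gene, e)] for e in run_exons if (gene, e) in regions]
                    if spans:
                        interval = (min(s[1] for s in spans), max(s[2] for s in spans))
                flags = ("single_unit_call",) if b - a == 1 else ()
                calls.append(
                    DosageCall(
                        scope="exon_run",
                        location=f"{gene}:{run_exons[0]}-{run_exons[-1]}",
                        observed_ratio=run_ratio,
                        expected_copies=int(round(2 * run_ratio)),
                        classification=kind,
                        n_units=b - a,
                        gene=gene,
                        exons=run_exons,
                        interval=interval,
                        flags=flags,
                    )
                )
    return calls


# ---------------------------------------------------------------------------
# Chromosome-level dosage
# ---------------------------------------------------------------------------


def chrom_dosage(
    cc: ChromCounts,
    test_sample: str,
    reference_samples: list[str],
    gain_threshold: float = GAIN_THRESHOLD,
    loss_threshold: float = LOSS_THRESHOLD,
    call_sex_chromosomes: bool = False,
) -> list[DosageCall]:
    """Per-chromosome dosage ratios and aneuploidy calls for one sample.

    For chromosome c, each sample's count is normalized by its autosomal
    total excluding c; the test sample's normalized value is divided by the
    median over references (assumed diploid on autosomes). A second pass
    additionally drops any chromosome flagged aberrant in the first pass
    from every denominator, so one aneuploidy does not bias the ratios of
    the unaffected chromosomes (which stay exactly 1.0 in noise-free data).
    Sex chromosomes get ratios too, but are only classified when
    ``call_sex_chromosomes`` (references must then be sex-matched).
    """
    if not reference_samples:
        raise ConfigurationError("need at least one reference sample")
    if test_sample in reference_samples:
        raise ConfigurationError("references must exclude the test sample")

    def _ratio(chrom: str, drop: frozenset[str]) -> float:
        def _denom(sample: str) -> float:
            rows = [
                c for c in cc.counts.index
                if c in AUTOSOMES and c != chrom and c not in drop
            ]
            d = float(cc.counts.loc[rows, sample].sum())
            if d == 0:
                raise ValidationError(f"zero autosomal total for {sample!r}")
            return d

        t = float(cc.counts.at[chrom, test_sample]) / _denom(test_sample)
        ref_vals = [
            float(cc.counts.at[chrom, r]) / _denom(r) for r in reference_samples
        ]
        ref_med = float(np.median(ref_vals))
        return t / ref_med if ref_med > 0 else float("nan")

    def _classify(chrom: str, ratio: float) -> str:
        if chrom in AUTOSOMES or call_sex_chromosomes:
            if ratio >= gain_threshold:
                return "gain"
            if ratio <= loss_threshold:
                return "loss"
        return "normal"

    first = {c: _ratio(c, frozenset()) for c in cc.chromosomes}
    aberrant = frozenset(
        c for c, r in first.items()
        if c in AUTOSOMES and _classify(c, r) != "normal"
    )
    autosomes_left = [
        c for c in cc.chromosomes if c in AUTOSOMES and c not in aberrant
    ]
    if aberrant and not autosomes_left:
        aberrant = frozenset()  # cannot renormalize if everything moved

    calls = []
    for chrom in cc.chromosomes:
        ratio = _ratio(chrom, aberrant - {chrom}) if aberrant else first[chrom]
        kind = _classify(chrom, ratio)
        calls.append(
            DosageCall(
                scope="chromosome",
                location=chrom,
                observed_ratio=ratio,
                expected_copies=int(round(2 * ratio)) if np.isfinite(ratio) else 0,
                classification=kind,
                n_units=1,
                flags=() if chrom in AUTOSOMES else ("sex_chromosome",),
            )
        )
    return calls


def segment_dosage(
    binned: BinnedCounts,
    test_sample: str,
    reference_samples: list[str],
    gain_threshold: float = GAIN_THRESHOLD,
    loss_threshold: float = LOSS_THRESHOLD,
    min_run: int = 1,
) -> list[DosageCall]:
    """Segmental (microdeletion/microduplication) calls along one chromosome.

    Each sample's bin profile is normalized by its total count (so library
    size and per-bin target content cancel against the reference median);
    the per-bin relative values are then rescaled by their own median, which
    pins the unaffected bins at 1.0 as long as the event spans fewer than
    half the bins. Maximal runs of bins beyond a threshold are reported with
    the genomic interval spanned by the run.
    """
    if not reference_samples:
        raise ConfigurationError("need at least one reference sample")
    df = binned.counts.astype(float)
    test = df[test_sample]
    if test.sum() == 0:
        raise ValidationError(f"test sample {test_sample!r} has zero total count")
    ref = df[reference_samples]
    ref_norm = ref / ref.sum(axis=0)
    ref_med = ref_norm.median(axis=1)
    rel = (test / test.sum()) / ref_med.where(ref_med > 0)
    rel_med = float(rel.median())
    if not rel_med > 0:
        raise ValidationError("cannot rescale: median relative dosage is not positive")
    ratios = rel / rel_med

    # bins with no reference signal carry no target content: they are
    # uninformative and must not break an event run
    informative = np.flatnonzero(~np.isnan(ratios.to_numpy(dtype=float)))
    vals = ratios.to_numpy(dtype=float)[informative]

    calls = []
    for kind, mask in (
        ("gain", vals >= gain_threshold),
        ("loss", vals <= loss_threshold),
    ):
        for a, b in _runs_beyond(mask):
            if b - a < min_run:
                continue
            run_ratio = float(np.median(vals[a:b]))
            bins = informative[a:b]
            start = min(binned.intervals[i][0] for i in bins)
            end = max(binned.intervals[i][1] for i in bins)
            calls.append(
                DosageCall(
                    scope="segment",
                    location=f"{binned.chrom}:{start}-{end}",
                    observed_ratio=run_ratio,
                    expected_copies=int(round(2 * run_ratio)),
                    classification=kind,
                    n_units=b - a,
                    interval=(start, end),
                    flags=("single_unit_call",) if b - a == 1 else (),
                )
            )
    return calls


# ---------------------------------------------------------------------------
# Sex inference
# ---------------------------------------------------------------------------


def _x_dosage(cc: ChromCounts, sample: str) -> float:
    if "chrX" not in cc.counts.index:
        raise ConfigurationError("panel has no X-chromosome targets")
    total = cc.autosomal_total(sample)
    if total == 0:
        raise ValidationError(f"zero autosomal total for {sample!r}")
    return float(cc.counts.at["chrX", sample]) / total


def infer_sex(
    cc: ChromCounts,
    sample: str,
    female_profile: float,
    male_profile: float,
    band: tuple[float, float] = (0.3, 0.7),
) -> str:
    """Assign female / male / undetermined from normalized X dosage.

    ``female_profile`` / ``male_profile`` are reference values of
    chrX count / autosomal total for known 46,XX and 46,XY samples (the
    female value is ~2x the male one). The sample's dosage is placed on the
    male(0)->female(1) axis; scores inside the open decision band come back
    ``undetermined``. Y dosage, where targeted, must agree or the call is
    ``undetermined``.
    """
    if female_profile <= male_profile:
        raise ConfigurationError("female X profile must exceed male X profile")
    d = _x_dosage(cc, sample)
    score = (d - male_profile) / (female_profile - male_profile)
    lo, hi = band
    if score >= hi:
        call = "female"
    elif score <= lo:
        call = "male"
    else:
        return "undetermined"
    if "chrY" in cc.counts.index:
        y = float(cc.counts.at["chrY", sample]) / cc.autosomal_total(sample)
        x_total = float(cc.counts.at["chrX", sample]) + float(cc.counts.at["chrY", sample])
        y_frac = float(cc.counts.at["chrY", sample]) / x_total if x_total else 0.0
        has_y = y_frac > 0.05  # male Y footprint share, generously below expectation
        if has_y != (call == "male"):
            return "undetermined"
    return call


def expected_copy_ratio(copies: int, baseline_ploidy: int = 2) -> float:
    """Expected dosage ratio for an integer copy number (qPCR RQ analogue)."""
    if copies < 0:
        raise ValidationError("copies must be >= 0")
    if baseline_ploidy <= 0:
        raise ValidationError("baseline ploidy must be positive")
    return copies / baseline_ploidy
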