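"""Synthetic data with the statistical structure the pipeline assumes.

Everything downstream — coverage QC, dosage calling, prioritization,
concordance arithmetic — is testable against generators in this module, with
no external data. All generators are pure functions of their inputs and the
seed in :class:`SimulationSpec`; a fixed seed gives identical output on
every call.

Depth model
-----------
The mean depth of exon *e* in sample *s* is

    mu(e, s) = mean_depth * capture_effect(e) * sample_scale(s) * copies(e, s) / 2

and observed depth is negative binomial about that mean with variance
``mu + dispersion * mu**2``. Capture efficiency genuinely varies per exon on
hybridization panels, hence the overdispersed (not Poisson) noise and the
log-normal per-exon capture effects. Chromosome read counts are multinomial
over per-chromosome weights proportional to on-target footprint times
``copies / 2``.

Noise-free mode (``noise_free=True``) replaces every random draw by its
expectation and flattens capture effects to 1, so closed-form dosage
expectations hold *exactly*; it is the oracle mode for the dosage caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .panel_io import (
    ConfigurationError,
    DiseaseGeneMap,
    HETEROZYGOUS,
    HOMOZYGOUS,
    HEMIZYGOUS,
    Panel,
    TargetRegion,
    ValidationError,
    VariantCall,
)
from .dosage import BinnedCounts, ChromCounts, DepthMatrix

__all__ = [
    "SimulationSpec",
    "DosageEvent",
    "Karyotype",
    "CaseTruth",
    "CaseSim",
    "build_panel",
    "demo_panel_and_map",
    "simulate_depths",
    "simulate_chrom_counts",
    "simulate_binned_counts",
    "simulate_case",
    "simulate_concordance_pair",
    "simulate_replicate_snv_sets",
]

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class DosageEvent:
    """One injected copy-number event (diploid baseline 2 copies).

    scope "exon_run": ``gene`` + ``exons`` name panel exons;
    scope "chromosome": ``chrom`` names a whole chromosome;
    scope "chromosomal_segment": ``chrom``, ``start``, ``end`` bound a segment.
    """

    scope: str
    copies: int
    gene: str | None = None
    exons: tuple[str, ...] = ()
    chrom: str | None = None
    start: int | None = None
    end: int | None = None

    def __post_init__(self):
        if self.copies < 0:
            raise ValidationError("copies must be >= 0")
        if self.scope not in ("exon_run", "chromosome", "chromosomal_segment"):
            raise ValidationError(f"unknown event scope {self.scope!r}")


@dataclass
class SimulationSpec:
    """Knobs for all generators.

    mean_depth defaults to 80-fold, the working depth at which the panel's
    stability was characterized; read_length 90 bp paired-end reads;
    nb_dispersion 0.05 (depth CV ~22% before Poisson noise, typical of
    uneven hybridization capture).
    """

    seed: int = 0
    n_controls: int = 10
    mean_depth: float = 80.0
    nb_dispersion: float = 0.05
    read_length: int = 90
    capture_effect_sigma: float = 0.25
    exon_capture_effects: np.ndarray | None = None
    events: list[DosageEvent] = field(default_factory=list)
    discordance_rate: float = 0.0
    replicate_jitter: tuple[float, float] = (0.01, 0.01)  # (add, drop) probabilities
    background_rate: float = 10.0
    noise_free: bool = False

    def __post_init__(self):
        if not 0.0 <= self.discordance_rate <= 1.0:
            raise ValidationError("discordance_rate must be in [0, 1]")
        if not all(0.0 <= p <= 1.0 for p in self.replicate_jitter):
            raise ValidationError("replicate_jitter probabilities must be in [0, 1]")
        if self.mean_depth <= 0:
            raise ValidationError("mean_depth must be positive")
        if self.n_controls < 1:
            raise ValidationError("need at least one control")
        if self.nb_dispersion < 0:
            raise ValidationError("nb_dispersion must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one named stream of this spec's seed."""
        return np.random.default_rng([int(self.seed), int(stream)])

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["exon_capture_effects"] = (
            None if self.exon_capture_effects is None
            else [float(x) for x in self.exon_capture_effects]
        )
        d["replicate_jitter"] = list(self.replicate_jitter)
        d["events"] = [asdict(e) | {"exons": list(e.exons)} for e in self.events]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationSpec":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        d["events"] = [
            DosageEvent(**{**e, "exons": tuple(e.get("exons", ()))})
            for e in d.get("events", [])
        ]
        d["replicate_jitter"] = tuple(d.get("replicate_jitter", (0.01, 0.01)))
        if d.get("exon_capture_effects") is not None:
            d["exon_capture_effects"] = np.asarray(d["exon_capture_effects"], float)
        return cls(**d)


# ---------------------------------------------------------------------------
# Panel construction
# ---------------------------------------------------------------------------


def build_panel(
    n_genes: int = 40,
    exons_per_gene: int = 6,
    exon_length: int = 150,
    gap: int = 2000,
    seed: int = 0,
    total_size: int | None = None,
    chromosomes: tuple[str, ...] = ("chr1", "chr2", "chr3", "chr17", "chrX", "chrY"),
    x_genes: int = 4,
    y_genes: int = 1,
) -> Panel:
    """Deterministic synthetic capture panel.

    Genes get equal-length, evenly spaced exons labelled CDS1..CDSn.
    The last ``x_genes`` + ``y_genes`` genes land on chrX / chrY; the rest
    round-robin over the autosomes listed. If ``total_size`` is given, the
    final exon is stretched or trimmed so the merged footprint is exactly
    that many bases.
    """
    if n_genes < x_genes + y_genes + 1:
        raise ValidationError("n_genes too small for the requested sex-gene layout")
    autosomes = [c for c in chromosomes if c not in ("chrX", "chrY")]
    regions: list[TargetRegion] = []
    cursor: dict[str, int] = {c: 100_000 for c in chromosomes}
    for g in range(n_genes):
        if g >= n_genes - y_genes:
            chrom = "chrY"
        elif g >= n_genes - y_genes - x_genes:
            chrom = "chrX"
        else:
            chrom = autosomes[g % len(autosomes)]
        gene = f"G{g + 1:04d}"
        pos = cursor[chrom]
        for e in range(exons_per_gene):
            regions.append(
                TargetRegion(chrom, pos, pos + exon_length, gene, f"CDS{e + 1}")
            )
            pos += exon_length + gap
        cursor[chrom] = pos + 10 * gap
    if total_size is not None:
        current = sum(r.length for r in regions)  # regions are disjoint by design
        delta = total_size - current
        last = regions[-1]
        new_end = last.end + delta
        if new_end <= last.start:
            raise ValidationError("total_size too small for this panel layout")
        regions[-1] = TargetRegion(
            last.chrom, last.start, new_end, last.gene, last.exon_label
        )
    return Panel(regions)


def demo_panel_and_map(
    n_genes: int = 40, n_diseases: int = 12, seed: int = 0, **panel_kwargs
) -> tuple[Panel, DiseaseGeneMap]:
    """A panel plus a matching disease->gene map with AD/AR/XL models.

    X-linked genes (those the panel places on chrX) get model XL; remaining
    genes alternate AR/AD. Diseases D01.. each own a slice of genes, every
    model represented among the diseases.
    """
    panel = build_panel(n_genes=n_genes, seed=seed, **panel_kwargs)
    x_set = {r.gene for r in panel.regions if r.chrom == "chrX"}
    y_set = {r.gene for r in panel.regions if r.chrom == "chrY"}
    genes = sorted(panel.genes - y_set)
    models_by_gene = {}
    for i, g in enumerate(genes):
        models_by_gene[g] = ("XL",) if g in x_set else (("AR",) if i % 2 else ("AD",))
    genes_by_disease: dict[str, list[str]] = {}
    per = max(1, len(genes) // n_diseases)
    for d in range(n_diseases):
        sl = genes[d * per : (d + 1) * per] or [genes[-1]]
        genes_by_disease[f"D{d + 1:02d}"] = sl
    return panel, DiseaseGeneMap(genes_by_disease, models_by_gene)


# ---------------------------------------------------------------------------
# Depth and count simulation
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu * (1 + dispersion).

    NB1 parameterization: the dispersion is a constant variance inflation
    over Poisson (dispersion 0 recovers Poisson), matching the small
    residual exon-to-exon noise seen after capture-effect normalization.
    """
    mu = np.asarray(mu, dtype=float)
    out = np.zeros_like(mu)
    pos = mu > 0
    if dispersion == 0:
        out[pos] = rng.poisson(mu[pos])
        return out
    # var = mu (1 + a)  =>  p = 1 / (1 + a), k = mu / a
    p = 1.0 / (1.0 + dispersion)
    k = mu[pos] / dispersion
    out[pos] = rng.negative_binomial(k, p)
    return out


def _capture_effects(panel: Panel, spec: SimulationSpec) -> np.ndarray:
    n = len(panel.regions)
    if spec.exon_capture_effects is not None:
        eff = np.asarray(spec.exon_capture_effects, dtype=float)
        if eff.shape != (n,):
            raise ValidationError("exon_capture_effects length must match panel exons")
        return eff
    if spec.noise_free:
        return np.ones(n)
    return spec.rng(1).lognormal(0.0, spec.capture_effect_sigma, size=n)


def _exon_copies(panel: Panel, events: list[DosageEvent]) -> np.ndarray:
    """Copy number per panel exon implied by exon_run events (baseline 2)."""
    copies = np.full(len(panel.regions), 2.0)
    index = {(r.gene, r.exon_label): i for i, r in enumerate(panel.regions)}
    for ev in events:
        if ev.scope != "exon_run":
            continue
        for exon in ev.exons:
            key = (ev.gene, exon)
            if key not in index:
                raise ValidationError(f"event names unknown exon {key}")
            copies[index[key]] = ev.copies
    return copies


def simulate_depths(
    panel: Panel,
    spec: SimulationSpec,
    events_by_sample: dict[str, list[DosageEvent]] | None = None,
    batch: str = "batch1",
) -> DepthMatrix:
    """Per-exon mean-depth matrix: n_controls diploid controls plus one test
    sample per entry of ``events_by_sample`` carrying its listed events.
    """
    events_by_sample = events_by_sample or {}
    eff = _capture_effects(panel, spec)
    rng = spec.rng(2)
    names, columns = [], []
    lengths = np.array([r.length for r in panel.regions], dtype=float)
    reads_per_depth = lengths / spec.read_length  # reads giving 1x over an exon

    def _sample_depths(copies: np.ndarray) -> np.ndarray:
        scale = 1.0 if spec.noise_free else rng.lognormal(0.0, 0.1)
        mu = spec.mean_depth * eff * scale * copies / 2.0
        if spec.noise_free:
            return mu
        # noise acts on the exon's read count; depth is count-derived
        counts = _nb_draw(rng, mu * reads_per_depth, spec.nb_dispersion)
        return counts / reads_per_depth

    diploid = np.full(len(panel.regions), 2.0)
    for i in range(spec.n_controls):
        names.append(f"C{i + 1:02d}")
        columns.append(_sample_depths(diploid))
    for sample, events in events_by_sample.items():
        names.append(sample)
        columns.append(_sample_depths(_exon_copies(panel, events)))

    df = pd.DataFrame(
        np.column_stack(columns),
        index=pd.MultiIndex.from_tuples(panel.exon_index(), names=["gene", "exon"]),
        columns=names,
    )
    regions = {
        (r.gene, r.exon_label): (r.chrom, r.start, r.end) for r in panel.regions
    }
    return DepthMatrix(df, {s: batch for s in names}, regions)


@dataclass(frozen=True)
class Karyotype:
    """Whole-genome dosage state of one sample.

    ``copies`` overrides whole-chromosome copy numbers (autosome baseline 2;
    sex chromosomes default from ``sex``: XX -> X:2/Y:0, XY -> X:1/Y:1).
    ``segments`` are (chrom, start, end, copies) sub-chromosomal events.
    """

    sex: str = "female"
    copies: dict[str, int] = field(default_factory=dict)
    segments: tuple[tuple[str, int, int, int], ...] = ()

    def chrom_copies(self, chrom: str) -> int:
        if chrom in self.copies:
            c = self.copies[chrom]
        elif chrom == "chrX":
            c = 2 if self.sex == "female" else 1
        elif chrom == "chrY":
            c = 0 if self.sex == "female" else 1
        else:
            c = 2
        if c < 0:
            raise ValidationError(f"negative copy number for {chrom}")
        return c


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def _chrom_weight(panel: Panel, kt: Karyotype, chrom: str) -> float:
    """Expected read-share weight: footprint x copies/2, segment-adjusted."""
    base = kt.chrom_copies(chrom)
    w = 0.0
    for r in panel.regions:
        if r.chrom != chrom:
            continue
        rem = r.length
        for (sc, s0, s1, scp) in kt.segments:
            if sc != chrom:
                continue
            ov = _overlap(r.start, r.end, s0, s1)
            if ov:
                w += ov * scp / 2.0
                rem -= ov
        w += rem * base / 2.0
    return w


def simulate_chrom_counts(
    panel: Panel,
    spec: SimulationSpec,
    karyotypes: dict[str, Karyotype],
    total_reads: int | None = None,
) -> ChromCounts:
    """Per-chromosome on-target read counts for each sample.

    Counts are multinomial over weights proportional to the chromosome's
    on-target footprint times copies/2 (noise-free: the expectations
    themselves). ``total_reads`` defaults to mean_depth x total_size /
    read_length.
    """
    if not karyotypes:
        raise ConfigurationError("no samples requested")
    if total_reads is None:
        total_reads = int(round(spec.mean_depth * panel.total_size / spec.read_length))
    chroms = sorted(panel.chromosomes, key=lambda c: (len(c), c))
    rng = spec.rng(3)
    data = {}
    for sample, kt in karyotypes.items():
        w = np.array([_chrom_weight(panel, kt, c) for c in chroms], dtype=float)
        if w.sum() <= 0:
            raise ValidationError(f"sample {sample!r} has zero total weight")
        p = w / w.sum()
        if spec.noise_free:
            data[sample] = total_reads * p
        else:
            data[sample] = rng.multinomial(total_reads, p).astype(float)
    df = pd.DataFrame(data, index=chroms)
    return ChromCounts(df, {s: kt.sex for s, kt in karyotypes.items()})


def simulate_binned_counts(
    panel: Panel,
    spec: SimulationSpec,
    chrom: str,
    bin_size: int,
    karyotypes: dict[str, Karyotype],
) -> BinnedCounts:
    """Read counts in ``bin_size`` windows tiling one chromosome's footprint.

    Expected count in a bin is mean_depth x (targeted bp in bin) /
    read_length, scaled by the local copy number from the sample's segments;
    negative-binomial noise as for depths (expectation in noise-free mode).
    """
    regs = [r for r in panel.regions if r.chrom == chrom]
    if not regs:
        raise ValidationError(f"panel has no targets on {chrom}")
    lo = min(r.start for r in regs)
    hi = max(r.end for r in regs)
    edges = list(range(lo, hi, bin_size)) + [hi]
    intervals = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]

    target_bp = np.zeros(len(intervals))
    for i, (b0, b1) in enumerate(intervals):
        target_bp[i] = sum(_overlap(r.start, r.end, b0, b1) for r in regs)

    rng = spec.rng(4)
    data = {}
    for sample, kt in karyotypes.items():
        base = kt.chrom_copies(chrom)
        mu = np.zeros(len(intervals))
        for i, (b0, b1) in enumerate(intervals):
            # weight targeted bp by local copies/2, segment-aware
            rem = target_bp[i]
            w = 0.0
            for (sc, s0, s1, scp) in kt.segments:
                if sc != chrom:
                    continue
                ov = sum(
                    _overlap(max(r.start, b0), min(r.end, b1), s0, s1)
                    for r in regs
                    if _overlap(r.start, r.end, b0, b1)
                )
                w += ov * scp / 2.0
                rem -= ov
            w += rem * base / 2.0
            mu[i] = spec.mean_depth * w / spec.read_length
        data[sample] = mu if spec.noise_free else _nb_draw(rng, mu, spec.nb_dispersion)
    return BinnedCounts(chrom, intervals, pd.DataFrame(data))


# ---------------------------------------------------------------------------
# Case simulation (variant call sets + trio genotypes)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CaseTruth:
    gene: str
    model: str
    mode: str
    causal: tuple[VariantCall, ...]
    de_novo: tuple[tuple[str, int, str, str], ...] = ()


@dataclass
class CaseSim:
    """Simulated case: per-person call sets, truth, and annotation rows."""

    calls: dict[str, list[VariantCall]]
    truth: CaseTruth
    annotations: pd.DataFrame
    proband_sex: str


_CASE_MODES = ("AR", "AR_compound", "AD_denovo", "AD_inherited", "XL")


def _random_variant(
    rng: np.random.Generator, panel: Panel, gene: str, used: set[int], *, exon: int = 0
) -> tuple[str, int, str, str]:
    regs = panel.regions_of_gene(gene)
    r = regs[exon % len(regs)]
    while True:
        pos = r.start + 1 + int(rng.integers(0, r.length))  # 1-based
        if pos not in used:
            used.add(pos)
            break
    ref, alt = rng.choice(_BASES, size=2, replace=False)
    return (r.chrom, pos, str(ref), str(alt))


def simulate_case(
    spec: SimulationSpec,
    disease_code: str,
    dmap: DiseaseGeneMap,
    panel: Panel,
    mode: str = "AR",
    trio: bool = True,
) -> CaseSim:
    """One diagnostic case with a causal configuration of known truth.

    Modes: AR (homozygote, carrier parents), AR_compound (two hets in trans),
    AD_denovo (het proband, negative parents), AD_inherited (het proband,
    one asymptomatic carrier parent), XL (hemizygous male, carrier mother).
    Background variants are common-population alleles transmitted
    Mendelian-consistently through the trio; ``background_rate`` 0 gives a
    call set holding exactly the causal variants.
    """
    if mode not in _CASE_MODES:
        raise ConfigurationError(f"unknown case mode {mode!r}")
    model = {"AR": "AR", "AR_compound": "AR", "XL": "XL"}.get(mode, "AD")
    genes = [
        g for g in dmap.candidates(disease_code) if model in dmap.models_by_gene[g]
    ]
    if not genes:
        raise ConfigurationError(
            f"disease {disease_code!r} has no candidate gene with model {model}"
        )
    rng = spec.rng(5)
    gene = genes[int(rng.integers(len(genes)))]
    proband_sex = "male" if mode == "XL" else ("female" if rng.random() < 0.5 else "male")

    used: set[int] = set()
    persons = ["proband", "father", "mother"] if trio else ["proband"]
    calls: dict[str, list[VariantCall]] = {p: [] for p in persons}
    causal: list[VariantCall] = []
    de_novo: list[tuple[str, int, str, str]] = []

    def _add(person, chrom, pos, ref, alt, zyg):
        calls[person].append(
            VariantCall(chrom, pos, ref, alt, gene=gene, zygosity=zyg)
        )

    v1 = _random_variant(rng, panel, gene, used, exon=0)
    if mode == "AR":
        _add("proband", *v1, HOMOZYGOUS)
        if trio:
            _add("father", *v1, HETEROZYGOUS)
            _add("mother", *v1, HETEROZYGOUS)
        causal.append(calls["proband"][-1])
    elif mode == "AR_compound":
        v2 = _random_variant(rng, panel, gene, used, exon=1)
        _add("proband", *v1, HETEROZYGOUS)
        _add("proband", *v2, HETEROZYGOUS)
        if trio:
            _add("father", *v1, HETEROZYGOUS)
            _add("mother", *v2, HETEROZYGOUS)
        causal.extend(calls["proband"][-2:])
    elif mode == "AD_denovo":
        _add("proband", *v1, HETEROZYGOUS)
        causal.append(calls["proband"][-1])
        de_novo.append(v1)
    elif mode == "AD_inherited":
        _add("proband", *v1, HETEROZYGOUS)
        if trio:
            carrier = "mother" if rng.random() < 0.5 else "father"
            _add(carrier, *v1, HETEROZYGOUS)
        causal.append(calls["proband"][-1])
    elif mode == "XL":
        _add("proband", *v1, HEMIZYGOUS)
        if trio:
            _add("mother", *v1, HETEROZYGOUS)
        causal.append(calls["proband"][-1])

    # annotation rows for causal variants: half known-pathogenic database hits,
    # half novel-but-predicted-deleterious (both prioritizable routes)
    ann_rows = []
    for i, v in enumerate(causal):
        known = bool(i % 2 == 0 if spec.noise_free else rng.random() < 0.5)
        ann_rows.append(
            {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "local_freq": np.nan if not known else 0.0,
                "pop_freq": np.nan if not known else 0.0,
                "known_pathogenic": known,
                "deleterious_votes": 2,
            }
        )

    # Mendelian-consistent common background variants
    if spec.background_rate > 0:
        n_pool = max(1, int(round(3 * spec.background_rate)))
        other_genes = sorted(panel.genes - {gene})
        for _ in range(n_pool):
            bg_gene = other_genes[int(rng.integers(len(other_genes)))]
            chrom, pos, ref, alt = _random_variant(rng, panel, bg_gene, used)
            f = float(rng.uniform(0.05, 0.5))
            ann_rows.append(
                {
                    "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                    "local_freq": f, "pop_freq": f,
                    "known_pathogenic": False, "deleterious_votes": 0,
                }
            )
            if trio:
                genos = {}
                for parent in ("father", "mother"):
                    u = rng.random()
                    genos[parent] = 2 if u < f * f else (1 if u < f * f + 2 * f * (1 - f) else 0)
                child = sum(
                    int(rng.random() < genos[p] / 2.0) for p in ("father", "mother")
                )
                genos["proband"] = child
                for person, n_alt in genos.items():
                    if n_alt == 0:
                        continue
                    zyg = HOMOZYGOUS if n_alt == 2 else HETEROZYGOUS
                    calls[person].append(
                        VariantCall(chrom, pos, ref, alt, gene=bg_gene, zygosity=zyg)
                    )
            else:
                u = rng.random()
                n_alt = 2 if u < f * f else (1 if u < f * f + 2 * f * (1 - f) else 0)
                if n_alt:
                    zyg = HOMOZYGOUS if n_alt == 2 else HETEROZYGOUS
                    calls["proband"].append(
                        VariantCall(chrom, pos, ref, alt, gene=bg_gene, zygosity=zyg)
                    )

    ann = pd.DataFrame(
        ann_rows,
        columns=[
            "chrom", "pos", "ref", "alt",
            "local_freq", "pop_freq", "known_pathogenic", "deleterious_votes",
        ],
    )
    return CaseSim(
        calls=calls,
        truth=CaseTruth(gene, model, mode, tuple(causal), tuple(de_novo)),
        annotations=ann,
        proband_sex=proband_sex,
    )


# ---------------------------------------------------------------------------
# Concordance and replicate-stability inputs
# ---------------------------------------------------------------------------


def simulate_concordance_pair(
    n_loci: int,
    discordance_rate: float,
    seed: int,
    n_discordant: int | None = None,
):
    """Paired NGS / array genotype tables over a shared locus set.

    ``n_discordant`` switches to deterministic mode: exactly that many loci
    get a discordant array genotype (otherwise each locus independently with
    probability ``discordance_rate``).
    """
    if n_loci <= 0:
        raise ValidationError("n_loci must be positive")
    if not 0.0 <= discordance_rate <= 1.0:
        raise ValidationError("discordance_rate must be in [0, 1]")
    rng = np.random.default_rng([int(seed), 6])
    ngs, array = {}, {}
    if n_discordant is not None:
        flip = np.zeros(n_loci, dtype=bool)
        flip[: int(n_discordant)] = True
    else:
        flip = rng.random(n_loci) < discordance_rate
    for i in range(n_loci):
        key = ("chr1", 1_000_000 + 100 * i)
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        u = rng.random()
        gt = (
            (str(ref), str(ref)) if u < 0.25
            else (str(ref), str(alt)) if u < 0.75
            else (str(alt), str(alt))
        )
        gt = tuple(sorted(gt))
        ngs[key] = gt
        if flip[i]:
            options = [
                tuple(sorted(g))
                for g in (
                    (str(ref), str(ref)), (str(ref), str(alt)), (str(alt), str(alt))
                )
            ]
            others = [g for g in options if g != gt]
            array[key] = others[int(rng.integers(len(others)))]
        else:
            array[key] = gt
    return ngs, array


def simulate_replicate_snv_sets(
    n_core: int, k: int, jitter: tuple[float, float], seed: int
) -> list[set]:
    """k replicate coding-SNV key sets sharing a core, with per-replicate
    add/drop jitter (p_add, p_drop)."""
    if k < 2:
        raise ValidationError("need at least two replicates")
    p_add, p_drop = jitter
    rng = np.random.default_rng([int(seed), 7])
    core = [("chr1", 2_000_000 + 50 * i, "A", "G") for i in range(n_core)]
    sets = []
    for rep in range(k):
        keep = rng.random(n_core) >= p_drop
        s = {core[i] for i in range(n_core) if keep[i]}
        n_add = int(rng.binomial(n_core, p_add))
        for j in range(n_add):
            s.add(("chr2", 9_000_000 + 1000 * rep + j, "C", "T"))
        sets.append(s)
    return sets
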