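"""Region-stratified trinucleotide mutational spectra.

Variants called separately in the tumour centre and periphery of each
patient are stratified into centre-only / periphery-only / shared sets;
recurrent cross-patient calls and known (dbSNP, non-clinical) variants are
removed; functional SNVs are kept; per-category sequencing strand bias is
filtered; SNVs are classified into the 96 pyrimidine-referenced
trinucleotide categories; category counts are corrected for the triplet
composition of the capture target and compared by cosine similarity.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariantRecord",
    "TripletSpectrum",
    "CATEGORIES",
    "SUBSTITUTIONS",
    "FUNCTIONAL_CLASSES",
    "read_variant_vcf",
    "stratify_regions",
    "recurrence_filter",
    "functional_filter",
    "strand_bias_filter",
    "classify_96",
    "classify_records",
    "exome_triplet_background",
    "normalize_spectrum",
    "cosine_similarity",
    "similarity_report",
    "run_pipeline",
]

BASES = "ACGT"
COMPLEMENT = str.maketrans("ACGT", "TGCA")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
#: canonical 96-category labels, substitution-major then 5'/3' context (ACGT order)
CATEGORIES = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)
_CATEGORY_INDEX = {lab: i for i, lab in enumerate(CATEGORIES)}

FUNCTIONAL_CLASSES = frozenset({"nonsynonymous", "splice_site", "stopgain", "stoploss"})


def _revcomp(s: str) -> str:
    return s.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class VariantRecord:
    """One annotated SNV or indel from a region-specific call set."""

    patient: str
    region: str  # "central" | "peripheral"
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    fwd_reads: int = 0
    rev_reads: int = 0
    functional_class: str = "other"
    dbsnp_flag: bool = False
    clinical_flag: bool = False

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Variant identity: (chrom, pos, ref, alt); genotype/depth ignored."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class TripletSpectrum:
    """96-category SNV spectrum with its triplet background."""

    counts: np.ndarray  # int, length 96
    background: dict[str, float] | None = None
    normalized: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must have 96 components")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.background is not None:
            self.normalized = normalize_spectrum(self.counts, self.background)
        elif self.counts.sum() > 0:
            self.normalized = self.counts / self.counts.sum()
        else:
            self.normalized = np.zeros(96)


# --------------------------------------------------------------------------
# VCF input


def read_variant_vcf(path: str | Path, patient: str, region: str) -> list[VariantRecord]:
    """Read a region-specific VCF with FWD/REV/FCLASS/DBSNP/CLIN INFO keys."""
    from cyvcf2 import VCF

    records = []
    for v in VCF(str(path)):
        info = dict(v.INFO)
        for alt in v.ALT:
            records.append(
                VariantRecord(
                    patient=patient,
                    region=region,
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    fwd_reads=int(info.get("FWD", 0)),
                    rev_reads=int(info.get("REV", 0)),
                    functional_class=str(info.get("FCLASS", "other")),
                    dbsnp_flag=bool(info.get("DBSNP", False)),
                    clinical_flag=bool(info.get("CLIN", False)),
                )
            )
    return records


# --------------------------------------------------------------------------
# stratification and filters


def stratify_regions(
    central: list[VariantRecord], peripheral: list[VariantRecord]
) -> dict[str, list[VariantRecord]]:
    """Split one patient's calls into central-only / peripheral-only / shared.

    Variant identity is (chrom, pos, ref, alt).  Duplicate identities
    within one region's set are an input error.
    """
    out: dict[str, list[VariantRecord]] = {}
    keysets = {}
    for name, recs in (("central", central), ("peripheral", peripheral)):
        keys = [r.key for r in recs]
        if len(keys) != len(set(keys)):
            raise ValueError(f"duplicate variant records in {name} set")
        keysets[name] = set(keys)
    shared = keysets["central"] & keysets["peripheral"]
    out["central_only"] = [r for r in central if r.key not in shared]
    out["peripheral_only"] = [r for r in peripheral if r.key not in shared]
    out["shared"] = [r for r in central if r.key in shared]
    return out


def recurrence_filter(
    per_patient: dict[str, list[VariantRecord]],
    threshold: int = 6,
) -> tuple[dict[str, list[VariantRecord]], list[VariantRecord]]:
    """Remove cross-patient recurrent calls and known non-clinical variants.

    A variant present (in either region) in at least ``threshold`` of the
    patients is removed everywhere, as is any record whose dbSNP flag is
    set without a clinical-context flag.  Presence in both regions of one
    patient counts as one patient-occurrence.
    """
    if threshold > len(per_patient):
        raise ValueError("recurrence threshold exceeds patient count")
    carriers: dict[tuple, set[str]] = defaultdict(set)
    for pid, recs in per_patient.items():
        for r in recs:
            carriers[r.key].add(pid)
    recurrent = {k for k, pids in carriers.items() if len(pids) >= threshold}
    kept: dict[str, list[VariantRecord]] = {}
    removed: list[VariantRecord] = []
    for pid, recs in per_patient.items():
        keep_list = []
        for r in recs:
            if r.key in recurrent or (r.dbsnp_flag and not r.clinical_flag):
                removed.append(r)
            else:
                keep_list.append(r)
        kept[pid] = keep_list
    return kept, removed


def functional_filter(
    records: list[VariantRecord],
) -> tuple[list[VariantRecord], int]:
    """Keep functional SNVs; carry indels through with their own class labels.

    Functional SNVs are nonsynonymous, splice-site, stop-gain or stop-loss.
    Records with no class annotation are skipped; their count is returned.
    """
    kept, skipped = [], 0
    for r in records:
        if not r.functional_class or r.functional_class == "missing":
            skipped += 1
            continue
        if not r.is_snv:
            kept.append(r)  # indels tabulated separately, never in spectra
        elif r.functional_class in FUNCTIONAL_CLASSES:
            kept.append(r)
    if skipped:
        warnings.warn(f"{skipped} record(s) without functional class skipped", stacklevel=2)
    return kept, skipped


def strand_bias_filter(
    records: list[VariantRecord],
    categories: dict[tuple, str],
    alpha: float = 0.01,
) -> tuple[list[VariantRecord], list[VariantRecord], set[str]]:
    """Per-category strand-bias filter.

    For each 96-category, the pooled forward vs reverse supporting-read
    counts of its SNVs are tested against balance (two-sided binomial test);
    a category rejecting at ``alpha`` is declared biased.  Within a biased
    category, an SNV is removed iff it has fewer than two supporting reads
    on the strand opposite to the bias.  Non-SNVs and SNVs in unbiased
    categories pass through untouched.

    Returns (kept, removed, biased_category_labels).
    """
    by_cat: dict[str, list[VariantRecord]] = defaultdict(list)
    passthrough: list[VariantRecord] = []
    for r in records:
        cat = categories.get(r.key) if r.is_snv else None
        if cat is None:
            passthrough.append(r)
        else:
            by_cat[cat].append(r)
    kept, removed = list(passthrough), []
    biased: set[str] = set()
    for cat, recs in by_cat.items():
        fwd = sum(r.fwd_reads for r in recs)
        rev = sum(r.rev_reads for r in recs)
        total = fwd + rev
        is_biased = False
        if total > 0:
            p = stats.binomtest(fwd, total, 0.5).pvalue
            is_biased = p < alpha
        if not is_biased:
            kept.extend(recs)
            continue
        biased.add(cat)
        minority_is_rev = fwd >= rev
        for r in recs:
            opposite = r.rev_reads if minority_is_rev else r.fwd_reads
            (removed if opposite < 2 else kept).append(r)
    return kept, removed, biased


# --------------------------------------------------------------------------
# 96-category classification and backgrounds


def classify_96(chrom: str, pos: int, ref: str, alt: str, reference) -> str | None:
    """Trinucleotide category of one SNV, pyrimidine-referenced.

    ``reference`` is a mapping of contig name to sequence string (e.g. a
    ``pyfaidx.Fasta``).  Purine-reference substitutions are
    reverse-complemented onto the pyrimidine strand, giving the canonical
    6 substitutions × 16 flanking contexts = 96 labels like ``"A[C>T]G"``.
    Returns None (with a warning) when the context contains an ambiguous
    base.
    """
    seq = reference[chrom]
    triplet = str(seq[pos - 2 : pos + 1]).upper()
    if len(triplet) < 3:
        raise ValueError(f"variant at {chrom}:{pos} too close to contig end for context")
    if triplet[1] != ref.upper():
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: sequence has {triplet[1]}, record says {ref}"
        )
    alt = alt.upper()
    if any(b not in BASES for b in triplet) or alt not in BASES:
        warnings.warn(f"ambiguous base in context at {chrom}:{pos}; record excluded", stacklevel=2)
        return None
    if triplet[1] in "AG":  # collapse to pyrimidine strand
        triplet = _revcomp(triplet)
        alt = alt.translate(COMPLEMENT)
    label = f"{triplet[0]}[{triplet[1]}>{alt}]{triplet[2]}"
    assert label in _CATEGORY_INDEX
    return label


def classify_records(records: list[VariantRecord], reference) -> dict[tuple, str]:
    """Category label per SNV identity; non-SNVs and ambiguous contexts omitted."""
    out = {}
    for r in records:
        if not r.is_snv:
            continue
        lab = classify_96(r.chrom, r.pos, r.ref, r.alt, reference)
        if lab is not None:
            out[r.key] = lab
    return out


def spectrum_counts(records: list[VariantRecord], categories: dict[tuple, str]) -> np.ndarray:
    counts = np.zeros(96)
    for r in records:
        lab = categories.get(r.key)
        if lab is not None:
            counts[_CATEGORY_INDEX[lab]] += 1
    return counts


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """0-based half-open target intervals from a 3+ column BED file."""
    intervals = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        intervals.append((f[0], int(f[1]), int(f[2])))
    return intervals


def exome_triplet_background(reference, targets) -> dict[str, float]:
    """Triplet composition of the capture target, pyrimidine-collapsed.

    Counts every 3-mer whose centre base lies inside a target interval
    (0-based half-open).  A triplet and its reverse complement are pooled
    into one pyrimidine-centred class; the returned dict has all 64 keys,
    with a purine-centred key mirroring its pyrimidine-centred partner, so
    any 96-category's context divides by its background unambiguously.
    """
    if not targets:
        raise ValueError("no target intervals")
    pyr_counts: Counter[str] = Counter()
    for chrom, start, end in targets:
        seq = str(reference[chrom][:]).upper()
        if end > len(seq):
            raise ValueError(f"target {chrom}:{start}-{end} outside reference bounds")
        lo = max(start, 1)
        hi = min(end, len(seq) - 1)
        for i in range(lo, hi):
            tri = seq[i - 1 : i + 2]
            if any(b not in BASES for b in tri):
                continue
            if tri[1] in "AG":
                tri = _revcomp(tri)
            pyr_counts[tri] += 1
    if not pyr_counts:
        raise ValueError("target contains no unambiguous pyrimidine-centred triplets")
    background = {}
    for tri in ("".join(t) for t in itertools.product(BASES, repeat=3)):
        key = _revcomp(tri) if tri[1] in "AG" else tri
        background[tri] = float(pyr_counts.get(key, 0))
    return background


def _category_context(label: str) -> str:
    return label[0] + label[2] + label[6]


def normalize_spectrum(counts: np.ndarray, background: dict[str, float]) -> np.ndarray:
    """Background-corrected relative spectrum.

    Each category count is divided by the target count of its trinucleotide
    context and the result rescaled to sum to 1.  A nonzero count with a
    zero background is a hard error (the observed context cannot exist in
    the target).
    """
    counts = np.asarray(counts, dtype=float)
    rates = np.zeros(96)
    for i, lab in enumerate(CATEGORIES):
        bg = background[_category_context(lab)]
        if counts[i] > 0 and bg == 0:
            raise ValueError(f"category {lab} observed but its context is absent from targets")
        rates[i] = counts[i] / bg if bg > 0 else 0.0
    total = rates.sum()
    return rates / total if total > 0 else rates


def cosine_similarity(u, v) -> float:
    """u·v / (‖u‖‖v‖) for non-negative spectra; in [0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if (u < 0).any() or (v < 0).any():
        raise ValueError("spectra must be non-negative")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


# --------------------------------------------------------------------------
# reporting and pipeline


@dataclass
class SimilarityReport:
    """Cosine-similarity summary of region-stratified spectra."""

    per_patient: pd.Series  # central-vs-peripheral similarity per patient
    cross_patient: pd.DataFrame  # patient × patient (pooled-strata spectra)
    merged: float  # merged central vs merged peripheral
    missing: list[str]  # patients with an empty stratum after filtering


def similarity_report(
    patient_spectra: dict[str, dict[str, TripletSpectrum]],
) -> SimilarityReport:
    """Pairwise and merged-strata cosine similarities.

    ``patient_spectra[pid]`` maps stratum name ("central"/"peripheral") to
    its spectrum.  Patients with an empty stratum are reported missing, not
    scored zero.
    """
    if not patient_spectra:
        raise ValueError("no patients")
    per_patient = {}
    pooled = {}
    missing = []
    for pid, strata in patient_spectra.items():
        c = strata.get("central")
        p = strata.get("peripheral")
        tot = np.zeros(96)
        for s in (c, p):
            if s is not None:
                tot += s.counts
        if tot.sum() > 0:
            bg = (c or p).background
            pooled[pid] = TripletSpectrum(tot, background=bg)
        if c is None or p is None or c.counts.sum() == 0 or p.counts.sum() == 0:
            missing.append(pid)
            per_patient[pid] = np.nan
        else:
            per_patient[pid] = cosine_similarity(c.normalized, p.normalized)
    pids = list(pooled)
    cross = pd.DataFrame(np.eye(len(pids)), index=pids, columns=pids)
    for i, a in enumerate(pids):
        for j in range(i + 1, len(pids)):
            b = pids[j]
            s = cosine_similarity(pooled[a].normalized, pooled[b].normalized)
            cross.iloc[i, j] = cross.iloc[j, i] = s
    merged_c = np.zeros(96)
    merged_p = np.zeros(96)
    bg = None
    for strata in patient_spectra.values():
        if "central" in strata:
            merged_c += strata["central"].counts
            bg = strata["central"].background
        if "peripheral" in strata:
            merged_p += strata["peripheral"].counts
    if merged_c.sum() == 0 or merged_p.sum() == 0:
        merged = np.nan
    else:
        merged = cosine_similarity(
            TripletSpectrum(merged_c, background=bg).normalized,
            TripletSpectrum(merged_p, background=bg).normalized,
        )
    return SimilarityReport(
        per_patient=pd.Series(per_patient),
        cross_patient=cross,
        merged=merged,
        missing=missing,
    )


@dataclass
class PipelineResult:
    stratified: dict[str, dict[str, list[VariantRecord]]]
    removed_recurrent: list[VariantRecord]
    removed_strand_bias: list[VariantRecord]
    biased_categories: set[str]
    patient_spectra: dict[str, dict[str, TripletSpectrum]]
    report: SimilarityReport
    background: dict[str, float]


def run_pipeline(
    patient_vcfs: dict[str, dict[str, str | Path]],
    reference,
    targets,
    recurrence_threshold: int = 6,
    bias_alpha: float = 0.01,
) -> PipelineResult:
    """Full region-stratified spectrum pipeline for one cohort.

    ``patient_vcfs[pid]`` maps "central"/"peripheral" to a VCF path.  Order
    of operations: cohort-wide recurrence + dbSNP filter, per-patient
    region stratification, functional filter, 96-classification,
    cohort-wide per-category strand-bias filter, background-corrected
    spectra and cosine-similarity report.
    """
    raw: dict[str, list[VariantRecord]] = {}
    for pid, files in patient_vcfs.items():
        raw[pid] = read_variant_vcf(files["central"], pid, "central") + read_variant_vcf(
            files["peripheral"], pid, "peripheral"
        )
    filtered, removed_recurrent = recurrence_filter(raw, threshold=recurrence_threshold)

    stratified: dict[str, dict[str, list[VariantRecord]]] = {}
    functional: dict[str, dict[str, list[VariantRecord]]] = {}
    for pid, recs in filtered.items():
        central = [r for r in recs if r.region == "central"]
        peripheral = [r for r in recs if r.region == "peripheral"]
        strata = stratify_regions(central, peripheral)
        stratified[pid] = strata
        functional[pid] = {
            "central": functional_filter(strata["central_only"])[0],
            "peripheral": functional_filter(strata["peripheral_only"])[0],
        }

    all_functional = [r for p in functional.values() for s in p.values() for r in s]
    categories = classify_records(all_functional, reference)
    kept_all, removed_bias, biased = strand_bias_filter(
        all_functional, categories, alpha=bias_alpha
    )
    kept_keys = {(r.patient, r.region, r.key) for r in kept_all}

    background = exome_triplet_background(reference, targets)
    patient_spectra: dict[str, dict[str, TripletSpectrum]] = {}
    for pid, strata in functional.items():
        patient_spectra[pid] = {}
        for stratum, recs in strata.items():
            keep = [
                r for r in recs if r.is_snv and (r.patient, r.region, r.key) in kept_keys
            ]
            counts = spectrum_counts(keep, categories)
            patient_spectra[pid][stratum] = TripletSpectrum(counts, background=background)
    report = similarity_report(patient_spectra)
    return PipelineResult(
        stratified=stratified,
        removed_recurrent=removed_recurrent,
        removed_strand_bias=removed_bias,
        biased_categories=biased,
        patient_spectra=patient_spectra,
        report=report,
        background=background,
    )
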