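"""Synthetic region-stratified variant call sets with known ground truth.

Emulates the design of a matched centre/periphery exome study: eight
patients, each with a central and a peripheral call set sharing truncal
variants, region-private functional SNVs and indels, SNV trinucleotide
contexts drawn from a configurable 96-category signature, planted
strand-bias artifacts in designated categories, cross-patient recurrent
artifacts and dbSNP-flagged known variants.  Output is a synthetic
single-contig reference FASTA, a whole-contig target BED, minimal VCF 4.2
files per patient/region and a truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import BASES, CATEGORIES, _revcomp

__all__ = ["VariantSimConfig", "VariantSimResult", "simulate_variant_tables", "default_signature"]

CONTIG = "chrS"


def default_signature() -> np.ndarray:
    """Mildly C>T-enriched 96-category signature (weight 3 vs 1, normalized)."""
    w = np.ones(96)
    for i, lab in enumerate(CATEGORIES):
        if lab[2:5] == "C>T":
            w[i] = 3.0
    return w / w.sum()


@dataclass(frozen=True)
class VariantSimConfig:
    """Cohort design for the synthetic sequencing fixture.

    Private-variant counts default to the study scale (central-rich,
    periphery-poor).  ``strand_bias_fraction`` is the number of planted
    biased-read artifacts as a fraction of the true private SNVs;
    ``biased_categories`` designates where they are planted (low-signature
    categories by default so bias detection is well separated from signal).
    """

    n_patients: int = 8
    n_shared_per_patient: int = 4
    n_central_private: int = 8
    n_peripheral_private: int = 3
    signature: np.ndarray = field(default_factory=default_signature)
    strand_bias_fraction: float = 0.10
    recurrent_artifact_count: int = 2
    n_dbsnp: int = 2
    n_indels_private: int = 1
    synonymous_fraction: float = 0.10
    biased_categories: tuple[str, ...] = ("T[T>A]T",)
    ref_length: int = 60_000
    seed: int = 0

    def validate(self) -> None:
        sig = np.asarray(self.signature, dtype=float)
        if sig.shape != (96,) or (sig < 0).any() or abs(sig.sum() - 1.0) > 1e-8:
            raise ValueError("signature must be a 96-vector of probabilities summing to 1")
        for name in (
            "n_patients",
            "n_shared_per_patient",
            "n_central_private",
            "n_peripheral_private",
            "recurrent_artifact_count",
            "n_dbsnp",
            "n_indels_private",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.strand_bias_fraction <= 1:
            raise ValueError("strand_bias_fraction must lie in [0, 1]")
        if self.ref_length < 100:
            raise ValueError("ref_length too small to host variants")
        for lab in self.biased_categories:
            if lab not in CATEGORIES:
                raise ValueError(f"unknown category {lab!r}")


@dataclass
class VariantSimResult:
    """Paths and ground truth of one simulated cohort."""

    reference_fasta: Path
    targets_bed: Path
    patient_vcfs: dict[str, dict[str, Path]]
    truth: pd.DataFrame
    config: VariantSimConfig


def _category_parts(label: str) -> tuple[str, str, str]:
    """(pyrimidine triplet, ref, alt) of a category label like A[C>T]G."""
    tri = label[0] + label[2] + label[6]
    return tri, label[2], label[4]


class _PositionPool:
    """Allocates variant positions at least 3 bp apart (non-overlapping contexts)."""

    def __init__(self, length: int, rng: np.random.Generator, max_tries: int = 10_000):
        self.length = length
        self.rng = rng
        self.max_tries = max_tries
        self.used: set[int] = set()

    def draw(self) -> int:
        for _ in range(self.max_tries):
            pos = int(self.rng.integers(3, self.length - 2))  # 1-based, context safe
            if all(abs(pos - u) >= 3 for u in self.used):
                self.used.add(pos)
                return pos
        raise RuntimeError("position collision: could not place variant after bounded retries")


def _draw_functional_class(rng: np.random.Generator, synonymous_fraction: float) -> str:
    if rng.random() < synonymous_fraction:
        return "synonymous"
    return str(rng.choice(
        ["nonsynonymous", "splice_site", "stopgain", "stoploss"],
        p=[0.80, 0.10, 0.08, 0.02],
    ))


def simulate_variant_tables(
    cfg: VariantSimConfig, out_dir: str | Path
) -> VariantSimResult:
    """Generate the synthetic cohort and write all files under ``out_dir``.

    SNV trinucleotide contexts are planted into the random reference so that
    the aggregate expected spectrum of true SNVs equals ``cfg.signature``.
    Deterministic for a given config and seed.
    """
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    seq = rng.choice(list(BASES), size=cfg.ref_length)
    pool = _PositionPool(cfg.ref_length, rng)
    patients = [f"P{i + 1}" for i in range(cfg.n_patients)]
    sig = np.asarray(cfg.signature, dtype=float)

    rows: list[dict] = []

    def plant_snv(category: str) -> tuple[int, str, str]:
        """Plant a context for ``category`` at a fresh position; return pos/ref/alt."""
        pos = pool.draw()
        tri, ref, alt = _category_parts(category)
        if rng.random() < 0.5:  # plant on the minus strand
            tri, ref, alt = _revcomp(tri), _revcomp(ref), _revcomp(alt)
        seq[pos - 2 : pos + 1] = list(tri)
        return pos, ref, alt

    def add(
        patient: str,
        region: str,
        pos: int,
        ref: str,
        alt: str,
        category: str,
        fclass: str,
        fwd: int,
        rev: int,
        artifact: str = "",
        dbsnp: bool = False,
    ) -> None:
        rows.append(
            dict(
                patient=patient,
                region=region,
                chrom=CONTIG,
                pos=pos,
                ref=ref,
                alt=alt,
                category=category,
                functional_class=fclass,
                fwd=fwd,
                rev=rev,
                artifact=artifact,
                dbsnp=int(dbsnp),
            )
        )

    def balanced_reads() -> tuple[int, int]:
        return 2 + int(rng.poisson(6)), 2 + int(rng.poisson(6))

    n_true_private = 0
    for pid in patients:
        for _ in range(cfg.n_shared_per_patient):
            cat = CATEGORIES[int(rng.choice(96, p=sig))]
            pos, ref, alt = plant_snv(cat)
            f, r = balanced_reads()
            add(pid, "shared", pos, ref, alt, cat, "nonsynonymous", f, r)
        for region, n in (("central", cfg.n_central_private), ("peripheral", cfg.n_peripheral_private)):
            for _ in range(n):
                cat = CATEGORIES[int(rng.choice(96, p=sig))]
                pos, ref, alt = plant_snv(cat)
                f, r = balanced_reads()
                fclass = _draw_functional_class(rng, cfg.synonymous_fraction)
                add(pid, region, pos, ref, alt, cat, fclass, f, r)
                n_true_private += 1
        for _ in range(cfg.n_indels_private):
            pos = pool.draw()
            base = str(seq[pos - 1])
            if rng.random() < 0.5:
                ref, alt = base, base + str(rng.choice(list(BASES)))
            else:
                ref, alt = base + str(seq[pos]), base
            f, r = balanced_reads()
            region = str(rng.choice(["central", "peripheral"]))
            add(pid, region, pos, ref, alt, "", "frameshift", f, r)

    # strand-bias artifacts: extreme forward skew in the designated categories
    n_bias = int(round(cfg.strand_bias_fraction * n_true_private))
    for k in range(n_bias):
        cat = cfg.biased_categories[k % len(cfg.biased_categories)]
        pos, ref, alt = plant_snv(cat)
        pid = str(rng.choice(patients))
        region = str(rng.choice(["central", "peripheral"]))
        fwd = 8 + int(rng.poisson(6))
        rev = int(rng.integers(0, 2))  # < 2 reads opposite the bias
        add(pid, region, pos, ref, alt, cat, "nonsynonymous", fwd, rev, artifact="strand_bias")

    # recurrent artifacts: one identity present in >= 6 patients' central sets
    min_carriers = min(6, cfg.n_patients)
    for _ in range(cfg.recurrent_artifact_count):
        cat = CATEGORIES[int(rng.choice(96, p=sig))]
        pos, ref, alt = plant_snv(cat)
        n_carriers = int(rng.integers(min_carriers, cfg.n_patients + 1))
        carriers = rng.choice(patients, size=n_carriers, replace=False)
        for pid in carriers:
            f, r = balanced_reads()
            add(str(pid), "central", pos, ref, alt, cat, "nonsynonymous", f, r, artifact="recurrent")

    # known variants without clinical context
    for _ in range(cfg.n_dbsnp):
        cat = CATEGORIES[int(rng.choice(96, p=sig))]
        pos, ref, alt = plant_snv(cat)
        pid = str(rng.choice(patients))
        region = str(rng.choice(["central", "peripheral"]))
        f, r = balanced_reads()
        add(pid, region, pos, ref, alt, cat, "nonsynonymous", f, r, artifact="dbsnp", dbsnp=True)

    truth = pd.DataFrame(rows)

    # ---- write reference, targets, VCFs, truth table
    ref_path = out_dir / "reference.fa"
    with open(ref_path, "w") as fh:
        fh.write(f">{CONTIG}\n")
        s = "".join(seq)
        for i in range(0, len(s), 70):
            fh.write(s[i : i + 70] + "\n")
    bed_path = out_dir / "targets.bed"
    bed_path.write_text(f"{CONTIG}\t0\t{cfg.ref_length}\n")

    header = (
        "##fileformat=VCFv4.2\n"
        f"##contig=<ID={CONTIG},length={cfg.ref_length}>\n"
        '##INFO=<ID=FWD,Number=1,Type=Integer,Description="Supporting reads, forward strand">\n'
        '##INFO=<ID=REV,Number=1,Type=Integer,Description="Supporting reads, reverse strand">\n'
        '##INFO=<ID=FCLASS,Number=1,Type=String,Description="Functional class">\n'
        '##INFO=<ID=DBSNP,Number=0,Type=Flag,Description="Known variant without clinical context">\n'
        '##INFO=<ID=CLIN,Number=0,Type=Flag,Description="Known variant with clinical context">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
    )
    patient_vcfs: dict[str, dict[str, Path]] = {}
    for pid in patients:
        patient_vcfs[pid] = {}
        for region_file in ("central", "peripheral"):
            sub = truth[
                (truth.patient == pid)
                & ((truth.region == region_file) | (truth.region == "shared"))
            ].sort_values("pos")
            path = out_dir / f"{pid}_{region_file}.vcf"
            with open(path, "w") as fh:
                fh.write(header)
                for rec in sub.itertuples(index=False):
                    info = f"FWD={rec.fwd};REV={rec.rev};FCLASS={rec.functional_class}"
                    if rec.dbsnp:
                        info += ";DBSNP"
                    fh.write(
                        f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\t.\t{info}\n"
                    )
            patient_vcfs[pid][region_file] = path
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return VariantSimResult(
        reference_fasta=ref_path,
        targets_bed=bed_path,
        patient_vcfs=patient_vcfs,
        truth=truth,
        config=cfg,
    )
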