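"""Somatic mutation ingest (VCF / MAF) and per-bin counting.

Internal coordinates are 0-based half-open throughout; VCF (1-based) and
MAF Start_Position (1-based) are converted on ingest.  A mutation at
position ``p`` belongs to a bin interval ``[start, end)`` iff
``start <= p < end``; indels are assigned by their leftmost reference
base.  Mutations on chromosomes absent from the binning, or falling in
gaps, are excluded from the constitutive counts but tallied in the
per-tumor total, since real cohorts contain contigs outside RT maps.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .binning import ChromatinBinning, RTBinning, ValidationError

logger = logging.getLogger(__name__)

#: MAF Variant_Classification values used as the neoantigen-class proxy.
NEOANTIGEN_CLASSES = frozenset(
    {
        "splice_site",
        "nonsense_mutation",
        "frame_shift_del",
        "frame_shift_ins",
        "nonstop_mutation",
        "translation_start_site",
        "in_frame_ins",
        "in_frame_del",
        "missense_mutation",
        "splice_region",
    }
)


def canonical_consequence(value: str) -> str:
    """Normalize a consequence label: lower-case, spaces/dashes → underscores."""
    return value.strip().lower().replace(" ", "_").replace("-", "_")


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation in internal (0-based) coordinates."""

    chrom: str
    pos: int
    ref: str
    alt: str
    mclass: str  # "SNV" or "indel"
    consequence: str | None = None
    deleterious: str = "unknown"  # "yes" | "no" | "unknown"
    gene: str | None = None


def classify_variant(ref: str, alt: str) -> str:
    return "SNV" if len(ref) == 1 and len(alt) == 1 and ref != alt else "indel"


def _deleterious_from_maf(sift, polyphen, impact) -> str:
    """Default consensus rule over the three MAF predictor columns.

    SIFT "deleterious" OR PolyPhen "probably_damaging" OR VEP IMPACT
    "HIGH" → yes; all three missing → unknown; otherwise no.  Any
    other consensus must be applied upstream of this reader.
    """
    vals = [sift, polyphen, impact]
    if all(pd.isna(v) or str(v).strip() == "" for v in vals):
        return "unknown"
    if not pd.isna(sift) and str(sift).lower().startswith("deleterious"):
        return "yes"
    if not pd.isna(polyphen) and "probably_damaging" in str(polyphen).lower():
        return "yes"
    if not pd.isna(impact) and str(impact).strip().upper() == "HIGH":
        return "yes"
    return "no"


def _read_vcf(path: str, pass_only: bool = False) -> list[MutationRecord]:
    records: list[MutationRecord] = []
    n_skipped = 0
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            if pass_only and rec.filter.keys() not in ([], ["PASS"]):
                continue
            if rec.alts is None:
                n_skipped += 1
                continue
            for alt in rec.alts:  # multi-allelic sites expand
                if alt is None or set(alt) - set("ACGTNacgtn"):
                    n_skipped += 1
                    continue
                records.append(
                    MutationRecord(
                        chrom=rec.chrom,
                        pos=rec.start,  # pysam start is already 0-based
                        ref=rec.ref,
                        alt=alt,
                        mclass=classify_variant(rec.ref, alt),
                    )
                )
    if n_skipped:
        logger.info("%s: skipped %d unparseable/symbolic records", path, n_skipped)
    return records


_MAF_REQUIRED = ["Chromosome", "Start_Position", "Reference_Allele",
                 "Tumor_Seq_Allele2"]


def _read_maf(path: str) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, low_memory=False)
    missing = [c for c in _MAF_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: MAF missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        ref = d["Reference_Allele"]
        alt = d["Tumor_Seq_Allele2"]
        # MAF encodes pure insertions/deletions with "-"
        ref = "" if ref in ("-", None) else ref
        alt = "" if alt in ("-", None) else alt
        consequence = d.get("Variant_Classification")
        records.append(
            MutationRecord(
                chrom=str(d["Chromosome"]),
                pos=int(d["Start_Position"]) - 1,
                ref=ref,
                alt=alt,
                mclass="SNV" if len(ref) == 1 and len(alt) == 1 and ref != alt
                else "indel",
                consequence=None if pd.isna(consequence) else str(consequence),
                deleterious=_deleterious_from_maf(
                    d.get("SIFT"), d.get("PolyPhen"), d.get("IMPACT")
                ),
                gene=None if pd.isna(d.get("Hugo_Symbol")) else d.get("Hugo_Symbol"),
            )
        )
    return records


def read_mutations(
    path: str, mclass_filter: str = "both", pass_only: bool = False
) -> list[MutationRecord]:
    """Read somatic mutations from a VCF (.vcf/.vcf.gz) or MAF (.maf/.tsv) file.

    ``mclass_filter`` keeps only SNVs, only indels, or both.
    """
    if mclass_filter not in ("SNV", "indel", "both"):
        raise ValueError(f"unknown mclass_filter {mclass_filter!r}")
    lower = path.lower()
    if lower.endswith((".vcf", ".vcf.gz")):
        records = _read_vcf(path, pass_only=pass_only)
    elif lower.endswith((".maf", ".maf.txt", ".tsv")):
        records = _read_maf(path)
    else:
        raise ValidationError(f"unknown mutation file format: {path}")
    if mclass_filter != "both":
        records = [r for r in records if r.mclass == mclass_filter]
    return records


@dataclass
class TumorMutationProfile:
    """Per-tumor mutation counts and per-Mb rates over a genomic binning."""

    tumor_id: str
    counts: dict[str, int]
    bin_sizes_mb: dict[str, float]
    total_all: int
    project_id: str = ""

    @property
    def rates(self) -> dict[str, float]:
        return {b: self.counts[b] / self.bin_sizes_mb[b] for b in self.counts}

    @property
    def total_constitutive(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def labels(self) -> list[str]:
        return list(self.counts)


def _bin_lookup_arrays(binning: RTBinning | ChromatinBinning):
    """Per-chromosome sorted (starts, ends, label index) arrays."""
    label_idx = {lab: i for i, lab in enumerate(binning.labels)}
    lut = {}
    for chrom, sub in binning.intervals.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        lut[chrom] = (
            sub["start"].to_numpy(np.int64),
            sub["end"].to_numpy(np.int64),
            np.array([label_idx[b] for b in sub["bin"]], dtype=np.int64),
        )
    return lut


def count_by_bins(
    mutations: list[MutationRecord] | pd.DataFrame,
    binning: RTBinning | ChromatinBinning,
    tumor_id: str = "",
    project_id: str = "",
) -> TumorMutationProfile:
    """Count mutations per bin; positions outside all bins are excluded
    from the bin counts but included in ``total_all``."""
    if isinstance(mutations, pd.DataFrame):
        chroms = mutations["chrom"].to_numpy()
        pos = mutations["pos"].to_numpy(np.int64)
    else:
        chroms = np.array([m.chrom for m in mutations])
        pos = np.array([m.pos for m in mutations], dtype=np.int64)
    lut = _bin_lookup_arrays(binning)
    counts = np.zeros(len(binning.labels), dtype=np.int64)
    if len(pos):
        order = np.argsort(chroms, kind="stable")
        chroms, pos = chroms[order], pos[order]
        uniq, starts_at = np.unique(chroms, return_index=True)
        bounds = list(starts_at) + [len(pos)]
        for c, lo, hi in zip(uniq, bounds[:-1], bounds[1:]):
            if c not in lut:
                continue
            s, e, lab = lut[c]
            p = pos[lo:hi]
            i = np.searchsorted(s, p, side="right") - 1
            ok = (i >= 0) & (p < e[np.clip(i, 0, None)])
            counts += np.bincount(lab[i[ok]], minlength=len(counts))
    return TumorMutationProfile(
        tumor_id=tumor_id,
        counts={lab: int(c) for lab, c in zip(binning.labels, counts)},
        bin_sizes_mb=dict(binning.bin_sizes_mb),
        total_all=int(len(pos)),
        project_id=project_id,
    )


def build_cohort_profiles(
    paths: list[str],
    binning: RTBinning | ChromatinBinning,
    mclass_filter: str = "both",
    projects: dict[str, str] | None = None,
) -> list[TumorMutationProfile]:
    """One profile per tumor file, ordered by tumor id.

    The tumor id is the file stem; duplicates are an error.
    """
    if not paths:
        raise ValidationError("need at least one tumor file")
    profiles = {}
    for path in paths:
        tid = os.path.basename(path)
        for suffix in (".vcf.gz", ".vcf", ".maf.txt", ".maf", ".tsv"):
            if tid.lower().endswith(suffix):
                tid = tid[: -len(suffix)]
                break
        if tid in profiles:
            raise ValidationError(f"duplicate tumor id {tid!r}")
        muts = read_mutations(path, mclass_filter=mclass_filter)
        prof = count_by_bins(
            muts, binning, tumor_id=tid,
            project_id=(projects or {}).get(tid, ""),
        )
        excluded = prof.total_all - prof.total_constitutive
        if prof.total_all:
            logger.info("%s: %.1f%% of mutations outside binned regions",
                        tid, 100 * excluded / prof.total_all)
        profiles[tid] = prof
    return [profiles[t] for t in sorted(profiles)]


def profiles_to_frame(profiles: list[TumorMutationProfile]) -> pd.DataFrame:
    """Cohort profile table: counts, rates and totals per tumor."""
    rows = []
    for p in profiles:
        row = {"tumor_id": p.tumor_id, "project": p.project_id}
        row.update({f"count_{b}": p.counts[b] for b in p.labels})
        row.update({f"rate_{b}": p.rates[b] for b in p.labels})
        row["total_constitutive"] = p.total_constitutive
        row["total_all"] = p.total_all
        rows.append(row)
    return pd.DataFrame(rows)
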