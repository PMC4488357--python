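"""Somatic mtDNA mutation catalogue: I/O, validation, filtering, summaries.

One catalogue row is one somatic mutation in one tumor, with its allele
frequencies in tumor DNA, matched normal DNA and tumor RNA.  The canonical
on-disk form is a UTF-8 TSV with a fixed header (see :data:`COLUMNS`); a
small import shim accepts VCF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "MutationRecord",
    "Catalogue",
    "read_catalogue",
    "write_catalogue",
    "read_vcf",
    "filter_rna_confirmed",
    "summarize_by_cancer",
    "tumors_with_mutation",
    "trim_alleles",
    "COLUMNS",
]

COLUMNS = (
    "sample_id",
    "cancer_type",
    "position",
    "ref",
    "alt",
    "vaf_dna",
    "vaf_normal",
    "vaf_rna",
    "rna_confirmed",
)


def trim_alleles(position: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Canonicalise padded allele strings (shared prefix/suffix bases).

    An SNV written as ``CA>TA`` or ``AC>AT`` trims to the plain
    single-base change with its position adjusted accordingly.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        position += 1
    return position, ref, alt


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation in one tumor."""

    sample_id: str
    cancer_type: str
    position: int  # 1-based position on the mitochondrial reference
    ref: str
    alt: str
    vaf_dna: float
    vaf_normal: float = 0.0
    vaf_rna: float | None = None
    rna_confirmed: bool = False

    def normalized(self) -> "MutationRecord":
        """Record with padded allele strings trimmed to canonical form."""
        pos, ref, alt = trim_alleles(self.position, self.ref, self.alt)
        if (pos, ref, alt) == (self.position, self.ref, self.alt):
            return self
        return replace(self, position=pos, ref=ref, alt=alt)

    @property
    def kind(self) -> str:
        _, ref, alt = trim_alleles(self.position, self.ref, self.alt)
        if len(ref) == 1 and len(alt) == 1:
            return "SNV"
        if len(alt) > len(ref):
            return "insertion"
        return "deletion"

    @property
    def is_indel(self) -> bool:
        return self.kind != "SNV"

    @property
    def key(self) -> tuple:
        return (self.sample_id, self.position, self.ref, self.alt)

    def validate(self, genome=None) -> list[str]:
        """Invariant violations of this record (empty list when valid)."""
        problems = []
        for name in ("vaf_dna", "vaf_normal", "vaf_rna"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                problems.append(f"{name}={v} outside [0, 1]")
        if not self.ref or not self.alt:
            problems.append("empty ref/alt allele")
        elif any(c not in "ACGT" for c in self.ref + self.alt):
            problems.append(f"non-ACGT allele {self.ref}>{self.alt}")
        elif self.ref == self.alt:
            problems.append("ref equals alt")
        if genome is not None and self.kind == "SNV":
            pos, ref, _ = trim_alleles(self.position, self.ref, self.alt)
            if genome.base(pos) != ref:
                problems.append(
                    f"ref {ref} does not match reference "
                    f"{genome.base(pos)} at {pos}"
                )
        return problems


class Catalogue:
    """Ordered collection of mutation records with unique record keys."""

    def __init__(self, records: Iterable[MutationRecord], provenance: str = ""):
        self.records = list(records)
        self.provenance = provenance
        keys = [r.key for r in self.records]
        if len(set(keys)) != len(keys):
            dupes = {k for k in keys if keys.count(k) > 1}
            raise ValueError(f"duplicate records: {sorted(dupes)[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MutationRecord]:
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, Catalogue) and self.records == other.records

    def subset(self, predicate: Callable[[MutationRecord], bool], provenance: str = "") -> "Catalogue":
        return Catalogue(
            [r for r in self.records if predicate(r)],
            provenance or self.provenance,
        )

    def snvs(self) -> "Catalogue":
        return self.subset(lambda r: r.kind == "SNV")

    def indels(self) -> "Catalogue":
        return self.subset(lambda r: r.is_indel)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": r.sample_id,
                    "cancer_type": r.cancer_type,
                    "position": r.position,
                    "ref": r.ref,
                    "alt": r.alt,
                    "vaf_dna": r.vaf_dna,
                    "vaf_normal": r.vaf_normal,
                    "vaf_rna": r.vaf_rna,
                    "rna_confirmed": r.rna_confirmed,
                }
                for r in self.records
            ],
            columns=list(COLUMNS),
        )


def _parse_float(value, field: str) -> float | None:
    if value is None or value == "" or (isinstance(value, float) and math.isnan(value)):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValueError(f"unparsable {field} value {value!r}")


def read_catalogue(
    path,
    schema: Mapping[str, str] | None = None,
    genome=None,
    provenance: str | None = None,
) -> Catalogue:
    """Read a catalogue TSV, validating every row.

    ``schema`` maps canonical column names to the file's column names (for
    importing third-party exports); by default the canonical names are
    expected.  Rows violating record invariants cause a ``ValueError``
    listing every offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    colmap = {c: (schema or {}).get(c, c) for c in COLUMNS}
    required = [colmap[c] for c in ("sample_id", "position", "ref", "alt", "vaf_dna")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")

    records = []
    errors = []
    for idx, row in df.iterrows():
        try:
            vaf_rna = (
                _parse_float(row.get(colmap["vaf_rna"]), "vaf_rna")
                if colmap["vaf_rna"] in df.columns
                else None
            )
            confirmed_raw = (
                row.get(colmap["rna_confirmed"], "")
                if colmap["rna_confirmed"] in df.columns
                else ""
            )
            rec = MutationRecord(
                sample_id=str(row[colmap["sample_id"]]),
                cancer_type=str(row.get(colmap["cancer_type"], "NA") or "NA"),
                position=int(row[colmap["position"]]),
                ref=str(row[colmap["ref"]]).upper(),
                alt=str(row[colmap["alt"]]).upper(),
                vaf_dna=_parse_float(row[colmap["vaf_dna"]], "vaf_dna"),
                vaf_normal=_parse_float(row.get(colmap["vaf_normal"], 0.0), "vaf_normal") or 0.0,
                vaf_rna=vaf_rna,
                rna_confirmed=str(confirmed_raw).strip().lower() in ("1", "true", "yes"),
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"row {idx}: {exc}")
            continue
        problems = rec.validate(genome=genome)
        if problems:
            errors.append(f"row {idx}: " + "; ".join(problems))
        else:
            records.append(rec)
    if errors:
        raise ValueError("invalid catalogue rows:\n" + "\n".join(errors))
    return Catalogue(records, provenance=provenance or str(path))


def write_catalogue(cat: Catalogue, path) -> None:
    """Write the canonical TSV form (stable formatting; round-trip safe)."""
    with open(path, "w") as fh:
        fh.write("\t".join(COLUMNS) + "\n")
        for r in cat.records:
            rna = "" if r.vaf_rna is None else f"{r.vaf_rna:.6g}"
            fh.write(
                f"{r.sample_id}\t{r.cancer_type}\t{r.position}\t{r.ref}\t{r.alt}\t"
                f"{r.vaf_dna:.6g}\t{r.vaf_normal:.6g}\t{rna}\t"
                f"{'true' if r.rna_confirmed else 'false'}\n"
            )


def read_vcf(path, sample_id: str = "unknown", cancer_type: str = "NA") -> Catalogue:
    """Import shim for VCF files with chrM records on reference coordinates.

    Allele frequencies are taken from INFO fields ``VAF`` (tumor DNA),
    ``VAFN`` (normal) and ``VAFR`` (RNA) when present.
    """
    import pysam

    records = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            if rec.chrom not in ("chrM", "MT", "chrMT", "M"):
                continue
            info = rec.info
            vaf_rna = info.get("VAFR")
            for alt in rec.alts or ():
                records.append(
                    MutationRecord(
                        sample_id=sample_id,
                        cancer_type=cancer_type,
                        position=rec.pos,
                        ref=rec.ref.upper(),
                        alt=alt.upper(),
                        vaf_dna=float(info.get("VAF", 0.0)),
                        vaf_normal=float(info.get("VAFN", 0.0)),
                        vaf_rna=None if vaf_rna is None else float(vaf_rna),
                        rna_confirmed=vaf_rna is not None,
                    )
                )
    return Catalogue(records, provenance=str(path))


def filter_rna_confirmed(cat: Catalogue, min_rna_vaf: float = 0.02) -> Catalogue:
    """Retain records with RNA support (vaf_rna >= threshold, or flag)."""

    def keep(r: MutationRecord) -> bool:
        if r.vaf_rna is not None:
            return r.vaf_rna >= min_rna_vaf
        return r.rna_confirmed

    filtered = cat.subset(keep, provenance=f"{cat.provenance} [rna-confirmed]")
    return Catalogue(
        [replace(r, rna_confirmed=True) for r in filtered.records],
        provenance=filtered.provenance,
    )


def summarize_by_cancer(cat: Catalogue, tumors_per_type: Mapping[str, int]) -> pd.DataFrame:
    """Per-cancer-type mutation burden summary plus an all-types TOTAL row.

    Columns: cancer_type, tumors, mutations, mutations_per_tumor (2 dp),
    indels, pct_indels (1 dp).
    """
    unknown = {r.cancer_type for r in cat} - set(tumors_per_type)
    if unknown:
        raise ValueError(f"unknown cancer codes: {sorted(unknown)}")
    rows = []
    for code in tumors_per_type:
        recs = [r for r in cat if r.cancer_type == code]
        n = len(recs)
        n_indel = sum(r.is_indel for r in recs)
        rows.append(
            {
                "cancer_type": code,
                "tumors": tumors_per_type[code],
                "mutations": n,
                "mutations_per_tumor": round(n / tumors_per_type[code], 2),
                "indels": n_indel,
                "pct_indels": round(100.0 * n_indel / n, 1) if n else 0.0,
            }
        )
    total_tumors = sum(tumors_per_type.values())
    n = len(cat)
    n_indel = sum(r.is_indel for r in cat)
    rows.append(
        {
            "cancer_type": "TOTAL",
            "tumors": total_tumors,
            "mutations": n,
            "mutations_per_tumor": round(n / total_tumors, 2) if total_tumors else 0.0,
            "indels": n_indel,
            "pct_indels": round(100.0 * n_indel / n, 1) if n else 0.0,
        }
    )
    return pd.DataFrame(rows)


def tumors_with_mutation(cat: Catalogue) -> int:
    """Number of distinct tumors carrying at least one mutation."""
    return len({r.sample_id for r in cat})
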