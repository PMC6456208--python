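"""Readers and writers for the formats the pipeline touches.

Variant input is VCF 4.x with a per-sample ``AD`` FORMAT field (the output
of samtools/bcftools-style calling), or an equivalent flat TSV. Coordinates
are 1-based in VCF and in every user-facing table; slicing into sequences is
0-based half-open internally.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

from .genotyping import AlleleDepth

log = logging.getLogger("spinsex")
if not log.handlers:  # stderr stage logging, auditable filter attrition
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)

_NUCS = set("ACGT")


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    MONOECIOUS = "monoecious"


class Role(str, Enum):
    PROGENY = "progeny"
    PARENT = "parent"
    UNRELATED = "unrelated"


@dataclass(frozen=True)
class Sample:
    sample_id: str
    sex: Sex
    role: Role = Role.PROGENY
    group: str = ""


@dataclass
class SampleSheet:
    """Sample metadata: one row per sequenced individual."""

    samples: list[Sample]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")

    def __iter__(self):
        return iter(self.samples)

    @property
    def ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def by_sex(self, sex: Sex, role: Role | None = Role.PROGENY) -> list[str]:
        return [
            s.sample_id
            for s in self.samples
            if s.sex == sex and (role is None or s.role == role)
        ]

    @property
    def progeny_females(self) -> list[str]:
        return self.by_sex(Sex.FEMALE)

    @property
    def progeny_males(self) -> list[str]:
        return self.by_sex(Sex.MALE)

    def require_both_sexes(self) -> None:
        if not self.progeny_females or not self.progeny_males:
            raise ValueError("need at least one male and one female progeny sample")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        needed = {"sample_id", "sex"}
        if not needed <= set(df.columns):
            raise ValueError(f"sample sheet needs columns {sorted(needed)}")
        samples = [
            Sample(
                sample_id=row.sample_id,
                sex=Sex(row.sex),
                role=Role(getattr(row, "role", "") or "progeny"),
                group=getattr(row, "group", "") or "",
            )
            for row in df.itertuples()
        ]
        return cls(samples)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {
                    "sample_id": s.sample_id,
                    "sex": s.sex.value,
                    "role": s.role.value,
                    "group": s.group,
                }
                for s in self.samples
            ]
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class VariantSite:
    """One SNP site: REF plus one or more ALT alleles, with per-sample depths.

    ``pos`` is 1-based on the unigene. Allele index 0 is REF; ALT alleles
    follow in file order. Multiallelic records are kept — they are what makes
    a three-allele segregation pattern detectable at all.
    """

    unigene_id: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    depths: Mapping[str, AlleleDepth] = field(hash=False)

    def __post_init__(self) -> None:
        for a in (self.ref, *self.alts):
            if not a or set(a) - _NUCS:
                raise ValueError(f"bad allele {a!r} at {self.unigene_id}:{self.pos}")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref, *self.alts)


@dataclass
class VariantTable:
    sites: list[VariantSite]
    samples: list[str]
    n_skipped_indels: int = 0

    def __iter__(self):
        return iter(self.sites)

    def __len__(self) -> int:
        return len(self.sites)


def _is_snp(ref: str, alts: Iterable[str]) -> bool:
    return len(ref) == 1 and all(len(a) == 1 and set(a) <= _NUCS for a in alts)


def read_variants(path: str | Path, samples: SampleSheet,
                  min_qual: float | None = None) -> VariantTable:
    """Read SNP records with per-sample REF/ALT depths from VCF or TSV.

    Indels and symbolic alleles are skipped (counted and logged). A record
    without depth information, or a sample column absent from the sample
    sheet, is a hard error.
    """
    path = Path(path)
    if path.suffix in {".tsv", ".txt"}:
        table = _read_variants_tsv(path, samples)
    else:
        table = _read_variants_vcf(path, samples, min_qual)
    log.info(
        "read %d SNP sites (%d samples, %d indel records skipped) from %s",
        len(table), len(table.samples), table.n_skipped_indels, path.name,
    )
    return table


def _read_variants_vcf(path: Path, samples: SampleSheet,
                       min_qual: float | None) -> VariantTable:
    vcf = VCF(str(path))
    known = set(samples.ids)
    unknown = [s for s in vcf.samples if s not in known]
    if unknown:
        raise ValueError(f"VCF samples not in sample sheet: {unknown}")
    cols = list(vcf.samples)
    sites: list[VariantSite] = []
    skipped = 0
    for v in vcf:
        alts = tuple(v.ALT)
        if not alts or not _is_snp(v.REF, alts):
            skipped += 1
            continue
        if min_qual is not None and (v.QUAL is None or v.QUAL < min_qual):
            continue
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            raise ValueError(f"record {v.CHROM}:{v.POS} has no AD field")
        depths = {}
        for i, name in enumerate(cols):
            row = [int(x) for x in ad[i]]
            row = [0 if x < 0 else x for x in row]  # missing AD entries -> 0
            depths[name] = AlleleDepth(row[0], tuple(row[1 : 1 + len(alts)]))
        sites.append(VariantSite(v.CHROM, v.POS, v.REF, alts, depths))
    return VariantTable(sites, cols, skipped)


def _read_variants_tsv(path: Path, samples: SampleSheet) -> VariantTable:
    """TSV dialect: unigene, pos, ref, alt (comma-joined), then
    <sample>_refdepth and <sample>_altdepth (comma-joined per ALT)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    base = {"unigene", "pos", "ref", "alt"}
    if not base <= set(df.columns):
        raise ValueError(f"variant TSV needs columns {sorted(base)}")
    cols = [c[: -len("_refdepth")] for c in df.columns if c.endswith("_refdepth")]
    known = set(samples.ids)
    unknown = [s for s in cols if s not in known]
    if unknown:
        raise ValueError(f"TSV samples not in sample sheet: {unknown}")
    for s in cols:
        if f"{s}_altdepth" not in df.columns:
            raise ValueError(f"sample {s} has refdepth but no altdepth column")
    sites: list[VariantSite] = []
    skipped = 0
    for row in df.itertuples(index=False):
        alts = tuple(row.alt.split(","))
        if not _is_snp(row.ref, alts):
            skipped += 1
            continue
        depths = {}
        for s in cols:
            ref_d = int(getattr(row, f"{s}_refdepth"))
            alt_d = tuple(int(x) for x in str(getattr(row, f"{s}_altdepth")).split(","))
            if len(alt_d) != len(alts):
                raise ValueError(f"depth arity mismatch for {s} at {row.unigene}:{row.pos}")
            depths[s] = AlleleDepth(ref_d, alt_d)
        sites.append(VariantSite(row.unigene, int(row.pos), row.ref, alts, depths))
    return VariantTable(sites, cols, skipped)


def write_variants_vcf(table: VariantTable, path: str | Path,
                       contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write a minimal VCF 4.2 with the AD FORMAT field."""
    lines = ["##fileformat=VCFv4.2"]
    if contig_lengths:
        for cid, ln in contig_lengths.items():
            lines.append(f"##contig=<ID={cid},length={ln}>")
    lines.append(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Allelic depths for the ref and alt alleles">'
    )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(table.samples)
    )
    for site in sorted(table.sites, key=lambda s: (s.unigene_id, s.pos)):
        cells = [site.unigene_id, str(site.pos), ".", site.ref,
                 ",".join(site.alts), ".", "PASS", ".", "AD"]
        for s in table.samples:
            d = site.depths[s]
            cells.append(",".join(str(x) for x in (d.ref_depth, *d.alt_depths)))
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA into {id: upper-cased sequence}; duplicate IDs are errors."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_results(records: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV: deterministic column order (as given),
    stable sort by unigene then position when those columns exist."""
    df = records.copy()
    sort_cols = [c for c in ("unigene", "pos") if c in df.columns]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="stable")
    df.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
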