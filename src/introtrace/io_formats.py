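"""Readers/writers for VCF, FASTA, BED/bedGraph and KASP plate CSV.

Coordinate convention: every position inside the package is 1-based and
intervals are closed ([start, end], both inclusive), matching VCF. BED and
bedGraph output converts to 0-based half-open at the boundary and nowhere
else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from cyvcf2 import VCF

GENOTYPES = ("hom_ref", "het", "hom_alt", "missing")

#: INFO keys carried through VCF round trips; values are floats.
INFO_KEYS = ("QD", "MQ", "FS", "SOR", "MQRankSum", "ReadPosRankSum")

#: Hard-filter thresholds applied to raw SNP calls. QD, MQ, MQRankSum and
#: ReadPosRankSum are lower bounds (a record fails when its value is below
#: the threshold); FS and SOR are upper bounds (fails when above).
DEFAULT_HARD_FILTER = {
    "QD": 2.0,
    "MQ": 40.0,
    "FS": 60.0,
    "SOR": 3.0,
    "MQRankSum": -12.5,
    "ReadPosRankSum": -8.0,
}

_LOWER_BOUND_KEYS = frozenset({"QD", "MQ", "MQRankSum", "ReadPosRankSum"})
_UPPER_BOUND_KEYS = frozenset({"FS", "SOR"})


@dataclass(slots=True)
class VariantRecord:
    """One biallelic variant call for a single sample.

    ``pos`` is 1-based. ``genotype`` is one of :data:`GENOTYPES`. ``info``
    holds optional float quality annotations keyed by :data:`INFO_KEYS`.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def indel_length(self) -> int:
        """Absolute length difference between ref and alt (0 for SNPs)."""
        return abs(len(self.ref) - len(self.alt))


@dataclass
class CallSet:
    """One sample's variants against a named reference, sorted by (chrom, pos)."""

    sample_id: str
    reference_name: str
    records: list[VariantRecord]

    def __post_init__(self) -> None:
        keys = [(r.chrom, r.pos) for r in self.records]
        if keys != sorted(keys):
            warnings.warn("records were unsorted; sorting by (chrom, pos)")
            self.records = sorted(self.records, key=lambda r: (r.chrom, r.pos))
            keys = sorted(keys)
        seen: set[tuple[str, int, str]] = set()
        for r in self.records:
            k = (r.chrom, r.pos, r.alt)
            if k in seen:
                raise ValueError(f"duplicate record at {r.chrom}:{r.pos} alt={r.alt}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def snps(self) -> list[VariantRecord]:
        return [r for r in self.records if r.is_snp]

    def indels(self) -> list[VariantRecord]:
        return [r for r in self.records if not r.is_snp]


@dataclass
class GenomeIndex:
    """Ordered chromosome names and lengths (bp)."""

    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        if len(self.chrom_lengths) == 0:
            raise ValueError("empty genome index")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return list(self.chrom_lengths)

    def __getitem__(self, name: str) -> int:
        return self.chrom_lengths[name]

    def __iter__(self):
        return iter(self.chrom_lengths.items())

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GenomeIndex":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], comment="#")
        return cls(dict(zip(df["chrom"].astype(str), df["length"].astype(int))))

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self.chrom_lengths.items():
                fh.write(f"{name}\t{length}\n")


def _genotype_from_alleles(alleles: Sequence[int], alt_index: int) -> str:
    """Map a diploid allele pair to a biallelic genotype for one split alt."""
    if any(a < 0 for a in alleles):
        return "missing"
    n = sum(1 for a in alleles if a == alt_index)
    if n == 2:
        return "hom_alt"
    if n == 1:
        return "het"
    return "hom_ref"


def read_callset(path: str | Path, sample: str, reference_name: str | None = None) -> CallSet:
    """Read one sample's calls from a VCF, splitting multi-allelic records.

    Records without a usable GT become genotype ``missing``. INFO floats are
    rounded to 6 significant digits (VCF INFO floats are single precision).
    """
    vcf = VCF(str(path))
    if sample not in vcf.samples:
        raise KeyError(
            f"sample {sample!r} not in VCF; available samples: {', '.join(vcf.samples)}"
        )
    sidx = vcf.samples.index(sample)
    records: list[VariantRecord] = []
    for v in vcf:
        gt = v.genotypes[sidx]
        alleles = tuple(int(a) for a in gt[:-1]) if gt else (-1, -1)
        info = {}
        for key in INFO_KEYS:
            val = v.INFO.get(key)
            if val is not None:
                info[key] = float(f"{float(val):.6g}")
        for ai, alt in enumerate(v.ALT, start=1):
            records.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    genotype=_genotype_from_alleles(alleles, ai),
                    info=dict(info),
                )
            )
    ref_name = reference_name if reference_name is not None else "unknown"
    return CallSet(sample_id=sample, reference_name=ref_name, records=records)


_GT_STRINGS = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "missing": "./."}

_VCF_HEADER_LINES = (
    ["##fileformat=VCFv4.2"]
    + [f'##INFO=<ID={k},Number=1,Type=Float,Description="{k}">' for k in INFO_KEYS]
    + ['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
)


def write_callset(cs: CallSet, path: str | Path, genome: GenomeIndex | None = None) -> None:
    """Write a CallSet as minimal VCF 4.2 (GT format, six INFO keys)."""
    with open(path, "w") as fh:
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        if genome is not None:
            for name, length in genome:
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + cs.sample_id + "\n"
        )
        for r in cs.records:
            info = (
                ";".join(f"{k}={r.info[k]:g}" for k in INFO_KEYS if k in r.info)
                if r.info
                else "."
            )
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\t{info or '.'}\tGT\t"
                f"{_GT_STRINGS[r.genotype]}\n"
            )


def hard_filter(cs: CallSet, thresholds: Mapping[str, float] | None = None) -> CallSet:
    """Remove records whose quality annotations violate fixed thresholds.

    A record is removed iff any *present* annotation violates its threshold;
    absent annotations never fail a record. Unknown threshold keys raise.
    """
    thr = dict(DEFAULT_HARD_FILTER)
    if thresholds is not None:
        unknown = set(thresholds) - set(DEFAULT_HARD_FILTER)
        if unknown:
            raise KeyError(
                f"unknown hard-filter keys: {sorted(unknown)}; "
                f"known keys: {sorted(DEFAULT_HARD_FILTER)}"
            )
        thr.update(thresholds)

    def passes(r: VariantRecord) -> bool:
        for key, bound in thr.items():
            if key not in r.info:
                continue
            val = r.info[key]
            if key in _LOWER_BOUND_KEYS and val < bound:
                return False
            if key in _UPPER_BOUND_KEYS and val > bound:
                return False
        return True

    return CallSet(
        sample_id=cs.sample_id,
        reference_name=cs.reference_name,
        records=[r for r in cs.records if passes(r)],
    )


def to_bed_interval(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based closed interval to 0-based half-open (BED)."""
    return start - 1, end


def write_bed(
    intervals: Iterable[tuple[str, int, int, str]], path: str | Path, header: str | None = None
) -> None:
    """Write (chrom, start, end, name) 1-based closed intervals as BED."""
    with open(path, "w") as fh:
        fh.write(f"# {header}\n" if header else "# BED intervals\n")
        for chrom, start, end, name in intervals:
            b0, b1 = to_bed_interval(start, end)
            fh.write(f"{chrom}\t{b0}\t{b1}\t{name}\n")


def write_bedgraph(
    rows: Iterable[tuple[str, int, int, float]], path: str | Path, name: str = "track"
) -> None:
    """Write (chrom, start, end, value) 1-based closed rows as bedGraph."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for chrom, start, end, value in rows:
            b0, b1 = to_bed_interval(start, end)
            fh.write(f"{chrom}\t{b0}\t{b1}\t{value:g}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Parse a bedGraph back to 1-based closed (chrom, start, end, value)."""
    with open(path) as fh:
        first = fh.readline()
    skip = 1 if first.startswith(("track", "#")) else 0
    df = pd.read_csv(
        path,
        sep="\t",
        skiprows=skip,
        header=None,
        names=["chrom", "start0", "end", "value"],
    )
    df["start"] = df["start0"].astype(int) + 1
    return df[["chrom", "start", "end", "value"]]


def read_plate_csv(path: str | Path):
    """Read a KASP plate export (columns well,sample,marker,FAM,HEX,ROX)."""
    from .kasp_genotyping import FluorescencePlate, Well

    df = pd.read_csv(path)
    required = {"well", "sample", "marker", "FAM", "HEX", "ROX"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns: {sorted(missing)}")
    markers = df["marker"].unique()
    if len(markers) != 1:
        raise ValueError(f"plate CSV must contain a single marker, found {list(markers)}")
    wells = [
        Well(str(r.well), str(r.sample), float(r.FAM), float(r.HEX), float(r.ROX))
        for r in df.itertuples()
    ]
    return FluorescencePlate(marker_id=str(markers[0]), wells=wells)


def write_plate_csv(plate, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("well,sample,marker,FAM,HEX,ROX\n")
        for w in plate.wells:
            fh.write(f"{w.well_id},{w.sample_id},{plate.marker_id},{w.fam:g},{w.hex:g},{w.rox:g}\n")
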