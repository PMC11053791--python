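"""Parental-origin classification of an improved line's SNPs.

Given call sets for an improved line and its two parents — the donor that
contributed a trait locus and the receptor (recurrent) parent that provides
the background — every SNP site of the improved line is assigned one of four
mutually exclusive categories:

* ``heterozygous`` — the improved line is het at the site;
* ``receptor``     — the receptor parent is homozygous for the same alt;
* ``donor``        — otherwise, the donor is homozygous for the same alt;
* ``unknown``      — neither parent carries the allele (third origin).

Receptor takes precedence over donor where both parents share the alt
allele: such sites are uninformative for introgression and belong to the
shared background. Sites absent from a parent's call set are treated as
homozygous reference in that parent (strict mode drops them instead). Sites
where the improved line is hom-ref or missing are excluded from the table.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .io_formats import CallSet

CATEGORIES = ("donor", "receptor", "heterozygous", "unknown")


def percent_2dp(count: int, total: int) -> float:
    """count/total as a percentage, half-up rounded to 2 decimals."""
    if total == 0:
        raise ZeroDivisionError("total is zero")
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(Decimal("0.01"), ROUND_HALF_UP)
    )


@dataclass
class TrioOriginTable:
    """Per-site origin categories plus the category count summary."""

    sites: pd.DataFrame  # columns: chrom, pos, category
    improved_sample: str
    donor_sample: str
    receptor_sample: str

    def __post_init__(self) -> None:
        bad = set(self.sites["category"].unique()) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories {bad}")
        if self.sites.duplicated(subset=["chrom", "pos"]).any():
            raise ValueError("duplicate (chrom, pos) in origin table")

    @property
    def total(self) -> int:
        return len(self.sites)

    def counts(self) -> dict[str, int]:
        vc = self.sites["category"].value_counts()
        return {c: int(vc.get(c, 0)) for c in CATEGORIES}

    def write_tsv(self, path: str | Path) -> None:
        self.sites.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(
        cls, path: str | Path, improved: str = "improved", donor: str = "donor",
        receptor: str = "receptor",
    ) -> "TrioOriginTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": int, "category": str})
        return cls(df[["chrom", "pos", "category"]], improved, donor, receptor)


def classify_trio(
    improved: CallSet,
    donor: CallSet,
    receptor: CallSet,
    strict_missing_parent: bool = False,
) -> TrioOriginTable:
    """Assign an origin category to every SNP of the improved line.

    All three call sets must share ``reference_name``. Only SNP records
    (single-base ref and alt) are classified; the improved line's hom-ref and
    missing sites are excluded. With ``strict_missing_parent`` sites where
    either parent has no record are dropped instead of assuming hom-ref.
    """
    refs = {improved.reference_name, donor.reference_name, receptor.reference_name}
    if len(refs) != 1:
        raise ValueError(f"call sets disagree on reference: {sorted(refs)}")

    def parent_lookup(cs: CallSet) -> dict[tuple[str, int], tuple[str, str]]:
        out = {}
        for r in cs.records:
            if r.is_snp:
                out[(r.chrom, r.pos)] = (r.genotype, r.alt)
        return out

    donor_gt = parent_lookup(donor)
    receptor_gt = parent_lookup(receptor)

    seen: set[tuple[str, int]] = set()
    rows = []
    for r in improved.records:
        if not r.is_snp or r.genotype in ("hom_ref", "missing"):
            continue
        key = (r.chrom, r.pos)
        if key in seen:
            raise ValueError(f"duplicate improved-line SNP at {r.chrom}:{r.pos}")
        seen.add(key)
        if strict_missing_parent and (key not in donor_gt or key not in receptor_gt):
            continue
        if r.genotype == "het":
            cat = "heterozygous"
        else:
            rec = receptor_gt.get(key, ("hom_ref", None))
            don = donor_gt.get(key, ("hom_ref", None))
            if rec[0] == "hom_alt" and rec[1] == r.alt:
                cat = "receptor"
            elif don[0] == "hom_alt" and don[1] == r.alt:
                cat = "donor"
            else:
                cat = "unknown"
        rows.append((r.chrom, r.pos, cat))

    sites = pd.DataFrame(rows, columns=["chrom", "pos", "category"])
    return TrioOriginTable(
        sites,
        improved_sample=improved.sample_id,
        donor_sample=donor.sample_id,
        receptor_sample=receptor.sample_id,
    )


def summarize_percentages(table: TrioOriginTable) -> pd.DataFrame:
    """One summary row: per-category counts and 2-decimal percentages.

    Percentages are on the printed 0-100 scale with half-up rounding.
    """
    if table.total == 0:
        raise ValueError("empty origin table")
    counts = table.counts()
    row: dict[str, object] = {"improved": table.improved_sample}
    for cat in CATEGORIES:
        row[f"n_{cat}"] = counts[cat]
        row[f"pct_{cat}"] = percent_2dp(counts[cat], table.total)
    row["total"] = table.total
    return pd.DataFrame([row])
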