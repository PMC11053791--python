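"""Synthetic trio genomes, KASP plates and amplicons with known ground truth.

The trio generator emulates a marker-assisted breeding scenario: a donor
variety contributes a trait locus into a receptor (recurrent parent)
background, yielding an improved line that matches the receptor everywhere
except inside a handful of donor-derived introgression segments. A minority
of the improved line's SNPs come from a third, unsequenced origin
("unknown"), placed in sub-clusters rather than uniformly — improved lines
bred through an intermediate cross carry clustered third-origin alleles, and
block detection must not mislabel them as donor. A small flat fraction of
sites is heterozygous (residual heterozygosity or calling error; the
generator does not distinguish the two).

All generators are pure functions of (config, seed); per-component
substreams are derived from the single seed via numpy SeedSequence spawning.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import CallSet, GenomeIndex, VariantRecord, write_callset
from .kasp_genotyping import FluorescencePlate, Well

_BASES = "ACGT"


def default_genome(n_chroms: int = 12, chrom_length: int = 2_000_000) -> GenomeIndex:
    """Miniature 12-chromosome genome (2 Mb each) for fast full-pipeline runs."""
    return GenomeIndex({f"chr{i:02d}": chrom_length for i in range(1, n_chroms + 1)})


def _ref_base_at(pos: int) -> str:
    # deterministic pseudo-random reference base, consistent across samples
    return _BASES[(pos * 2654435761) % 4]


@dataclass
class TrioSimConfig:
    """Study conditions for the trio simulator.

    Densities are expected SNPs per bp against the shared reference
    (~7e-4/bp, scaled from a few-hundred-thousand SNPs over a ~374 Mb rice
    genome). ``unknown_fraction`` and ``het_fraction`` default to the
    category shares seen in real improved lines (~7% third-origin, ~0.4%
    heterozygous). The default introgression segment covers ~30% of one
    synthetic chromosome, the scaled analogue of a 5-10 Mb block around a
    target locus on a ~36 Mb chromosome.
    """

    genome: GenomeIndex = field(default_factory=default_genome)
    donor_density: float = 7e-4
    receptor_density: float = 7e-4
    introgression_segments: list[tuple[str, int, int]] = field(
        default_factory=lambda: [("chr02", 700_001, 1_300_000)]
    )
    unknown_fraction: float = 0.07
    het_fraction: float = 0.004
    n_unknown_clusters: int = 4
    unknown_cluster_width: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        for frac, name in ((self.unknown_fraction, "unknown_fraction"),
                           (self.het_fraction, "het_fraction")):
            if not 0 <= frac <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.unknown_fraction + self.het_fraction >= 1:
            raise ValueError("unknown_fraction + het_fraction must be < 1")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.introgression_segments:
            if chrom not in self.genome.chrom_lengths:
                raise ValueError(f"segment chromosome {chrom} not in genome")
            if not (1 <= start < end <= self.genome[chrom]):
                raise ValueError(f"segment {chrom}:{start}-{end} outside bounds")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, segs in by_chrom.items():
            segs.sort()
            for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping segments on {chrom}")


@dataclass
class TrioSimResult:
    donor: CallSet
    receptor: CallSet
    improved: CallSet
    truth: pd.DataFrame  # chrom, pos, category
    segments: list[tuple[str, int, int]]

    def write(self, outdir: str | Path, genome: GenomeIndex) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for cs in (self.donor, self.receptor, self.improved):
            p = outdir / f"{cs.sample_id}.vcf"
            write_callset(cs, p, genome=genome)
            paths[cs.sample_id] = p
        truth_path = outdir / "truth_origins.tsv"
        self.truth.to_csv(truth_path, sep="\t", index=False)
        paths["truth"] = truth_path
        genome_path = outdir / "genome.tsv"
        genome.write_tsv(genome_path)
        paths["genome"] = genome_path
        seg_path = outdir / "truth_segments.tsv"
        pd.DataFrame(self.segments, columns=["chrom", "start", "end"]).to_csv(
            seg_path, sep="\t", index=False
        )
        paths["segments"] = seg_path
        return paths


def _draw_parent_sites(rng: np.random.Generator, length: int, density: float) -> np.ndarray:
    n = rng.poisson(density * length)
    n = min(n, length)
    return np.sort(rng.choice(length, size=n, replace=False) + 1)


def _alt_for(rng: np.random.Generator, ref: str, exclude: str | None = None) -> str:
    choices = [b for b in _BASES if b != ref and b != exclude]
    return choices[rng.integers(len(choices))]


def simulate_trio(cfg: TrioSimConfig) -> TrioSimResult:
    """Simulate donor, receptor and improved-line call sets plus ground truth.

    The improved line equals the receptor outside the configured segments and
    the donor inside them; ``unknown_fraction`` of its sites carry a third
    allele absent from both parents (in sub-clusters); ``het_fraction`` of
    sites are flipped heterozygous. Truth labels follow the same precedence
    as trio classification (receptor before donor on shared alleles), so they
    are exact by construction.
    """
    ss = np.random.SeedSequence(cfg.seed)
    d_rng, r_rng, u_rng, h_rng = (np.random.default_rng(c) for c in ss.spawn(4))

    donor_records: list[VariantRecord] = []
    receptor_records: list[VariantRecord] = []
    improved_base: list[tuple[str, int, str, str]] = []  # chrom,pos,ref,alt from parents
    donor_alleles: dict[tuple[str, int], str] = {}
    receptor_alleles: dict[tuple[str, int], str] = {}

    segs_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in cfg.introgression_segments:
        segs_by_chrom.setdefault(chrom, []).append((start, end))

    for chrom, length in cfg.genome:
        d_pos = _draw_parent_sites(d_rng, length, cfg.donor_density)
        r_pos = _draw_parent_sites(r_rng, length, cfg.receptor_density)
        for pos in d_pos:
            ref = _ref_base_at(pos)
            alt = _alt_for(d_rng, ref)
            donor_records.append(VariantRecord(chrom, int(pos), ref, alt, "hom_alt"))
            donor_alleles[(chrom, int(pos))] = alt
        for pos in r_pos:
            ref = _ref_base_at(pos)
            alt = _alt_for(r_rng, ref)
            receptor_records.append(VariantRecord(chrom, int(pos), ref, alt, "hom_alt"))
            receptor_alleles[(chrom, int(pos))] = alt

        segs = segs_by_chrom.get(chrom, [])

        def in_segment(pos: int) -> bool:
            return any(s <= pos <= e for s, e in segs)

        for pos in r_pos:
            if not in_segment(int(pos)):
                improved_base.append(
                    (chrom, int(pos), _ref_base_at(int(pos)), receptor_alleles[(chrom, int(pos))])
                )
        for pos in d_pos:
            if in_segment(int(pos)):
                improved_base.append(
                    (chrom, int(pos), _ref_base_at(int(pos)), donor_alleles[(chrom, int(pos))])
                )

    # third-origin sites in sub-clusters, absent from both parents
    n_base = len(improved_base)
    u = cfg.unknown_fraction
    n_unknown = int(u_rng.poisson(u / (1 - u) * n_base)) if u > 0 else 0
    taken = {(c, p) for c, p, _, _ in improved_base}
    taken |= set(donor_alleles) | set(receptor_alleles)
    unknown_sites: list[tuple[str, int, str, str]] = []
    if n_unknown > 0:
        chrom_names = cfg.genome.names
        centers = []
        for _ in range(max(1, cfg.n_unknown_clusters)):
            chrom = chrom_names[int(u_rng.integers(len(chrom_names)))]
            length = cfg.genome[chrom]
            margin = min(cfg.unknown_cluster_width // 2, length // 4)
            center = int(u_rng.integers(margin + 1, length - margin + 1))
            centers.append((chrom, center, margin))
        placed = 0
        attempts = 0
        while placed < n_unknown and attempts < 50 * n_unknown:
            attempts += 1
            chrom, center, margin = centers[int(u_rng.integers(len(centers)))]
            pos = int(u_rng.integers(center - margin, center + margin + 1))
            if (chrom, pos) in taken:
                continue
            ref = _ref_base_at(pos)
            alt = _alt_for(u_rng, ref)
            unknown_sites.append((chrom, pos, ref, alt))
            taken.add((chrom, pos))
            placed += 1

    # assemble improved line, flip a flat fraction heterozygous
    all_sites = improved_base + unknown_sites
    all_sites.sort(key=lambda t: (t[0], t[1]))
    het_mask = h_rng.random(len(all_sites)) < cfg.het_fraction
    improved_records = []
    truth_rows = []
    for (chrom, pos, ref, alt), is_het in zip(all_sites, het_mask):
        gt = "het" if is_het else "hom_alt"
        improved_records.append(VariantRecord(chrom, pos, ref, alt, gt))
        if is_het:
            cat = "heterozygous"
        elif receptor_alleles.get((chrom, pos)) == alt:
            cat = "receptor"
        elif donor_alleles.get((chrom, pos)) == alt:
            cat = "donor"
        else:
            cat = "unknown"
        truth_rows.append((chrom, pos, cat))

    ref_name = "synthetic_ref"
    return TrioSimResult(
        donor=CallSet("donor", ref_name, donor_records),
        receptor=CallSet("receptor", ref_name, receptor_records),
        improved=CallSet("improved", ref_name, improved_records),
        truth=pd.DataFrame(truth_rows, columns=["chrom", "pos", "category"]),
        segments=list(cfg.introgression_segments),
    )


def make_category_fixture(
    counts: dict[str, int],
    genome: GenomeIndex | None = None,
    seed: int = 0,
    improved_sample: str = "improved",
) -> tuple[CallSet, CallSet, CallSet]:
    """Construct a trio whose origin classification has exact category counts.

    ``counts`` maps donor/receptor/heterozygous/unknown to the desired number
    of improved-line SNP sites in that category. Sites are placed uniformly
    at random across the genome; parents are built so the trio rules produce
    each category exactly (donor sites carried hom-alt by the donor only,
    receptor sites by the receptor, heterozygous sites het in the improved
    line, unknown sites by neither parent).
    """
    genome = genome or default_genome()
    total = sum(counts.values())
    if total > genome.total_length // 2:
        raise ValueError("genome too small for the requested number of sites")
    rng = np.random.default_rng(seed)

    # allocate sites to chromosomes proportionally to length
    lengths = np.array([l for _, l in genome], dtype=float)
    alloc = np.floor(lengths / lengths.sum() * total).astype(int)
    while alloc.sum() < total:
        alloc[int(rng.integers(len(alloc)))] += 1

    positions: list[tuple[str, int]] = []
    for (chrom, length), n in zip(genome, alloc):
        pos = rng.choice(length, size=int(n), replace=False) + 1
        positions.extend((chrom, int(p)) for p in np.sort(pos))
    order = rng.permutation(len(positions))  # interleave categories along chromosomes
    positions = [positions[i] for i in order]

    categories = (
        ["donor"] * counts.get("donor", 0)
        + ["receptor"] * counts.get("receptor", 0)
        + ["heterozygous"] * counts.get("heterozygous", 0)
        + ["unknown"] * counts.get("unknown", 0)
    )
    improved, donor, receptor = [], [], []
    for (chrom, pos), cat in zip(positions, categories):
        ref = _ref_base_at(pos)
        alt = _alt_for(rng, ref)
        if cat == "heterozygous":
            improved.append(VariantRecord(chrom, pos, ref, alt, "het"))
        else:
            improved.append(VariantRecord(chrom, pos, ref, alt, "hom_alt"))
        if cat == "donor":
            donor.append(VariantRecord(chrom, pos, ref, alt, "hom_alt"))
        elif cat == "receptor":
            receptor.append(VariantRecord(chrom, pos, ref, alt, "hom_alt"))
        elif cat == "unknown":
            # a different alt in the donor keeps the site uninformative
            other = _alt_for(rng, ref, exclude=alt)
            donor.append(VariantRecord(chrom, pos, ref, other, "hom_alt"))

    ref_name = "synthetic_ref"
    key = lambda r: (r.chrom, r.pos)
    return (
        CallSet("donor", ref_name, sorted(donor, key=key)),
        CallSet("receptor", ref_name, sorted(receptor, key=key)),
        CallSet(improved_sample, ref_name, sorted(improved, key=key)),
    )


# --------------------------------------------------------------------------
# KASP plates

#: Default cluster means in normalized (FAM/ROX, HEX/ROX) coordinates.
DEFAULT_CLUSTER_MEANS = {
    "allele1_hom": (1.0, 0.15),
    "allele2_hom": (0.15, 1.0),
    "het": (0.75, 0.75),
    "ntc": (0.04, 0.04),
}


@dataclass
class PlateSimConfig:
    well_genotypes: list[str]  # allele1_hom | allele2_hom | het | ntc per well
    cluster_means: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLUSTER_MEANS)
    )
    dispersion: float = 0.03  # sd of normalized coordinates within a cluster
    ntc_dispersion: float = 0.01
    rox_mean: float = 1000.0
    rox_cv: float = 0.05
    marker_id: str = "marker"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.well_genotypes) == 0:
            raise ValueError("plate must contain at least one well")
        unknown = set(self.well_genotypes) - set(self.cluster_means)
        if unknown:
            raise ValueError(f"wells reference undefined clusters: {sorted(unknown)}")
        if self.dispersion <= 0 or self.ntc_dispersion <= 0:
            raise ValueError("dispersions must be positive")
        means = list(self.cluster_means.values())
        if len({m for m in means}) != len(means):
            raise ValueError("cluster means must be pairwise distinct")


def simulate_plate(cfg: PlateSimConfig) -> tuple[FluorescencePlate, list[str]]:
    """Simulate one KASP plate; returns (plate, per-well truth genotypes)."""
    rng = np.random.default_rng(cfg.seed)
    wells = []
    for i, geno in enumerate(cfg.well_genotypes):
        mx, my = cfg.cluster_means[geno]
        sd = cfg.ntc_dispersion if geno == "ntc" else cfg.dispersion
        x = max(0.0, rng.normal(mx, sd))
        y = max(0.0, rng.normal(my, sd))
        rox = max(1.0, rng.normal(cfg.rox_mean, cfg.rox_cv * cfg.rox_mean))
        wells.append(
            Well(f"W{i + 1:03d}", f"S{i + 1:03d}", x * rox, y * rox, rox)
        )
    return FluorescencePlate(cfg.marker_id, wells), list(cfg.well_genotypes)


def panel_plate_config(
    n_samples: int = 194,
    n_mutant: int = 18,
    n_het: int = 0,
    n_ntc: int = 2,
    marker_id: str = "S627N",
    seed: int = 0,
    **kwargs,
) -> PlateSimConfig:
    """Plate layout for a variety panel: mutant wells first, then wild type."""
    genos = (
        ["allele2_hom"] * n_mutant
        + ["het"] * n_het
        + ["allele1_hom"] * (n_samples - n_mutant - n_het)
        + ["ntc"] * n_ntc
    )
    return PlateSimConfig(well_genotypes=genos, marker_id=marker_id, seed=seed, **kwargs)


# --------------------------------------------------------------------------
# amplicons


@dataclass(slots=True)
class AmpliconPair:
    name: str
    kind: str  # indel | caps
    ref_seq: str
    donor_seq: str
    indel_start: int | None = None  # 1-based on ref_seq
    indel_len: int | None = None
    snp_pos: int | None = None  # 1-based, site-altering SNP (caps)
    site_lost_in: str | None = None  # which allele lost the enzyme site


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _scrub_motif(seq: str, motif_regex: re.Pattern, rng: np.random.Generator) -> str:
    """Destroy every motif occurrence by mutating one fixed base per match."""
    seq = list(seq)
    while True:
        m = motif_regex.search("".join(seq))
        if m is None:
            return "".join(seq)
        i = m.start()
        seq[i] = {"G": "C", "C": "G", "A": "T", "T": "A"}[seq[i]]


def simulate_amplicons(
    n: int,
    indel_sizes: list[int],
    enzyme_site: str = "GANTC",
    seed: int = 0,
    amplicon_len: int = 191,
    primer_len: int = 20,
) -> list[AmpliconPair]:
    """Generate reference/donor amplicon pairs with planted variants.

    The first ``len(indel_sizes)`` pairs carry a deletion of the given size
    in the donor allele; remaining pairs carry a single SNP that destroys one
    planted ``enzyme_site`` instance in the donor allele. Primer landing
    sites (first/last ``primer_len`` bases of the reference) are kept free of
    edits so in-silico PCR works on both alleles.
    """
    if any(s < 1 for s in indel_sizes):
        raise ValueError("indel sizes must be >= 1")
    if len(indel_sizes) > n:
        raise ValueError("more indel sizes than amplicons")
    from .marker_design import _motif_regex  # shared IUPAC handling

    motif_re = _motif_regex(enzyme_site)
    rng = np.random.default_rng(seed)
    pairs: list[AmpliconPair] = []
    for i in range(n):
        if i < len(indel_sizes):
            size = indel_sizes[i]
            if amplicon_len - 2 * primer_len - size < 10:
                raise ValueError(
                    f"indel size {size} too large for {amplicon_len} bp amplicon"
                )
            ref = _scrub_motif(_random_seq(rng, amplicon_len), motif_re, rng)
            lo = primer_len + 5
            hi = amplicon_len - primer_len - 5 - size
            start = int(rng.integers(lo, hi + 1))  # 1-based
            donor = ref[: start - 1] + ref[start - 1 + size :]
            pairs.append(
                AmpliconPair(
                    name=f"amp{i + 1:02d}_indel{size}",
                    kind="indel",
                    ref_seq=ref,
                    donor_seq=donor,
                    indel_start=start,
                    indel_len=size,
                )
            )
        else:
            base = _scrub_motif(_random_seq(rng, amplicon_len), motif_re, rng)
            lo = primer_len + 5
            hi = amplicon_len - primer_len - 5 - len(enzyme_site)
            p0 = int(rng.integers(lo, hi + 1))  # 0-based motif start
            concrete = "".join(
                _BASES[int(rng.integers(4))] if b.upper() == "N" else b.upper()
                for b in enzyme_site
            )
            ref = base[:p0] + concrete + base[p0 + len(concrete):]
            ref = _plant_only(ref, motif_re, p0, rng)
            # SNP at the final motif base destroys the site in the donor allele
            snp0 = p0 + len(concrete) - 1
            for alt in _BASES:
                if alt == ref[snp0]:
                    continue
                donor = ref[:snp0] + alt + ref[snp0 + 1:]
                if not motif_re.search(donor):
                    break
            else:  # pragma: no cover - last base of GANTC-style motifs always breaks
                raise RuntimeError("could not destroy planted site")
            pairs.append(
                AmpliconPair(
                    name=f"amp{i + 1:02d}_caps",
                    kind="caps",
                    ref_seq=ref,
                    donor_seq=donor,
                    snp_pos=snp0 + 1,
                    site_lost_in="donor",
                )
            )
    return pairs


def _plant_only(seq: str, motif_re: re.Pattern, keep0: int, rng: np.random.Generator) -> str:
    """Scrub accidental motif copies created by planting, keeping the one at keep0."""
    chars = list(seq)
    while True:
        hits = [m.start() for m in motif_re.finditer("".join(chars)) if m.start() != keep0]
        if not hits:
            return "".join(chars)
        i = hits[0]
        chars[i] = {"G": "C", "C": "G", "A": "T", "T": "A"}[chars[i]]


def write_amplicon_fasta(pairs: list[AmpliconPair], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = []
    for p in pairs:
        records.append(SeqRecord(Seq(p.ref_seq), id=f"{p.name}|ref", description=""))
        records.append(SeqRecord(Seq(p.donor_seq), id=f"{p.name}|donor", description=""))
    SeqIO.write(records, str(path), "fasta")
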