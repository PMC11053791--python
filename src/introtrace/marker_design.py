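"""Design of PCR-based markers: codominant InDel, CAPS and KASP assays.

Three marker classes are supported, all targeted at tracing a donor allele
through a breeding program:

* **InDel markers** — primer pairs flanking an insertion/deletion so the two
  alleles give gel-resolvable product lengths (codominant on agarose).
* **CAPS markers** — a SNP that creates or destroys a restriction site; the
  PCR product digests into different fragment patterns per allele.
* **KASP primer sets** — two tailed allele-specific forward primers that
  differ only at the 3'-terminal base (the SNP), plus a common reverse.

Primer selection here is deliberately simple: fixed-length exact-match
primers screened for GC content and single-site uniqueness on the provided
template. Thermodynamic QC (Tm, dimers, genome-wide specificity) is left to
external primer tools and can be layered on top.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .io_formats import CallSet, VariantRecord

# --------------------------------------------------------------------------
# restriction enzymes

#: name -> (IUPAC recognition motif, cut offset after motif position i means
#: the cut falls between motif base i-1 and i; HinfI G^ANTC has offset 1).
ENZYMES: dict[str, tuple[str, int]] = {
    "HinfI": ("GANTC", 1),
    "EcoRI": ("GAATTC", 1),
    "HindIII": ("AAGCTT", 1),
    "TaqI": ("TCGA", 1),
    "DdeI": ("CTNAG", 1),
    "MseI": ("TTAA", 1),
    "AluI": ("AGCT", 2),
}

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def _motif_regex(motif: str) -> re.Pattern:
    return re.compile("(?=(" + "".join(_IUPAC[b] for b in motif.upper()) + "))")


def _resolve_enzyme(enzyme: str | tuple[str, int]) -> tuple[str, str, int]:
    if isinstance(enzyme, tuple):
        motif, offset = enzyme
        return f"motif:{motif}", motif, offset
    if enzyme not in ENZYMES:
        raise KeyError(
            f"unknown enzyme {enzyme!r}; built-ins: {', '.join(sorted(ENZYMES))}"
        )
    motif, offset = ENZYMES[enzyme]
    return enzyme, motif, offset


def find_sites(seq: str, motif: str) -> list[int]:
    """0-based start positions of all (possibly overlapping) motif matches."""
    return [m.start() for m in _motif_regex(motif).finditer(seq.upper())]


def insilico_digest(amplicon: str, enzyme: str | tuple[str, int]) -> list[int]:
    """Fragment lengths after complete digestion of an amplicon.

    Digestion runs to completion, leftmost site first; a motif instance is
    only cut if it lies entirely within one fragment (overlapping sites
    destroyed by an earlier cut are skipped). Fragment lengths always sum to
    the amplicon length.
    """
    _, motif, offset = _resolve_enzyme(enzyme)
    seq = amplicon.upper()
    cuts: list[int] = []
    last_cut = 0
    for p in find_sites(seq, motif):
        if p < last_cut:  # site straddles a previous cut: already destroyed
            continue
        cut = p + offset
        if 0 < cut < len(seq):
            cuts.append(cut)
            last_cut = cut
    bounds = [0] + cuts + [len(seq)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


# --------------------------------------------------------------------------
# in-silico PCR


@dataclass(slots=True)
class PcrProduct:
    status: str  # ok | no_forward_site | no_reverse_site | multiple_sites | invalid_orientation
    start: int | None = None  # 1-based inclusive
    end: int | None = None
    length: int | None = None
    sequence: str | None = None

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _find_matches(template: str, primer: str, max_mismatch: int) -> list[int]:
    if max_mismatch == 0:
        out, i = [], template.find(primer)
        while i != -1:
            out.append(i)
            i = template.find(primer, i + 1)
        return out
    out = []
    n, m = len(template), len(primer)
    for i in range(n - m + 1):
        mism = 0
        for a, b in zip(template[i : i + m], primer):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            out.append(i)
    return out


def insilico_pcr(
    template: str, fwd: str, rev: str, max_mismatch: int = 0
) -> PcrProduct:
    """Predict the PCR product of a primer pair on one template.

    The product spans from the forward primer's 5' end to the 3' end of the
    reverse primer's binding site (reverse primer given 5'->3' on the
    opposite strand). Each primer must bind exactly once.
    """
    if len(fwd) < 15 or len(rev) < 15:
        raise ValueError("primers must be >= 15 bp")
    template = template.upper()
    fwd, rev = fwd.upper(), rev.upper()
    f_hits = _find_matches(template, fwd, max_mismatch)
    r_hits = _find_matches(template, str(Seq(rev).reverse_complement()), max_mismatch)
    if not f_hits:
        return PcrProduct("no_forward_site")
    if not r_hits:
        return PcrProduct("no_reverse_site")
    if len(f_hits) > 1 or len(r_hits) > 1:
        return PcrProduct("multiple_sites")
    f0, r0 = f_hits[0], r_hits[0]
    end0 = r0 + len(rev)  # 0-based exclusive
    if end0 <= f0 + len(fwd):
        return PcrProduct("invalid_orientation")
    return PcrProduct(
        "ok", start=f0 + 1, end=end0, length=end0 - f0, sequence=template[f0:end0]
    )


# --------------------------------------------------------------------------
# marker candidates


@dataclass
class MarkerCandidate:
    """A designed InDel or CAPS marker with predicted per-allele products."""

    marker_type: str  # indel | caps
    chrom: str | None
    position: int  # 1-based variant position (on the provided template)
    forward: str
    reverse: str
    product_lengths: dict[str, int]  # allele name -> PCR product length
    fragment_lengths: dict[str, list[int]] = field(default_factory=dict)  # caps only
    enzyme: str | None = None
    enzyme_motif: str | None = None

    def __post_init__(self) -> None:
        if self.marker_type not in ("indel", "caps"):
            raise ValueError(f"unknown marker type {self.marker_type}")
        if self.marker_type == "caps":
            a, b = (sorted(v) for v in self.fragment_lengths.values())
            if a == b:
                raise ValueError("CAPS alleles must yield different fragment patterns")


@dataclass
class KaspPrimerSet:
    """Two tailed allele-specific forwards + a common reverse for one SNP."""

    allele1_forward: str  # tail1 + core ending in the allele-1 base
    allele2_forward: str
    common_reverse: str
    tail1: str
    tail2: str
    chrom: str | None
    pos: int
    ref: str
    alt: str

    def untailed(self) -> tuple[str, str]:
        return (
            self.allele1_forward[len(self.tail1):],
            self.allele2_forward[len(self.tail2):],
        )

    def __post_init__(self) -> None:
        u1, u2 = self.untailed()
        if len(u1) != len(u2):
            raise ValueError("allele-specific cores differ in length")
        diffs = [i for i, (a, b) in enumerate(zip(u1, u2)) if a != b]
        if diffs != [len(u1) - 1]:
            raise ValueError(
                "allele-specific forwards must differ only at the 3'-terminal base"
            )


def gc_fraction(seq: str) -> float:
    seq = seq.upper()
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def annotate_cds_variant(cds: str, pos: int, ref_base: str, alt_base: str):
    """Codon-level annotation of a single-base substitution in a CDS.

    ``pos`` is the 1-based position within the coding sequence. Returns a
    :class:`CdsAnnotation` with codon number ceil(pos/3), ref/alt codons and
    amino acids under the standard genetic code, and the effect class.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    if not (1 <= pos <= len(cds)):
        raise ValueError(f"position {pos} outside CDS of length {len(cds)}")
    observed = cds[pos - 1]
    if observed != ref_base.upper():
        raise ValueError(f"reference mismatch at CDS {pos}: observed {observed}, "
                         f"expected {ref_base}")
    codon_number = math.ceil(pos / 3)
    pic = (pos - 1) % 3  # 0-based position in codon
    ref_codon = cds[3 * (codon_number - 1) : 3 * codon_number]
    alt_codon = ref_codon[:pic] + alt_base.upper() + ref_codon[pic + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        effect = "synonymous"
    elif alt_aa == "*":
        effect = "nonsense"
    else:
        effect = "missense"
    return CdsAnnotation(
        cds_pos=pos, codon_number=codon_number, position_in_codon=pic + 1,
        ref_codon=ref_codon, alt_codon=alt_codon, ref_aa=ref_aa, alt_aa=alt_aa,
        effect=effect,
    )


@dataclass(slots=True)
class CdsAnnotation:
    cds_pos: int
    codon_number: int
    position_in_codon: int  # 1..3
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    effect: str  # synonymous | missense | nonsense

    @property
    def protein_change(self) -> str:
        return f"{self.ref_aa}{self.codon_number}{self.alt_aa}"


def find_linked_indels(
    callset: CallSet,
    target: tuple[str, int],
    flank_bp: int,
    min_len: int = 20,
    max_len: int = 80,
) -> list[VariantRecord]:
    """InDels within +/- flank_bp of a target locus, gel-resolvable by size.

    The window is closed on both ends; results are sorted by distance to the
    target, then by position.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive")
    chrom, pos = target
    hits = [
        r
        for r in callset.records
        if r.chrom == chrom
        and not r.is_snp
        and min_len <= r.indel_length <= max_len
        and pos - flank_bp <= r.pos <= pos + flank_bp
    ]
    return sorted(hits, key=lambda r: (abs(r.pos - pos), r.pos))


def _pick_primer(seq: str, full_templates: Sequence[str], length: int,
                 gc_range: tuple[float, float]) -> str | None:
    """First window of `seq` with acceptable GC and unique in all templates."""
    for i in range(0, len(seq) - length + 1):
        cand = seq[i : i + length]
        if not (gc_range[0] <= gc_fraction(cand) <= gc_range[1]):
            continue
        if all(
            len(_find_matches(t, cand, 0))
            + len(_find_matches(t, str(Seq(cand).reverse_complement()), 0))
            == 1
            for t in full_templates
        ):
            return cand
    return None


def design_indel_marker(
    ref_template: str,
    alt_template: str,
    indel_start: int,
    indel_len: int,
    primer_len: int = 20,
    product_range: tuple[int, int] = (80, 300),
    size_diff_range: tuple[int, int] = (20, 80),
    gc_range: tuple[float, float] = (0.40, 0.60),
    chrom: str | None = None,
) -> MarkerCandidate | None:
    """Design a codominant InDel marker on a pair of allele templates.

    ``indel_start`` is the 1-based start of the deleted/inserted bases on the
    reference template; the alternate template lacks (or carries) those
    bases. Returns None when no primer pair satisfies the constraints.
    """
    if not (size_diff_range[0] <= indel_len <= size_diff_range[1]):
        return None
    templates = [ref_template.upper(), alt_template.upper()]
    up = templates[0][: indel_start - 1]
    down = templates[0][indel_start - 1 + indel_len :]
    fwd = _pick_primer(up, templates, primer_len, gc_range)
    rev_region = down
    rev = None
    if fwd is not None:
        for j in range(0, len(rev_region) - primer_len + 1):
            window = rev_region[j : j + primer_len]
            cand = str(Seq(window).reverse_complement())
            if not (gc_range[0] <= gc_fraction(cand) <= gc_range[1]):
                continue
            products = [insilico_pcr(t, fwd, cand) for t in templates]
            if all(p.ok for p in products):
                lengths = [p.length for p in products]
                if (
                    product_range[0] <= max(lengths) <= product_range[1]
                    and abs(lengths[0] - lengths[1]) == indel_len
                ):
                    rev = cand
                    break
    if fwd is None or rev is None:
        return None
    p_ref = insilico_pcr(templates[0], fwd, rev)
    p_alt = insilico_pcr(templates[1], fwd, rev)
    return MarkerCandidate(
        marker_type="indel",
        chrom=chrom,
        position=indel_start,
        forward=fwd,
        reverse=rev,
        product_lengths={"ref": p_ref.length, "alt": p_alt.length},
    )


def design_caps(
    ref_seq: str,
    alt_seq: str,
    enzymes: Mapping[str, tuple[str, int]] | None = None,
    chrom: str | None = None,
) -> MarkerCandidate | None:
    """CAPS candidate for a SNP: some enzyme cuts exactly one allele at it.

    ``ref_seq`` and ``alt_seq`` must be the same amplicon differing at one
    base. Returns the first enzyme (alphabetical) whose recognition site
    overlaps the SNP in exactly one allele, with fragment predictions for
    both alleles, or None.
    """
    ref_seq, alt_seq = ref_seq.upper(), alt_seq.upper()
    if len(ref_seq) != len(alt_seq):
        raise ValueError("CAPS alleles must be equal length (SNP only)")
    diffs = [i for i, (a, b) in enumerate(zip(ref_seq, alt_seq)) if a != b]
    if len(diffs) != 1:
        raise ValueError(f"expected exactly one differing base, found {len(diffs)}")
    snp0 = diffs[0]
    for name in sorted(enzymes or ENZYMES):
        motif, offset = (enzymes or ENZYMES)[name]
        mlen = len(motif)
        ref_over = [p for p in find_sites(ref_seq, motif) if p <= snp0 < p + mlen]
        alt_over = [p for p in find_sites(alt_seq, motif) if p <= snp0 < p + mlen]
        if (len(ref_over) > 0) != (len(alt_over) > 0):
            frag_ref = insilico_digest(ref_seq, (motif, offset))
            frag_alt = insilico_digest(alt_seq, (motif, offset))
            if sorted(frag_ref) == sorted(frag_alt):
                continue
            return MarkerCandidate(
                marker_type="caps",
                chrom=chrom,
                position=snp0 + 1,
                forward=ref_seq[:20],
                reverse=str(Seq(ref_seq[-20:]).reverse_complement()),
                product_lengths={"ref": len(ref_seq), "alt": len(alt_seq)},
                fragment_lengths={"ref": frag_ref, "alt": frag_alt},
                enzyme=name,
                enzyme_motif=motif,
            )
    return None


#: Standard KASP universal tails (FAM- and HEX-coupled in the master mix).
KASP_TAIL_FAM = "GAAGGTGACCAAGTTCATGCT"
KASP_TAIL_HEX = "GAAGGTCGGAGTCAACGGATT"


def design_kasp(
    flank_seq: str,
    pos: int,
    ref_base: str,
    alt_base: str,
    primer_len: int = 25,
    rev_len: int = 20,
    product_range: tuple[int, int] = (50, 120),
    tail1: str = KASP_TAIL_FAM,
    tail2: str = KASP_TAIL_HEX,
    chrom: str | None = None,
) -> KaspPrimerSet:
    """Design a KASP primer set for a SNP inside ``flank_seq``.

    ``pos`` is the 1-based SNP position on ``flank_seq`` (carrying the ref
    base). Both allele-specific forwards end exactly at the SNP (3' terminus
    = ref vs alt base) with tails prepended; the common reverse anneals to
    the opposite strand within ``product_range`` of the forward's 5' end.
    """
    flank_seq = flank_seq.upper()
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if not (1 <= pos <= len(flank_seq)):
        raise ValueError("SNP position outside the flank sequence")
    if flank_seq[pos - 1] != ref_base:
        raise ValueError(
            f"reference mismatch at flank position {pos}: observed {flank_seq[pos - 1]}"
        )
    if pos < primer_len + 1 or len(flank_seq) - pos < 25:
        raise ValueError(
            f"need >= {primer_len} bp upstream and >= 25 bp downstream flank"
        )
    core_ref = flank_seq[pos - primer_len : pos]
    core_alt = core_ref[:-1] + alt_base
    fwd_start0 = pos - primer_len  # 0-based
    reverse = None
    for product in range(product_range[0], product_range[1] + 1):
        end0 = fwd_start0 + product  # 0-based exclusive product end
        if end0 > len(flank_seq) or end0 - rev_len <= pos:
            continue
        window = flank_seq[end0 - rev_len : end0]
        cand = str(Seq(window).reverse_complement())
        if 0.35 <= gc_fraction(cand) <= 0.65:
            reverse = cand
            break
    if reverse is None:
        # fall back to the largest feasible product regardless of GC
        end0 = min(len(flank_seq), fwd_start0 + product_range[1])
        if end0 - rev_len <= pos:
            raise ValueError("flank too short downstream for the common reverse primer")
        reverse = str(Seq(flank_seq[end0 - rev_len : end0]).reverse_complement())
    return KaspPrimerSet(
        allele1_forward=tail1 + core_ref,
        allele2_forward=tail2 + core_alt,
        common_reverse=reverse,
        tail1=tail1,
        tail2=tail2,
        chrom=chrom,
        pos=pos,
        ref=ref_base,
        alt=alt_base,
    )
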