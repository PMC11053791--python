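"""End-to-end orchestration: simulate -> call/classify -> blocks -> design.

Stages exchange plain files (VCF/TSV/CSV/BED) so each one is independently
testable and a run can be resumed from retained intermediates. A failed
stage aborts the run with its name and cause; partial outputs are kept and a
MANIFEST file records which stages completed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .io_formats import GenomeIndex, read_callset, write_plate_csv
from .introgression import call_blocks, export_tracks, scaled_window_params, windowed_density
from .kasp_genotyping import call_genotypes, calls_to_frame, normalize_plate, summarize_panel
from .marker_design import design_caps, design_indel_marker
from .synthetic_data import (
    PlateSimConfig,
    TrioSimConfig,
    panel_plate_config,
    simulate_amplicons,
    simulate_plate,
    simulate_trio,
    write_amplicon_fasta,
)
from .trio_origin import TrioOriginTable, classify_trio, summarize_percentages

logger = logging.getLogger("introtrace")

_KNOWN_SECTIONS = {"trio", "plate", "amplicons", "blocks", "kasp"}


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    overrides: dict[str, dict] = field(default_factory=dict)
    verbosity: int = 1

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = set(self.overrides) - _KNOWN_SECTIONS
        if unknown:
            raise ValueError(
                f"unknown config sections: {sorted(unknown)}; known: {sorted(_KNOWN_SECTIONS)}"
            )
        for section, params in self.overrides.items():
            defaults = _section_defaults(section)
            bad = set(params) - set(defaults)
            if bad:
                raise ValueError(f"unknown parameters in [{section}]: {sorted(bad)}")


def _section_defaults(section: str) -> dict:
    if section == "trio":
        return {
            f: None
            for f in TrioSimConfig.__dataclass_fields__
        }
    if section == "plate":
        return {f: None for f in PlateSimConfig.__dataclass_fields__} | {
            "n_samples": None, "n_mutant": None, "n_het": None, "n_ntc": None,
            "marker_id": None,
        }
    if section == "amplicons":
        return {"n": None, "indel_sizes": None, "enzyme_site": None, "amplicon_len": None}
    if section == "blocks":
        return {
            "window": None, "step": None, "min_fraction": None,
            "min_snps": None, "min_windows": None,
        }
    if section == "kasp":
        return {"k_expected": None, "signal_threshold": None, "min_confidence": None}
    raise ValueError(section)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate -> kasp-call -> classify -> blocks -> design.

    Returns the machine-readable summary (also written as summary.json).
    Deterministic given (config, seed): the summary contains no timestamps.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    manifest_path = out / "MANIFEST"
    summary: dict = {"version": __version__, "seed": config.seed}
    t_all = time.time()

    def stage(name: str):
        logger.info("stage %s starting", name)
        manifest.append(name)

    def fail(name: str, exc: Exception):
        manifest_path.write_text(
            "\n".join(manifest[:-1]) + f"\nFAILED: {name}: {exc}\n"
        )
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    ov = config.overrides

    # ---- simulate -------------------------------------------------------
    stage("simulate")
    try:
        trio_cfg = TrioSimConfig(seed=config.seed, **ov.get("trio", {}))
        trio = simulate_trio(trio_cfg)
        paths = trio.write(out, trio_cfg.genome)
        plate_params = dict(ov.get("plate", {}))
        plate_cfg = panel_plate_config(seed=config.seed + 1, **plate_params)
        plate, plate_truth = simulate_plate(plate_cfg)
        write_plate_csv(plate, out / "plate.csv")
        pd.DataFrame({"well": [w.well_id for w in plate.wells], "truth": plate_truth}).to_csv(
            out / "plate_truth.tsv", sep="\t", index=False
        )
        amp_params = {"n": 6, "indel_sizes": [49, 24, 41, 49, 46]} | ov.get("amplicons", {})
        amplicons = simulate_amplicons(seed=config.seed + 2, **amp_params)
        write_amplicon_fasta(amplicons, out / "amplicons.fasta")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail("simulate", exc)

    # ---- kasp-call ------------------------------------------------------
    stage("kasp-call")
    try:
        kasp_params = ov.get("kasp", {})
        norm = normalize_plate(
            plate, signal_threshold=kasp_params.get("signal_threshold", 0.2)
        )
        calls = call_genotypes(
            norm,
            plate.marker_id,
            k_expected=kasp_params.get("k_expected", 2),
            min_confidence=kasp_params.get("min_confidence", 0.1),
        )
        frame = calls_to_frame(calls)
        frame.to_csv(out / "kasp_calls.tsv", sep="\t", index=False)
        sample_calls = frame[frame["call"] != "no_call"]
        _, freqs = summarize_panel(sample_calls)
        freqs.to_csv(out / "kasp_frequencies.tsv", sep="\t", index=False)
        summary["kasp"] = {
            "marker": plate.marker_id,
            "carriers": int(freqs["carriers"].iloc[0]),
            "n_varieties": int(freqs["n_varieties"].iloc[0]),
            "frequency_pct": float(freqs["frequency_pct"].iloc[0]),
        }
    except Exception as exc:  # noqa: BLE001
        fail("kasp-call", exc)

    # ---- classify -------------------------------------------------------
    stage("classify")
    try:
        improved = read_callset(paths["improved"], "improved", "synthetic_ref")
        donor = read_callset(paths["donor"], "donor", "synthetic_ref")
        receptor = read_callset(paths["receptor"], "receptor", "synthetic_ref")
        table = classify_trio(improved, donor, receptor)
        table.write_tsv(out / "origins.tsv")
        summ = summarize_percentages(table)
        summ.to_csv(out / "origin_summary.tsv", sep="\t", index=False)
        summary["origins"] = json.loads(summ.iloc[0].to_json())
    except Exception as exc:  # noqa: BLE001
        fail("classify", exc)

    # ---- blocks ---------------------------------------------------------
    stage("blocks")
    try:
        genome = trio_cfg.genome
        block_params = dict(ov.get("blocks", {}))
        window = block_params.get("window")
        step = block_params.get("step")
        if window is None or step is None:
            w, s = scaled_window_params(genome)
            window = window or w
            step = step or s
        track = windowed_density(table, genome, window=window, step=step)
        blocks = call_blocks(
            track,
            min_fraction=block_params.get("min_fraction", 0.5),
            min_snps=block_params.get("min_snps", 10),
            min_windows=block_params.get("min_windows", 2),
            table=table,
        )
        export_tracks(track, blocks, out / "donor_fraction.bedgraph", out / "blocks.bed")
        summary["blocks"] = [
            {
                "chrom": b.chrom, "start": b.start, "end": b.end,
                "n_snps": b.n_snps, "mean_fraction": round(b.mean_fraction, 4),
            }
            for b in blocks
        ]
    except Exception as exc:  # noqa: BLE001
        fail("blocks", exc)

    # ---- design ---------------------------------------------------------
    stage("design")
    try:
        markers = []
        for pair in amplicons:
            if pair.kind == "indel":
                cand = design_indel_marker(
                    pair.ref_seq, pair.donor_seq, pair.indel_start, pair.indel_len
                )
            else:
                cand = design_caps(pair.ref_seq, pair.donor_seq)
            if cand is None:
                continue
            markers.append(
                {
                    "name": pair.name,
                    "type": cand.marker_type,
                    "forward": cand.forward,
                    "reverse": cand.reverse,
                    "product_ref": cand.product_lengths.get("ref"),
                    "product_alt": cand.product_lengths.get("alt"),
                    "enzyme": cand.enzyme or ".",
                    "fragments_ref": ",".join(map(str, cand.fragment_lengths.get("ref", []))) or ".",
                    "fragments_alt": ",".join(map(str, cand.fragment_lengths.get("alt", []))) or ".",
                }
            )
        pd.DataFrame(markers).to_csv(out / "markers.tsv", sep="\t", index=False)
        summary["markers"] = markers
    except Exception as exc:  # noqa: BLE001
        fail("design", exc)

    manifest.append("complete")
    manifest_path.write_text("\n".join(manifest) + "\n")
    logger.info("pipeline finished in %.1fs", time.time() - t_all)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
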