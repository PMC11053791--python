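"""Genotype calling from KASP endpoint fluorescence.

KASP (Kompetitive Allele-Specific PCR) reads a biallelic SNP from two
dye-coupled allele-specific forward primers: the FAM-tailed primer amplifies
allele 1, the HEX-tailed primer allele 2, and ROX is a passive reference dye.
Each well is reduced to the normalized coordinates x = FAM/ROX and
y = HEX/ROX; genotype clusters then separate by the angle theta = atan2(y, x)
around the origin (allele-1 homozygotes hug the x axis, allele-2 homozygotes
the y axis, heterozygotes sit on the diagonal, and no-template wells stay
near the origin).

Calling is deterministic: 1-D k-means on theta with quantile-spread
initialisation, k picked by silhouette (k = 1 when the angular spread of
signal wells is negligible), nearest-centroid assignment, and a confidence
score 1 - d_own/d_next in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

CALLS = ("allele1_hom", "allele2_hom", "het", "no_call")

#: Normalized magnitude below which a well is treated as no-template/failed.
DEFAULT_SIGNAL_THRESHOLD = 0.2
#: Calls with a lower centroid-separation confidence become no_call.
DEFAULT_MIN_CONFIDENCE = 0.1
#: Angular spread (radians) under which all signal wells form one cluster.
_SINGLE_CLUSTER_SPREAD = 0.05


class Well(NamedTuple):
    well_id: str
    sample_id: str
    fam: float
    hex: float
    rox: float


@dataclass
class FluorescencePlate:
    """Raw per-well FAM/HEX/ROX intensities for one KASP marker."""

    marker_id: str
    wells: list[Well]

    def __post_init__(self) -> None:
        for w in self.wells:
            if w.fam < 0 or w.hex < 0 or w.rox < 0:
                raise ValueError(f"negative intensity in well {w.well_id}")

    def __len__(self) -> int:
        return len(self.wells)


@dataclass(slots=True)
class GenotypeCall:
    sample_id: str
    marker_id: str
    call: str
    normalized_x: float
    normalized_y: float
    confidence: float

    def __post_init__(self) -> None:
        if self.call not in CALLS:
            raise ValueError(f"unknown call {self.call!r}")


def normalize_plate(
    plate: FluorescencePlate, signal_threshold: float = DEFAULT_SIGNAL_THRESHOLD
) -> pd.DataFrame:
    """ROX-normalize a plate to (x, y) = (FAM/ROX, HEX/ROX) per well.

    Wells with ROX == 0 or normalized magnitude sqrt(x^2+y^2) below
    ``signal_threshold`` are flagged ``low_signal`` (never fatal).
    """
    if len(plate) == 0:
        raise ValueError("empty plate")
    rows = []
    for w in plate.wells:
        if w.rox <= 0:
            rows.append((w.well_id, w.sample_id, np.nan, np.nan, 0.0, True))
            continue
        x = w.fam / w.rox
        y = w.hex / w.rox
        mag = float(np.hypot(x, y))
        rows.append((w.well_id, w.sample_id, x, y, mag, mag < signal_threshold))
    return pd.DataFrame(
        rows, columns=["well_id", "sample_id", "x", "y", "magnitude", "low_signal"]
    )


def _choose_k(theta: np.ndarray, k_max: int) -> int:
    if np.ptp(theta) < _SINGLE_CLUSTER_SPREAD or len(theta) < 3:
        return 1
    best_k, best_score = 1, -np.inf
    X = theta.reshape(-1, 1)
    for k in range(2, min(k_max, len(theta) - 1) + 1):
        km = _fit_kmeans(theta, k)
        labels = km.labels_
        if len(np.unique(labels)) < k:
            continue
        score = silhouette_score(X, labels)
        if score > best_score:
            best_k, best_score = k, score
    return best_k


def _fit_kmeans(theta: np.ndarray, k: int) -> KMeans:
    # seeds spread evenly over the observed angle range: deterministic, and
    # robust to unbalanced genotype classes (quantile seeding can drop two
    # seeds into one dominant cluster)
    lo, hi = float(theta.min()), float(theta.max())
    init = np.array([lo + (i + 0.5) / k * (hi - lo) for i in range(k)]).reshape(-1, 1)
    return KMeans(n_clusters=k, init=init, n_init=1, random_state=0).fit(theta.reshape(-1, 1))


def call_genotypes(
    normalized: pd.DataFrame,
    marker_id: str,
    k_expected: int = 3,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> list[GenotypeCall]:
    """Cluster signal wells on theta = atan2(y, x) and assign genotypes.

    The cluster with the smallest mean angle becomes allele1_hom (the FAM
    allele), the largest allele2_hom (HEX); with three clusters the middle is
    het. Low-signal wells and wells below ``min_confidence`` are no_call.
    Centroid ties are broken by x-coordinate (lower x = larger angle rank).
    """
    if k_expected not in (2, 3):
        raise ValueError("k_expected must be 2 or 3")
    sig = normalized[~normalized["low_signal"]]
    calls: dict[str, GenotypeCall] = {}
    for row in normalized[normalized["low_signal"]].itertuples():
        calls[row.well_id] = GenotypeCall(
            row.sample_id, marker_id, "no_call",
            float(row.x) if np.isfinite(row.x) else float("nan"),
            float(row.y) if np.isfinite(row.y) else float("nan"),
            0.0,
        )
    if len(sig) < k_expected:
        warnings.warn(
            f"only {len(sig)} signal wells for k_expected={k_expected}; all no_call"
        )
        for row in sig.itertuples():
            calls[row.well_id] = GenotypeCall(
                row.sample_id, marker_id, "no_call", row.x, row.y, 0.0
            )
        return [calls[w] for w in normalized["well_id"]]

    theta = np.arctan2(sig["y"].to_numpy(), sig["x"].to_numpy())
    k = _choose_k(theta, k_expected)
    if k == 1:
        centroids = np.array([theta.mean()])
        labels = np.zeros(len(theta), dtype=int)
    else:
        km = _fit_kmeans(theta, k)
        centroids = km.cluster_centers_.ravel()
        labels = km.labels_

    # order clusters by angle; tie-break on mean x of members
    mean_x = np.array(
        [sig["x"].to_numpy()[labels == c].mean() for c in range(len(centroids))]
    )
    order = np.lexsort((-mean_x, centroids))  # ascending theta, then descending x
    rank_of = {int(c): int(r) for r, c in enumerate(order)}
    if k == 1:
        names = {0: "allele1_hom"}
    elif k == 2:
        names = {0: "allele1_hom", 1: "allele2_hom"}
    else:
        names = {0: "allele1_hom", 1: "het", 2: "allele2_hom"}

    sorted_centroids = centroids[order]
    for i, row in enumerate(sig.itertuples()):
        c = int(labels[i])
        d_own = abs(theta[i] - centroids[c])
        if k == 1:
            conf = 1.0
        else:
            others = np.delete(sorted_centroids, rank_of[c])
            d_next = np.min(np.abs(theta[i] - others))
            conf = float(np.clip(1.0 - d_own / d_next if d_next > 0 else 0.0, 0.0, 1.0))
        call = names[rank_of[c]] if conf >= min_confidence else "no_call"
        calls[row.well_id] = GenotypeCall(row.sample_id, marker_id, call, row.x, row.y, conf)
    return [calls[w] for w in normalized["well_id"]]


def calls_to_frame(calls: Sequence[GenotypeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.sample_id, c.marker_id, c.call, c.normalized_x, c.normalized_y, c.confidence)
            for c in calls
        ],
        columns=["sample_id", "marker_id", "call", "x", "y", "confidence"],
    )


def summarize_panel(
    calls: pd.DataFrame,
    mutant_call: str = "allele2_hom",
    count_het: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize per-variety haplotypes and panel frequencies across markers.

    ``calls`` must hold one or more rows per (sample, marker) with a ``call``
    column. A variety counts as a carrier of a marker's mutant haplotype when
    it is homozygous for the mutant allele (``mutant_call``); heterozygous
    calls are reported but only counted with ``count_het=True``. Conflicting
    duplicate wells for one variety collapse to no_call.

    Returns (per-variety table, per-marker frequency table); frequency is
    carriers / total varieties as a percentage rounded to 2 decimals.
    """
    markers = sorted(calls["marker_id"].unique())
    samples = sorted(calls["sample_id"].unique())
    missing = [
        (s, m)
        for s in samples
        for m in markers
        if calls[(calls["sample_id"] == s) & (calls["marker_id"] == m)].empty
    ]
    if missing:
        raise ValueError(f"missing calls for (sample, marker) pairs: {missing[:5]} ...")

    def consensus(group: pd.DataFrame) -> str:
        unique = set(group["call"])
        if len(unique) == 1:
            return unique.pop()
        warnings.warn(
            f"conflicting duplicate wells for sample {group['sample_id'].iat[0]}; no_call"
        )
        return "no_call"

    rows = []
    for s in samples:
        row = {"sample_id": s}
        carried = []
        for m in markers:
            call = consensus(calls[(calls["sample_id"] == s) & (calls["marker_id"] == m)])
            row[m] = call
            if call == mutant_call or (count_het and call == "het"):
                carried.append(m)
        row["mutant_haplotypes"] = ";".join(carried) if carried else "."
        rows.append(row)
    varieties = pd.DataFrame(rows)

    from .trio_origin import percent_2dp  # shared half-up rounding

    freq_rows = []
    for m in markers:
        carriers = int((varieties[m] == mutant_call).sum())
        if count_het:
            carriers += int((varieties[m] == "het").sum())
        freq_rows.append((m, carriers, len(samples), percent_2dp(carriers, len(samples))))
    freqs = pd.DataFrame(
        freq_rows, columns=["marker_id", "carriers", "n_varieties", "frequency_pct"]
    )
    return varieties, freqs


def plot_plate(normalized: pd.DataFrame, calls: Sequence[GenotypeCall], path) -> None:
    """Scatter plot of normalized well coordinates colored by call."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = calls_to_frame(calls)
    colors = {"allele1_hom": "tab:blue", "allele2_hom": "tab:red", "het": "tab:green",
              "no_call": "0.6"}
    fig, ax = plt.subplots(figsize=(5, 5))
    for call, grp in frame.groupby("call"):
        ax.scatter(grp["x"], grp["y"], s=18, c=colors.get(call, "k"), label=call)
    ax.set_xlabel("FAM / ROX")
    ax.set_ylabel("HEX / ROX")
    ax.legend(frameon=False)
    marker = frame["marker_id"].iat[0] if len(frame) else ""
    ax.set_title(f"KASP genotype clusters {marker}".strip())
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
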