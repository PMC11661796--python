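"""Mutual-information footprinting and hotspot calling.

For each position i of a parent's daughter library, the mutual information
between nucleotide identity b and the rounded fluorescence score f,

    I_i(b,f) = sum_{b,f} p_i(b,f) log2[ p_i(b,f) / (p_i(b) p(f)) ]
               - (n_b - 1)(n_f - 1) log2(e) / (2N),

with n_b = n_f = 4 and N the library size, marks positions where mutations
change expression. The subtracted term is the leading finite-sample bias
correction of the plug-in estimator; the O(N^-2) remainder is dropped.

The library is split into three equal pseudo-replicates; each replicate's
profile is Gaussian-smoothed (sigma = 1 position), and the cross-replicate
mean minus one standard deviation — truncated below 0.0005 bits — is the
"adjusted" profile. Hotspots are local maxima of the adjusted profile at or
above its 90th percentile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .dna import encode_many
from .motif_scan import MotifHit

MI_TRUNCATION = 0.0005  # bits
LOG2E = np.log2(np.e)


@dataclass
class MIProfile:
    parent_id: str
    channel: str
    mean_mi: np.ndarray
    std_mi: np.ndarray
    adjusted: np.ndarray
    n: int  # library size behind the profile


@dataclass(frozen=True)
class Hotspot:
    parent_id: str
    channel: str
    peak_position: int
    peak_adjusted_mi: float
    overlap_class: str = ""


def split_pseudoreplicates(n_records: int, seed) -> list[np.ndarray]:
    """Random partition of record indices into 3 subsets with sizes within 1."""
    if n_records < 3:
        raise ValueError("need at least 3 records for pseudo-replicates")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_records)
    return [np.sort(part) for part in np.array_split(perm, 3)]


def round_fluorescence(F: np.ndarray) -> np.ndarray:
    """Round-half-up to the nearest whole bin in {1,2,3,4} (1.5 -> 2)."""
    return np.clip(np.floor(np.asarray(F, dtype=float) + 0.5).astype(int), 1, 4)


def mutual_information(encoded: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Corrected per-position MI (bits) between base identity and rounded F.

    Parameters
    ----------
    encoded : (N, L) int array of daughter sequences.
    F : (N,) fluorescence scores (finite).

    The naive plug-in term uses 0*log(0) = 0; the correction can make
    near-independent positions slightly negative.
    """
    encoded = np.asarray(encoded)
    F = np.asarray(F, dtype=float)
    if encoded.ndim != 2 or encoded.shape[0] != F.shape[0]:
        raise ValueError("shape mismatch between sequences and scores")
    n = encoded.shape[0]
    if n == 0:
        raise ValueError("empty subset")
    if not np.isfinite(F).all():
        raise ValueError("non-finite fluorescence scores")
    f = round_fluorescence(F) - 1  # 0..3
    correction = 9.0 * LOG2E / (2.0 * n)
    mi = np.empty(encoded.shape[1])
    for i in range(encoded.shape[1]):
        joint = np.bincount(encoded[:, i] * 4 + f, minlength=16).reshape(4, 4) / n
        pb = joint.sum(axis=1, keepdims=True)
        pf = joint.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = joint * np.log2(joint / (pb * pf))
        mi[i] = np.nansum(terms) - correction
    return mi


def smooth_profile(mi: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Gaussian smoothing (sigma in positions, reflect boundary)."""
    return gaussian_filter1d(np.asarray(mi, dtype=float), sigma=sigma, mode="reflect")


def adjusted_mi(mean_mi: np.ndarray, std_mi: np.ndarray, floor: float = MI_TRUNCATION) -> np.ndarray:
    """mean - std, with anything below the truncation floor set to 0 bits."""
    mean_mi = np.asarray(mean_mi, dtype=float)
    std_mi = np.asarray(std_mi, dtype=float)
    if mean_mi.shape != std_mi.shape:
        raise ValueError("mean/std length mismatch")
    a = mean_mi - std_mi
    a[a < floor] = 0.0
    return a


def mi_profile(
    sequences: Sequence[str],
    F: np.ndarray,
    seed,
    parent_id: str = "",
    channel: str = "gfp",
    sigma: float = 1.0,
    smooth_each_replicate: bool = True,
) -> MIProfile:
    """Pseudo-replicated, smoothed, adjusted MI profile for one parent/channel.

    By default each replicate's raw profile is smoothed before the
    cross-replicate mean and standard deviation are taken; set
    ``smooth_each_replicate=False`` to smooth the mean/std instead.
    """
    F = np.asarray(F, dtype=float)
    keep = np.isfinite(F)
    enc = encode_many(list(sequences))[keep]
    F = F[keep]
    parts = split_pseudoreplicates(len(F), seed)
    profiles = np.stack([mutual_information(enc[idx], F[idx]) for idx in parts])
    if smooth_each_replicate:
        profiles = np.stack([smooth_profile(p, sigma) for p in profiles])
        mean = profiles.mean(axis=0)
        std = profiles.std(axis=0)
    else:
        mean = smooth_profile(profiles.mean(axis=0), sigma)
        std = smooth_profile(profiles.std(axis=0), sigma)
    return MIProfile(
        parent_id=parent_id,
        channel=channel,
        mean_mi=mean,
        std_mi=std,
        adjusted=adjusted_mi(mean, std),
        n=len(F),
    )


def find_hotspots(adjusted: np.ndarray, percentile: float = 90.0) -> list[int]:
    """Local maxima of the adjusted profile at or above its percentile.

    A position qualifies when its value reaches the (linearly interpolated)
    percentile of the whole array, zeros included, and strictly exceeds both
    neighbours; the two boundary positions can never qualify.
    """
    a = np.asarray(adjusted, dtype=float)
    if a.size < 3:
        raise ValueError("profile too short")
    thr = np.percentile(a, percentile)
    peaks = []
    for i in range(1, a.size - 1):
        if a[i] >= thr and a[i] > a[i - 1] and a[i] > a[i + 1]:
            peaks.append(i)
    return peaks


def call_hotspots(profile: MIProfile, percentile: float = 90.0) -> list[Hotspot]:
    return [
        Hotspot(
            parent_id=profile.parent_id,
            channel=profile.channel,
            peak_position=i,
            peak_adjusted_mi=float(profile.adjusted[i]),
        )
        for i in find_hotspots(profile.adjusted, percentile)
    ]


def classify_hotspot_overlap(
    peak_position: int,
    hits10: Sequence[MotifHit],
    hits35: Sequence[MotifHit],
    window: int = 3,
) -> str:
    """Which motif classes fall within +-window bp of a hotspot peak.

    A motif overlaps when its half-open interval intersects the closed
    interval [peak - window, peak + window]. Returns one of
    ``minus10_only`` / ``minus35_only`` / ``both`` / ``neither``.
    """

    def any_overlap(hits):
        lo, hi = peak_position - window, peak_position + window
        return any(h.start <= hi and h.end - 1 >= lo for h in hits)

    has10 = any_overlap(hits10)
    has35 = any_overlap(hits35)
    if has10 and has35:
        return "both"
    if has10:
        return "minus10_only"
    if has35:
        return "minus35_only"
    return "neither"


def write_profile_tsv(profile: MIProfile, path) -> None:
    pd.DataFrame(
        {
            "position": np.arange(profile.mean_mi.size),
            "mean_mi": profile.mean_mi,
            "std_mi": profile.std_mi,
            "adjusted_mi": profile.adjusted,
        }
    ).to_csv(path, sep="\t", index=False)


def write_hotspots_tsv(hotspots: Sequence[Hotspot], path) -> None:
    with open(path, "w") as fh:
        for h in hotspots:
            fh.write(
                f"{h.parent_id}\t{h.peak_position - 3}\t{h.peak_position + 4}\t"
                f"hotspot\t{h.peak_adjusted_mi:.6f}\t{h.channel}\n"
            )
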