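"""Sliding-window motif gain/loss association testing.

For every window of PWM width along a parent, daughters are partitioned by
whether their own window scores at or above the matrix threshold
("Motif (+)" vs "Motif (-)"). When both groups hold more than 10 values,
the fluorescence difference is tested with a two-sided Mann-Whitney U test;
tests with p < 0.05 lying within +-3 bp of a mutual-information hotspot are
recorded and Benjamini-Hochberg corrected. An association is called a
significant effect when its q-value passes the FDR and the median
fluorescence difference exceeds 0.5 a.u. in magnitude. The same machinery
is generic over the −10, −35, H-NS, and UP-element matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .dna import encode, encode_many
from .motif_scan import MotifHit, PWM

MIN_GROUP = 10  # groups must be strictly larger than this
HOTSPOT_PROXIMITY = 3  # bp
EFFECT_THRESHOLD = 0.5  # a.u.


@dataclass
class AssociationRecord:
    parent_id: str
    channel: str
    window_start: int
    motif_class: str
    direction: str  # "gain" | "loss"
    n_with: int
    n_without: int
    delta_F: float
    p: float
    q: float | None
    near_hotspot: bool
    significant_effect: bool | None

    @property
    def effect(self) -> float:
        """Fluorescence change in the direction of the mutational event.

        Gains report median(F_with) - median(F_without); losses report the
        change upon losing the box, i.e. the negation — a destroyed
        promoter shows a negative loss effect.
        """
        return self.delta_F if self.direction == "gain" else -self.delta_F


@dataclass(frozen=True)
class GainEvent:
    new_hit: MotifHit
    overlapped_parent_hit: MotifHit | None
    gain_type: str  # "homo" | "hetero" | "non_overlapping"


def window_partition(
    daughter_scores: np.ndarray, F: np.ndarray, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Split fluorescence scores by above/below-threshold window score."""
    daughter_scores = np.asarray(daughter_scores, dtype=float)
    F = np.asarray(F, dtype=float)
    mask = daughter_scores >= threshold
    return F[mask], F[~mask]


def mwu_association(
    F_with: np.ndarray, F_without: np.ndarray, min_n: int = MIN_GROUP
) -> tuple[float, float] | None:
    """Two-sided MWU p-value and median difference, or None (skip).

    Computed only when both groups contain strictly more than *min_n*
    values. ``delta_F = median(F_with) - median(F_without)``. Ties use the
    normal approximation with tie correction (scipy's default for tied or
    large samples).
    """
    F_with = np.asarray(F_with, dtype=float)
    F_without = np.asarray(F_without, dtype=float)
    if F_with.size <= min_n or F_without.size <= min_n:
        return None
    res = mannwhitneyu(F_with, F_without, alternative="two-sided")
    delta = float(np.median(F_with) - np.median(F_without))
    return float(res.pvalue), delta


def bh_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted values (step-up)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _near_hotspot(window_start: int, width: int, peaks: Sequence[int], proximity: int) -> bool:
    return any(
        window_start <= pk + proximity and window_start + width - 1 >= pk - proximity
        for pk in peaks
    )


def association_tests(
    parent_seq: str,
    daughter_seqs: Sequence[str] | np.ndarray,
    F: np.ndarray,
    pwm: PWM,
    threshold: float | None = None,
    min_n: int = MIN_GROUP,
):
    """Run the windowed partition + MWU at every window start.

    Yields ``(window_start, direction, n_with, n_without, p, delta_F)`` for
    every window where both groups are large enough. Exposed separately
    from :func:`scan_associations` so null behaviour (e.g. label shuffles)
    can be examined without the hotspot/alpha gating.
    """
    enc = daughter_seqs if isinstance(daughter_seqs, np.ndarray) else encode_many(list(daughter_seqs))
    F = np.asarray(F, dtype=float)
    keep = np.isfinite(F)
    enc, F = enc[keep], F[keep]
    thr = pwm.threshold if threshold is None else threshold
    scores = pwm.score_positions(enc)  # (N, n_windows)
    parent_scores = pwm.score_positions(encode(parent_seq))
    for ws in range(scores.shape[1]):
        res = mwu_association(*window_partition(scores[:, ws], F, thr), min_n=min_n)
        if res is None:
            continue
        p, delta = res
        n_with = int((scores[:, ws] >= thr).sum())
        direction = "loss" if parent_scores[ws] >= thr else "gain"
        yield ws, direction, n_with, int(len(F) - n_with), p, delta


def scan_associations(
    parent_id: str,
    parent_seq: str,
    daughter_seqs: Sequence[str] | np.ndarray,
    F: np.ndarray,
    pwm: PWM,
    hotspot_peaks: Sequence[int],
    channel: str = "gfp",
    threshold: float | None = None,
    alpha: float = 0.05,
    fdr: float = 0.05,
    effect: float = EFFECT_THRESHOLD,
    min_n: int = MIN_GROUP,
    proximity: int = HOTSPOT_PROXIMITY,
    correct: bool = True,
) -> list[AssociationRecord]:
    """Full gain/loss association scan for one parent/channel/motif class.

    Records every hotspot-proximal test with p < alpha. The direction is
    "loss" when the parent itself carries an above-threshold box in the
    window, otherwise "gain". With ``correct=True`` BH q-values and the
    significant-effect flag are assigned within this record set; pass
    ``correct=False`` and use :func:`assign_qvalues` to pool families
    across parents instead.
    """
    records = []
    for ws, direction, n_with, n_without, p, delta in association_tests(
        parent_seq, daughter_seqs, F, pwm, threshold, min_n
    ):
        if p >= alpha or not _near_hotspot(ws, pwm.width, hotspot_peaks, proximity):
            continue
        records.append(
            AssociationRecord(
                parent_id=parent_id,
                channel=channel,
                window_start=ws,
                motif_class=pwm.name,
                direction=direction,
                n_with=n_with,
                n_without=n_without,
                delta_F=delta,
                p=p,
                q=None,
                near_hotspot=True,
                significant_effect=None,
            )
        )
    if correct:
        assign_qvalues(records, fdr=fdr, effect=effect)
    return records


def assign_qvalues(
    records: Sequence[AssociationRecord],
    fdr: float = 0.05,
    effect: float = EFFECT_THRESHOLD,
) -> Sequence[AssociationRecord]:
    """BH-correct a pooled family of association records in place.

    The intended family is all recorded tests for one motif class and
    channel across parents (channels are corrected separately).
    """
    if not records:
        return records
    qs = bh_qvalues([r.p for r in records])
    for r, q in zip(records, qs):
        r.q = float(q)
        r.significant_effect = bool(q <= fdr and abs(r.delta_F) > effect)
    return records


def records_to_frame(records: Iterable[AssociationRecord]) -> pd.DataFrame:
    cols = [
        "parent_id", "channel", "motif_class", "window_start", "direction",
        "n_with", "n_without", "delta_F", "effect", "p", "q", "near_hotspot",
        "significant_effect",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)


# ---------------------------------------------------------------------------
# new-box census

def new_box_carriers(
    parent_seq: str,
    daughter_seqs: Sequence[str] | np.ndarray,
    pwm: PWM,
    threshold: float | None = None,
) -> dict[int, list[int]]:
    """Map each new-box start to the daughters that carry it.

    A "new box" is a window position scoring at or above threshold in at
    least one daughter but below threshold in the parent.
    """
    enc = daughter_seqs if isinstance(daughter_seqs, np.ndarray) else encode_many(list(daughter_seqs))
    thr = pwm.threshold if threshold is None else threshold
    parent_hits = pwm.score_positions(encode(parent_seq)) >= thr
    scores = pwm.score_positions(enc) >= thr
    out: dict[int, list[int]] = {}
    for ws in np.nonzero(scores.any(axis=0) & ~parent_hits)[0]:
        out[int(ws)] = np.nonzero(scores[:, ws])[0].tolist()
    return out


def new_box_census(
    parent_seq: str,
    daughter_seqs: Sequence[str] | np.ndarray,
    pwm: PWM,
    threshold: float | None = None,
) -> set[int]:
    """Unique start positions of boxes absent in the parent but present in
    at least one daughter."""
    return set(new_box_carriers(parent_seq, daughter_seqs, pwm, threshold))


def classify_gain(new_hit: MotifHit, parent_hits: Sequence[MotifHit]) -> list[GainEvent]:
    """Classify a new box against the parent's preexisting boxes.

    A homo-gain overlaps a parent box of the same class, a hetero-gain one
    of a different class; with overlaps of both kinds the homo event takes
    precedence but both are reported. A new box overlapping nothing is
    ``non_overlapping``.
    """
    homo = [h for h in parent_hits if new_hit.overlaps(h) and h.motif_class == new_hit.motif_class]
    hetero = [h for h in parent_hits if new_hit.overlaps(h) and h.motif_class != new_hit.motif_class]
    events = []
    for h in homo:
        events.append(GainEvent(new_hit, h, "homo"))
    for h in hetero:
        events.append(GainEvent(new_hit, h, "hetero"))
    if not events:
        events.append(GainEvent(new_hit, None, "non_overlapping"))
    return events


def census_spacing_and_tgn(
    new_minus10: Mapping[int, Sequence[int]],
    new_minus35: Mapping[int, Sequence[int]],
    parent_hits10: Sequence[MotifHit],
    parent_hits35: Sequence[MotifHit],
    daughter_seqs: Sequence[str],
    spacer_min: int = 15,
    spacer_max: int = 20,
    box_width: int = 6,
) -> dict[str, int]:
    """Summary counts over new-box censuses.

    Counts (1) new boxes with a cognate box — new or preexisting — at a
    15-20 bp spacer, and (2) new −10 boxes whose creating daughter carries
    the TG extension (TG at offsets −3..−2).
    """
    starts10 = set(new_minus10) | {h.start for h in parent_hits10}
    starts35 = set(new_minus35) | {h.start for h in parent_hits35}
    n_spaced = 0
    for s10 in new_minus10:
        if any(spacer_min <= s10 - (s35 + box_width) <= spacer_max for s35 in starts35):
            n_spaced += 1
    for s35 in new_minus35:
        if any(spacer_min <= s10 - (s35 + box_width) <= spacer_max for s10 in starts10):
            n_spaced += 1
    n_tgn = 0
    for s10, carriers in new_minus10.items():
        if s10 >= 3 and any(daughter_seqs[d][s10 - 3 : s10 - 1] == "TG" for d in carriers):
            n_tgn += 1
    return {
        "n_new_minus10": len(new_minus10),
        "n_new_minus35": len(new_minus35),
        "n_new_boxes": len(new_minus10) + len(new_minus35),
        "n_spaced": n_spaced,
        "n_tgn": n_tgn,
    }
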