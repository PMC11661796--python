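"""Parent-level promoter-emergence statistics.

P_new — the fraction of a parent's daughters whose fluorescence score
reaches the 1.5 a.u. promoter threshold — is the per-parent probability of
promoter emergence. Across parents it follows a sigmoid of the parent's own
fluorescence,

    P_new(x) = L / (1 + exp(-k (x - x0))),

whose inflection x0 sits at the promoter threshold. This module fits that
curve, regresses P_new against simple sequence features and k-mer counts,
builds scrambling null distributions for hotspot/motif overlap with
chi-squared goodness-of-fit comparisons, and flags H-NS knockout
fluorescence outliers by the 1.5*IQR rule.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .mi_hotspots import classify_hotspot_overlap
from .motif_association import bh_qvalues
from .motif_scan import PWM, scan_sequence
from .sortseq_io import PROMOTER_THRESHOLD

OVERLAP_CATEGORIES = ("minus10_only", "minus35_only", "both", "neither")


@dataclass
class ParentSummary:
    parent_id: str
    channel: str
    F_parent: float
    P_new: float
    n_daughters: int
    gc_content: float
    n_minus10: int
    n_minus35: int


@dataclass
class SigmoidFit:
    L: float
    x0: float
    k: float
    covariance: np.ndarray
    pvalues: dict[str, float]
    degenerate: bool

    def predict(self, x):
        return sigmoid(np.asarray(x, dtype=float), self.L, self.x0, self.k)


def sigmoid(x, L, x0, k):
    """Canonical increasing logistic: L / (1 + exp(-k (x - x0)))."""
    return L / (1.0 + np.exp(-k * (x - x0)))


def compute_pnew(F: Sequence[float], threshold: float = PROMOTER_THRESHOLD) -> float:
    """Fraction of daughters whose fluorescence reaches the promoter threshold."""
    F = np.asarray(F, dtype=float)
    F = F[np.isfinite(F)]
    if F.size == 0:
        raise ValueError("no daughters with a finite fluorescence score")
    return float((F >= threshold).mean())


def fit_sigmoid(
    x: Sequence[float],
    y: Sequence[float],
    p0: tuple[float, float, float] | None = None,
    maxfev: int = 20000,
) -> SigmoidFit:
    """Nonlinear least-squares sigmoid fit of P_new against parent fluorescence.

    Initialization defaults to (max(y), 1.5 a.u., 10); L is bounded in
    (0, 1]. Per-parameter Wald p-values come from the asymptotic covariance.
    A fit collapsing to L ~ 0 (all-zero response) is flagged degenerate.

    Raises RuntimeError with the initial values on non-convergence.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points to fit a 3-parameter sigmoid")
    if p0 is None:
        p0 = (max(float(y.max()), 1e-3), 1.5, 10.0)
    try:
        popt, pcov = optimize.curve_fit(
            sigmoid, x, y, p0=p0,
            bounds=([1e-9, -np.inf, -np.inf], [1.0, np.inf, np.inf]),
            maxfev=maxfev,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"sigmoid fit did not converge (p0={p0}): {exc}") from exc
    se = np.sqrt(np.diag(pcov))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, popt / se, np.inf)
    pvals = dict(zip(("L", "x0", "k"), 2.0 * stats.norm.sf(np.abs(z))))
    return SigmoidFit(
        L=float(popt[0]),
        x0=float(popt[1]),
        k=float(popt[2]),
        covariance=pcov,
        pvalues=pvals,
        degenerate=bool(popt[0] < 1e-6 or np.allclose(y, 0.0)),
    )


def feature_regression(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """OLS of P_new on a per-parent feature: (slope, Wald p for slope=0, r^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.allclose(x, x[0]):
        raise ValueError("zero-variance feature")
    if np.allclose(y, y[0]):
        # degenerate response: flat fit, no explanatory power
        return 0.0, 1.0, 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.pvalue), float(res.rvalue**2)


# ---------------------------------------------------------------------------
# k-mer analysis

def enumerate_kmers(kmin: int = 1, kmax: int = 6) -> list[str]:
    """All ACGT k-mers for k in [kmin, kmax]; 5460 of them for 1..6."""
    return [
        "".join(t)
        for k in range(kmin, kmax + 1)
        for t in itertools.product("ACGT", repeat=k)
    ]


def count_kmers(seq: str, kmin: int = 1, kmax: int = 6) -> Counter:
    """Overlapping occurrence counts of every k-mer present in *seq*."""
    counts: Counter = Counter()
    for k in range(kmin, kmax + 1):
        for i in range(len(seq) - k + 1):
            counts[seq[i : i + k]] += 1
    return counts


def kmer_analysis(
    parent_seqs: Mapping[str, str],
    pnew: Mapping[str, float],
    kmin: int = 1,
    kmax: int = 6,
    min_count: int = 3,
    fdr: float = 0.05,
) -> tuple[pd.DataFrame, list[str], dict[str, list[str]]]:
    """Regress per-parent k-mer occurrence counts against P_new.

    *parent_seqs* maps parent id to the analyzed-strand sequence (top for
    GFP, reverse complement for RFP); counts are overlapping. Only k-mers
    occurring at least *min_count* times in at least one parent enter the
    regression; q-values are BH at the given FDR. Returns the full result
    table, the significant k-mer list, and a leave-one-out report mapping
    each parent to the k-mers still significant with that parent removed.
    """
    ids = list(parent_seqs)
    if len(ids) < 3:
        raise ValueError("need >= 3 parents")
    per_parent = {pid: count_kmers(parent_seqs[pid], kmin, kmax) for pid in ids}
    candidates = sorted(
        {km for c in per_parent.values() for km, n in c.items() if n >= min_count},
        key=lambda s: (len(s), s),
    )
    y = np.array([pnew[pid] for pid in ids], dtype=float)

    def regress(subset_ids, yy):
        rows = []
        for km in candidates:
            xx = np.array([per_parent[pid][km] for pid in subset_ids], dtype=float)
            if np.allclose(xx, xx[0]):
                rows.append((km, np.nan, 1.0, 0.0, int(xx.max())))
                continue
            slope, p, r2 = feature_regression(xx, yy)
            rows.append((km, slope, p, r2, int(xx.max())))
        df = pd.DataFrame(rows, columns=["kmer", "slope", "p", "r2", "max_count"])
        df["q"] = bh_qvalues(df["p"].to_numpy())
        return df

    table = regress(ids, y)
    significant = table.loc[table["q"] <= fdr, "kmer"].tolist()
    loo = {}
    for drop in ids:
        keep = [pid for pid in ids if pid != drop]
        sub = regress(keep, np.array([pnew[pid] for pid in keep], dtype=float))
        loo[drop] = sub.loc[sub["q"] <= fdr, "kmer"].tolist()
    return table, significant, loo


# ---------------------------------------------------------------------------
# scrambling nulls

def scramble_whole_parent(seq: str, seed) -> str:
    """Uniform random permutation of the sequence; composition preserved."""
    rng = np.random.default_rng(seed)
    chars = np.array(list(seq))
    return "".join(chars[rng.permutation(len(chars))])


def scramble_motif_region(
    seq: str,
    start: int,
    width: int,
    pwms_to_avoid: Sequence[PWM],
    seed,
    max_tries: int = 1000,
) -> str:
    """Shuffle only [start, start+width), avoiding creation of new motifs.

    The accepted permutation must not introduce any above-threshold hit of
    an avoided PWM overlapping the shuffled region that was not already
    present in the original sequence. Raises RuntimeError when *max_tries*
    permutations all fail.
    """
    if start < 0 or start + width > len(seq):
        raise ValueError("region outside sequence")
    rng = np.random.default_rng(seed)

    def offending(candidate: str) -> bool:
        for pwm in pwms_to_avoid:
            lo = max(0, start - pwm.width + 1)
            hi = min(len(seq) - pwm.width, start + width - 1)
            if hi < lo:
                continue
            orig = {h.start for h in scan_sequence(pwm, seq)}
            for h in scan_sequence(pwm, candidate):
                if lo <= h.start <= hi and h.start not in orig:
                    return True
        return False

    region = np.array(list(seq[start : start + width]))
    for _ in range(max_tries):
        shuffled = "".join(region[rng.permutation(width)])
        candidate = seq[:start] + shuffled + seq[start + width :]
        if not offending(candidate):
            return candidate
    raise RuntimeError(f"no acceptable shuffle of region [{start},{start + width}) in {max_tries} tries")


def overlap_null_counts(
    parents: Sequence[tuple[str, Sequence[int]]],
    pwm10: PWM,
    pwm35: PWM,
    seed,
    n_reps: int = 1,
    proximity: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed vs scrambled hotspot/motif overlap category counts.

    *parents* is a sequence of (sequence, hotspot peak positions). Each
    parent is scanned for −10/−35 boxes and every hotspot classified; the
    scrambled condition permutes each parent's sequence (hotspot
    coordinates held fixed) and reclassifies. Returns two length-4 vectors
    in OVERLAP_CATEGORIES order; with n_reps > 1 the scrambled counts are
    per-replicate averages.
    """
    rng = np.random.default_rng(seed)
    observed = np.zeros(4)
    scrambled = np.zeros(4)
    for seq, peaks in parents:
        h10 = scan_sequence(pwm10, seq)
        h35 = scan_sequence(pwm35, seq)
        for pk in peaks:
            cat = classify_hotspot_overlap(pk, h10, h35, window=proximity)
            observed[OVERLAP_CATEGORIES.index(cat)] += 1
        for _ in range(n_reps):
            sseq = scramble_whole_parent(seq, rng)
            s10 = scan_sequence(pwm10, sseq)
            s35 = scan_sequence(pwm35, sseq)
            for pk in peaks:
                cat = classify_hotspot_overlap(pk, s10, s35, window=proximity)
                scrambled[OVERLAP_CATEGORIES.index(cat)] += 1
    return observed, scrambled / n_reps


def chisq_goodness_of_fit(
    observed: Sequence[float], expected: Sequence[float]
) -> tuple[float, float, int]:
    """chi2 = sum (O-E)^2 / E with df = len - 1 (3 for the four overlap classes)."""
    O = np.asarray(observed, dtype=float)
    E = np.asarray(expected, dtype=float)
    if O.shape != E.shape:
        raise ValueError("observed/expected length mismatch")
    if (E <= 0).any():
        raise ValueError("expected counts must all be positive")
    chi2 = float(((O - E) ** 2 / E).sum())
    df = O.size - 1
    return chi2, float(stats.chi2.sf(chi2, df)), df


def hns_candidate_outliers(deltas: Mapping[str, float] | pd.Series) -> list[str]:
    """Parents whose knockout-vs-wild-type fluorescence change is a Tukey outlier.

    Values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR] (quartiles by linear
    interpolation) are flagged, two-sided. Apply separately per channel.
    """
    s = pd.Series(deltas, dtype=float)
    if s.size < 4:
        raise ValueError("need >= 4 values")
    q1, q3 = np.percentile(s.to_numpy(), [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return s.index[(s < lo) | (s > hi)].tolist()


def parent_summaries(
    parent_rows: Sequence[tuple[str, str, str, float, Sequence[float]]],
    pwm10: PWM,
    pwm35: PWM,
    threshold: float = PROMOTER_THRESHOLD,
) -> list[ParentSummary]:
    """Build ParentSummary records.

    *parent_rows* holds (parent_id, channel, analyzed-strand sequence,
    parent F, daughter F values).
    """
    out = []
    for pid, channel, seq, F_parent, F_daughters in parent_rows:
        F_daughters = np.asarray(F_daughters, dtype=float)
        out.append(
            ParentSummary(
                parent_id=pid,
                channel=channel,
                F_parent=float(F_parent),
                P_new=compute_pnew(F_daughters, threshold),
                n_daughters=int(np.isfinite(F_daughters).sum()),
                gc_content=(seq.count("G") + seq.count("C")) / len(seq),
                n_minus10=len(scan_sequence(pwm10, seq)),
                n_minus35=len(scan_sequence(pwm35, seq)),
            )
        )
    return out
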