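"""Sort-seq read/table ingestion, filtering, and fluorescence scoring.

The experiment sorts a mutant reporter library into four fluorescence bins
per channel (GFP on the top strand, RFP on the bottom strand) and sequences
each bin. A variant's fluorescence score is the read-weighted mean bin
index,

    F = sum_f f * Reads_f / sum_f Reads_f,   f in {1,2,3,4},

in arbitrary units from 1.0 (no expression) to 4.0 (strong expression). A
sequence with F >= 1.5 a.u. is called a promoter.

This module accepts either merged oriented reads carrying bin barcodes or a
pre-tabulated daughter table (CSV with per-bin read counts), maps each
daughter to its closest parent by Hamming distance, applies the library
quality filters, and attaches per-channel fluorescence scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dna import encode, encode_many, revcomp

ECORI = "GAATTC"  # 5' cut site; the bin barcode sits immediately upstream
BAMHI = "GGATCC"  # 3' cut site

GFP_BINS = ["gfp_bin1", "gfp_bin2", "gfp_bin3", "gfp_bin4"]
RFP_BINS = ["rfp_bin1", "rfp_bin2", "rfp_bin3", "rfp_bin4"]
COUNT_COLUMNS = GFP_BINS + RFP_BINS + ["unsorted_reads"]

PROMOTER_THRESHOLD = 1.5  # a.u.


class ReadRejected(Exception):
    """A read failed orientation/demultiplexing; ``.reason`` says why."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class ParentSequence:
    """A 150 bp template strand view.

    Each template contributes two parents: the top strand read by the GFP
    channel and the bottom strand (reverse complement) read by RFP.
    """

    parent_id: str
    sequence: str

    @property
    def bottom_strand(self) -> str:
        return revcomp(self.sequence)


def read_parents_fasta(path) -> list[ParentSequence]:
    from Bio import SeqIO

    return [
        ParentSequence(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_parents_fasta(parents: Iterable[ParentSequence], path) -> None:
    with open(path, "w") as fh:
        for p in parents:
            fh.write(f">{p.parent_id}\n{p.sequence}\n")


# ---------------------------------------------------------------------------
# read orientation and demultiplexing

def orient_and_demux(read: str, barcode_table: Mapping[str, str]) -> tuple[str, str]:
    """Orient a merged read, identify its bin barcode, and strip the scaffold.

    The read must contain both the EcoRI and BamHI cut sites; if BamHI
    precedes EcoRI the reverse complement is taken first. The exact barcode
    immediately 5' of the EcoRI site selects the bin. Returns
    ``(insert, bin_label)`` where the insert is the sequence strictly
    between the two sites.

    Raises
    ------
    ReadRejected
        If either cut site is missing or no barcode matches.
    """
    read = read.upper()
    if ECORI not in read or BAMHI not in read:
        rc = revcomp(read)
        if ECORI in rc and BAMHI in rc:
            read = rc
        else:
            missing = [s for n, s in (("EcoRI", ECORI), ("BamHI", BAMHI)) if s not in read and s not in rc]
            raise ReadRejected(f"missing cut site(s): {','.join(missing) or 'orientation'}")
    eco = read.find(ECORI)
    bam = read.find(BAMHI)
    if bam < eco:
        read = revcomp(read)
        eco = read.find(ECORI)
        bam = read.find(BAMHI)
        if bam < eco:
            raise ReadRejected("cut sites could not be consistently oriented")
    for label, barcode in barcode_table.items():
        if eco >= len(barcode) and read[eco - len(barcode) : eco] == barcode:
            return read[eco + len(ECORI) : bam], label
    raise ReadRejected("unknown barcode upstream of EcoRI site")


def read_barcode_table(path) -> dict[str, str]:
    """TSV with columns (bin_label, barcode)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["bin", "barcode"], dtype=str)
    return dict(zip(df["bin"], df["barcode"].str.upper()))


def tabulate_reads(
    reads: Iterable[str], barcode_table: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count oriented reads per (insert, bin) into a daughter table.

    Bin labels must be the table column names (``gfp_bin1`` ...
    ``unsorted_reads``). Returns (table, rejection log).
    """
    counts: dict[str, dict[str, int]] = {}
    rejects = []
    for i, read in enumerate(reads):
        try:
            insert, label = orient_and_demux(read, barcode_table)
        except ReadRejected as exc:
            rejects.append({"read_index": i, "reason": exc.reason})
            continue
        row = counts.setdefault(insert, {c: 0 for c in COUNT_COLUMNS})
        row[label] += 1
    table = pd.DataFrame(
        [{"sequence": seq, **row} for seq, row in counts.items()],
        columns=["sequence", *COUNT_COLUMNS],
    )
    return table, pd.DataFrame(rejects, columns=["read_index", "reason"])


def read_fastx(path) -> list[str]:
    """Sequences from a FASTA or FASTQ file of merged reads."""
    from Bio import SeqIO

    path = str(path)
    fmt = "fastq" if path.endswith(("fastq", "fq")) else "fasta"
    return [str(rec.seq).upper() for rec in SeqIO.parse(path, fmt)]


# ---------------------------------------------------------------------------
# fluorescence scores

def fluorescence_score(reads: Sequence[float]) -> float:
    """Read-weighted mean bin index over bins 1..4; NaN for all-zero counts."""
    reads = np.asarray(reads, dtype=float)
    if reads.shape[-1] != 4:
        raise ValueError("expected counts for exactly 4 bins")
    total = reads.sum()
    if total == 0:
        return float("nan")
    return float((reads * np.arange(1, 5)).sum() / total)


def fluorescence_scores(table: pd.DataFrame, channel: str) -> pd.Series:
    """Vectorized per-row F for one channel; NaN where the channel has no reads."""
    cols = GFP_BINS if channel == "gfp" else RFP_BINS
    counts = table[cols].to_numpy(dtype=float)
    total = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (counts * np.arange(1, 5)).sum(axis=1) / total
    return pd.Series(np.where(total > 0, f, np.nan), index=table.index)


def classify_promoter(F: float, threshold: float = PROMOTER_THRESHOLD, inclusive: bool = True) -> bool:
    """Promoter call at the 1.5 a.u. boundary (>= by default; configurable)."""
    return bool(F >= threshold) if inclusive else bool(F > threshold)


# ---------------------------------------------------------------------------
# parent mapping

def map_to_parent(
    seq: str, parents: Sequence[ParentSequence]
) -> tuple[str, int, bool]:
    """Assign *seq* to the minimum-Hamming-distance parent.

    Ties break by parent input order and are flagged. Returns
    ``(parent_id, hamming, ambiguous)``.
    """
    if not parents:
        raise ValueError("no parents supplied")
    enc_parents = encode_many([p.sequence for p in parents])
    if enc_parents.shape[1] != len(seq):
        raise ValueError("daughter/parent length mismatch")
    dists = (enc_parents != encode(seq)).sum(axis=1)
    best = int(dists.argmin())
    ambiguous = bool((dists == dists[best]).sum() > 1)
    return parents[best].parent_id, int(dists[best]), ambiguous


def assign_parents(table: pd.DataFrame, parents: Sequence[ParentSequence]) -> pd.DataFrame:
    """Add parent_id / hamming / ambiguous columns by minimum Hamming distance."""
    enc_parents = encode_many([p.sequence for p in parents])
    ids = np.array([p.parent_id for p in parents])
    out = table.copy()
    lengths = table["sequence"].str.len()
    parent_id = np.full(len(table), "", dtype=object)
    hamming = np.full(len(table), -1, dtype=int)
    ambiguous = np.zeros(len(table), dtype=bool)
    ok = lengths == enc_parents.shape[1]
    if ok.any():
        enc = encode_many(table.loc[ok, "sequence"].tolist())
        # (N, P) distance matrix; libraries here are small enough to hold it
        dists = (enc[:, None, :] != enc_parents[None, :, :]).sum(axis=2)
        best = dists.argmin(axis=1)
        ham = dists[np.arange(len(best)), best]
        parent_id[np.where(ok)[0]] = ids[best]
        hamming[np.where(ok)[0]] = ham
        ambiguous[np.where(ok)[0]] = (dists == ham[:, None]).sum(axis=1) > 1
    out["parent_id"] = parent_id
    out["hamming"] = hamming
    out["ambiguous"] = ambiguous
    return out


# ---------------------------------------------------------------------------
# filtering

def filter_daughters(
    table: pd.DataFrame,
    length: int = 150,
    min_unsorted: int = 1,
    min_total_reads: int = 30,
    max_hamming: int = 10,
    min_daughters_per_parent: int = 2000,
    count_unsorted_in_total: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the library quality filters; returns (survivors, rejection log).

    Retains records with the wild-type length, at least one read in the
    unsorted library, >= *min_total_reads* reads in the entire dataset
    (all eight bins plus the unsorted library by default), and Hamming
    distance <= *max_hamming*; then drops every parent — and all its
    daughters — with fewer than *min_daughters_per_parent* surviving unique
    daughters. One reason is logged per dropped record (the first failing
    rule, in the order above). Idempotent.
    """
    df = table
    total_cols = COUNT_COLUMNS if count_unsorted_in_total else GFP_BINS + RFP_BINS
    reasons = pd.Series("", index=df.index, dtype=object)
    bad_len = df["sequence"].str.len() != length
    reasons[bad_len] = "length"
    bad_unsorted = (df["unsorted_reads"] < min_unsorted) & (reasons == "")
    reasons[bad_unsorted] = "unsorted"
    bad_total = (df[total_cols].sum(axis=1) < min_total_reads) & (reasons == "")
    reasons[bad_total] = "min-reads"
    bad_ham = (df["hamming"] > max_hamming) & (reasons == "")
    reasons[bad_ham] = "distance"
    surviving = df[reasons == ""]
    per_parent = surviving.groupby("parent_id")["sequence"].nunique()
    small = set(per_parent.index[per_parent < min_daughters_per_parent])
    bad_parent = surviving["parent_id"].isin(small)
    reasons[bad_parent.index[bad_parent]] = "parent-too-small"
    kept = df[reasons == ""].reset_index(drop=True)
    log = pd.DataFrame(
        {"sequence": df.loc[reasons != "", "sequence"], "reason": reasons[reasons != ""]}
    ).reset_index(drop=True)
    return kept, log


def score_table(
    table: pd.DataFrame, parents: Sequence[ParentSequence] | None = None, **filter_kwargs
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full table pipeline: map to parents, filter, attach F_gfp / F_rfp."""
    df = table
    if parents is not None:
        df = assign_parents(df, parents)
    if "hamming" not in df.columns:
        raise ValueError("table lacks parent assignments; supply parents")
    df, log = filter_daughters(df, **filter_kwargs)
    df = df.copy()
    df["F_gfp"] = fluorescence_scores(df, "gfp")
    df["F_rfp"] = fluorescence_scores(df, "rfp")
    return df, log


def read_daughter_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ["sequence", *COUNT_COLUMNS] if c not in df.columns]
    if missing:
        raise ValueError(f"daughter table missing columns: {missing}")
    return df


def write_daughter_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
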