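"""Position-weight-matrix construction and promoter motif scanning.

PWMs are log2-odds matrices over {A,C,G,T} against a uniform 25% background.
A window is called a motif hit when its summed log-odds score reaches the
matrix threshold, which defaults to the total information content of the
matrix — the convention under which the sigma70 −10 and −35 box matrices
used in this field have thresholds of 3.98 and 3.39 bits. "Low-affinity"
boxes use half those thresholds.

Coordinates are 0-based, half-open, on the analyzed strand. The bottom
strand is scanned on the reverse complement; ``map_to_top`` converts a
bottom-frame start back to top-strand coordinates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .dna import BASE_INDEX, encode, encode_many, revcomp, validate

# Published threshold conventions for the matrices this pipeline is built
# around (bits). The strict thresholds equal each matrix's information
# content; the low-affinity thresholds are exactly half of them. The
# UP-element matrix uses a fixed published threshold and a relaxed one at a
# quarter of it.
MINUS10_THRESHOLD = 3.98
MINUS35_THRESHOLD = 3.39
MINUS10_LOW_AFFINITY = 1.99
MINUS35_LOW_AFFINITY = 1.70
UP_ELEMENT_THRESHOLD = 19.2
UP_ELEMENT_RELAXED = 4.8

#: IUPAC degeneracy codes used when a matrix is only available as a consensus.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

#: AT-rich UP-element consensus (22 bp), upstream of the −35 box.
UP_ELEMENT_CONSENSUS = "NNAAAWWTWTTTTNNWAAASYM"


@dataclass(frozen=True)
class PWM:
    """A log2-odds position weight matrix against a uniform background.

    Attributes
    ----------
    name : str
        Motif class label (e.g. ``minus10``).
    width : int
        Number of positions.
    log_odds : np.ndarray
        Shape ``(width, 4)``, columns ordered A, C, G, T, in bits. With
        pseudocount 0 an unobserved base scores ``-inf``.
    counts : np.ndarray
        The raw instance counts the matrix was built from (width, 4).
    pseudocount : float
        Additive count applied per base when converting counts to
        frequencies.
    threshold : float
        Default bit-score call threshold (the information content unless
        overridden).
    info_content : float
        Total information content in bits under the uniform background.
    """

    name: str
    width: int
    log_odds: np.ndarray
    counts: np.ndarray
    pseudocount: float
    threshold: float
    info_content: float

    def score(self, window: str) -> float:
        return score_window(self, window)

    def score_positions(self, encoded: np.ndarray) -> np.ndarray:
        """Score every window of encoded sequence(s).

        Parameters
        ----------
        encoded : np.ndarray
            Either a 1-D encoded sequence of length L or an (N, L) array.

        Returns
        -------
        np.ndarray of window scores, shape ``(..., L - width + 1)``.
        """
        if encoded.shape[-1] < self.width:
            raise ValueError("sequence shorter than PWM width")
        win = sliding_window_view(encoded, self.width, axis=-1)
        return self.log_odds[np.arange(self.width), win].sum(axis=-1)

    def with_threshold(self, threshold: float) -> "PWM":
        return replace(self, threshold=threshold)


@dataclass(frozen=True)
class MotifHit:
    """An above-threshold PWM match on one analyzed strand.

    ``start`` is 0-based on the analyzed strand; the occupied interval is
    half-open ``[start, start + width)``.
    """

    parent_id: str
    strand: str  # "top" | "bottom"
    start: int
    width: int
    score: float
    motif_class: str
    tgn_extended: bool = False

    @property
    def end(self) -> int:
        return self.start + self.width

    def overlaps(self, other: "MotifHit") -> bool:
        """Nonempty intersection of the two half-open intervals."""
        return self.start < other.end and other.start < self.end


def load_instances(path) -> list[str]:
    """Read aligned motif instances from FASTA or one-sequence-per-line text."""
    text = Path(path).read_text()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if any(ln.startswith(">") for ln in lines):
        from Bio import SeqIO

        return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
    return [ln.upper() for ln in lines]


def build_pwm(instances: Sequence[str], pseudocount: float = 0.0, name: str = "motif") -> PWM:
    """Build a PWM from equal-length aligned instances.

    Frequencies are ``(count + pseudocount) / (n + 4*pseudocount)``;
    log-odds are taken against the uniform 25% background. The default
    threshold equals the total information content.
    """
    if not instances:
        raise ValueError("empty instance list")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    width = len(instances[0])
    if width < 1:
        raise ValueError("instances must have width >= 1")
    for inst in instances:
        if len(inst) != width:
            raise ValueError(f"ragged instance lengths: {len(inst)} != {width}")
        validate(inst)
    enc = encode_many(instances)
    counts = np.zeros((width, 4), dtype=float)
    for j in range(width):
        counts[j] = np.bincount(enc[:, j], minlength=4)
    return _pwm_from_counts(counts, pseudocount, name)


def _pwm_from_counts(counts: np.ndarray, pseudocount: float, name: str) -> PWM:
    n = counts.sum(axis=1, keepdims=True)
    freqs = (counts + pseudocount) / (n + 4.0 * pseudocount)
    with np.errstate(divide="ignore"):
        log_odds = np.log2(freqs / 0.25)
    plogp = np.where(freqs > 0, freqs * np.log2(np.where(freqs > 0, freqs, 1.0)), 0.0)
    info = float((2.0 + plogp.sum(axis=1)).sum())
    return PWM(
        name=name,
        width=counts.shape[0],
        log_odds=log_odds,
        counts=counts,
        pseudocount=float(pseudocount),
        threshold=info,
        info_content=info,
    )


def pwm_from_consensus(
    consensus: str, name: str = "motif", threshold: float | None = None
) -> PWM:
    """Build a PWM from an IUPAC consensus string.

    Degenerate letters expand to equal frequencies over their allowed
    bases. Used when a matrix is published only as a consensus (the
    UP element); pass the published ``threshold`` where one exists.
    """
    consensus = consensus.upper()
    counts = np.zeros((len(consensus), 4), dtype=float)
    for j, letter in enumerate(consensus):
        if letter not in IUPAC:
            raise ValueError(f"unknown IUPAC code {letter!r} at position {j}")
        allowed = IUPAC[letter]
        for b in allowed:
            counts[j, BASE_INDEX[b]] = 1.0 / len(allowed)
    pwm = _pwm_from_counts(counts, 0.0, name)
    if threshold is not None:
        pwm = pwm.with_threshold(threshold)
    return pwm


def up_element_pwm(relaxed: bool = False) -> PWM:
    """The UP-element consensus matrix at its published (or relaxed) threshold."""
    thr = UP_ELEMENT_RELAXED if relaxed else UP_ELEMENT_THRESHOLD
    return pwm_from_consensus(UP_ELEMENT_CONSENSUS, name="UP", threshold=thr)


def score_window(pwm: PWM, window: str) -> float:
    """Bit score of a single window of length ``pwm.width``; ``-inf`` allowed."""
    if len(window) != pwm.width:
        raise ValueError(f"window length {len(window)} != PWM width {pwm.width}")
    enc = encode(window)
    return float(pwm.log_odds[np.arange(pwm.width), enc].sum())


def scan_sequence(
    pwm: PWM,
    seq: str,
    threshold: float | None = None,
    parent_id: str = "",
    strand: str = "top",
) -> list[MotifHit]:
    """Return hits at every start whose window score reaches *threshold*.

    Scans the given strand only; scan the reverse complement separately for
    bottom-strand hits. Hits are sorted by start. ``threshold=None`` uses the
    matrix default; ``threshold=-inf`` returns every window.
    """
    if len(seq) < pwm.width:
        raise ValueError("sequence shorter than PWM width")
    thr = pwm.threshold if threshold is None else threshold
    scores = pwm.score_positions(encode(seq))
    hits = []
    for start in np.nonzero(scores >= thr)[0]:
        hit = MotifHit(
            parent_id=parent_id,
            strand=strand,
            start=int(start),
            width=pwm.width,
            score=float(scores[start]),
            motif_class=pwm.name,
        )
        if pwm.name == "minus10":
            hit = replace(hit, tgn_extended=annotate_tgn(seq, hit))
        hits.append(hit)
    return hits


def scan_both_strands(
    pwm: PWM, seq: str, threshold: float | None = None, parent_id: str = ""
) -> dict[str, list[MotifHit]]:
    """Scan the top strand and the reverse complement (bottom frame)."""
    return {
        "top": scan_sequence(pwm, seq, threshold, parent_id, "top"),
        "bottom": scan_sequence(pwm, revcomp(seq), threshold, parent_id, "bottom"),
    }


def map_to_top(start: int, width: int, seq_length: int) -> int:
    """Convert a bottom-frame start to the equivalent top-strand start."""
    return seq_length - width - start


def annotate_tgn(seq: str, hit: MotifHit) -> bool:
    """True iff a TG dinucleotide sits at offsets −3..−2 from a −10 hexamer.

    The extended −10 motif is TG, one spacer base, then the hexamer
    (TGnTATAAT). A hit too close to the sequence start is simply False.
    """
    if hit.motif_class != "minus10":
        raise ValueError("TGn annotation applies to minus10 hits only")
    if hit.start < 3:
        return False
    return seq[hit.start - 3 : hit.start - 1] == "TG"


def pair_boxes(
    hits35: Iterable[MotifHit],
    hits10: Iterable[MotifHit],
    spacer_min: int = 15,
    spacer_max: int = 20,
) -> list[tuple[MotifHit, MotifHit]]:
    """All (−35, −10) pairs whose spacer lies in [spacer_min, spacer_max].

    The spacer is the gap between the end of the −35 hexamer and the start
    of the −10 hexamer: ``minus10.start − (minus35.start + 6)``. The
    canonical sigma70 promoter has a 17±1 bp spacer.
    """
    pairs = []
    for h35 in hits35:
        for h10 in hits10:
            spacer = h10.start - (h35.start + 6)
            if spacer_min <= spacer <= spacer_max:
                pairs.append((h35, h10))
    return pairs


# ---------------------------------------------------------------------------
# serialization

def pwm_to_json(pwm: PWM, path=None) -> str:
    payload = {
        "name": pwm.name,
        "width": pwm.width,
        "counts": pwm.counts.tolist(),
        "pseudocount": pwm.pseudocount,
        "threshold": pwm.threshold,
    }
    text = json.dumps(payload, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def pwm_from_json(source) -> PWM:
    """Load a PWM from a JSON string or file path."""
    if isinstance(source, (str, bytes)) and not str(source).lstrip().startswith("{"):
        source = Path(source).read_text()
    elif isinstance(source, Path):
        source = source.read_text()
    payload = json.loads(source)
    pwm = _pwm_from_counts(
        np.asarray(payload["counts"], dtype=float), payload["pseudocount"], payload["name"]
    )
    thr = payload.get("threshold")
    if thr is not None and not math.isclose(thr, pwm.threshold):
        pwm = pwm.with_threshold(thr)
    return pwm


def hits_to_bed(hits: Iterable[MotifHit], path=None) -> str:
    """BED-like TSV: parent_id, start, end, motif_class, score, strand (+/−)."""
    lines = []
    for h in hits:
        strand = "+" if h.strand == "top" else "-"
        lines.append(
            f"{h.parent_id}\t{h.start}\t{h.end}\t{h.motif_class}\t{h.score:.4f}\t{strand}"
        )
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        Path(path).write_text(text)
    return text
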